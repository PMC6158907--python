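"""Escher pathway-map handling: parsing, model consistency checks, flux
overlay export, and a basic static SVG rendering.

Escher maps (schema 1) are JSON documents of the form ``[header, body]``:
the header carries the map name and schema identifier, the body the drawable
graph — nodes (metabolite circles plus marker nodes along reaction arrows)
and reactions (polyline/Bezier segments between nodes), all keyed by BiGG
identifiers so flux values computed on a model can be joined onto the map.

The SVG renderer is deliberately minimal: one path per segment with stroke
width scaled linearly in |flux|.  It produces deterministic, valid SVG 1.1
for figures and diffing, not a re-implementation of the interactive viewer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping
from xml.etree import ElementTree

from .lp_core import FluxSolution, OPTIMAL

__all__ = [
    "MapNode",
    "MapSegment",
    "MapReaction",
    "EscherMap",
    "FluxOverlay",
    "MapFormatError",
    "MapValidationError",
    "parse_escher_map",
    "check_map_model",
    "export_flux_overlay",
    "parse_flux_overlay",
    "render_svg",
]

NODE_TYPES = frozenset({"metabolite", "midmarker", "multimarker"})


class MapFormatError(ValueError):
    """Document does not have the Escher schema-1 [header, body] shape."""


class MapValidationError(ValueError):
    """Map parses but contains dangling references."""


@dataclass(frozen=True)
class MapNode:
    id: str
    node_type: str
    x: float
    y: float
    bigg_id: str | None = None


@dataclass(frozen=True)
class MapSegment:
    id: str
    from_node: str
    to_node: str
    b1: tuple[float, float] | None = None
    b2: tuple[float, float] | None = None


@dataclass(frozen=True)
class MapReaction:
    id: str
    bigg_id: str
    label_x: float
    label_y: float
    segments: tuple[MapSegment, ...]


@dataclass(frozen=True)
class EscherMap:
    """Drawable pathway graph keyed by BiGG reaction identifiers."""

    map_name: str
    schema: str
    canvas: Mapping[str, float]
    nodes: Mapping[str, MapNode]
    reactions: Mapping[str, MapReaction]

    @property
    def reaction_bigg_ids(self) -> tuple[str, ...]:
        return tuple(r.bigg_id for r in self.reactions.values())


@dataclass(frozen=True)
class FluxOverlay:
    """Reaction-id -> flux mapping ready for visualization as reaction data."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for rid, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite overlay value for {rid!r}: {v}")


def _point(obj: Any) -> tuple[float, float] | None:
    if not isinstance(obj, Mapping):
        return None
    try:
        return (float(obj["x"]), float(obj["y"]))
    except (KeyError, TypeError, ValueError):
        return None


def parse_escher_map(document: str | bytes | list) -> EscherMap:
    """Parse an Escher map (schema 1) from JSON text or a decoded list.

    Unknown header fields are tolerated and ignored (schema URLs drift
    between Escher releases); the body must carry ``nodes`` and
    ``reactions``, and every segment endpoint must name a declared node.
    """
    if isinstance(document, (str, bytes)):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise MapFormatError(f"document is not valid JSON: {exc}") from exc
    if not isinstance(document, list) or len(document) != 2:
        raise MapFormatError(
            "Escher map must be a two-element JSON array [header, body]"
        )
    header, body = document
    if not isinstance(header, Mapping) or not isinstance(body, Mapping):
        raise MapFormatError("Escher map header and body must both be JSON objects")
    for key in ("nodes", "reactions"):
        if key not in body:
            raise MapFormatError(f"map body missing required key {key!r}")

    nodes: dict[str, MapNode] = {}
    for node_id, entry in body["nodes"].items():
        node_type = entry.get("node_type", "")
        if node_type not in NODE_TYPES:
            raise MapValidationError(
                f"node {node_id!r} has unknown node_type {node_type!r}"
            )
        bigg_id = entry.get("bigg_id")
        if node_type == "metabolite" and not bigg_id:
            raise MapValidationError(f"metabolite node {node_id!r} lacks a bigg_id")
        nodes[str(node_id)] = MapNode(
            id=str(node_id),
            node_type=node_type,
            x=float(entry.get("x", 0.0)),
            y=float(entry.get("y", 0.0)),
            bigg_id=bigg_id,
        )

    reactions: dict[str, MapReaction] = {}
    for rxn_id, entry in body["reactions"].items():
        bigg_id = entry.get("bigg_id")
        if not bigg_id:
            raise MapValidationError(f"map reaction {rxn_id!r} lacks a bigg_id")
        segments = []
        for seg_id, seg in entry.get("segments", {}).items():
            from_node = str(seg.get("from_node_id"))
            to_node = str(seg.get("to_node_id"))
            for endpoint in (from_node, to_node):
                if endpoint not in nodes:
                    raise MapValidationError(
                        f"segment {seg_id!r} of reaction {rxn_id!r} references "
                        f"undeclared node {endpoint!r}"
                    )
            segments.append(
                MapSegment(
                    id=str(seg_id),
                    from_node=from_node,
                    to_node=to_node,
                    b1=_point(seg.get("b1")),
                    b2=_point(seg.get("b2")),
                )
            )
        reactions[str(rxn_id)] = MapReaction(
            id=str(rxn_id),
            bigg_id=str(bigg_id),
            label_x=float(entry.get("label_x", 0.0)),
            label_y=float(entry.get("label_y", 0.0)),
            segments=tuple(segments),
        )

    return EscherMap(
        map_name=str(header.get("map_name", "")),
        schema=str(header.get("schema", "")),
        canvas=dict(body.get("canvas", {})),
        nodes=nodes,
        reactions=reactions,
    )


@dataclass(frozen=True)
class MapModelDiagnostic:
    """One map/model mismatch; ``severity`` 'error' for map reactions the
    model lacks, 'info' for model reactions absent from the map (normal for
    maps that show only a sub-network)."""

    severity: str
    bigg_id: str
    message: str


def check_map_model(escher_map: EscherMap, model) -> list[MapModelDiagnostic]:
    """Cross-check a map against a model.

    A map is *compatible* with a model when every reaction drawn on the map
    exists in the model (no 'error'-severity diagnostics); the reverse
    direction is reported informationally only.
    """
    model_ids = set(model.reaction_ids)
    map_ids = set(escher_map.reaction_bigg_ids)
    diagnostics = [
        MapModelDiagnostic(
            "error", bigg_id, f"map reaction {bigg_id!r} is absent from the model"
        )
        for bigg_id in sorted(map_ids - model_ids)
    ]
    diagnostics.extend(
        MapModelDiagnostic(
            "info", bigg_id, f"model reaction {bigg_id!r} is not drawn on the map"
        )
        for bigg_id in sorted(model_ids - map_ids)
    )
    return diagnostics


def export_flux_overlay(solution: FluxSolution, escher_map: EscherMap) -> str:
    """Serialize a solution as Escher 'reaction data': a flat id->flux JSON
    object restricted to reactions drawn on the map.

    Raises ``ValueError`` for non-optimal solutions, which carry no fluxes.
    """
    if solution.status != OPTIMAL:
        raise ValueError(
            f"cannot export an overlay from a solution with status {solution.status!r}"
        )
    assert solution.fluxes is not None
    map_ids = set(escher_map.reaction_bigg_ids)
    values = {
        rid: flux for rid, flux in solution.fluxes.items() if rid in map_ids
    }
    return json.dumps(dict(sorted(values.items())))


def parse_flux_overlay(document: str | bytes) -> FluxOverlay:
    """Inverse of :func:`export_flux_overlay`."""
    data = json.loads(document)
    if not isinstance(data, Mapping):
        raise MapFormatError("flux overlay must be a flat JSON object")
    return FluxOverlay(values={str(k): float(v) for k, v in data.items()})


# ---------------------------------------------------------------------------
# SVG rendering

#: default stroke-width endpoints, px
DEFAULT_SCALE = (2.0, 14.0)
_SVG_NS = "http://www.w3.org/2000/svg"


def _segment_path(escher_map: EscherMap, seg: MapSegment) -> str:
    start = escher_map.nodes[seg.from_node]
    end = escher_map.nodes[seg.to_node]
    if seg.b1 is not None and seg.b2 is not None:
        return (
            f"M {start.x:.2f},{start.y:.2f} "
            f"C {seg.b1[0]:.2f},{seg.b1[1]:.2f} {seg.b2[0]:.2f},{seg.b2[1]:.2f} "
            f"{end.x:.2f},{end.y:.2f}"
        )
    return f"M {start.x:.2f},{start.y:.2f} L {end.x:.2f},{end.y:.2f}"


def render_svg(
    escher_map: EscherMap,
    overlay: FluxOverlay,
    scale: tuple[float, float] = DEFAULT_SCALE,
) -> str:
    """Render the map as static SVG with flux-scaled arrow widths.

    Stroke width is linear in |flux| normalized to the overlay's largest
    |flux|: the largest flux is drawn at ``scale[1]`` px, a zero flux at
    ``scale[0]`` px.  Reactions with no overlay entry are drawn dashed at the
    minimum width.  Output is deterministic (reactions and segments sorted by
    id) and valid XML; an empty map yields an empty drawing.
    """
    min_width, max_width = scale
    if not (0 < min_width <= max_width):
        raise ValueError(f"scale must satisfy 0 < min <= max, got {scale}")
    max_abs = max((abs(v) for v in overlay.values.values()), default=0.0)

    svg = ElementTree.Element(
        "svg", {"xmlns": _SVG_NS, "version": "1.1"}
    )
    canvas = escher_map.canvas
    if canvas:
        svg.set(
            "viewBox",
            f"{canvas.get('x', 0)} {canvas.get('y', 0)} "
            f"{canvas.get('width', 100)} {canvas.get('height', 100)}",
        )
    for rxn in sorted(escher_map.reactions.values(), key=lambda r: r.id):
        flux = overlay.values.get(rxn.bigg_id)
        if flux is None:
            width = min_width
            dashed = True
        else:
            frac = 0.0 if max_abs == 0 else abs(flux) / max_abs
            width = min_width + (max_width - min_width) * frac
            dashed = False
        group = ElementTree.SubElement(
            svg, "g", {"id": f"reaction-{rxn.id}", "data-bigg-id": rxn.bigg_id}
        )
        for seg in sorted(rxn.segments, key=lambda s: s.id):
            attrs = {
                "d": _segment_path(escher_map, seg),
                "stroke": "#334E75",
                "stroke-width": f"{width:.3f}",
                "fill": "none",
                "stroke-linecap": "round",
            }
            if dashed:
                attrs["stroke-dasharray"] = "6 4"
            ElementTree.SubElement(group, "path", attrs)
    for node in sorted(escher_map.nodes.values(), key=lambda n: n.id):
        if node.node_type != "metabolite":
            continue
        ElementTree.SubElement(
            svg,
            "circle",
            {
                "cx": f"{node.x:.2f}",
                "cy": f"{node.y:.2f}",
                "r": "8",
                "fill": "#E0865B",
                "data-bigg-id": node.bigg_id or "",
            },
        )
    return ElementTree.tostring(svg, encoding="unicode")
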