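"""Reference genome-scale models as COBRA JSON, without downloads.

The canonical teaching model for FBA — the *E. coli* K-12 MG1655 core
network of central glucose metabolism (95 reactions, 72 metabolites; BiGG id
``e_coli_core``) — and the full genome-scale reconstruction iJO1366 ship
with COBRApy as compressed SBML.  This module converts those bundled files
to COBRA JSON at run time using COBRApy itself (the standard converter for
formats this package does not read) and hands the JSON text to
:func:`fluxlens.model_io.parse_cobra_json`.

COBRApy is an optional dependency (``pip install fluxlens[data]``); all
analysis downstream of the JSON text is independent of it.
"""

from __future__ import annotations

import os
from functools import lru_cache

from .model_io import MetabolicModel, parse_cobra_json

__all__ = [
    "e_coli_core_json",
    "ijo1366_json",
    "load_e_coli_core",
    "load_ijo1366",
]

# bundled-file names inside cobra's data directory
_BUNDLED = {
    "e_coli_core": "textbook.xml.gz",  # the BiGG e_coli_core network
    "iJO1366": "iJO1366.xml.gz",
}


def _cobra_modules():
    try:
        import cobra
        import cobra.io
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise RuntimeError(
            "the bundled reference models require the optional dependency "
            "'cobra' (install with: pip install fluxlens[data])"
        ) from exc
    return cobra


@lru_cache(maxsize=None)
def _bundled_json(name: str) -> str:
    cobra = _cobra_modules()
    path = os.path.join(os.path.dirname(cobra.__file__), "data", _BUNDLED[name])
    if not os.path.exists(path):  # pragma: no cover - environment-dependent
        raise FileNotFoundError(f"bundled model file not found: {path}")
    model = cobra.io.read_sbml_model(path)
    return cobra.io.to_json(model)


def e_coli_core_json() -> str:
    """COBRA JSON text for the *E. coli* core model (cached per process)."""
    return _bundled_json("e_coli_core")


def ijo1366_json() -> str:
    """COBRA JSON text for iJO1366 (slow on first call; cached per process)."""
    return _bundled_json("iJO1366")


def load_e_coli_core() -> MetabolicModel:
    """The *E. coli* core model, parsed."""
    return parse_cobra_json(e_coli_core_json())


def load_ijo1366() -> MetabolicModel:
    """The iJO1366 genome-scale model, parsed."""
    return parse_cobra_json(ijo1366_json())
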