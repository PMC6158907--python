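"""Shared fixtures: reference models (converted once per session) and small
hand-written documents."""

import json

import pytest

from fluxlens import SessionState, parse_cobra_json
from fluxlens.fixtures import add_1propanol_pathway, make_chain

# -- hand-written documents -------------------------------------------------

ONE_REACTION_DOC = {
    "id": "one_reaction",
    "metabolites": [{"id": "A_e", "name": "A", "compartment": "e"}],
    "reactions": [
        {
            "id": "EX_A_e",
            "name": "A exchange",
            "metabolites": {"A_e": -1.0},
            "lower_bound": -10.0,
            "upper_bound": 1000.0,
        }
    ],
    "genes": [],
}

MINIMAL_MAP = [
    {
        "map_name": "minimal",
        "map_id": "m1",
        "schema": "https://escher.github.io/escher/jsonschema/1-0-0#",
    },
    {
        "reactions": {
            "r1": {
                "bigg_id": "CONV_1",
                "label_x": 150.0,
                "label_y": 80.0,
                "segments": {
                    "s1": {"from_node_id": "n1", "to_node_id": "n2"},
                    "s2": {"from_node_id": "n2", "to_node_id": "n3"},
                },
            }
        },
        "nodes": {
            "n1": {"node_type": "metabolite", "x": 100.0, "y": 100.0, "bigg_id": "A0_c"},
            "n2": {"node_type": "midmarker", "x": 150.0, "y": 100.0},
            "n3": {"node_type": "metabolite", "x": 200.0, "y": 100.0, "bigg_id": "A1_c"},
        },
        "text_labels": {},
        "canvas": {"x": 0.0, "y": 0.0, "width": 300.0, "height": 200.0},
    },
]


@pytest.fixture
def one_reaction_doc():
    return json.loads(json.dumps(ONE_REACTION_DOC))


@pytest.fixture
def minimal_map_json():
    return json.dumps(MINIMAL_MAP)


@pytest.fixture
def chain3():
    return make_chain(3, 10.0)


@pytest.fixture
def chain3_state(chain3):
    return SessionState.from_model(chain3)


# -- reference models (slow conversions cached for the whole session) -------


@pytest.fixture(scope="session")
def core_json():
    from fluxlens import datasets

    return datasets.e_coli_core_json()


@pytest.fixture(scope="session")
def core_model(core_json):
    return parse_cobra_json(core_json)


@pytest.fixture(scope="session")
def biomass_id(core_model):
    (reaction,) = core_model.objective_reactions()
    return reaction.id


@pytest.fixture
def core_state(core_model):
    return SessionState.from_model(core_model)


@pytest.fixture(scope="session")
def ijo_model():
    from fluxlens import datasets

    return datasets.load_ijo1366()


@pytest.fixture(scope="session")
def propanol_states(ijo_model):
    """Session states for iJO1366 carrying the reconstructed 1-propanol
    routes: 'single' = keto-acid route only, 'synergistic' = + citramalate."""
    return {
        "single": SessionState.from_model(add_1propanol_pathway(ijo_model)),
        "synergistic": SessionState.from_model(
            add_1propanol_pathway(ijo_model, include_citramalate=True)
        ),
    }
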