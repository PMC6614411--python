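import pytest

from fluxcondition import ExpressionSimSpec, generate_expression, generate_toy_gem
from fluxcondition.gpr import parse_gpr
from fluxcondition.model import MetabolicModel, Metabolite, Reaction
from fluxcondition.synthetic import generate_interactions


def make_model(reactions, objective=None, model_id="test"):
    """Build a model from (id, stoich, lb, ub) or (id, stoich, lb, ub, gpr,
    subsystem) tuples, declaring metabolites implicitly."""
    rxns = []
    mets = set()
    for entry in reactions:
        rid, stoich, lb, ub = entry[:4]
        gpr = parse_gpr(entry[4]) if len(entry) > 4 else parse_gpr("")
        subsystem = entry[5] if len(entry) > 5 else ""
        rxns.append(
            Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                     gpr=gpr, subsystem=subsystem)
        )
        mets.update(stoich)
    return MetabolicModel(
        id=model_id,
        metabolites=[Metabolite(id=m, compartment="c") for m in sorted(mets)],
        reactions=rxns,
        compartments=["c"],
        objective_reaction_id=objective,
    )


@pytest.fixture(scope="session")
def toy_gem():
    model, truth = generate_toy_gem()
    return model, truth


@pytest.fixture(scope="session")
def toy_model(toy_gem):
    return toy_gem[0]


@pytest.fixture(scope="session")
def toy_truth(toy_gem):
    return toy_gem[1]


@pytest.fixture(scope="session")
def toy_expression(toy_model):
    expr, truth = generate_expression(ExpressionSimSpec(seed=0), toy_model)
    return expr, truth


@pytest.fixture(scope="session")
def toy_edges(toy_model):
    return generate_interactions(toy_model, seed=0)


@pytest.fixture()
def linear_chain():
    """in -> A -> B -> biomass drain, bottleneck 10 on uptake."""
    return make_model(
        [
            ("R_in", {"A": 1}, 0, 10),
            ("R_ab", {"A": -1, "B": 1}, 0, 1000),
            ("R_out", {"B": -1}, 0, 1000),
        ],
        objective="R_out",
    )


@pytest.fixture()
def diamond_model():
    """A reachable via two parallel routes, bottleneck 10 upstream."""
    return make_model(
        [
            ("R_in", {"A": 1}, 0, 10),
            ("R2a", {"A": -1, "B": 1}, 0, 1000),
            ("R2b", {"A": -1, "B": 1}, 0, 1000),
            ("R_out", {"B": -1}, 0, 1000),
        ],
        objective="R_out",
    )
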