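import numpy as np
import pytest

import commflux as cf


@pytest.fixture
def toy_a():
    return cf.toy_model_a()


@pytest.fixture
def toy_b():
    return cf.toy_model_b()


@pytest.fixture
def glc_media():
    return cf.Media("glc", {"EX_glc": 10.0})


@pytest.fixture
def toy_a_fed(toy_a, glc_media):
    return cf.apply_media(toy_a, glc_media)


@pytest.fixture
def broken():
    return cf.make_broken_fixtures()


@pytest.fixture
def toy_community(toy_a, toy_b):
    return cf.merge_models([toy_a, toy_b], ["a", "b"])


def to_cobra(model):
    """Convert to a cobra model solved with GLPK — the independent LP oracle."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        mid: cobra.Metabolite(mid, compartment=model.metabolites[mid].compartment or "c")
        for mid in model.metabolite_ids()
    }
    rxns = []
    for rid in model.reaction_ids():
        rxn = model.reactions[rid]
        cr = cobra.Reaction(rid, lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound)
        rxns.append((cr, {mets[m]: c for m, c in rxn.stoichiometry.items()}))
    cm.add_reactions([r for r, _ in rxns])
    for cr, stoich in rxns:
        cr.add_metabolites(stoich)
    if model.objective_id is not None:
        cm.objective = model.objective_id
    cm.solver = "glpk"
    return cm


def random_network(rng: np.random.Generator, n_rxn: int = 8, n_met: int = 5):
    """A random small flux network with finite bounds (never unbounded).

    Two boundary columns (single-metabolite source/sink) guarantee something
    can flow; internal columns get 2-3 random integer coefficients. Zero flux
    is always feasible since every lower bound is <= 0.
    """
    mets = [cf.Metabolite(f"m{i}", compartment="c") for i in range(n_met)]
    model = cf.MetabolicModel(f"rand{rng.integers(1 << 30)}", metabolites=mets)
    model.add_reaction(cf.Reaction("src", {"m0": 1.0}, 0.0, float(rng.integers(1, 11))))
    model.add_reaction(cf.Reaction(
        f"snk", {f"m{n_met - 1}": -1.0}, 0.0, 1000.0))
    for j in range(n_rxn - 2):
        k = int(rng.integers(2, 4))
        which = rng.choice(n_met, size=k, replace=False)
        coeffs = rng.integers(1, 3, size=k).astype(float)
        signs = rng.choice([-1.0, 1.0], size=k)
        if (signs > 0).all() or (signs < 0).all():
            signs[0] = -signs[0]
        stoich = {f"m{i}": s * c for i, s, c in zip(which, signs, coeffs)}
        lb = -1000.0 if rng.random() < 0.4 else 0.0
        model.add_reaction(cf.Reaction(f"r{j}", stoich, lb, 1000.0))
    model.objective_id = "snk"
    return model
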