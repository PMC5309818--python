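import numpy as np
import pytest

from timbr import MetabolicNetwork, Metabolite, Reaction, parse_gpr
from timbr.fixtures import FixtureSpec, toy_network


@pytest.fixture
def chain_network() -> MetabolicNetwork:
    """Minimal uptake -> conversion -> secretion chain: EX_A (lb=-10),
    A[e] -> B[e] is replaced by a transport-free single-compartment
    conversion so kinds stay simple."""
    net = MetabolicNetwork("chain")
    net.add_metabolite(Metabolite("A", "e"))
    net.add_metabolite(Metabolite("B", "e"))
    net.add_reaction(Reaction("EX_A", {"A[e]": -1.0}, -10.0, 1000.0))
    net.add_reaction(Reaction("conv", {"A[e]": -1.0, "B[e]": 1.0}, 0.0, 1000.0))
    net.add_reaction(Reaction("EX_B", {"B[e]": -1.0}, 0.0, 1000.0))
    return net


@pytest.fixture
def toy(request) -> MetabolicNetwork:
    return toy_network(FixtureSpec(seed=getattr(request, "param", 1)))


def random_network(seed: int) -> MetabolicNetwork:
    """Seeded random fixture network for round-trip properties."""
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(
        seed=seed,
        n_pathways=int(rng.integers(1, 4)),
        pathway_length=int(rng.integers(3, 6)),
        fraction_reversible=float(rng.uniform(0, 1)),
    )
    return toy_network(spec)


def to_cobra(network: MetabolicNetwork):
    """Convert a network to a cobrapy model (independent solver route)."""
    import cobra

    model = cobra.Model(network.id)
    mets = {
        key: cobra.Metabolite(key.replace("[", "_").replace("]", ""),
                              compartment=m.compartment)
        for key, m in network.metabolites.items()
    }
    for rxn in network.reactions.values():
        r = cobra.Reaction(rxn.id, lower_bound=rxn.lb, upper_bound=rxn.ub)
        model.add_reactions([r])
        r.add_metabolites({mets[k]: c for k, c in rxn.stoichiometry.items()})
        r.gene_reaction_rule = rxn.gpr.to_string()
    return model


def assert_steady_state(network: MetabolicNetwork, fluxes: dict[str, float],
                        tol: float = 1e-6) -> None:
    S = network.stoichiometric_matrix()
    v = np.array([fluxes[rid] for rid in network.reactions])
    residual = np.abs(S @ v).max()
    assert residual < tol, f"mass balance violated: |S v| = {residual}"
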