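"""Deterministic toy-network generators.

Every other module is testable offline against these fixtures: linear
uptake→conversion→secretion pathways with a biomass sink, paired
"species A / species B" networks differing by a planted reaction delta
(mirroring, e.g., the rat-only urate→allantoin degradation), an
energy-coupling fixture for should-fail ATP tasks, and planted
expression changes that uniformly up- or down-regulate the genes of one
pathway so that signal recovery by the scoring pipeline can be checked
exactly.  Fixtures use flux units on the fmol·cell⁻¹·h⁻¹ scale with
uptake bounds around 10.  Same seed, same fixture, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import TaskDefinition
from .gpr import parse_gpr
from .network import MetabolicNetwork, Metabolite, NetworkError, Reaction

GPR_PROFILES = ("single", "isozyme", "complex", "nested")


@dataclass
class FixtureSpec:
    """Parameters of a generated toy network."""

    seed: int = 0
    n_pathways: int = 2
    pathway_length: int = 3
    fraction_reversible: float = 0.25
    gpr_profile: tuple[str, ...] = GPR_PROFILES
    species_delta: tuple[str, ...] = ("delta1",)
    uptake_bound: float = 10.0
    big_bound: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("need at least one pathway")
        if self.pathway_length < 3:
            raise ValueError("pathway_length must be >= 3 "
                             "(transport in, conversion(s), transport out)")
        bad = set(self.gpr_profile) - set(GPR_PROFILES)
        if bad:
            raise ValueError(f"unknown gpr profiles: {sorted(bad)}")


def _profile_gpr(profile: str, tag: str) -> str:
    if profile == "single":
        return f"g{tag}a"
    if profile == "isozyme":
        return f"g{tag}a or g{tag}b"
    if profile == "complex":
        return f"g{tag}a and g{tag}b"
    return f"(g{tag}a and g{tag}b) or g{tag}c"


def toy_network(spec: FixtureSpec) -> MetabolicNetwork:
    """Build the standard pathway fixture.

    Each pathway p: uptake exchange ``EX_A{p}`` (lb = -uptake_bound),
    transport ``A{p}[e] -> A{p}[c]``, ``pathway_length - 2`` biochemical
    conversions ending in ``P{p}[c]``, transport out and secretion
    exchange ``EX_P{p}``.  A biomass reaction consumes every ``P{p}[c]``
    and is the model objective.  GPR profiles cycle over the internal
    reactions; a seeded fraction of the conversions is reversible.
    """
    rng = np.random.default_rng(spec.seed)
    net = MetabolicNetwork(f"toy_s{spec.seed}")
    profile_cycle = 0

    def next_gpr(tag: str) -> str:
        nonlocal profile_cycle
        profile = spec.gpr_profile[profile_cycle % len(spec.gpr_profile)]
        profile_cycle += 1
        return _profile_gpr(profile, tag)

    for p in range(1, spec.n_pathways + 1):
        a, prod = f"A{p}", f"P{p}"
        net.add_metabolite(Metabolite(a, "e"))
        net.add_metabolite(Metabolite(a, "c"))
        net.add_metabolite(Metabolite(prod, "e"))
        net.add_metabolite(Metabolite(prod, "c"))
        n_conv = spec.pathway_length - 2
        inter = [f"M{p}_{k}" for k in range(1, n_conv)]
        for m in inter:
            net.add_metabolite(Metabolite(m, "c"))
        chain = [a] + inter + [prod]

        net.add_reaction(Reaction(
            f"EX_{a}", {f"{a}[e]": -1.0}, -spec.uptake_bound, spec.big_bound))
        net.add_reaction(Reaction(
            f"T{p}_in", {f"{a}[e]": -1.0, f"{a}[c]": 1.0},
            0.0, spec.big_bound, gpr=parse_gpr(next_gpr(f"{p}t"))))
        for k in range(n_conv):
            reversible = rng.random() < spec.fraction_reversible
            net.add_reaction(Reaction(
                f"B{p}_{k + 1}",
                {f"{chain[k]}[c]": -1.0, f"{chain[k + 1]}[c]": 1.0},
                -spec.big_bound if reversible else 0.0, spec.big_bound,
                gpr=parse_gpr(next_gpr(f"{p}b{k + 1}"))))
        net.add_reaction(Reaction(
            f"T{p}_out", {f"{prod}[c]": -1.0, f"{prod}[e]": 1.0},
            0.0, spec.big_bound, gpr=parse_gpr(next_gpr(f"{p}o"))))
        net.add_reaction(Reaction(
            f"EX_{prod}", {f"{prod}[e]": -1.0}, 0.0, spec.big_bound))

    net.add_reaction(Reaction(
        "biomass",
        {f"P{p}[c]": -1.0 for p in range(1, spec.n_pathways + 1)},
        0.0, spec.big_bound))
    net.objective_id = "biomass"
    return net


def paired_networks(spec: FixtureSpec) -> tuple[MetabolicNetwork, MetabolicNetwork]:
    """Two networks sharing one namespace, differing by a reaction delta.

    For each name ``d`` in ``spec.species_delta`` both networks carry a
    product metabolite ``D_d`` with transport and exchange, but only
    network A carries the conversion ``P1[c] -> D_d[c]`` (the pattern of
    a species-specific degradation step).  Task asymmetry — "produce
    D_d from A1" — then holds between A and B.
    """
    if not spec.species_delta:
        raise NetworkError("species_delta must be non-empty")
    base = toy_network(spec)
    for d in spec.species_delta:
        if f"D_{d}[c]" in base.metabolites or f"conv_{d}" in base.reactions:
            raise NetworkError(f"delta id {d!r} collides with shared ids")
    net_a = base
    net_b = toy_network(spec)
    net_a.id, net_b.id = f"toy_s{spec.seed}_A", f"toy_s{spec.seed}_B"
    for net in (net_a, net_b):
        for d in spec.species_delta:
            net.add_metabolite(Metabolite(f"D_{d}", "c"))
            net.add_metabolite(Metabolite(f"D_{d}", "e"))
            net.add_reaction(Reaction(
                f"T_{d}", {f"D_{d}[c]": -1.0, f"D_{d}[e]": 1.0},
                0.0, spec.big_bound))
            net.add_reaction(Reaction(
                f"EX_D_{d}", {f"D_{d}[e]": -1.0}, 0.0, spec.big_bound))
    for d in spec.species_delta:  # the species-specific step, A only
        net_a.add_reaction(Reaction(
            f"conv_{d}", {"P1[c]": -1.0, f"D_{d}[c]": 1.0},
            0.0, spec.big_bound, gpr=parse_gpr(f"g_{d}")))
    return net_a, net_b


def energy_fixture() -> tuple[MetabolicNetwork, list[TaskDefinition]]:
    """Small energy-coupled network plus its task suite.

    Work output requires ATP; ATP regeneration requires a carbon source.
    The should-fail task asserts that no work (no ATP rephosphorylation)
    is possible with only inorganic inputs; the control task shows the
    same output is feasible once glucose-like carbon is supplied.
    """
    net = MetabolicNetwork("energy_fixture")
    for mid, comp in [("glc", "e"), ("glc", "c"), ("pi", "e"), ("pi", "c"),
                      ("h2o", "e"), ("h2o", "c"), ("atp", "c"), ("adp", "c"),
                      ("waste", "c"), ("waste", "e"), ("work", "c"),
                      ("work", "e")]:
        net.add_metabolite(Metabolite(mid, comp))
    big = 1000.0
    rxns = [
        Reaction("EX_glc", {"glc[e]": -1.0}, -10.0, big),
        Reaction("EX_pi", {"pi[e]": -1.0}, -big, big),
        Reaction("EX_h2o", {"h2o[e]": -1.0}, -big, big),
        Reaction("EX_waste", {"waste[e]": -1.0}, 0.0, big),
        Reaction("EX_work", {"work[e]": -1.0}, 0.0, big),
        Reaction("T_glc", {"glc[e]": -1.0, "glc[c]": 1.0}, 0.0, big,
                 gpr=parse_gpr("g_tglc")),
        Reaction("T_pi", {"pi[e]": -1.0, "pi[c]": 1.0}, -big, big),
        Reaction("T_h2o", {"h2o[e]": -1.0, "h2o[c]": 1.0}, -big, big),
        Reaction("T_waste", {"waste[c]": -1.0, "waste[e]": 1.0}, 0.0, big),
        Reaction("T_work", {"work[c]": -1.0, "work[e]": 1.0}, 0.0, big),
        # substrate-level phosphorylation: carbon powers ATP synthesis
        Reaction("glycolysis",
                 {"glc[c]": -1.0, "adp[c]": -2.0, "pi[c]": -2.0,
                  "atp[c]": 2.0, "waste[c]": 1.0, "h2o[c]": 2.0},
                 0.0, big, gpr=parse_gpr("g_gly1 and g_gly2")),
        # ATP hydrolysis drives work
        Reaction("atpase",
                 {"atp[c]": -1.0, "h2o[c]": -1.0, "adp[c]": 1.0,
                  "pi[c]": 1.0, "work[c]": 1.0},
                 0.0, big, gpr=parse_gpr("g_atpase")),
    ]
    for rxn in rxns:
        net.add_reaction(rxn)
    tasks = [
        TaskDefinition(
            id="work_from_inorganic",
            description="no ATP rephosphorylation from inorganic inputs alone",
            inputs=[("pi[e]", 0.0, 1000.0), ("h2o[e]", 0.0, 1000.0)],
            outputs=[("work[e]", 1.0, 1000.0)],
            should_fail=True,
        ),
        TaskDefinition(
            id="work_from_carbon",
            description="work output once a carbon source is supplied",
            inputs=[("glc[e]", 0.0, 10.0), ("pi[e]", 0.0, 1000.0),
                    ("h2o[e]", 0.0, 1000.0)],
            outputs=[("work[e]", 1.0, 1000.0),
                     ("waste[e]", 0.0, 1000.0)],
        ),
    ]
    return net, tasks


def species_task(spec: FixtureSpec, delta: str | None = None) -> TaskDefinition:
    """Task asserting the species-specific capability of a paired
    fixture: produce the delta product from the pathway-1 substrate."""
    d = delta or spec.species_delta[0]
    return TaskDefinition(
        id=f"produce_D_{d}",
        description=f"synthesize D_{d} from A1 uptake",
        inputs=[("A1[e]", 0.0, spec.uptake_bound)],
        outputs=[(f"D_{d}[e]", 0.1, spec.uptake_bound)],
    )


def producing_pathway(network: MetabolicNetwork,
                      target_metabolite: str) -> list[str]:
    """Backward closure of reactions producing a metabolite key.

    On the acyclic fixtures this closure is exactly the synthesis
    pathway.  Exchange reactions are excluded (boundary uptake is not a
    synthesis step)."""
    from .network import EXCHANGE, classify_reaction_kind

    kinds = classify_reaction_kind(network)
    visited_mets: set[str] = set()
    pathway: list[str] = []
    frontier = [target_metabolite]
    while frontier:
        met = frontier.pop()
        if met in visited_mets:
            continue
        visited_mets.add(met)
        for rxn in network.reactions.values():
            if kinds[rxn.id] == EXCHANGE:
                continue
            if rxn.stoichiometry.get(met, 0.0) > 0 and rxn.id not in pathway:
                pathway.append(rxn.id)
                frontier.extend(
                    k for k, c in rxn.stoichiometry.items() if c < 0
                )
    return pathway


def planted_expression(network: MetabolicNetwork, target_metabolite: str,
                       direction: str = "up", effect_log2fc: float = 2.0,
                       background_sd: float = 0.25, seed: int = 0,
                       compound: str = "planted"):
    """Expression table with a planted pathway-level signal.

    Every gene on the producing pathway of ``target_metabolite`` gets
    ``log2fc = +/-effect_log2fc`` with q = 0.01 (significant); every
    other network gene draws an insignificant background change
    Normal(0, background_sd) with q = 0.5.
    """
    from .scoring import ExpressionChanges

    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    pathway = producing_pathway(network, target_metabolite)
    pathway_genes: set[str] = set()
    for rid in pathway:
        pathway_genes |= network.reactions[rid].gpr.genes()
    if not pathway_genes:
        raise NetworkError(
            f"no gene-associated producing pathway for {target_metabolite}"
        )
    rng = np.random.default_rng(seed)
    effect = effect_log2fc if direction == "up" else -effect_log2fc
    rows = []
    for gid in network.genes:
        if gid in pathway_genes:
            rows.append({"gene_id": gid, "log2fc": effect, "qvalue": 0.01})
        else:
            rows.append({"gene_id": gid,
                         "log2fc": float(rng.normal(0.0, background_sd))
                         if background_sd > 0 else 0.0,
                         "qvalue": 0.5})
    return ExpressionChanges(pd.DataFrame(rows), compound=compound,
                             organism=network.id)
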