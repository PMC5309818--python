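"""In-memory model of a compartmentalized genome-scale metabolic network.

The network stores metabolites (keyed by ``id[compartment]``), reactions
with stoichiometry, flux bounds and GPR rules, and the gene inventory.
It exposes the stoichiometric matrix ``S`` (one row per metabolite, one
column per reaction) used by the linear-programming engine, an
irreversible split where every reversible reaction becomes a forward and
a reverse column with non-negative bounds, and summary statistics of the
kind used to compare genome-scale reconstructions (gene counts,
enzymatic/isozymic/enzyme-complex reactions, mean GPR size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .gpr import GPRRule

BIOCHEMICAL = "biochemical"
TRANSPORT = "transport"
EXCHANGE = "exchange"


class NetworkError(ValueError):
    """Structural problem in a metabolic network."""


@dataclass(frozen=True)
class Gene:
    id: str
    organism: str = "other"

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("gene id must be non-empty")


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    formula: str | None = None

    @property
    def key(self) -> str:
        """Compartment-qualified identifier, e.g. ``glc[c]``."""
        return f"{self.id}[{self.compartment}]"


@dataclass
class Reaction:
    """A reaction column: stoichiometry maps metabolite keys to
    coefficients (negative = consumed), bounds in model flux units."""

    id: str
    stoichiometry: dict[str, float]
    lb: float
    ub: float
    gpr: GPRRule = field(default_factory=GPRRule.empty)
    subsystem: str = ""

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise NetworkError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")
        if not self.stoichiometry:
            raise NetworkError(f"reaction {self.id} has zero metabolites")

    @property
    def reversible(self) -> bool:
        return self.lb < 0 and self.ub > 0


class MetabolicNetwork:
    """Container for genes, metabolites and reactions of one organism."""

    def __init__(self, id: str = "model") -> None:
        self.id = id
        self.genes: dict[str, Gene] = {}
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.compartments: set[str] = set()
        self.objective_id: str | None = None

    # -- construction -------------------------------------------------
    def add_compartment(self, compartment: str) -> None:
        self.compartments.add(compartment)

    def add_gene(self, gene: Gene) -> None:
        self.genes.setdefault(gene.id, gene)

    def add_metabolite(self, met: Metabolite) -> None:
        if met.key in self.metabolites:
            raise NetworkError(f"duplicate metabolite {met.key}")
        self.compartments.add(met.compartment)
        self.metabolites[met.key] = met

    def add_reaction(self, rxn: Reaction, register_genes: bool = True,
                     organism: str = "other") -> None:
        if rxn.id in self.reactions:
            raise NetworkError(f"duplicate reaction id {rxn.id}")
        for key in rxn.stoichiometry:
            if key not in self.metabolites:
                raise NetworkError(
                    f"reaction {rxn.id} references undeclared metabolite {key}"
                )
        for gid in rxn.gpr.genes():
            if register_genes:
                self.add_gene(Gene(gid, organism))
            elif gid not in self.genes:
                raise NetworkError(
                    f"reaction {rxn.id} GPR references undeclared gene {gid}"
                )
        self.reactions[rxn.id] = rxn

    def copy(self) -> "MetabolicNetwork":
        out = MetabolicNetwork(self.id)
        out.genes = dict(self.genes)
        out.metabolites = dict(self.metabolites)
        out.compartments = set(self.compartments)
        out.objective_id = self.objective_id
        for rxn in self.reactions.values():
            out.reactions[rxn.id] = Reaction(
                rxn.id, dict(rxn.stoichiometry), rxn.lb, rxn.ub, rxn.gpr,
                rxn.subsystem,
            )
        return out

    # -- matrix view --------------------------------------------------
    @property
    def metabolite_index(self) -> dict[str, int]:
        return {k: i for i, k in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> dict[str, int]:
        return {k: i for i, k in enumerate(self.reactions)}

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        midx = self.metabolite_index
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions.values()):
            for key, coef in rxn.stoichiometry.items():
                rows.append(midx[key])
                cols.append(j)
                data.append(float(coef))
        return sparse.csr_matrix(
            (data, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions.values()], dtype=float)
        ub = np.array([r.ub for r in self.reactions.values()], dtype=float)
        return lb, ub

    # -- reaction classification --------------------------------------
    def reaction_kind(self, rxn_id: str) -> str:
        return classify_reaction_kind(self)[rxn_id]

    def exchange_reactions(self) -> dict[str, str]:
        """Map exchange reaction id -> metabolite key it exchanges."""
        out = {}
        for rid, kind in classify_reaction_kind(self).items():
            if kind == EXCHANGE:
                out[rid] = next(iter(self.reactions[rid].stoichiometry))
        return out

    def exchange_for(self, metabolite_key: str) -> str | None:
        """Exchange reaction id for a metabolite key, or None."""
        for rid, key in self.exchange_reactions().items():
            if key == metabolite_key:
                return rid
        return None


def classify_reaction_kind(network: MetabolicNetwork) -> dict[str, str]:
    """Classify every reaction as exchange, transport or biochemical.

    Exchange: boundary reaction touching exactly one metabolite.
    Transport: participants span >= 2 compartments (takes priority over
    any chemical transformation that also occurs).  Biochemical: the rest.
    """
    kinds: dict[str, str] = {}
    for rxn in network.reactions.values():
        mets = list(rxn.stoichiometry)
        if not mets:
            raise NetworkError(f"reaction {rxn.id} has zero metabolites")
        if len(mets) == 1:
            kinds[rxn.id] = EXCHANGE
            continue
        comps = {network.metabolites[k].compartment for k in mets}
        kinds[rxn.id] = TRANSPORT if len(comps) >= 2 else BIOCHEMICAL
    return kinds


@dataclass
class IrreversibleNetwork:
    """Irreversible split of a network: each reversible reaction becomes a
    forward and a reverse column so that every lower bound is >= 0.

    ``columns`` lists ``(reaction_id, direction)`` with direction +1 for
    the forward and -1 for the reverse column; the net flux of a source
    reaction is ``v_fwd - v_rev``.
    """

    source: MetabolicNetwork
    S: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    columns: list[tuple[str, int]]

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def column(self, rxn_id: str, direction: int = 1) -> int:
        for j, (rid, d) in enumerate(self.columns):
            if rid == rxn_id and d == direction:
                return j
        raise KeyError(f"no column for reaction {rxn_id!r} direction {direction}")

    def columns_for(self, rxn_id: str) -> list[int]:
        return [j for j, (rid, _) in enumerate(self.columns) if rid == rxn_id]

    def net_flux(self, v: np.ndarray) -> dict[str, float]:
        """Map an irreversible flux vector back to source net fluxes."""
        out = {rid: 0.0 for rid in self.source.reactions}
        for value, (rid, direction) in zip(v, self.columns):
            out[rid] += direction * float(value)
        return out


def make_irreversible(network: MetabolicNetwork) -> IrreversibleNetwork:
    """Split reversible reactions into forward/reverse columns.

    A source reaction with bounds ``[-a, b]`` (a, b > 0) yields a forward
    column bounded ``[0, b]`` and a reverse column (negated stoichiometry)
    bounded ``[0, a]``.  Irreversible reactions keep a single column; a
    strictly-negative reaction (``ub <= 0``) is represented by its reverse
    column alone so all lower bounds are non-negative.
    """
    midx = network.metabolite_index
    columns: list[tuple[str, int]] = []
    lb: list[float] = []
    ub: list[float] = []
    rows, cols, data = [], [], []

    def add_column(rxn: Reaction, direction: int, low: float, high: float) -> None:
        j = len(columns)
        columns.append((rxn.id, direction))
        lb.append(low)
        ub.append(high)
        for key, coef in rxn.stoichiometry.items():
            rows.append(midx[key])
            cols.append(j)
            data.append(direction * float(coef))

    for rxn in network.reactions.values():
        if rxn.lb >= 0:
            add_column(rxn, 1, rxn.lb, rxn.ub)
        elif rxn.ub <= 0:
            add_column(rxn, -1, -rxn.ub, -rxn.lb)
        else:
            add_column(rxn, 1, 0.0, rxn.ub)
            add_column(rxn, -1, 0.0, -rxn.lb)

    S = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(network.metabolites), len(columns))
    )
    return IrreversibleNetwork(
        source=network, S=S, lb=np.array(lb), ub=np.array(ub), columns=columns
    )


@dataclass
class NetworkStats:
    """Reconstruction summary statistics."""

    genes: int
    reactions: int
    metabolites: int
    enzymatic: int
    isozymic: int
    enzyme_complex: int
    non_enzymatic: int
    mean_gpr_size: float
    dual_species_fraction: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {
            "genes": self.genes,
            "reactions": self.reactions,
            "metabolites": self.metabolites,
            "enzymatic": self.enzymatic,
            "isozymic": self.isozymic,
            "enzyme_complex": self.enzyme_complex,
            "non_enzymatic": self.non_enzymatic,
            "mean_gpr_size": self.mean_gpr_size,
        }
        if self.dual_species_fraction is not None:
            out["dual_species_fraction"] = self.dual_species_fraction
        return out


def _contains_op(rule: GPRRule, op: str) -> bool:
    if rule.op == op:
        return True
    return any(_contains_op(c, op) for c in rule.children)


def network_stats(network: MetabolicNetwork,
                  paired: MetabolicNetwork | None = None) -> NetworkStats:
    """Summary statistics of a reconstruction.

    Enzymatic = non-empty GPR; isozymic = rule containing an OR;
    enzyme-complex = rule containing an AND; mean GPR size averages the
    distinct-gene count over enzymatic reactions.  With a ``paired``
    network of the other species, ``dual_species_fraction`` is the
    fraction of reactions gene-associated in at least one network that
    are gene-associated in both.
    """
    enzymatic = isozymic = complexes = 0
    sizes: list[int] = []
    for rxn in network.reactions.values():
        if rxn.gpr.is_empty:
            continue
        enzymatic += 1
        sizes.append(rxn.gpr.size())
        if _contains_op(rxn.gpr, "or"):
            isozymic += 1
        if _contains_op(rxn.gpr, "and"):
            complexes += 1
    dual: float | None = None
    if paired is not None:
        assoc_a = {rid for rid, r in network.reactions.items() if not r.gpr.is_empty}
        assoc_b = {rid for rid, r in paired.reactions.items() if not r.gpr.is_empty}
        union = assoc_a | assoc_b
        dual = (len(assoc_a & assoc_b) / len(union)) if union else 0.0
    return NetworkStats(
        genes=len(network.genes),
        reactions=len(network.reactions),
        metabolites=len(network.metabolites),
        enzymatic=enzymatic,
        isozymic=isozymic,
        enzyme_complex=complexes,
        non_enzymatic=len(network.reactions) - enzymatic,
        mean_gpr_size=float(np.mean(sizes)) if sizes else 0.0,
        dual_species_fraction=dual,
    )
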