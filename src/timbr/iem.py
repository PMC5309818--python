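"""Biomarker prediction for inborn errors of metabolism (IEMs).

An IEM is modelled as the loss of one or more causal genes.  Reactions
whose GPR rule evaluates false without those genes are the affected
reactions.  The healthy condition forces each affected reaction to at
least 90% of its FBA-maximal flux under open-exchange media; the
disease condition blocks the affected reactions entirely.  For each
candidate biomarker, the feasible flux range of its exchange reaction
is computed under both conditions by FVA and the interval shift is
called elevated, reduced or unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    OPTIMAL,
    EngineError,
    FluxRange,
    MediaConstraints,
    fba,
    fva,
    open_exchange_media,
)
from .network import MetabolicNetwork

ELEVATED = "elevated"
REDUCED = "reduced"
UNCHANGED = "unchanged"

FORCE_FRACTION = 0.9

#: default inorganic-ion list for open-exchange media (metabolite ids;
#: matched against exchanged metabolites of the target network)
DEFAULT_ION_IDS = (
    "h2o", "h", "na1", "k", "cl", "ca2", "mg2", "fe2", "pi", "so4",
    "hco3", "o2",
)


@dataclass
class IEMCase:
    """One inborn error: causal genes and expected biomarker shifts."""

    id: str
    genes: list[str]
    biomarkers: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"IEM case {self.id} has no causal genes")


@dataclass
class BiomarkerCall:
    metabolite: str
    healthy: FluxRange | None
    disease: FluxRange | None
    call: str
    expected: str | None = None

    @property
    def correct(self) -> bool | None:
        if self.expected is None:
            return None
        return self.call == self.expected


def affected_reactions(network: MetabolicNetwork,
                       genes: list[str] | set[str]) -> list[str]:
    """Reactions disabled by deleting ``genes``: enzymatic reactions
    whose GPR evaluates false with the causal genes absent and every
    other gene present."""
    missing = [g for g in genes if g not in network.genes]
    if missing:
        raise ValueError(f"genes not in network: {missing}")
    present = set(network.genes) - set(genes)
    return [
        rxn.id for rxn in network.reactions.values()
        if not rxn.gpr.is_empty and not rxn.gpr.evaluate(present)
    ]


def _call_from_ranges(healthy: FluxRange, disease: FluxRange) -> str:
    """Reduce two FVA intervals to a directional call by the shift of
    the interval midpoint sum, with a relative tolerance."""
    tol = 1e-6 * max(1.0, abs(healthy.max_flux))
    shift = (disease.min_flux + disease.max_flux) - (
        healthy.min_flux + healthy.max_flux
    )
    if shift > tol:
        return ELEVATED
    if shift < -tol:
        return REDUCED
    return UNCHANGED


@dataclass
class IEMPrediction:
    case: IEMCase
    calls: list[BiomarkerCall]
    affected: list[str]
    evaluable: bool
    note: str = ""


def predict_iem(network: MetabolicNetwork, case: IEMCase,
                media: MediaConstraints | None = None,
                force_fraction: float = FORCE_FRACTION,
                simultaneous: bool = True) -> IEMPrediction:
    """Predict biomarker shifts for one IEM case.

    For each affected reaction the FBA maximum-|flux| direction under
    ``media`` (default: open-exchange over :data:`DEFAULT_ION_IDS`
    present in the network) sets the healthy forcing level at
    ``force_fraction`` of that optimum; affected reactions with zero
    attainable flux impose no forcing.  With ``simultaneous`` (default)
    all affected reactions are forced together; otherwise each biomarker
    FVA is repeated per forced reaction and the ranges unioned.
    An infeasible healthy forcing marks the case unevaluable.
    """
    if media is None:
        present = {m for m in DEFAULT_ION_IDS
                   if network.exchange_for(f"{m}[e]")}
        media = open_exchange_media(network, [f"{m}[e]" for m in present])
    affected = affected_reactions(network, case.genes)

    # per-reaction forcing bounds for the healthy condition
    forcing: dict[str, tuple[float, float]] = {}
    for rid in affected:
        fwd = fba(network, rid, media, maximize=True)
        rev = fba(network, rid, media, maximize=False)
        vmax = fwd.objective_value if fwd.status == OPTIMAL else 0.0
        vmin = rev.objective_value if rev.status == OPTIMAL else 0.0
        if abs(vmax) >= abs(vmin) and vmax > 0:
            forcing[rid] = (force_fraction * vmax, np.inf)
        elif abs(vmin) > abs(vmax) and vmin < 0:
            forcing[rid] = (-np.inf, force_fraction * vmin)
        # zero max flux in both directions: no forcing possible

    def condition_network(bounds: dict[str, tuple[float, float]]):
        net = network.copy()
        for rid, (lo, hi) in bounds.items():
            rxn = net.reactions[rid]
            rxn.lb = max(rxn.lb, lo) if np.isfinite(lo) else rxn.lb
            rxn.ub = min(rxn.ub, hi) if np.isfinite(hi) else rxn.ub
            if rxn.lb > rxn.ub:
                raise EngineError(f"forcing infeasible for {rid}")
        return net

    disease_net = condition_network({rid: (0.0, 0.0) for rid in affected})

    biomarker_exchanges = {}
    for met, _ in case.biomarkers:
        ex = network.exchange_for(met)
        if ex is None:
            return IEMPrediction(case, [], affected, False,
                                 note=f"biomarker {met} not exchangeable")
        biomarker_exchanges[met] = ex
    ex_ids = list(biomarker_exchanges.values())

    try:
        if simultaneous or not forcing:
            healthy_net = condition_network(forcing)
            healthy_ranges = fva(healthy_net, ex_ids, media)
        else:
            healthy_ranges = {}
            for rid, bound in forcing.items():
                part = fva(condition_network({rid: bound}), ex_ids, media)
                for ex, rng in part.items():
                    prev = healthy_ranges.get(ex)
                    if prev is None:
                        healthy_ranges[ex] = rng
                    else:
                        healthy_ranges[ex] = FluxRange(
                            ex, min(prev.min_flux, rng.min_flux),
                            max(prev.max_flux, rng.max_flux),
                        )
        disease_ranges = fva(disease_net, ex_ids, media)
    except EngineError as exc:
        return IEMPrediction(case, [], affected, False, note=str(exc))

    calls = []
    for met, expected in case.biomarkers:
        ex = biomarker_exchanges[met]
        h, d = healthy_ranges[ex], disease_ranges[ex]
        calls.append(BiomarkerCall(met, h, d, _call_from_ranges(h, d), expected))
    return IEMPrediction(case, calls, affected, True)


@dataclass
class IEMEvaluation:
    """Per-direction sensitivity summary across IEM cases."""

    table: pd.DataFrame  # rows: elevated, reduced, total

    def sensitivity(self, stratum: str = "total") -> float:
        row = self.table.loc[stratum]
        return row["correct"] / row["count"] if row["count"] else float("nan")

    def summary(self) -> str:
        lines = ["IEM biomarker prediction sensitivity",
                 f"{'stratum':<10}{'count':>6}{'correct':>9}{'sens':>8}"]
        for stratum, row in self.table.iterrows():
            sens = row["correct"] / row["count"] if row["count"] else float("nan")
            lines.append(f"{stratum:<10}{int(row['count']):>6}"
                         f"{int(row['correct']):>9}{100 * sens:>7.1f}%")
        return "\n".join(lines)


def evaluate_iem(predictions: list[IEMPrediction]) -> IEMEvaluation:
    """Tally correct elevated/reduced calls over all evaluable cases."""
    counts = {ELEVATED: [0, 0], REDUCED: [0, 0]}
    for pred in predictions:
        if not pred.evaluable:
            continue
        for call in pred.calls:
            if call.expected not in counts:
                continue
            counts[call.expected][0] += 1
            if call.correct:
                counts[call.expected][1] += 1
    total = [sum(v[0] for v in counts.values()),
             sum(v[1] for v in counts.values())]
    table = pd.DataFrame(
        {
            "count": [counts[ELEVATED][0], counts[REDUCED][0], total[0]],
            "correct": [counts[ELEVATED][1], counts[REDUCED][1], total[1]],
        },
        index=[ELEVATED, REDUCED, "total"],
    )
    return IEMEvaluation(table)


class IEMStudy:
    """Model-style wrapper: run a catalogue of IEM cases against one
    network and evaluate Table-style sensitivity."""

    def __init__(self, network: MetabolicNetwork, cases: list[IEMCase],
                 media: MediaConstraints | None = None, **kwargs) -> None:
        self.network = network
        self.cases = cases
        self.media = media
        self.kwargs = kwargs

    def fit(self) -> tuple[list[IEMPrediction], IEMEvaluation]:
        predictions = [
            predict_iem(self.network, case, self.media, **self.kwargs)
            for case in self.cases
        ]
        return predictions, evaluate_iem(predictions)
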