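"""TIMBR: transcriptionally inferred metabolic biomarker response.

Given a metabolic network and a table of per-gene log2 fold changes with
FDR q-values for one compound, TIMBR scores every exchangeable
metabolite by how consistent the expression changes are with its
production.  The steps:

1. Insignificant changes (q >= 0.1) are set to zero; each reaction's
   genes are summarized through its GPR rule (isozymes average, complex
   subunits take the largest-magnitude change).
2. Default weights (1 biochemical, 2 transport, doubled without gene
   association or expression data) are transformed reciprocally:
   ``w_control = w_default * 2**r`` and ``w_treatment = w_default / 2**r``,
   so upregulated reactions are cheap under treatment and expensive
   under control.
3. For each metabolite, secretion is forced to
   ``min(100, 0.9 * v_max)`` flux units (v_max from FVA) and the global
   network demand — the minimum total weighted flux — is computed under
   both weight vectors on the irreversible network.
4. The raw production score ``(d_control - d_treatment) /
   (d_control + d_treatment)`` is z-normalized across all scored
   metabolites: positive scores mean expression favours production.

The :class:`Timbr` model object wraps the pipeline; :meth:`Timbr.fit`
returns a :class:`TimbrResults` carrying the score table, classification
helpers and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .engine import (
    OPTIMAL,
    MediaConstraints,
    fva,
    min_weighted_flux,
)
from .gpr import GPRRule
from .network import (
    BIOCHEMICAL,
    MetabolicNetwork,
    classify_reaction_kind,
    make_irreversible,
)

STATUS_SCORED = "scored"
STATUS_SKIPPED = "skipped_unproducible"
STATUS_INFEASIBLE = "infeasible"

DATA_SUMMARIZED = "summarized"
DATA_NO_GPR = "no_gpr"
DATA_NO_DATA = "no_data"

PRODUCTION_CAP = 100.0  # fmol per cell per hour
FVA_FRACTION = 0.9
UNPRODUCIBLE_TOL = 1e-9


@dataclass
class ExpressionChanges:
    """Per-gene log2 fold change and FDR q-value for one compound."""

    data: pd.DataFrame  # columns: gene_id, log2fc, qvalue
    compound: str = ""
    organism: str = ""

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "qvalue"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"expression table needs columns {sorted(required)}")
        q = self.data["qvalue"]
        if ((q < 0) | (q > 1)).any():
            raise ValueError("q-values must lie in [0, 1]")

    def gene_ids(self) -> set[str]:
        return set(self.data["gene_id"].astype(str))

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.data["gene_id"].astype(str),
                        self.data["log2fc"].astype(float)))


def filter_significant(expr: ExpressionChanges,
                       q_threshold: float = 0.1) -> ExpressionChanges:
    """Zero out log2 fold changes whose q-value is not below threshold."""
    df = expr.data.copy()
    df.loc[df["qvalue"] >= q_threshold, "log2fc"] = 0.0
    return ExpressionChanges(df, expr.compound, expr.organism)


def compound_suitability(expr: ExpressionChanges, model_gene_set: set[str],
                         min_fraction: float = 0.01,
                         q_threshold: float = 0.1) -> tuple[bool, int]:
    """Screen a compound for model integration: suitable iff it
    significantly alters at least ``min_fraction`` of the model genes
    present on the platform (boundary inclusive)."""
    if not model_gene_set:
        raise ValueError("model gene set is empty")
    df = expr.data
    significant = set(df.loc[df["qvalue"] < q_threshold, "gene_id"].astype(str))
    affected = len(significant & model_gene_set)
    return affected / len(model_gene_set) >= min_fraction, affected


# --------------------------------------------------------------------
# GPR summarization and weights

def summarize_gpr(rule: GPRRule, expr: ExpressionChanges | dict[str, float]
                  ) -> float:
    """Summarize gene-level log2 fold changes into one reaction value.

    OR nodes (isozymes) take the arithmetic mean of child values, so an
    upregulated isozyme is diluted by unaffected ones; AND nodes
    (enzyme complexes) take the child with the largest absolute value
    (ties broken toward the positive value, then the first child).
    Genes absent from the table contribute 0.  ``expr`` should already
    be significance-filtered.
    """
    values = expr if isinstance(expr, dict) else expr.as_mapping()

    def walk(node: GPRRule) -> float:
        if node.op == "empty":
            return 0.0
        if node.op == "gene":
            return float(values.get(node.gene, 0.0))
        child_vals = [walk(c) for c in node.children]
        if node.op == "or":
            return float(np.mean(child_vals))
        best = child_vals[0]
        for v in child_vals[1:]:
            if abs(v) > abs(best) or (abs(v) == abs(best) and v > best):
                best = v
        return best

    return walk(rule)


@dataclass
class ReactionSummary:
    reaction_id: str
    value: float
    data_status: str


def summarize_network(network: MetabolicNetwork, expr: ExpressionChanges,
                      platform_genes: set[str] | None = None
                      ) -> dict[str, ReactionSummary]:
    """Per-reaction summarized values with data-status bookkeeping.

    A reaction has status ``no_gpr`` when non-enzymatic and ``no_data``
    when none of its genes appear on the expression platform (the
    platform defaults to the genes present in the expression table).
    """
    platform = platform_genes if platform_genes is not None else expr.gene_ids()
    values = expr.as_mapping()
    out = {}
    for rxn in network.reactions.values():
        genes = rxn.gpr.genes()
        if not genes:
            out[rxn.id] = ReactionSummary(rxn.id, 0.0, DATA_NO_GPR)
        elif not (genes & platform):
            out[rxn.id] = ReactionSummary(rxn.id, 0.0, DATA_NO_DATA)
        else:
            out[rxn.id] = ReactionSummary(
                rxn.id, summarize_gpr(rxn.gpr, values), DATA_SUMMARIZED
            )
    return out


def default_weights(irrev, summaries: dict[str, ReactionSummary]) -> np.ndarray:
    """Default weight per irreversible column: 1 for biochemical, 2 for
    transport and exchange reactions, doubled for reactions with no gene
    association or no expression data.  Both split directions of a
    reversible reaction share the weight."""
    kinds = classify_reaction_kind(irrev.source)
    w = np.empty(irrev.n_columns)
    for j, (rid, _) in enumerate(irrev.columns):
        base = 1.0 if kinds[rid] == BIOCHEMICAL else 2.0
        if summaries[rid].data_status != DATA_SUMMARIZED:
            base *= 2.0
        w[j] = base
    return w


def timbr_weights(w_default: np.ndarray | float, r: np.ndarray | float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Reciprocal treatment/control weight transforms.

    ``fold = 2**r``; control weights are ``w_default * fold`` and
    treatment weights ``w_default / fold``, so upregulated reactions
    (r > 0) are cheaper to use in the treatment condition and more
    expensive in the control condition.  Identity at r = 0, and
    ``w_control * w_treatment == w_default**2`` always.
    """
    fold = np.power(2.0, r)
    w_default = np.asarray(w_default, dtype=float)
    return w_default / fold, w_default * fold


def condition_weights(irrev, summaries: dict[str, ReactionSummary]
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (w_default, w_treatment, w_control) column vectors."""
    w_def = default_weights(irrev, summaries)
    r = np.array([summaries[rid].value for rid, _ in irrev.columns])
    w_trt, w_ctl = timbr_weights(w_def, r)
    return w_def, w_trt, w_ctl


# --------------------------------------------------------------------
# production scoring

def production_bound(irrev, metabolite_key: str,
                     media: MediaConstraints | None = None,
                     cap: float = PRODUCTION_CAP,
                     fraction: float = FVA_FRACTION) -> float | None:
    """Minimum forced secretion rate for one metabolite.

    Returns ``min(cap, fraction * v_max)`` where ``v_max`` is the FVA
    maximum of the metabolite's exchange (secretion direction) under the
    media; ``None`` marks an unproducible metabolite (v_max ~ 0).
    Raises when the metabolite has no exchange reaction.
    """
    ex = irrev.source.exchange_for(metabolite_key)
    if ex is None:
        raise ValueError(f"metabolite {metabolite_key} has no exchange reaction")
    ranges = fva(irrev.source, [ex], media=media)
    vmax = ranges[ex].max_flux
    if vmax <= UNPRODUCIBLE_TOL:
        return None
    return min(cap, fraction * vmax)


def raw_production_score(demand_treatment: float, demand_control: float
                         ) -> float:
    """Symmetric relative demand difference,
    ``(d_control - d_treatment) / (d_control + d_treatment)``: positive
    when the treatment condition needs less weighted flux, i.e. when
    expression changes favour production."""
    if demand_treatment <= 0 or demand_control <= 0:
        raise ValueError("demands must be positive")
    return (demand_control - demand_treatment) / (
        demand_control + demand_treatment
    )


def normalize_scores(raw: np.ndarray | pd.Series) -> np.ndarray:
    """z-score transform (sample standard deviation, n-1 denominator)
    across the scored metabolites; a zero-variance vector maps to all
    zeros with a warning."""
    arr = np.asarray(raw, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two scored metabolites to normalize")
    sd = arr.std(ddof=1)
    if sd == 0:
        warnings.warn("raw production scores have zero variance; "
                      "normalized scores set to 0", stacklevel=2)
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd


# --------------------------------------------------------------------
# model / results

class Timbr:
    """TIMBR model for one network + one compound's expression changes.

    Parameters
    ----------
    network : MetabolicNetwork
        Model of the organism, in its default (e.g. relaxed
        physiological) bounds or combined with ``media``.
    expression : ExpressionChanges
        Per-gene log2 fold changes with FDR q-values.
    media : MediaConstraints, optional
        Exchange-bound overrides applied both to the FVA used for
        production bounds and to the weighted-flux solves.
    q_threshold : float
        Significance cutoff applied to q-values before summarization.
    """

    def __init__(self, network: MetabolicNetwork,
                 expression: ExpressionChanges,
                 media: MediaConstraints | None = None,
                 q_threshold: float = 0.1,
                 production_cap: float = PRODUCTION_CAP,
                 fva_fraction: float = FVA_FRACTION,
                 platform_genes: set[str] | None = None) -> None:
        self.network = network
        self.expression = expression
        self.media = media
        self.q_threshold = q_threshold
        self.production_cap = production_cap
        self.fva_fraction = fva_fraction
        self.platform_genes = platform_genes

    def fit(self, metabolites: list[str] | None = None) -> "TimbrResults":
        """Run the TIMBR pipeline over the exchangeable metabolites.

        ``metabolites`` restricts scoring to the given metabolite keys
        (default: every metabolite with an exchange reaction).
        """
        net = self.network
        irrev = make_irreversible(net)
        if self.media is not None:
            self.media.validate(net)
            ridx = net.reaction_index
            for rid, (lo, hi) in self.media.bounds.items():
                for j in irrev.columns_for(rid):
                    _, direction = irrev.columns[j]
                    if direction == 1:
                        irrev.lb[j] = max(0.0, lo)
                        irrev.ub[j] = max(0.0, hi)
                    else:
                        irrev.lb[j] = max(0.0, -hi)
                        irrev.ub[j] = max(0.0, -lo)
        filtered = filter_significant(self.expression, self.q_threshold)
        summaries = summarize_network(net, filtered, self.platform_genes)
        w_def, w_trt, w_ctl = condition_weights(irrev, summaries)

        exchanges = net.exchange_reactions()
        if metabolites is None:
            metabolites = list(dict.fromkeys(exchanges.values()))
        rows = []
        for met in metabolites:
            ex = net.exchange_for(met)
            if ex is None:
                raise ValueError(f"metabolite {met} has no exchange reaction")
            bound = production_bound(
                irrev, met, self.media,
                cap=self.production_cap, fraction=self.fva_fraction,
            )
            if bound is None:
                rows.append({"metabolite": met, "exchange": ex,
                             "min_rate": np.nan, "demand_treatment": np.nan,
                             "demand_control": np.nan, "raw_score": np.nan,
                             "status": STATUS_SKIPPED})
                continue
            col = irrev.column(ex, 1)
            trt = min_weighted_flux(irrev, w_trt, col, bound)
            ctl = min_weighted_flux(irrev, w_ctl, col, bound)
            if trt.status != OPTIMAL or ctl.status != OPTIMAL:
                rows.append({"metabolite": met, "exchange": ex,
                             "min_rate": bound, "demand_treatment": np.nan,
                             "demand_control": np.nan, "raw_score": np.nan,
                             "status": STATUS_INFEASIBLE})
                continue
            raw = raw_production_score(trt.demand, ctl.demand)
            rows.append({"metabolite": met, "exchange": ex,
                         "min_rate": bound, "demand_treatment": trt.demand,
                         "demand_control": ctl.demand, "raw_score": raw,
                         "status": STATUS_SCORED})
        scores = pd.DataFrame(
            rows, columns=["metabolite", "exchange", "min_rate",
                           "demand_treatment", "demand_control",
                           "raw_score", "status"],
        )
        scored = scores["status"] == STATUS_SCORED
        scores["production_score"] = np.nan
        if scored.sum() >= 2:
            scores.loc[scored, "production_score"] = normalize_scores(
                scores.loc[scored, "raw_score"].to_numpy()
            )
        elif scored.sum() == 1:
            scores.loc[scored, "production_score"] = 0.0
        return TimbrResults(model=self, scores=scores,
                            weights=pd.DataFrame({
                                "reaction_id": [rid for rid, _ in irrev.columns],
                                "direction": [d for _, d in irrev.columns],
                                "w_default": w_def,
                                "w_treatment": w_trt,
                                "w_control": w_ctl,
                            }))


@dataclass
class TimbrResults:
    """Fitted TIMBR production scores for one compound and organism."""

    model: Timbr
    scores: pd.DataFrame
    weights: pd.DataFrame

    @property
    def scored(self) -> pd.DataFrame:
        return self.scores[self.scores["status"] == STATUS_SCORED]

    def score_series(self) -> pd.Series:
        return self.scored.set_index("metabolite")["production_score"]

    def rank_of(self, metabolite: str) -> int:
        """1-based rank of a metabolite by descending production score."""
        s = self.score_series().sort_values(ascending=False)
        return int(np.where(s.index == metabolite)[0][0]) + 1

    def classify(self, lower_q: float = 0.25, upper_q: float = 0.75
                 ) -> pd.Series:
        return classify_predictions(self.score_series(), lower_q, upper_q)

    def summary(self) -> str:
        expr = self.model.expression
        lines = [
            "TIMBR production scores",
            "=" * 54,
            f"compound:  {expr.compound or '-'}    "
            f"organism: {expr.organism or '-'}",
            f"network:   {self.model.network.id} "
            f"({len(self.model.network.reactions)} reactions, "
            f"{len(self.model.network.genes)} genes)",
            f"metabolites scored: {len(self.scored)} of {len(self.scores)}",
            "-" * 54,
        ]
        table = self.scores.sort_values(
            "production_score", ascending=False, na_position="last"
        )
        lines.append(f"{'metabolite':<18}{'demand_trt':>11}{'demand_ctl':>11}"
                     f"{'score':>9}  status")
        for row in table.itertuples():
            dt = f"{row.demand_treatment:.3f}" if np.isfinite(row.demand_treatment) else "-"
            dc = f"{row.demand_control:.3f}" if np.isfinite(row.demand_control) else "-"
            ps = f"{row.production_score:+.3f}" if np.isfinite(row.production_score) else "-"
            lines.append(f"{row.metabolite:<18}{dt:>11}{dc:>11}{ps:>9}  {row.status}")
        return "\n".join(lines)


# --------------------------------------------------------------------
# cross-species comparison and validation

@dataclass
class CorrelationRecord:
    name: str
    n: int
    r: float
    p_value: float
    q_value: float | None = None
    label: str | None = None  # positive | uncorrelated | negative


def compare_species(scores_a: pd.Series, scores_b: pd.Series,
                    name: str = "") -> CorrelationRecord:
    """Pearson correlation of paired production scores (e.g. rat vs
    human for one compound) with a two-sided p-value."""
    joined = pd.concat([scores_a, scores_b], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        return CorrelationRecord(name, n, np.nan, np.nan, label="undefined")
    r, p = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
    return CorrelationRecord(name, n, float(r), float(p))


def classify_correlations(records: list[CorrelationRecord],
                          fdr: float = 0.1) -> list[CorrelationRecord]:
    """Benjamini–Hochberg adjust correlation p-values across a family of
    compounds and label each one positive / uncorrelated / negative."""
    from statsmodels.stats.multitest import multipletests

    defined = [rec for rec in records if np.isfinite(rec.p_value)]
    if defined:
        _, qvals, _, _ = multipletests(
            [rec.p_value for rec in defined], method="fdr_bh"
        )
        for rec, q in zip(defined, qvals):
            rec.q_value = float(q)
            if q < fdr:
                rec.label = "positive" if rec.r > 0 else "negative"
            else:
                rec.label = "uncorrelated"
    return records


ELEVATED = "elevated"
REDUCED = "reduced"
UNCHANGED = "unchanged"


def classify_predictions(scores: pd.Series, lower_q: float = 0.25,
                         upper_q: float = 0.75) -> pd.Series:
    """Call each metabolite elevated / reduced / unchanged by whether
    its production score falls in the top or bottom quantile of the full
    scored set (boundaries inclusive)."""
    lo = scores.quantile(lower_q)
    hi = scores.quantile(upper_q)
    calls = pd.Series(UNCHANGED, index=scores.index, dtype=object)
    calls[scores >= hi] = ELEVATED
    calls[scores <= lo] = REDUCED
    return calls


@dataclass
class CallEvaluation:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    mcc: float | None


def evaluate_calls(calls: pd.Series, truth: pd.Series) -> CallEvaluation:
    """Confusion-matrix evaluation of biomarker calls.

    Positives are experimentally changed metabolites (truth elevated or
    reduced); a prediction counts as positive when called elevated or
    reduced.  Reports sensitivity, specificity and Matthews correlation
    coefficient (None when the MCC denominator vanishes).
    """
    joined = pd.concat([calls.rename("call"), truth.rename("truth")],
                       axis=1, join="inner")
    pos = joined["truth"] != UNCHANGED
    called = joined["call"] != UNCHANGED
    tp = int((pos & called).sum())
    fp = int((~pos & called).sum())
    tn = int((~pos & ~called).sum())
    fn = int((pos & ~called).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else None
    return CallEvaluation(tp, fp, tn, fn, sens, spec,
                          float(mcc) if mcc is not None else None)
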