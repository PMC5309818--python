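"""Consensus orthology scoring and GPR translation between species.

Human→rat orthologue annotations collected from five genomics databases
(RGD, Homologene, Ensembl, KEGG, UniProt) are aggregated into one table
with a database score (1–5, the number of databases annotating a pair),
filtered for promiscuous mappings, ranked per human gene by database
score then gene confidence, and thresholded into a consensus subset.
The consensus table then drives translation of human GPR rules into
rat GPR rules, replacing each human leaf by the OR of its retained rat
orthologues and reporting every lossy event (dropped isozyme, broken
enzyme complex, fully orphaned rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .gpr import GPRRule
from .network import MetabolicNetwork

SOURCES = ("rgd", "homologene", "ensembl", "kegg", "uniprot")

#: translation event severities, mildest first
EVENT_OK = "ok"
EVENT_ISOZYME_DROPPED = "isozyme_dropped"
EVENT_BROKEN_COMPLEX = "broken_complex"
EVENT_ORPHANED = "orphaned"
_SEVERITY = (EVENT_OK, EVENT_ISOZYME_DROPPED, EVENT_BROKEN_COMPLEX, EVENT_ORPHANED)


class OrthologyError(ValueError):
    pass


@dataclass
class OrthologyTable:
    """Aggregated orthologue pairs with per-database flags.

    ``data`` columns: ``human_gene, rat_gene``, one boolean column per
    source in :data:`SOURCES`, ``db_score``, optional ``human_conf`` /
    ``rat_conf`` ordinal confidence columns and, after ranking,
    ``rank`` (1 = best orthologue of a human gene).
    """

    data: pd.DataFrame
    provenance: str = ""

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    @property
    def n_human_genes(self) -> int:
        return self.data["human_gene"].nunique()

    @property
    def n_rat_genes(self) -> int:
        return self.data["rat_gene"].nunique()

    def mapping(self) -> dict[str, list[str]]:
        """human gene -> rat orthologues, in rank order when ranked."""
        df = self.data
        if "rank" in df.columns:
            df = df.sort_values(["human_gene", "rank"])
        return {
            h: list(g["rat_gene"])
            for h, g in df.groupby("human_gene", sort=False)
        }


def aggregate_pairs(per_database_tables: Mapping[str, pd.DataFrame],
                    confidences: pd.DataFrame | None = None) -> OrthologyTable:
    """Union per-database ``(human_gene, rat_gene)`` tables into one
    flagged table with ``db_score`` = number of annotating databases.

    ``confidences`` may supply ``gene_id, conf`` rows used to attach
    ``human_conf``/``rat_conf`` ordinal columns.
    """
    unknown = set(per_database_tables) - set(SOURCES)
    if unknown:
        raise OrthologyError(f"unknown orthology sources: {sorted(unknown)}")
    frames = []
    for source, df in per_database_tables.items():
        part = df[["human_gene", "rat_gene"]].astype(str).drop_duplicates()
        part = part.assign(source=source)
        frames.append(part)
    if not frames:
        raise OrthologyError("no orthology tables supplied")
    long = pd.concat(frames, ignore_index=True)
    wide = (
        long.assign(flag=True)
        .pivot_table(index=["human_gene", "rat_gene"], columns="source",
                     values="flag", aggfunc="any", fill_value=False)
        .reindex(columns=list(SOURCES), fill_value=False)
        .reset_index()
    )
    wide.columns.name = None
    wide["db_score"] = wide[list(SOURCES)].sum(axis=1).astype(int)
    if confidences is not None:
        conf = confidences.set_index("gene_id")["conf"]
        wide["human_conf"] = wide["human_gene"].map(conf)
        wide["rat_conf"] = wide["rat_gene"].map(conf)
    return OrthologyTable(data=wide)


def exclude_promiscuous(table: OrthologyTable,
                        max_orthologs: int = 10) -> OrthologyTable:
    """Drop every human gene mapped to ``max_orthologs`` or more rat
    orthologues (boundary inclusive: ten partners means exclusion at the
    default)."""
    if max_orthologs < 1:
        raise OrthologyError("max_orthologs must be >= 1")
    counts = table.data.groupby("human_gene")["rat_gene"].transform("count")
    kept = table.data[counts < max_orthologs].reset_index(drop=True)
    return OrthologyTable(data=kept, provenance=table.provenance)


def rank_orthologs(table: OrthologyTable) -> OrthologyTable:
    """Assign orthology ranks within each human gene.

    Pairs are prioritized by database score (descending), then rat gene
    confidence (descending, missing = lowest), then rat gene id
    (ascending) as a deterministic final tie-break.
    """
    df = table.data.copy()
    conf = df["rat_conf"] if "rat_conf" in df.columns else pd.Series(
        np.nan, index=df.index
    )
    conf = pd.to_numeric(conf, errors="coerce").fillna(-np.inf)
    order = df.assign(_conf=conf).sort_values(
        ["human_gene", "db_score", "_conf", "rat_gene"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    order["rank"] = order.groupby("human_gene").cumcount() + 1
    df = order.drop(columns="_conf").sort_index().reset_index(drop=True)
    return OrthologyTable(data=df, provenance=table.provenance)


def filter_consensus(table: OrthologyTable, min_dbs: int = 2,
                     max_rank: int = 2) -> OrthologyTable:
    """Consensus subset: pairs annotated in at least ``min_dbs``
    databases with per-human-gene rank at most ``max_rank``."""
    df = table.data
    if "rank" not in df.columns:
        df = rank_orthologs(table).data
    kept = df[(df["db_score"] >= min_dbs) & (df["rank"] <= max_rank)]
    return OrthologyTable(data=kept.reset_index(drop=True),
                          provenance=table.provenance)


# --------------------------------------------------------------------
# GPR translation

@dataclass
class TranslationReport:
    """Per-rule record of lossy translation events."""

    events: list[str] = field(default_factory=list)

    @property
    def status(self) -> str:
        worst = EVENT_OK
        for ev in self.events:
            if _SEVERITY.index(ev) > _SEVERITY.index(worst):
                worst = ev
        return worst

    def add(self, event: str) -> None:
        self.events.append(event)


def _translate_node(rule: GPRRule, mapping: dict[str, list[str]],
                    report: TranslationReport,
                    parent_op: str | None) -> GPRRule | None:
    if rule.op == "gene":
        rats = mapping.get(rule.gene, [])
        if not rats:
            if parent_op == "and":
                report.add(EVENT_BROKEN_COMPLEX)
            elif parent_op == "or":
                report.add(EVENT_ISOZYME_DROPPED)
            return None
        return GPRRule.or_([GPRRule.leaf(r) for r in rats])
    translated = [
        _translate_node(c, mapping, report, rule.op) for c in rule.children
    ]
    kept = [t for t in translated if t is not None]
    if not kept:
        return None
    if rule.op == "and":
        return GPRRule.and_(kept)
    return GPRRule.or_(kept)


def translate_gpr(rule: GPRRule,
                  table: OrthologyTable) -> tuple[GPRRule, TranslationReport]:
    """Translate a human GPR rule into a rat GPR rule.

    Each human leaf becomes the OR of its retained rat orthologues.  A
    leaf with no orthologue is dropped: from an OR node the remaining
    isozymes stand (recorded ``isozyme_dropped``); from an AND node the
    complex degrades to its mapped subunits (``broken_complex``).  A
    rule losing every leaf becomes empty and is flagged ``orphaned``.
    """
    report = TranslationReport()
    if rule.is_empty:
        return rule, report
    mapping = table.mapping()
    out = _translate_node(rule, mapping, report, None)
    if out is None:
        report.add(EVENT_ORPHANED)
        return GPRRule.empty(), report
    return out, report


def translate_network(network: MetabolicNetwork, table: OrthologyTable,
                      model_id: str | None = None,
                      organism: str = "rat"
                      ) -> tuple[MetabolicNetwork, pd.DataFrame]:
    """Translate every GPR of a network, returning the draft network of
    the target species and a per-reaction report table
    (``reaction_id, status``)."""
    draft = MetabolicNetwork(model_id or f"{network.id}_draft")
    draft.compartments = set(network.compartments)
    draft.objective_id = network.objective_id
    for met in network.metabolites.values():
        draft.add_metabolite(met)
    rows = []
    for rxn in network.reactions.values():
        new_rule, report = translate_gpr(rxn.gpr, table)
        from .network import Reaction

        draft.add_reaction(
            Reaction(rxn.id, dict(rxn.stoichiometry), rxn.lb, rxn.ub,
                     new_rule, rxn.subsystem),
            organism=organism,
        )
        rows.append({"reaction_id": rxn.id, "status": report.status})
    return draft, pd.DataFrame(rows, columns=["reaction_id", "status"])


def read_pair_tables(paths: Mapping[str, str | "Path"]) -> OrthologyTable:
    """Read per-source tab-delimited pair tables and aggregate them."""
    tables = {
        source: pd.read_csv(path, sep="\t", dtype=str)
        for source, path in paths.items()
    }
    return aggregate_pairs(tables)


def read_aggregated_table(path) -> OrthologyTable:
    """Read a pre-aggregated five-flag table (consensus layout)."""
    df = pd.read_csv(path, sep="\t")
    df["human_gene"] = df["human_gene"].astype(str)
    df["rat_gene"] = df["rat_gene"].astype(str)
    for source in SOURCES:
        if source not in df.columns:
            raise OrthologyError(f"aggregated table missing column {source!r}")
        df[source] = df[source].astype(bool)
    if "db_score" not in df.columns:
        df["db_score"] = df[list(SOURCES)].sum(axis=1).astype(int)
    if df.duplicated(["human_gene", "rat_gene"]).any():
        raise OrthologyError("duplicate (human_gene, rat_gene) rows")
    return OrthologyTable(data=df)
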