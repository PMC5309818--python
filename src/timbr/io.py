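"""Model and table I/O.

Two model formats are supported: SBML Level 3 with the FBC package
(bounds, gene products, GPR associations), read and written through
libSBML, and a tab-delimited spreadsheet dialect with one reaction per
row (``id, equation, gpr, lb, ub, subsystem``) where equations use
``=>`` (irreversible) or ``<=>`` (reversible) and metabolite tokens are
``id[compartment]``.  Also here: loaders for media constraint tables,
metabolic-task files (a plain-text block dialect plus the RAVEN-style
Excel layout), differential-expression tables and IEM case tables.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .gpr import GPRRule, parse_gpr
from .network import MetabolicNetwork, Metabolite, NetworkError, Reaction

# --------------------------------------------------------------------
# equation strings

_MET_RE = re.compile(r"^(?:(?P<coef>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?"
                     r"(?P<id>[^\[\]\s]+)\[(?P<comp>[^\[\]\s]+)\]$")


def _parse_side(side: str) -> list[tuple[float, str, str]]:
    side = side.strip()
    if not side:
        return []
    out = []
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            continue
        m = _MET_RE.match(term)
        if not m:
            raise NetworkError(f"malformed metabolite term {term!r}")
        coef = float(m.group("coef")) if m.group("coef") else 1.0
        out.append((coef, m.group("id"), m.group("comp")))
    return out


def parse_equation(equation: str) -> tuple[dict[tuple[str, str], float], bool]:
    """Parse an equation string into ``{(met_id, compartment): coef}`` and
    a reversibility flag.  Coefficients are negative on the left side."""
    if "<=>" in equation:
        left, right = equation.split("<=>", 1)
        reversible = True
    elif "=>" in equation:
        left, right = equation.split("=>", 1)
        reversible = False
    else:
        raise NetworkError(f"equation {equation!r} lacks '=>' or '<=>'")
    stoich: dict[tuple[str, str], float] = {}
    for coef, mid, comp in _parse_side(left):
        stoich[(mid, comp)] = stoich.get((mid, comp), 0.0) - coef
    for coef, mid, comp in _parse_side(right):
        stoich[(mid, comp)] = stoich.get((mid, comp), 0.0) + coef
    if not stoich:
        raise NetworkError(f"equation {equation!r} has no metabolites")
    return stoich, reversible


def format_equation(rxn: Reaction) -> str:
    def fmt(key: str, coef: float) -> str:
        c = abs(coef)
        return key if c == 1.0 else f"{c:g} {key}"

    left = [fmt(k, c) for k, c in rxn.stoichiometry.items() if c < 0]
    right = [fmt(k, c) for k, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<=>" if rxn.reversible else "=>"
    return f"{' + '.join(left)} {arrow} {' + '.join(right)}".strip()


# --------------------------------------------------------------------
# spreadsheet model dialect

_TABLE_COLUMNS = ["id", "equation", "gpr", "lb", "ub", "subsystem"]


def read_table_model(path: str | Path, model_id: str | None = None,
                     organism: str = "other") -> MetabolicNetwork:
    """Read the tab-delimited model dialect into a network.

    Malformed rows (bad stoichiometry, duplicate ids, unparsable GPRs)
    are collected and reported together in one :class:`NetworkError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise NetworkError(f"model table missing columns: {missing}")
    net = MetabolicNetwork(model_id or path.stem)
    errors: list[str] = []
    for _, row in df.iterrows():
        rid = row["id"].strip()
        try:
            stoich, reversible = parse_equation(row["equation"])
            for (mid, comp) in stoich:
                key = f"{mid}[{comp}]"
                if key not in net.metabolites:
                    net.add_metabolite(Metabolite(mid, comp))
            lb = float(row["lb"]) if row["lb"] != "" else (-1000.0 if reversible else 0.0)
            ub = float(row["ub"]) if row["ub"] != "" else 1000.0
            if not reversible and lb < 0:
                lb = 0.0
            rxn = Reaction(
                id=rid,
                stoichiometry={f"{m}[{c}]": v for (m, c), v in stoich.items()},
                lb=lb, ub=ub,
                gpr=parse_gpr(row["gpr"]),
                subsystem=row["subsystem"],
            )
            net.add_reaction(rxn, organism=organism)
        except (NetworkError, ValueError) as exc:
            errors.append(f"{rid}: {exc}")
    if errors:
        raise NetworkError("model table load failed:\n" + "\n".join(errors))
    return net


def write_table_model(network: MetabolicNetwork, path: str | Path) -> None:
    rows = []
    for rxn in network.reactions.values():
        rows.append({
            "id": rxn.id,
            "equation": format_equation(rxn),
            "gpr": rxn.gpr.to_string(),
            "lb": rxn.lb,
            "ub": rxn.ub,
            "subsystem": rxn.subsystem,
        })
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------
# SBML Level 3 + FBC

def _escape_sid(raw: str) -> str:
    """Escape an arbitrary identifier into a valid SBML SId fragment."""
    out = []
    for ch in raw:
        if ch.isalnum() or ch == "_":
            out.append(ch)
        else:
            out.append(f"__{ord(ch)}__")
    return "".join(out)


def _unescape_sid(sid: str) -> str:
    return re.sub(r"__(\d+)__", lambda m: chr(int(m.group(1))), sid)


def write_sbml(network: MetabolicNetwork, path: str | Path) -> None:
    """Write a network as SBML Level 3 Version 1 with FBC version 2."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(_escape_sid(network.id))
    mplug = model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp in sorted(network.compartments):
        c = model.createCompartment()
        c.setId(f"C_{_escape_sid(comp)}")
        c.setConstant(True)

    for met in network.metabolites.values():
        s = model.createSpecies()
        s.setId(f"M_{_escape_sid(met.id)}__IN__{_escape_sid(met.compartment)}")
        s.setName(met.name or met.id)
        s.setCompartment(f"C_{_escape_sid(met.compartment)}")
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)

    for gene in network.genes.values():
        gp = mplug.createGeneProduct()
        gp.setId(f"G_{_escape_sid(gene.id)}")
        gp.setLabel(gene.id)
        gp.setName(gene.organism)

    def bound_param(rid: str, which: str, value: float) -> str:
        pid = f"B_{which}_{_escape_sid(rid)}"
        p = model.createParameter()
        p.setId(pid)
        p.setValue(float(value))
        p.setConstant(True)
        return pid

    def build_assoc(parent, rule: GPRRule) -> None:
        if rule.op == "gene":
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(f"G_{_escape_sid(rule.gene)}")
        elif rule.op == "and":
            node = parent.createAnd()
            for child in rule.children:
                build_assoc(node, child)
        elif rule.op == "or":
            node = parent.createOr()
            for child in rule.children:
                build_assoc(node, child)

    for rxn in network.reactions.values():
        r = model.createReaction()
        r.setId(f"R_{_escape_sid(rxn.id)}")
        r.setFast(False)
        r.setReversible(rxn.lb < 0)
        if rxn.subsystem:
            r.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>"
            )
        for key, coef in rxn.stoichiometry.items():
            met = network.metabolites[key]
            sid = f"M_{_escape_sid(met.id)}__IN__{_escape_sid(met.compartment)}"
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.id, "lb", rxn.lb))
        rplug.setUpperFluxBound(bound_param(rxn.id, "ub", rxn.ub))
        if not rxn.gpr.is_empty:
            assoc = rplug.createGeneProductAssociation()
            build_assoc(assoc, rxn.gpr)

    if network.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(f"R_{_escape_sid(network.objective_id)}")
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _assoc_to_rule(assoc, label_of: dict[str, str]):
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        return GPRRule.leaf(label_of[assoc.getGeneProduct()])
    children = [
        _assoc_to_rule(assoc.getAssociation(i), label_of)
        for i in range(assoc.getNumAssociations())
    ]
    if isinstance(assoc, libsbml.FbcAnd):
        return GPRRule.and_(children)
    if isinstance(assoc, libsbml.FbcOr):
        return GPRRule.or_(children)
    raise NetworkError(f"unsupported GPR association node {assoc}")


def read_sbml(path: str | Path) -> MetabolicNetwork:
    """Read an SBML Level 3 FBC model into a network."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise NetworkError(f"SBML parse error: {err.getMessage()}")
    model = doc.getModel()
    if model is None:
        raise NetworkError("SBML file contains no model")
    mplug = model.getPlugin("fbc")
    net = MetabolicNetwork(_unescape_sid(model.getId()) or "model")

    comp_name = {}
    for i in range(model.getNumCompartments()):
        c = model.getCompartment(i)
        comp_name[c.getId()] = _unescape_sid(c.getId()[2:]) \
            if c.getId().startswith("C_") else c.getId()
        net.add_compartment(comp_name[c.getId()])

    species_key = {}
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        comp = comp_name[s.getCompartment()]
        sid = s.getId()
        raw = sid[2:] if sid.startswith("M_") else sid
        marker = f"__IN__{_escape_sid(comp)}"
        if raw.endswith(marker):
            raw = raw[: -len(marker)]
        mid = _unescape_sid(raw)
        met = Metabolite(mid, comp, name=s.getName() or mid)
        net.add_metabolite(met)
        species_key[sid] = met.key

    label_of = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or _unescape_sid(gp.getId()[2:])
            label_of[gp.getId()] = label
            from .network import Gene
            net.add_gene(Gene(label, gp.getName() or "other"))

    def param_value(pid: str) -> float:
        p = model.getParameter(pid)
        if p is None:
            raise NetworkError(f"missing bound parameter {pid}")
        return p.getValue()

    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        rid = _unescape_sid(r.getId()[2:]) if r.getId().startswith("R_") else r.getId()
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            key = species_key[ref.getSpecies()]
            stoich[key] = stoich.get(key, 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            key = species_key[ref.getSpecies()]
            stoich[key] = stoich.get(key, 0.0) + ref.getStoichiometry()
        rplug = r.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = param_value(rplug.getLowerFluxBound())
            ub = param_value(rplug.getUpperFluxBound())
        else:  # fall back on the reversible flag
            lb, ub = (-1000.0, 1000.0) if r.getReversible() else (0.0, 1000.0)
        rule = GPRRule.empty()
        if rplug is not None and rplug.isSetGeneProductAssociation():
            rule = _assoc_to_rule(
                rplug.getGeneProductAssociation().getAssociation(), label_of
            )
        subsystem = ""
        if r.isSetNotes():
            m = re.search(r"SUBSYSTEM:\s*([^<]+)", r.getNotesString())
            if m:
                subsystem = m.group(1).strip()
        net.add_reaction(
            Reaction(rid, stoich, lb, ub, rule, subsystem), register_genes=True
        )

    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            target = obj.getFluxObjective(0).getReaction()
            net.objective_id = _unescape_sid(target[2:]) \
                if target.startswith("R_") else target
    return net


# --------------------------------------------------------------------
# media, tasks, expression, IEM cases

def read_media_table(path: str | Path, label: str = "custom"):
    """Media table: tab-delimited with columns ``reaction_id, lb, ub``."""
    from .engine import MediaConstraints

    df = pd.read_csv(path, sep="\t", dtype={"reaction_id": str})
    bounds = {
        str(row.reaction_id): (float(row.lb), float(row.ub))
        for row in df.itertuples()
    }
    return MediaConstraints(bounds=bounds, label=label)


def write_media_table(media, path: str | Path) -> None:
    rows = [
        {"reaction_id": rid, "lb": lb, "ub": ub}
        for rid, (lb, ub) in media.bounds.items()
    ]
    pd.DataFrame(rows, columns=["reaction_id", "lb", "ub"]).to_csv(
        path, sep="\t", index=False
    )


def read_task_file(path: str | Path):
    """Plain-text task dialect.

    Blocks are introduced by ``TASK <id> <description>``; subsequent
    ``IN met[comp] lb ub`` / ``OUT met[comp] lb ub`` rows list allowed
    uptakes and required secretions, and an optional ``SHOULD_FAIL`` row
    marks a task asserting a known incapability.
    """
    from .engine import TaskDefinition

    tasks: list[TaskDefinition] = []
    current = None

    def close() -> None:
        if current is not None:
            tasks.append(TaskDefinition(**current))

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(None, 3)
        tag = parts[0].upper()
        if tag == "TASK":
            close()
            current = {
                "id": parts[1],
                "description": parts[2] if len(parts) > 2 else "",
                "inputs": [], "outputs": [], "should_fail": False,
            }
        elif tag in ("IN", "OUT"):
            if current is None:
                raise ValueError(f"{tag} row before any TASK row")
            met, lo, hi = parts[1], float(parts[2]), float(parts[3])
            current["inputs" if tag == "IN" else "outputs"].append((met, lo, hi))
        elif tag == "SHOULD_FAIL":
            current["should_fail"] = True
        else:
            raise ValueError(f"unrecognized task row {line!r}")
    close()
    return tasks


def write_task_file(tasks, path: str | Path) -> None:
    lines = []
    for task in tasks:
        lines.append(f"TASK\t{task.id}\t{task.description}")
        for met, lo, hi in task.inputs:
            lines.append(f"IN\t{met}\t{lo:g}\t{hi:g}")
        for met, lo, hi in task.outputs:
            lines.append(f"OUT\t{met}\t{lo:g}\t{hi:g}")
        if task.should_fail:
            lines.append("SHOULD_FAIL")
    Path(path).write_text("\n".join(lines) + "\n")


def read_raven_tasks(path: str | Path):
    """Load a RAVEN-style Excel task sheet.

    Expected columns (first sheet): ID, DESCRIPTION, IN, IN LB, IN UB,
    OUT, OUT LB, OUT UB, SHOULD FAIL.  Multiple metabolites within one
    cell are separated by semicolons; blank ID rows continue the
    previous task.
    """
    from .engine import TaskDefinition

    df = pd.read_excel(path, dtype=str).fillna("")
    df.columns = [str(c).strip().upper() for c in df.columns]
    tasks: list[TaskDefinition] = []
    current = None
    for _, row in df.iterrows():
        if row.get("ID", ""):
            if current is not None:
                tasks.append(TaskDefinition(**current))
            current = {
                "id": row["ID"], "description": row.get("DESCRIPTION", ""),
                "inputs": [], "outputs": [],
                "should_fail": row.get("SHOULD FAIL", "").strip().lower()
                in ("1", "true", "yes"),
            }
        if current is None:
            continue
        for side, col_lb, col_ub, dest in (
            ("IN", "IN LB", "IN UB", "inputs"),
            ("OUT", "OUT LB", "OUT UB", "outputs"),
        ):
            mets = [m.strip() for m in row.get(side, "").split(";") if m.strip()]
            lbs = [x.strip() for x in row.get(col_lb, "").split(";")]
            ubs = [x.strip() for x in row.get(col_ub, "").split(";")]
            for k, met in enumerate(mets):
                lo = float(lbs[k]) if k < len(lbs) and lbs[k] else 0.0
                hi = float(ubs[k]) if k < len(ubs) and ubs[k] else 1000.0
                current[dest].append((met, lo, hi))
    if current is not None:
        tasks.append(TaskDefinition(**current))
    return tasks


def read_expression_table(path: str | Path, compound: str = "",
                          organism: str = ""):
    """Expression table: tab-delimited ``gene_id, log2fc, qvalue``."""
    from .scoring import ExpressionChanges

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return ExpressionChanges(
        data=df[["gene_id", "log2fc", "qvalue"]].copy(),
        compound=compound, organism=organism,
    )


def read_iem_cases(path: str | Path):
    """IEM case table: ``iem_id, gene_ids`` (semicolon-separated),
    ``biomarker_id, expected_direction`` — one biomarker per row."""
    from .iem import IEMCase

    df = pd.read_csv(path, sep="\t", dtype=str)
    cases: dict[str, IEMCase] = {}
    for row in df.itertuples():
        genes = [g.strip() for g in row.gene_ids.split(";") if g.strip()]
        case = cases.get(row.iem_id)
        if case is None:
            case = IEMCase(id=row.iem_id, genes=genes, biomarkers=[])
            cases[row.iem_id] = case
        case.biomarkers.append((row.biomarker_id, row.expected_direction))
    return list(cases.values())
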