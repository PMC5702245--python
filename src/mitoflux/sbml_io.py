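"""Model serialisation: SBML (modern and legacy dialects) and a TSV table.

The TSV dialect mirrors a curation spreadsheet: one reaction per row with a
human-readable equation string, bounds, gene mappings and the provenance
columns (directionality evidence, localisation evidence, heart expression).
Metabolite attributes ride along in ``#!`` header lines so a table file
round-trips to an identical model.

SBML writing defaults to Level 3 with the ``fbc`` package (flux bounds,
objective, charges, gene products); the legacy dialect is Level 2 Version 1
with bounds and objective coefficients in kinetic-law parameters, matching
how older curated models were distributed.  Reading accepts both.
"""

from __future__ import annotations

import json
import re
from typing import Dict, List, Optional, Tuple
from xml.sax import saxutils

import libsbml

from .model_core import (
    BOUNDARY,
    BOUNDARY_EXCHANGE,
    CATEGORIES,
    COMPARTMENT_SUFFIX,
    CYTOSOLIC,
    DEFAULT_BOUND,
    METABOLIC,
    MITOCHONDRIAL,
    MITO_TRANSPORT,
    PSEUDO,
    Metabolite,
    ModelNetwork,
    Reaction,
)

__all__ = ["read_table", "write_table", "read_sbml", "write_sbml", "TableParseError"]

_ANNOTATION_COLUMNS = (
    "directionality_evidence",
    "localisation_evidence",
    "heart_expression",
)
_HEADER = (
    "id",
    "equation",
    "lower",
    "upper",
    "genes",
    "subsystem",
    "category",
    *_ANNOTATION_COLUMNS,
    "other_annotation",
)

_COMPARTMENT_CODE = {CYTOSOLIC: "c", MITOCHONDRIAL: "m", BOUNDARY: "b"}
_CODE_COMPARTMENT = {
    "c": CYTOSOLIC,
    "cytosol": CYTOSOLIC,
    "cytosolic": CYTOSOLIC,
    "m": MITOCHONDRIAL,
    "mito": MITOCHONDRIAL,
    "mitochondrion": MITOCHONDRIAL,
    "mitochondrial": MITOCHONDRIAL,
    "b": BOUNDARY,
    "e": BOUNDARY,
    "boundary": BOUNDARY,
    "extracellular": BOUNDARY,
}


class TableParseError(ValueError):
    """Malformed reaction-table input; carries line number and token."""


class SBMLReadError(ValueError):
    """Structured SBML validation/read failure."""


# ---------------------------------------------------------------------------
# equation grammar
# ---------------------------------------------------------------------------


def _format_side(terms: List[Tuple[str, float]]) -> str:
    parts = []
    for met, coeff in terms:
        parts.append(met if coeff == 1 else f"{coeff:.15g} {met}")
    return " + ".join(parts)


def format_equation(reaction: Reaction) -> str:
    left = [(m, -c) for m, c in reaction.stoichiometry.items() if c < 0]
    right = [(m, c) for m, c in reaction.stoichiometry.items() if c > 0]
    arrow = "<=>" if reaction.lower_bound < 0 else "->"
    return f"{_format_side(left)} {arrow} {_format_side(right)}".strip()


def parse_equation(text: str, line: Optional[int] = None) -> Tuple[Dict[str, float], bool]:
    """Parse ``"a A + 0.82 B -> C"`` into a stoichiometry map.

    Returns (stoichiometry, reversible).  Coefficients are whitespace
    separated decimals; a bare metabolite token means coefficient 1.
    """
    where = f" (line {line})" if line is not None else ""
    if "<=>" in text:
        arrow, reversible = "<=>", True
    elif "->" in text:
        arrow, reversible = "->", False
    else:
        raise TableParseError(f"no reaction arrow in {text!r}{where}")
    left, _, right = text.partition(arrow)
    stoich: Dict[str, float] = {}

    def consume(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for token in side.split(" + "):
            token = token.strip()
            if not token:
                raise TableParseError(f"empty term in {text!r}{where}")
            pieces = token.split()
            if len(pieces) == 1:
                met, coeff = pieces[0], 1.0
            elif len(pieces) == 2:
                try:
                    coeff = float(pieces[0])
                except ValueError:
                    raise TableParseError(
                        f"bad coefficient {pieces[0]!r} in {text!r}{where}"
                    ) from None
                met = pieces[1]
            else:
                raise TableParseError(f"bad term {token!r} in {text!r}{where}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    consume(left, -1.0)
    consume(right, +1.0)
    return {m: c for m, c in stoich.items() if c != 0}, reversible


def _format_genes(genes: List[Tuple[str, str]]) -> str:
    return ";".join(f"{sym}|{acc}" for sym, acc in genes)


def _parse_genes(text: str) -> List[Tuple[str, str]]:
    out: List[Tuple[str, str]] = []
    for chunk in filter(None, (t.strip() for t in text.split(";"))):
        sym, _, acc = chunk.partition("|")
        out.append((sym, acc))
    return out


# ---------------------------------------------------------------------------
# TSV table
# ---------------------------------------------------------------------------


def write_table(model: ModelNetwork, path: str) -> None:
    lines = []
    for met in model.metabolites.values():
        lines.append(
            "#! metabolite\t"
            + "\t".join(
                [
                    met.id,
                    met.name,
                    met.compartment,
                    str(met.charge),
                    met.formula or "",
                    "1" if met.is_pmf else "0",
                ]
            )
        )
    if model.objective_id:
        lines.append(f"#! objective\t{model.objective_id}")
    if model.notes:
        lines.append(f"#! notes\t{model.notes}")
    lines.append("\t".join(_HEADER))
    for rxn in model.reactions.values():
        ann = dict(rxn.annotation)
        row = [
            rxn.id,
            format_equation(rxn),
            f"{rxn.lower_bound:.15g}",
            f"{rxn.upper_bound:.15g}",
            _format_genes(rxn.genes),
            rxn.subsystem,
            rxn.category,
        ]
        row += [ann.pop(col, "") for col in _ANNOTATION_COLUMNS]
        row.append(json.dumps(ann, sort_keys=True) if ann else "")
        lines.append("\t".join(row))
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def _metabolite_from_suffix(met_id: str) -> Metabolite:
    for compartment, suffix in COMPARTMENT_SUFFIX.items():
        if met_id.endswith(suffix):
            return Metabolite(met_id, met_id, compartment,
                              0, None, met_id.startswith("pmf_"))
    raise TableParseError(
        f"metabolite {met_id!r} has no known compartment suffix (_c or _m)"
    )


def read_table(path: str) -> ModelNetwork:
    """Read the TSV reaction-table dialect back into a model.

    Parse errors report the offending line and token.  Metabolites missing
    from the ``#!`` header lines are reconstructed from their compartment
    suffix (unknown suffixes are an error).
    """
    model = ModelNetwork()
    declared: Dict[str, Metabolite] = {}
    header: Optional[List[str]] = None
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#!"):
                fields = line[2:].strip().split("\t")
                kind = fields[0]
                if kind == "metabolite":
                    mid, name, compartment, charge, formula, pmf = fields[1:7]
                    declared[mid] = Metabolite(
                        mid, name, compartment, int(charge),
                        formula or None, pmf == "1",
                    )
                elif kind == "objective":
                    model.objective_id = fields[1]
                elif kind == "notes":
                    model.notes = fields[1]
                continue
            if line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                if tuple(header) != _HEADER:
                    raise TableParseError(
                        f"unexpected header {header} (line {lineno}); "
                        f"expected {list(_HEADER)}"
                    )
                continue
            if len(cells) != len(_HEADER):
                raise TableParseError(
                    f"expected {len(_HEADER)} columns, got {len(cells)} "
                    f"(line {lineno})"
                )
            row = dict(zip(_HEADER, cells))
            stoich, reversible = parse_equation(row["equation"], lineno)
            try:
                lb, ub = float(row["lower"]), float(row["upper"])
            except ValueError:
                raise TableParseError(
                    f"bad bounds {row['lower']!r}/{row['upper']!r} "
                    f"(line {lineno})"
                ) from None
            if reversible and lb >= 0:
                lb = min(lb, -0.0)
            if not reversible and lb < 0:
                raise TableParseError(
                    f"{row['id']}: '->' arrow with negative lower bound "
                    f"(line {lineno})"
                )
            annotation = {
                col: row[col] for col in _ANNOTATION_COLUMNS if row[col]
            }
            if row["other_annotation"]:
                annotation.update(json.loads(row["other_annotation"]))
            if row["category"] not in CATEGORIES:
                raise TableParseError(
                    f"unknown category {row['category']!r} (line {lineno})"
                )
            for met_id in stoich:
                if met_id not in model.metabolites:
                    model.add_metabolite(
                        declared.get(met_id) or _metabolite_from_suffix(met_id)
                    )
            model.add_reaction(
                Reaction(
                    id=row["id"],
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    genes=_parse_genes(row["genes"]),
                    subsystem=row["subsystem"],
                    category=row["category"],
                    annotation=annotation,
                )
            )
    if header is None:
        raise TableParseError(f"{path}: no header row found")
    model.validate(allow_orphans=True)
    return model


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

_NOTE_KEYS = ("subsystem", "category", "annotation_json", "is_pmf", "name")


def _notes_string(pairs: Dict[str, str]) -> str:
    body = "".join(
        f"<p>{k}: {saxutils.escape(v)}</p>" for k, v in pairs.items() if v
    )
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">' + body + "</body>"
    )


def _parse_notes(node) -> Dict[str, str]:
    out: Dict[str, str] = {}
    if node is None:
        return out
    text = libsbml.XMLNode.convertXMLNodeToString(node)
    for match in re.finditer(r"<p>\s*([^:<]+):\s*(.*?)</p>", text, re.S):
        out[match.group(1).strip()] = saxutils.unescape(
            match.group(2).strip(), {"&quot;": '"', "&apos;": "'"}
        )
    return out


def _check_errors(document, action: str) -> None:
    errors = [
        document.getError(i).getMessage()
        for i in range(document.getNumErrors())
        if document.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if errors:
        raise SBMLReadError(f"{action} failed: " + " | ".join(errors))


def write_sbml(model: ModelNetwork, path: str, dialect: str = "l3fbc") -> None:
    """Serialise to SBML.

    ``dialect="l3fbc"`` (default) writes Level 3 Version 1 with the fbc
    extension carrying bounds, objective, charges and gene products.
    ``dialect="l2v1"`` writes legacy Level 2 Version 1 with bounds in
    kinetic-law parameters.
    """
    if dialect == "l3fbc":
        _write_l3(model, path)
    elif dialect == "l2v1":
        _write_l2(model, path)
    else:
        raise ValueError(f"unknown SBML dialect {dialect!r}")


def _sanitize(sid: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", sid)


def _write_l3(model: ModelNetwork, path: str) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    document = libsbml.SBMLDocument(ns)
    document.setPackageRequired("fbc", False)
    sbml_model = document.createModel()
    sbml_model.setId("mitoflux_model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)
    for code in dict.fromkeys(
        _COMPARTMENT_CODE[m.compartment] for m in model.metabolites.values()
    ):
        comp = sbml_model.createCompartment()
        comp.setId(code)
        comp.setConstant(True)
        comp.setSize(1.0)
    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId("M_" + _sanitize(met.id))
        sp.setName(met.name)
        sp.setCompartment(_COMPARTMENT_CODE[met.compartment])
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(met.compartment == BOUNDARY)
        sp.setConstant(False)
        sp.setInitialAmount(0.0)
        splug = sp.getPlugin("fbc")
        splug.setCharge(met.charge)
        if met.formula:
            splug.setChemicalFormula(met.formula)
        if met.is_pmf:
            sp.setNotes(_notes_string({"is_pmf": "true"}))
    genes_seen: Dict[str, str] = {}
    for rxn in model.reactions.values():
        for sym, acc in rxn.genes:
            genes_seen.setdefault(sym, acc)
    for sym, acc in genes_seen.items():
        gp = mplug.createGeneProduct()
        gp.setId("G_" + _sanitize(sym))
        gp.setLabel(sym)
        if acc:
            gp.setName(acc)
    for i, rxn in enumerate(model.reactions.values()):
        lb_id, ub_id = f"lb_{i}", f"ub_{i}"
        for pid, value in ((lb_id, rxn.lower_bound), (ub_id, rxn.upper_bound)):
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
        sr = sbml_model.createReaction()
        sr.setId("R_" + _sanitize(rxn.id))
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(lb_id)
        rplug.setUpperFluxBound(ub_id)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies("M_" + _sanitize(met_id))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        if rxn.genes:
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(
                " and ".join("G_" + _sanitize(sym) for sym, _ in rxn.genes)
            )
        sr.setNotes(
            _notes_string(
                {
                    "subsystem": rxn.subsystem,
                    "category": rxn.category,
                    "annotation_json": json.dumps(rxn.annotation, sort_keys=True)
                    if rxn.annotation
                    else "",
                }
            )
        )
    if model.objective_id:
        objective = mplug.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        flux = objective.createFluxObjective()
        flux.setReaction("R_" + _sanitize(model.objective_id))
        flux.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")
    libsbml.writeSBMLToFile(document, path)


def _write_l2(model: ModelNetwork, path: str) -> None:
    document = libsbml.SBMLDocument(2, 1)
    sbml_model = document.createModel()
    sbml_model.setId("mitoflux_model")
    for code in dict.fromkeys(
        _COMPARTMENT_CODE[m.compartment] for m in model.metabolites.values()
    ):
        comp = sbml_model.createCompartment()
        comp.setId(code)
    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId("M_" + _sanitize(met.id))
        sp.setName(met.name)
        sp.setCompartment(_COMPARTMENT_CODE[met.compartment])
        sp.setCharge(met.charge)
        sp.setBoundaryCondition(met.compartment == BOUNDARY)
        notes = {}
        if met.formula:
            notes["FORMULA"] = met.formula
        if met.is_pmf:
            notes["is_pmf"] = "true"
        if notes:
            sp.setNotes(_notes_string(notes))
    for rxn in model.reactions.values():
        sr = sbml_model.createReaction()
        sr.setId("R_" + _sanitize(rxn.id))
        sr.setReversible(rxn.lower_bound < 0)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies("M_" + _sanitize(met_id))
            ref.setStoichiometry(abs(coeff))
        law = sr.createKineticLaw()
        law.setFormula("FLUX_VALUE")
        for pid, value in (
            ("LOWER_BOUND", rxn.lower_bound),
            ("UPPER_BOUND", rxn.upper_bound),
            ("FLUX_VALUE", 0.0),
            (
                "OBJECTIVE_COEFFICIENT",
                1.0 if rxn.id == model.objective_id else 0.0,
            ),
        ):
            par = law.createParameter()
            par.setId(pid)
            par.setValue(value)
        notes = {
            "subsystem": rxn.subsystem,
            "category": rxn.category,
            "annotation_json": json.dumps(rxn.annotation, sort_keys=True)
            if rxn.annotation
            else "",
        }
        if rxn.genes:
            notes["GENE_ASSOCIATION"] = " and ".join(s for s, _ in rxn.genes)
            notes["GENE_ACCESSIONS"] = _format_genes(rxn.genes)
        sr.setNotes(_notes_string(notes))
    libsbml.writeSBMLToFile(document, path)


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def read_sbml(path: str) -> ModelNetwork:
    """Read either SBML dialect back into a ModelNetwork.

    Accepts our own Level 3 + fbc output, the legacy Level 2 Version 1
    kinetic-law encoding, and externally produced models of either kind
    (reaction categories are then inferred from the compartments touched).
    """
    reader = libsbml.SBMLReader()
    document = reader.readSBML(path)
    _check_errors(document, f"reading {path}")
    sbml_model = document.getModel()
    if sbml_model is None:
        raise SBMLReadError(f"{path}: no model element")
    model = ModelNetwork()
    fbc = sbml_model.getPlugin("fbc")

    compartment_of: Dict[str, str] = {}
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        label = (comp.getName() or comp.getId()).strip().lower()
        mapped = _CODE_COMPARTMENT.get(label) or _CODE_COMPARTMENT.get(
            comp.getId().strip().lower()
        )
        if mapped is None:
            raise SBMLReadError(
                f"unknown compartment {comp.getId()!r} (name {comp.getName()!r})"
            )
        compartment_of[comp.getId()] = mapped

    species_map: Dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        compartment = compartment_of[sp.getCompartment()]
        mid = _strip_prefix(sp.getId(), "M_")
        suffix = COMPARTMENT_SUFFIX.get(compartment)
        if suffix and not mid.endswith(suffix):
            mid += suffix
        notes = _parse_notes(sp.getNotes())
        charge = 0
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetCharge():
            charge = splug.getCharge()
        elif sp.isSetCharge():
            charge = sp.getCharge()
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        elif "FORMULA" in notes:
            formula = notes["FORMULA"] or None
        is_pmf = notes.get("is_pmf", "").lower() == "true" or mid.startswith("pmf_")
        species_map[sp.getId()] = mid
        if mid not in model.metabolites:
            model.add_metabolite(
                Metabolite(mid, sp.getName() or mid, compartment, charge,
                           formula, is_pmf)
            )

    gene_label: Dict[str, Tuple[str, str]] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_label[gp.getId()] = (gp.getLabel() or gp.getId(),
                                      gp.getName() or "")

    objective_id = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getObjective(fbc.getActiveObjectiveId()) or fbc.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_id = _strip_prefix(
                active.getFluxObjective(0).getReaction(), "R_"
            )

    parameters = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        rid = _strip_prefix(sr.getId(), "R_")
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = species_map[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = species_map[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            continue
        lb = -DEFAULT_BOUND if sr.getReversible() else 0.0
        ub = DEFAULT_BOUND
        rplug = sr.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = parameters.get(rplug.getLowerFluxBound(), lb)
            ub = parameters.get(rplug.getUpperFluxBound(), ub)
        elif sr.isSetKineticLaw():
            law = sr.getKineticLaw()
            for j in range(law.getNumParameters()):
                par = law.getParameter(j)
                if par.getId() == "LOWER_BOUND":
                    lb = par.getValue()
                elif par.getId() == "UPPER_BOUND":
                    ub = par.getValue()
                elif (
                    par.getId() == "OBJECTIVE_COEFFICIENT"
                    and par.getValue() == 1.0
                    and objective_id is None
                ):
                    objective_id = rid
        notes = _parse_notes(sr.getNotes())
        genes: List[Tuple[str, str]] = []
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                text = assoc.toInfix()
                for gid in re.findall(r"G_[A-Za-z0-9_]+", text):
                    genes.append(gene_label.get(gid, (_strip_prefix(gid, "G_"), "")))
        elif "GENE_ACCESSIONS" in notes:
            genes = _parse_genes(notes["GENE_ACCESSIONS"])
        elif "GENE_ASSOCIATION" in notes:
            genes = [
                (sym.strip(), "")
                for sym in re.split(r"\band\b|\bor\b", notes["GENE_ASSOCIATION"])
                if sym.strip()
            ]
        category = notes.get("category") or _infer_category(rid, stoich, model)
        annotation = {}
        if notes.get("annotation_json"):
            annotation = json.loads(notes["annotation_json"])
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                genes=genes,
                subsystem=notes.get("subsystem", ""),
                category=category,
                annotation=annotation,
            )
        )
    model.objective_id = (
        objective_id if objective_id in model.reactions else model.objective_id
    )
    model.validate(allow_orphans=True)
    return model


def _infer_category(rid: str, stoich: Dict[str, float], model: ModelNetwork) -> str:
    if rid.startswith(("OF_", "DM_", "sink_")):
        return PSEUDO
    comps = {
        model.metabolites[m].compartment for m in stoich if m in model.metabolites
    } - {BOUNDARY}
    if comps == {CYTOSOLIC, MITOCHONDRIAL}:
        return MITO_TRANSPORT
    if not comps or (comps == {CYTOSOLIC} and len(stoich) == 1):
        return BOUNDARY_EXCHANGE
    if comps == {CYTOSOLIC} and all(c < 0 for c in stoich.values()):
        return BOUNDARY_EXCHANGE
    if len(stoich) == 1:
        return PSEUDO
    return METABOLIC
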