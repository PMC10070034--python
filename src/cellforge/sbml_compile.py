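"""Compile one tabular model definition into two executable SBML targets.

``biochem_only``
    The protein-biochemistry reaction network alone.  Every mRNA species is
    a boundary-condition species: the ODE system never changes it, the
    hybrid engine sets it from the gene-expression module once per
    communication interval.

``integrated``
    A single self-contained SBML file embedding the mean-field gene
    expression alongside the biochemistry, eliminating inter-module
    communication.  Per gene it adds two species (active/inactive promoter
    copies, conserved sum) and four reactions (activation with the Hill
    regulation inlined into the kinetic law, inactivation, transcription,
    mRNA degradation).  mRNA and promoter species carry molecule-count
    semantics (hasOnlySubstanceUnits); biochemistry kinetic laws see mRNA
    through the explicit ``nM_per_molecule`` conversion parameter, exactly
    as the hybrid engine converts counts at the module boundary.

Both targets are SBML Level 3 Version 2 and pass libsbml consistency
validation with zero errors.  Compilation is deterministic: the same
directory always yields byte-identical documents.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import libsbml
import sympy as sp

from .gene_module import UnitContext
from .model_tables import (
    ModelDefinition,
    ReactionRecord,
    model_fingerprint,
    parse_rate_law,
    read_model_tables,
    validate_model,
)

__all__ = [
    "CompiledModel",
    "SbmlCompileError",
    "build_biochem_sbml",
    "build_integrated_sbml",
    "compile_both",
    "validate_sbml",
    "read_document",
]

ACTIVE_SUFFIX = "__active"
INACTIVE_SUFFIX = "__inactive"
CONV_PARAM = "nM_per_molecule"
AVOGADRO_PARAM = "avogadro"


class SbmlCompileError(ValueError):
    pass


@dataclass(frozen=True)
class CompiledModel:
    target: str  # "biochem_only" | "integrated"
    sbml_text: str
    index_map: dict[str, int]
    provenance: dict

    @property
    def n_state(self) -> int:
        return len(self.index_map)


def read_document(compiled: CompiledModel) -> libsbml.SBMLDocument:
    doc = libsbml.readSBMLFromString(compiled.sbml_text)
    if doc.getModel() is None:
        raise SbmlCompileError("compiled model text does not parse as SBML")
    return doc


def validate_sbml(sbml_text: str) -> list[str]:
    """Independent SBML consistency validation; returns error messages.

    Unit-consistency checks are excluded: the dialect deliberately mixes nM
    concentrations with molecule counts and documents the conversion.
    """
    doc = libsbml.readSBMLFromString(sbml_text)
    errors: list[str] = []
    for i in range(doc.getNumErrors()):
        e = doc.getError(i)
        if e.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            errors.append(f"read error: {e.getMessage().strip()}")
    if errors:
        return errors
    doc.setConsistencyChecks(libsbml.LIBSBML_CAT_UNITS_CONSISTENCY, False)
    doc.checkConsistency()
    for i in range(doc.getNumErrors()):
        e = doc.getError(i)
        if e.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            errors.append(e.getMessage().strip())
    return errors


# ---------------------------------------------------------------------------
# expression plumbing


def _sympy_to_l3(expr: sp.Expr) -> str:
    return sp.sstr(expr).replace("**", "^")


def _formula_for_reaction(
    rxn: ReactionRecord, mrna_ids: set[str], counts_mode: bool
) -> str:
    """Dialect rate law -> L3 formula, converting mRNA symbols to nM when the
    target stores mRNA as molecule counts."""
    expr = parse_rate_law(rxn.rate_law)
    if counts_mode:
        conv = sp.Symbol(CONV_PARAM)
        subs = {
            sp.Symbol(mid): sp.Symbol(mid) * conv
            for mid in mrna_ids
            if sp.Symbol(mid) in expr.free_symbols
        }
        if subs:
            expr = expr.subs(subs, simultaneous=True)
    return _sympy_to_l3(expr)


def _set_math(kl: libsbml.KineticLaw, formula: str, rxn_id: str) -> None:
    ast = libsbml.parseL3Formula(formula)
    if ast is None:
        raise SbmlCompileError(
            f"rate law of reaction {rxn_id!r} is not expressible in SBML math: "
            f"{libsbml.getLastParseL3Error()}"
        )
    kl.setMath(ast)


# ---------------------------------------------------------------------------
# document assembly


def _new_document(model_id: str) -> tuple[libsbml.SBMLDocument, libsbml.Model]:
    doc = libsbml.SBMLDocument(3, 2)
    m = doc.createModel()
    m.setId(model_id)
    return doc, m


def _add_compartments(m: libsbml.Model, model: ModelDefinition) -> None:
    for cid, vol in model.compartments:
        c = m.createCompartment()
        c.setId(cid)
        c.setSize(vol)
        c.setSpatialDimensions(3)
        c.setConstant(True)


def _add_parameter(m: libsbml.Model, pid: str, value: float) -> None:
    p = m.createParameter()
    p.setId(pid)
    p.setValue(value)
    p.setConstant(True)


def _add_species(
    m: libsbml.Model,
    sid: str,
    compartment: str,
    *,
    concentration: float | None = None,
    amount: float | None = None,
    boundary: bool = False,
    substance_units: bool = False,
) -> None:
    s = m.createSpecies()
    s.setId(sid)
    s.setCompartment(compartment)
    if concentration is not None:
        s.setInitialConcentration(concentration)
    else:
        s.setInitialAmount(amount)
    s.setBoundaryCondition(boundary)
    s.setHasOnlySubstanceUnits(substance_units)
    s.setConstant(False)


def _add_reaction(
    m: libsbml.Model,
    rid: str,
    reactants: list[tuple[str, float]],
    products: list[tuple[str, float]],
    modifiers: list[str],
    formula: str,
    local_params: list[tuple[str, float]],
) -> None:
    r = m.createReaction()
    r.setId(rid)
    r.setReversible(False)
    for sid, coeff in reactants:
        ref = r.createReactant()
        ref.setSpecies(sid)
        ref.setStoichiometry(float(coeff))
        ref.setConstant(True)
    for sid, coeff in products:
        ref = r.createProduct()
        ref.setSpecies(sid)
        ref.setStoichiometry(float(coeff))
        ref.setConstant(True)
    for sid in modifiers:
        ref = r.createModifier()
        ref.setSpecies(sid)
    kl = r.createKineticLaw()
    _set_math(kl, formula, rid)
    for name, value in local_params:
        lp = kl.createLocalParameter()
        lp.setId(name)
        lp.setValue(value)


def _add_biochem_reactions(
    m: libsbml.Model, model: ModelDefinition, counts_mode: bool
) -> None:
    species_ids = set(model.species_index())
    mrna_ids = set(model.mrna_species_ids())
    for rxn in model.reactions:
        formula = _formula_for_reaction(rxn, mrna_ids, counts_mode)
        in_rxn = {sid for sid, _ in rxn.reactants} | {sid for sid, _ in rxn.products}
        law_species = {
            str(s) for s in parse_rate_law(rxn.rate_law).free_symbols
        } & species_ids
        modifiers = sorted(law_species - in_rxn)
        _add_reaction(
            m, rxn.id, list(rxn.reactants), list(rxn.products), modifiers,
            formula, list(rxn.parameters),
        )


def _regulated_kon_formula(model: ModelDefinition, gene_id: str) -> tuple[str, list[str]]:
    """Build the inlined k_on,eff formula factors and the regulator list."""
    factors: list[str] = []
    regulators: list[str] = []
    for j, term in enumerate(model.regulations_for(gene_id)):
        r = term.regulator_species
        occ = (
            f"(reg{j}_w * {r}^reg{j}_h / (reg{j}_K^reg{j}_h + {r}^reg{j}_h))"
        )
        if term.mode == "activator":
            factors.append(f"(1 + {occ})")
        else:
            factors.append(f"(1 / (1 + {occ}))")
        regulators.append(r)
    return " * ".join(factors), regulators


def _regulation_local_params(model: ModelDefinition, gene_id: str) -> list[tuple[str, float]]:
    params: list[tuple[str, float]] = []
    for j, term in enumerate(model.regulations_for(gene_id)):
        params += [
            (f"reg{j}_K", term.half_max_nM),
            (f"reg{j}_h", term.hill),
            (f"reg{j}_w", term.weight),
        ]
    return params


def _add_gene_machinery(m: libsbml.Model, model: ModelDefinition) -> None:
    """Per-gene species and reactions of the integrated target."""
    default_comp = model.compartments[0][0]
    comp_of = {s.id: s.compartment for s in model.species}
    for gene in model.genes:
        comp = comp_of.get(gene.mrna_species, default_comp)
        act_id = gene.id + ACTIVE_SUFFIX
        inact_id = gene.id + INACTIVE_SUFFIX
        _add_species(m, act_id, comp, amount=float(gene.init_active),
                     substance_units=True)
        _add_species(m, inact_id, comp,
                     amount=float(gene.total_alleles - gene.init_active),
                     substance_units=True)
        hill_factors, regulators = _regulated_kon_formula(model, gene.id)
        kon_formula = f"k_on * {inact_id}"
        if hill_factors:
            kon_formula += " * " + hill_factors
        _add_reaction(
            m, f"{gene.id}__activation",
            [(inact_id, 1)], [(act_id, 1)], sorted(set(regulators)),
            kon_formula,
            [("k_on", gene.k_on)] + _regulation_local_params(model, gene.id),
        )
        _add_reaction(
            m, f"{gene.id}__inactivation",
            [(act_id, 1)], [(inact_id, 1)], [],
            f"k_off * {act_id}", [("k_off", gene.k_off)],
        )
        _add_reaction(
            m, f"{gene.id}__transcription",
            [(act_id, 1)], [(act_id, 1), (gene.mrna_species, 1)], [],
            f"k_tc * {act_id}", [("k_tc", gene.k_tc)],
        )
        _add_reaction(
            m, f"{gene.id}__degradation",
            [(gene.mrna_species, 1)], [], [],
            f"k_deg * {gene.mrna_species}", [("k_deg", gene.k_deg)],
        )


def _finish(
    doc: libsbml.SBMLDocument,
    target: str,
    index_map: dict[str, int],
    provenance: dict,
) -> CompiledModel:
    text = libsbml.writeSBMLToString(doc)
    errors = validate_sbml(text)
    if errors:
        raise SbmlCompileError(
            "generated SBML failed consistency validation: " + "; ".join(errors[:5])
        )
    return CompiledModel(target=target, sbml_text=text, index_map=index_map,
                         provenance=provenance)


def _check_model(model: ModelDefinition) -> None:
    errors = [i for i in validate_model(model) if i.severity == "error"]
    if errors:
        raise SbmlCompileError(
            "model failed validation: " + "; ".join(str(i) for i in errors[:5])
        )
    taken = set(model.species_index())
    for gene in model.genes:
        for sid in (gene.id + ACTIVE_SUFFIX, gene.id + INACTIVE_SUFFIX):
            if sid in taken:
                raise SbmlCompileError(
                    f"species id {sid!r} collides with a generated gene-state id"
                )


def _provenance(model: ModelDefinition, source: str) -> dict:
    return {"source": source, "content_hash": model_fingerprint(model)}


def build_biochem_sbml(
    model: ModelDefinition,
    units: UnitContext = UnitContext(),
    source: str = "<memory>",
) -> CompiledModel:
    """Biochemistry-only target: mRNA species become boundary conditions."""
    _check_model(model)
    doc, m = _new_document("biochem_only")
    _add_compartments(m, model)
    _add_parameter(m, CONV_PARAM, units.nM_per_molecule)
    _add_parameter(m, AVOGADRO_PARAM, units.avogadro)
    for s in model.species:
        _add_species(m, s.id, s.compartment, concentration=s.initial_nM,
                     boundary=s.is_mrna)
    _add_biochem_reactions(m, model, counts_mode=False)
    index_map = {s.id: i for i, s in enumerate(model.species)}
    return _finish(doc, "biochem_only", index_map, _provenance(model, source))


def build_integrated_sbml(
    model: ModelDefinition,
    units: UnitContext = UnitContext(),
    source: str = "<memory>",
) -> CompiledModel:
    """Single-file target embedding mean-field gene expression."""
    _check_model(model)
    doc, m = _new_document("integrated")
    _add_compartments(m, model)
    _add_parameter(m, CONV_PARAM, units.nM_per_molecule)
    _add_parameter(m, AVOGADRO_PARAM, units.avogadro)
    gene_by_mrna = model.gene_for_mrna()
    for s in model.species:
        if s.is_mrna and s.id in gene_by_mrna:
            _add_species(m, s.id, s.compartment,
                         amount=float(gene_by_mrna[s.id].init_mrna_count),
                         substance_units=True)
        elif s.is_mrna:
            # orphan mRNA with no producing gene: counts from concentration
            _add_species(m, s.id, s.compartment,
                         amount=round(s.initial_nM / units.nM_per_molecule),
                         substance_units=True)
        else:
            _add_species(m, s.id, s.compartment, concentration=s.initial_nM)
    _add_biochem_reactions(m, model, counts_mode=True)
    _add_gene_machinery(m, model)
    index_map = {s.id: i for i, s in enumerate(model.species)}
    n = len(index_map)
    for gene in model.genes:
        index_map[gene.id + ACTIVE_SUFFIX] = n
        index_map[gene.id + INACTIVE_SUFFIX] = n + 1
        n += 2
    return _finish(doc, "integrated", index_map, _provenance(model, source))


def compile_both(
    directory: str | Path,
    units: UnitContext = UnitContext(),
) -> tuple[CompiledModel, CompiledModel]:
    """Read one model directory and compile both targets from the same parse."""
    model = read_model_tables(directory)
    src = str(directory)
    return (
        build_biochem_sbml(model, units=units, source=src),
        build_integrated_sbml(model, units=units, source=src),
    )


def write_compiled(compiled: CompiledModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(compiled.sbml_text, encoding="utf-8")
    return path
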