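"""Tabular model-definition format: read, validate, write.

A model is five tab-separated UTF-8 files with fixed names and header rows
(plus one optional file), living together in one directory:

``compartments.tsv``
    ``id``, ``volume_L``
``species.tsv``
    ``id``, ``name``, ``compartment``, ``initial_nM``, ``is_mrna`` (0/1).
    Row order defines the canonical state-vector order.
``reactions.tsv``
    ``id``, ``reactants``, ``products``, ``rate_law``.  Reactant/product
    lists are ``speciesId*coeff`` items joined by ``;`` (empty string for a
    source/sink side).  Rate laws are arithmetic expressions over species
    ids and parameter names using ``+ - * / ^`` and parentheses.
``ratelaw_params.tsv``
    ``reaction_id``, ``name``, ``value`` — parameters local to one reaction.
``genes.tsv``
    ``id``, ``total_alleles``, ``k_on``, ``k_off``, ``k_tc``, ``k_deg``,
    ``mrna_species``, ``init_active``, ``init_mrna_count`` — the telegraph
    gene-expression parameters (switching, transcription, mRNA decay).
``regulation.tsv`` (optional)
    ``gene_id``, ``regulator_species``, ``mode`` (activator/repressor),
    ``half_max_nM``, ``hill``, ``weight`` — Hill-type modulation of k_on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import sympy as sp
from sympy.parsing.sympy_parser import parse_expr, standard_transformations

__all__ = [
    "SpeciesRecord",
    "ReactionRecord",
    "GeneRecord",
    "RegulationTerm",
    "ModelDefinition",
    "Issue",
    "ModelTableError",
    "read_model_tables",
    "validate_model",
    "write_model_tables",
    "parse_rate_law",
]

_ID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

TABLE_FILES = {
    "compartments": "compartments.tsv",
    "species": "species.tsv",
    "reactions": "reactions.tsv",
    "ratelaw_params": "ratelaw_params.tsv",
    "genes": "genes.tsv",
}
REGULATION_FILE = "regulation.tsv"


class ModelTableError(ValueError):
    """Raised when a model directory cannot be parsed into a valid model."""


@dataclass(frozen=True)
class SpeciesRecord:
    id: str
    name: str
    compartment: str
    initial_nM: float
    is_mrna: bool = False


@dataclass(frozen=True)
class ReactionRecord:
    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_law: str
    parameters: tuple[tuple[str, float], ...] = ()

    def parameter_map(self) -> dict[str, float]:
        return dict(self.parameters)


@dataclass(frozen=True)
class GeneRecord:
    id: str
    total_alleles: int
    k_on: float
    k_off: float
    k_tc: float
    k_deg: float
    mrna_species: str
    init_active: int
    init_mrna_count: int


@dataclass(frozen=True)
class RegulationTerm:
    gene_id: str
    regulator_species: str
    mode: str  # "activator" | "repressor"
    half_max_nM: float
    hill: float
    weight: float


@dataclass(frozen=True)
class ModelDefinition:
    compartments: tuple[tuple[str, float], ...]
    species: tuple[SpeciesRecord, ...]
    reactions: tuple[ReactionRecord, ...]
    genes: tuple[GeneRecord, ...]
    regulations: tuple[RegulationTerm, ...] = ()

    def compartment_map(self) -> dict[str, float]:
        return dict(self.compartments)

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def mrna_species_ids(self) -> list[str]:
        return [s.id for s in self.species if s.is_mrna]

    def gene_for_mrna(self) -> dict[str, GeneRecord]:
        return {g.mrna_species: g for g in self.genes}

    def regulations_for(self, gene_id: str) -> list[RegulationTerm]:
        return [r for r in self.regulations if r.gene_id == gene_id]


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    table: str
    row: object  # row id or index
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.table}:{self.row}: {self.message}"


# ---------------------------------------------------------------------------
# rate-law expressions


def parse_rate_law(text: str, allowed: Iterable[str] | None = None) -> sp.Expr:
    """Parse a rate-law expression of the restricted arithmetic grammar.

    The grammar admits ``+ - * / ^``, parentheses, numeric literals and
    identifiers.  ``^`` denotes power.  Raises :class:`ModelTableError` on a
    syntax error, on any function call, or (when ``allowed`` is given) on an
    identifier outside the allowed set.
    """
    if not text or not text.strip():
        raise ModelTableError("empty rate law")
    src = text.replace("^", "**")
    try:
        expr = parse_expr(
            src,
            transformations=standard_transformations,
            evaluate=True,
        )
    except Exception as exc:  # sympy raises many flavours
        raise ModelTableError(f"cannot parse rate law {text!r}: {exc}") from exc
    if expr.atoms(sp.Function):
        raise ModelTableError(
            f"rate law {text!r} uses function calls; only + - * / ^ are allowed"
        )
    if allowed is not None:
        extra = {str(s) for s in expr.free_symbols} - set(allowed)
        if extra:
            raise ModelTableError(
                f"rate law {text!r} references undeclared symbols {sorted(extra)}"
            )
    return expr


def rate_law_symbols(text: str) -> set[str]:
    return {str(s) for s in parse_rate_law(text).free_symbols}


# ---------------------------------------------------------------------------
# reading


def _read_tsv(directory: Path, fname: str, required: bool = True) -> pd.DataFrame | None:
    path = directory / fname
    if not path.is_file():
        if required:
            raise ModelTableError(f"missing model table file: {fname} (in {directory})")
        return None
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, fname: str, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ModelTableError(f"{fname}: missing columns {missing}")


def _parse_species_list(text: str, reaction_id: str, side: str) -> tuple[tuple[str, int], ...]:
    text = text.strip()
    if not text:
        return ()
    out: list[tuple[str, int]] = []
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        if "*" in item:
            sid, _, coeff_s = item.partition("*")
            try:
                coeff = int(coeff_s)
            except ValueError:
                raise ModelTableError(
                    f"reaction {reaction_id}: bad stoichiometry {item!r} in {side}"
                ) from None
        else:
            sid, coeff = item, 1
        out.append((sid.strip(), coeff))
    return tuple(out)


def _to_float(val: str, where: str) -> float:
    try:
        return float(val)
    except ValueError:
        raise ModelTableError(f"{where}: cannot parse number {val!r}") from None


def _to_int(val: str, where: str) -> int:
    try:
        return int(val)
    except ValueError:
        raise ModelTableError(f"{where}: cannot parse integer {val!r}") from None


def _to_bool(val: str, where: str) -> bool:
    v = val.strip().lower()
    if v in {"1", "true", "yes"}:
        return True
    if v in {"0", "false", "no", ""}:
        return False
    raise ModelTableError(f"{where}: cannot parse flag {val!r}")


def read_model_tables(directory_path: str | Path) -> ModelDefinition:
    """Read a model directory into a :class:`ModelDefinition`.

    The returned model has been validated; any error-severity issue raises
    :class:`ModelTableError` naming the offending table, row and symbol.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise ModelTableError(f"model directory not found: {directory}")

    comp_df = _read_tsv(directory, TABLE_FILES["compartments"])
    _require_columns(comp_df, "compartments.tsv", ["id", "volume_L"])
    compartments = tuple(
        (r["id"], _to_float(r["volume_L"], f"compartments.tsv:{r['id']}"))
        for _, r in comp_df.iterrows()
    )

    sp_df = _read_tsv(directory, TABLE_FILES["species"])
    _require_columns(sp_df, "species.tsv", ["id", "name", "compartment", "initial_nM", "is_mrna"])
    species = tuple(
        SpeciesRecord(
            id=r["id"],
            name=r["name"],
            compartment=r["compartment"],
            initial_nM=_to_float(r["initial_nM"], f"species.tsv:{r['id']}"),
            is_mrna=_to_bool(r["is_mrna"], f"species.tsv:{r['id']}"),
        )
        for _, r in sp_df.iterrows()
    )

    par_df = _read_tsv(directory, TABLE_FILES["ratelaw_params"])
    _require_columns(par_df, "ratelaw_params.tsv", ["reaction_id", "name", "value"])
    params_by_rxn: dict[str, list[tuple[str, float]]] = {}
    for _, r in par_df.iterrows():
        params_by_rxn.setdefault(r["reaction_id"], []).append(
            (r["name"], _to_float(r["value"], f"ratelaw_params.tsv:{r['reaction_id']}/{r['name']}"))
        )

    rxn_df = _read_tsv(directory, TABLE_FILES["reactions"])
    _require_columns(rxn_df, "reactions.tsv", ["id", "reactants", "products", "rate_law"])
    reactions = []
    for _, r in rxn_df.iterrows():
        rid = r["id"]
        parse_rate_law(r["rate_law"])  # syntax check; names reaction on failure
        reactions.append(
            ReactionRecord(
                id=rid,
                reactants=_parse_species_list(r["reactants"], rid, "reactants"),
                products=_parse_species_list(r["products"], rid, "products"),
                rate_law=r["rate_law"],
                parameters=tuple(params_by_rxn.get(rid, ())),
            )
        )

    gene_df = _read_tsv(directory, TABLE_FILES["genes"])
    _require_columns(
        gene_df,
        "genes.tsv",
        ["id", "total_alleles", "k_on", "k_off", "k_tc", "k_deg",
         "mrna_species", "init_active", "init_mrna_count"],
    )
    genes = tuple(
        GeneRecord(
            id=r["id"],
            total_alleles=_to_int(r["total_alleles"], f"genes.tsv:{r['id']}"),
            k_on=_to_float(r["k_on"], f"genes.tsv:{r['id']}"),
            k_off=_to_float(r["k_off"], f"genes.tsv:{r['id']}"),
            k_tc=_to_float(r["k_tc"], f"genes.tsv:{r['id']}"),
            k_deg=_to_float(r["k_deg"], f"genes.tsv:{r['id']}"),
            mrna_species=r["mrna_species"],
            init_active=_to_int(r["init_active"], f"genes.tsv:{r['id']}"),
            init_mrna_count=_to_int(r["init_mrna_count"], f"genes.tsv:{r['id']}"),
        )
        for _, r in gene_df.iterrows()
    )

    reg_df = _read_tsv(directory, REGULATION_FILE, required=False)
    regulations: tuple[RegulationTerm, ...] = ()
    if reg_df is not None:
        _require_columns(
            reg_df, "regulation.tsv",
            ["gene_id", "regulator_species", "mode", "half_max_nM", "hill", "weight"],
        )
        regulations = tuple(
            RegulationTerm(
                gene_id=r["gene_id"],
                regulator_species=r["regulator_species"],
                mode=r["mode"].strip().lower(),
                half_max_nM=_to_float(r["half_max_nM"], f"regulation.tsv:{r['gene_id']}"),
                hill=_to_float(r["hill"], f"regulation.tsv:{r['gene_id']}"),
                weight=_to_float(r["weight"], f"regulation.tsv:{r['gene_id']}"),
            )
            for _, r in reg_df.iterrows()
        )

    model = ModelDefinition(
        compartments=compartments,
        species=species,
        reactions=tuple(reactions),
        genes=genes,
        regulations=regulations,
    )
    errors = [i for i in validate_model(model) if i.severity == "error"]
    if errors:
        raise ModelTableError(
            "model failed validation: " + "; ".join(str(i) for i in errors[:10])
        )
    return model


# ---------------------------------------------------------------------------
# validation


def validate_model(model: ModelDefinition) -> list[Issue]:
    """Check every structural invariant; returns issues, never raises."""
    issues: list[Issue] = []

    def err(table: str, row: object, msg: str) -> None:
        issues.append(Issue("error", table, row, msg))

    comp_ids = set()
    for cid, vol in model.compartments:
        if not _ID_RE.match(cid):
            err("compartments", cid, f"invalid identifier {cid!r}")
        if cid in comp_ids:
            err("compartments", cid, f"duplicate compartment id {cid!r}")
        comp_ids.add(cid)
        if not vol > 0:
            err("compartments", cid, f"volume must be > 0, got {vol}")

    species_ids: set[str] = set()
    for srec in model.species:
        if not _ID_RE.match(srec.id):
            err("species", srec.id, f"invalid identifier {srec.id!r}")
        if srec.id in species_ids:
            err("species", srec.id, f"duplicate species id {srec.id!r}")
        species_ids.add(srec.id)
        if srec.compartment not in comp_ids:
            err("species", srec.id, f"unknown compartment {srec.compartment!r}")
        if srec.initial_nM < 0:
            err("species", srec.id, f"initial_nM must be >= 0, got {srec.initial_nM}")

    mrna_ids = {s.id for s in model.species if s.is_mrna}

    rxn_ids: set[str] = set()
    for rxn in model.reactions:
        if not _ID_RE.match(rxn.id):
            err("reactions", rxn.id, f"invalid identifier {rxn.id!r}")
        if rxn.id in rxn_ids:
            err("reactions", rxn.id, f"duplicate reaction id {rxn.id!r}")
        rxn_ids.add(rxn.id)
        for side_name, side in (("reactants", rxn.reactants), ("products", rxn.products)):
            for sid, coeff in side:
                if sid not in species_ids:
                    err("reactions", rxn.id, f"unknown species {sid!r} in {side_name}")
                if not (isinstance(coeff, int) and coeff > 0):
                    err("reactions", rxn.id,
                        f"stoichiometric coefficient for {sid!r} must be a positive integer")
                if sid in mrna_ids:
                    err("reactions", rxn.id,
                        f"mRNA species {sid!r} may not be a reactant/product of a "
                        "biochemistry reaction (mRNA is owned by the gene-expression "
                        "module; reference it in the rate law instead)")
        declared = species_ids | {n for n, _ in rxn.parameters}
        try:
            expr = parse_rate_law(rxn.rate_law)
        except ModelTableError as exc:
            err("reactions", rxn.id, str(exc))
            continue
        extra = {str(s) for s in expr.free_symbols} - declared
        if extra:
            err("reactions", rxn.id,
                f"rate law references undeclared symbols {sorted(extra)}")

    gene_ids: set[str] = set()
    for g in model.genes:
        if not _ID_RE.match(g.id):
            err("genes", g.id, f"invalid identifier {g.id!r}")
        if g.id in gene_ids:
            err("genes", g.id, f"duplicate gene id {g.id!r}")
        gene_ids.add(g.id)
        for rate_name in ("k_on", "k_off", "k_tc", "k_deg"):
            if getattr(g, rate_name) < 0:
                err("genes", g.id, f"{rate_name} must be >= 0")
        if g.total_alleles < 0:
            err("genes", g.id, "total_alleles must be >= 0")
        if not (0 <= g.init_active <= g.total_alleles):
            err("genes", g.id,
                f"init_active {g.init_active} outside [0, total_alleles={g.total_alleles}]")
        if g.init_mrna_count < 0:
            err("genes", g.id, "init_mrna_count must be >= 0")
        if g.mrna_species not in species_ids:
            err("genes", g.id, f"unknown mrna_species {g.mrna_species!r}")
        elif g.mrna_species not in mrna_ids:
            err("genes", g.id, f"mrna_species {g.mrna_species!r} is not flagged is_mrna")

    mrna_owner: dict[str, str] = {}
    for g in model.genes:
        if g.mrna_species in mrna_owner:
            err("genes", g.id,
                f"mrna_species {g.mrna_species!r} already owned by gene {mrna_owner[g.mrna_species]!r}")
        mrna_owner[g.mrna_species] = g.id
    for sid in mrna_ids - set(mrna_owner):
        issues.append(Issue("warning", "species", sid,
                            f"species {sid!r} flagged is_mrna but no gene produces it"))

    for idx, reg in enumerate(model.regulations):
        if reg.gene_id not in gene_ids:
            err("regulation", idx, f"unknown gene {reg.gene_id!r}")
        if reg.regulator_species not in species_ids:
            err("regulation", idx, f"unknown regulator species {reg.regulator_species!r}")
        if reg.mode not in {"activator", "repressor"}:
            err("regulation", idx, f"mode must be activator|repressor, got {reg.mode!r}")
        if not reg.half_max_nM > 0:
            err("regulation", idx, f"half_max_nM must be > 0, got {reg.half_max_nM}")
        if reg.hill < 1:
            err("regulation", idx, f"hill exponent must be >= 1, got {reg.hill}")
        if reg.weight < 0:
            err("regulation", idx, f"weight must be >= 0, got {reg.weight}")

    return issues


# ---------------------------------------------------------------------------
# writing


def _fmt(x: object) -> str:
    if isinstance(x, bool):
        return "1" if x else "0"
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _fmt_side(side: tuple[tuple[str, int], ...]) -> str:
    return ";".join(f"{sid}*{coeff}" if coeff != 1 else sid for sid, coeff in side)


def write_model_tables(model: ModelDefinition, directory_path: str | Path) -> list[Path]:
    """Write the tabular file set; ``read_model_tables`` inverts it exactly.

    Floats are serialized with ``repr`` so the round trip is bit-exact and a
    second write of the re-read model is byte-identical.
    """
    errors = [i for i in validate_model(model) if i.severity == "error"]
    if errors:
        raise ModelTableError(
            "refusing to write invalid model: " + "; ".join(str(i) for i in errors[:5])
        )
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def table(fname: str, header: list[str], rows: list[list[object]]) -> None:
        path = directory / fname
        lines = ["\t".join(header)]
        lines += ["\t".join(_fmt(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(path)

    table("compartments.tsv", ["id", "volume_L"],
          [[cid, vol] for cid, vol in model.compartments])
    table("species.tsv", ["id", "name", "compartment", "initial_nM", "is_mrna"],
          [[s.id, s.name, s.compartment, s.initial_nM, s.is_mrna] for s in model.species])
    table("reactions.tsv", ["id", "reactants", "products", "rate_law"],
          [[r.id, _fmt_side(r.reactants), _fmt_side(r.products), r.rate_law]
           for r in model.reactions])
    table("ratelaw_params.tsv", ["reaction_id", "name", "value"],
          [[r.id, name, value] for r in model.reactions for name, value in r.parameters])
    table("genes.tsv",
          ["id", "total_alleles", "k_on", "k_off", "k_tc", "k_deg",
           "mrna_species", "init_active", "init_mrna_count"],
          [[g.id, g.total_alleles, g.k_on, g.k_off, g.k_tc, g.k_deg,
            g.mrna_species, g.init_active, g.init_mrna_count] for g in model.genes])
    if model.regulations:
        table(REGULATION_FILE,
              ["gene_id", "regulator_species", "mode", "half_max_nM", "hill", "weight"],
              [[t.gene_id, t.regulator_species, t.mode, t.half_max_nM, t.hill, t.weight]
               for t in model.regulations])
    else:
        # remove a stale optional file so write(read(write(m))) is exact
        stale = directory / REGULATION_FILE
        if stale.exists():
            stale.unlink()
    return written


def model_fingerprint(model: ModelDefinition) -> str:
    """Content hash of a model, stable across read/write round trips."""
    import hashlib

    h = hashlib.sha256()
    h.update(repr(model).encode())
    return h.hexdigest()
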