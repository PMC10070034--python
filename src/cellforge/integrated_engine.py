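"""Single-session simulation of the integrated SBML target.

The integrated target is one ODE system covering gene expression (mean
field) and protein biochemistry, so a run is a single solver session over
the whole horizon with output sampled on the communication grid — no
per-step restarts, no inter-module handoff.  The trajectory is labelled
identically to the hybrid engine's (species in nM, per-gene active-allele
and mRNA-count columns) so the compare module can pair columns directly.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import libsbml
import numpy as np
from scipy.integrate import solve_ivp

from ._rhs import OdeSystem
from .hybrid_engine import SimConfig, SimulationError, Trajectory, _clamp_negative
from .sbml_compile import (
    ACTIVE_SUFFIX,
    CONV_PARAM,
    INACTIVE_SUFFIX,
    CompiledModel,
    SbmlCompileError,
    read_document,
)

__all__ = ["run_integrated", "load_sbml", "SbmlLoadError"]


class SbmlLoadError(ValueError):
    pass


def _gene_layout(doc: libsbml.SBMLDocument) -> tuple[list[str], dict[str, str]]:
    """Gene ids (in document order) and gene id -> mRNA species id."""
    model = doc.getModel()
    gene_ids = []
    for i in range(model.getNumSpecies()):
        sid = model.getSpecies(i).getId()
        if sid.endswith(ACTIVE_SUFFIX):
            gene_ids.append(sid[: -len(ACTIVE_SUFFIX)])
    mrna_of: dict[str, str] = {}
    for gid in gene_ids:
        rxn = model.getReaction(f"{gid}__transcription")
        if rxn is None:
            raise SbmlLoadError(f"gene {gid!r} has no transcription reaction")
        for k in range(rxn.getNumProducts()):
            sid = rxn.getProduct(k).getSpecies()
            if sid != gid + ACTIVE_SUFFIX:
                mrna_of[gid] = sid
    return gene_ids, mrna_of


def run_integrated(compiled: CompiledModel, config: SimConfig) -> Trajectory:
    """Integrate the whole model in one deterministic solver session.

    ``config.mode`` is ignored: the integrated target is always
    deterministic.  Exactly one solver initialization is performed
    (``Trajectory.n_solver_inits == 1``).
    """
    if compiled.target != "integrated":
        raise ValueError(
            f"run_integrated needs an integrated target, got {compiled.target!r}"
        )
    doc = read_document(compiled)
    ode = OdeSystem.from_document(doc)
    conv = ode.parameters.get(CONV_PARAM, 1.0)
    gene_ids, mrna_of = _gene_layout(doc)
    gene_state_ids = {gid + suf for gid in gene_ids for suf in (ACTIVE_SUFFIX, INACTIVE_SUFFIX)}
    base_ids = [sid for sid in ode.species_ids if sid not in gene_state_ids]
    count_cols = {
        i for i, sid in enumerate(ode.species_ids)
        if ode.substance_units[i] and sid not in gene_state_ids
    }

    times = config.time_grid()
    sol = solve_ivp(
        ode.rhs, (0.0, config.duration), ode.y0, method=config.solver,
        rtol=config.rel_tol, atol=config.abs_tol, t_eval=times,
    )
    if not sol.success:
        raise SimulationError(f"ODE solver failed: {sol.message}")
    raw = sol.y.T.copy()  # [n_recorded, n_state]
    for k in range(raw.shape[0]):
        raw[k] = _clamp_negative(raw[k], config.abs_tol, float(times[k]))

    labels = list(base_ids) + [
        f"{gid}__{q}" for gid in gene_ids for q in ("active", "mrna")
    ]
    states = np.empty((raw.shape[0], len(labels)))
    for j, sid in enumerate(base_ids):
        col = raw[:, ode.index(sid)]
        states[:, j] = col * conv if ode.index(sid) in count_cols else col
    off = len(base_ids)
    for i, gid in enumerate(gene_ids):
        states[:, off + 2 * i] = raw[:, ode.index(gid + ACTIVE_SUFFIX)]
        states[:, off + 2 * i + 1] = raw[:, ode.index(mrna_of[gid])]

    return Trajectory(
        times=times, states=states, labels=labels, mode="integrated",
        seed=None, n_solver_inits=1, handoff=None,
    )


_UNSUPPORTED = (
    ("getNumRules", "rule"),
    ("getNumEvents", "event"),
    ("getNumConstraints", "constraint"),
    ("getNumFunctionDefinitions", "function definition"),
    ("getNumInitialAssignments", "initial assignment"),
)


def load_sbml(path: str | Path) -> CompiledModel:
    """Load a previously built SBML file back into a :class:`CompiledModel`.

    Only this framework's dialect is supported: pure reaction networks.
    Events, rules, constraints, function definitions and initial
    assignments raise :class:`SbmlLoadError` naming the construct.  The
    target is detected from boundary species (present only in the
    biochemistry-only build).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = libsbml.readSBMLFromString(text)
    model = doc.getModel()
    if model is None or any(
        doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        for i in range(doc.getNumErrors())
    ):
        raise SbmlLoadError(f"{path} is not valid SBML")
    for getter, name in _UNSUPPORTED:
        if getattr(model, getter)() > 0:
            raise SbmlLoadError(f"unsupported SBML construct in {path}: {name}")
    has_boundary = any(
        model.getSpecies(i).getBoundaryCondition()
        for i in range(model.getNumSpecies())
    )
    target = "biochem_only" if has_boundary else "integrated"
    index_map = {
        model.getSpecies(i).getId(): i for i in range(model.getNumSpecies())
    }
    return CompiledModel(
        target=target,
        sbml_text=text,
        index_map=index_map,
        provenance={
            "source": str(path),
            "content_hash": hashlib.sha256(text.encode()).hexdigest(),
        },
    )
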