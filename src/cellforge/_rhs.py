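"""Executable ODE right-hand sides compiled from SBML documents.

The compiled targets are plain reaction networks (no events, rules or
delays), so the RHS is the stoichiometry matrix applied to a vector of
kinetic-law fluxes.  Kinetic laws are parsed from SBML math back into sympy
expressions, all parameters (global and reaction-local) are substituted
numerically, and the flux vector is lambdified to numpy once per model.

Rows of boundary-condition species are zeroed: the ODE system treats them
as externally set inputs, which is how the hybrid engine feeds mRNA
concentrations into the biochemistry module between communication steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import libsbml
import numpy as np
import sympy as sp
from sympy.parsing.sympy_parser import parse_expr, standard_transformations

from .sbml_compile import CompiledModel, read_document

__all__ = ["OdeSystem", "RhsError"]


class RhsError(ValueError):
    pass


def _l3_to_sympy(formula: str) -> sp.Expr:
    try:
        return parse_expr(formula.replace("^", "**"),
                          transformations=standard_transformations)
    except Exception as exc:
        raise RhsError(f"cannot parse kinetic law {formula!r}: {exc}") from exc


@dataclass
class OdeSystem:
    species_ids: list[str]
    y0: np.ndarray
    boundary: np.ndarray  # bool mask; rows with zero derivative
    substance_units: np.ndarray  # bool mask; value is a molecule count
    stoichiometry: np.ndarray  # [n_species, n_reactions]
    flux_exprs: list[sp.Expr]
    parameters: dict[str, float]
    _flux_fn: Callable = field(repr=False, default=None)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def index(self, sid: str) -> int:
        return self.species_ids.index(sid)

    @classmethod
    def from_compiled(cls, compiled: CompiledModel) -> "OdeSystem":
        return cls.from_document(read_document(compiled))

    @classmethod
    def from_document(cls, doc: libsbml.SBMLDocument) -> "OdeSystem":
        model = doc.getModel()
        n_sp = model.getNumSpecies()
        species_ids = [model.getSpecies(i).getId() for i in range(n_sp)]
        sp_index = {sid: i for i, sid in enumerate(species_ids)}
        y0 = np.zeros(n_sp)
        boundary = np.zeros(n_sp, dtype=bool)
        substance = np.zeros(n_sp, dtype=bool)
        for i in range(n_sp):
            s = model.getSpecies(i)
            if s.isSetInitialConcentration():
                y0[i] = s.getInitialConcentration()
            elif s.isSetInitialAmount():
                y0[i] = s.getInitialAmount()
            boundary[i] = s.getBoundaryCondition()
            substance[i] = s.getHasOnlySubstanceUnits()

        params = {
            model.getParameter(i).getId(): model.getParameter(i).getValue()
            for i in range(model.getNumParameters())
        }
        comp_sizes = {
            model.getCompartment(i).getId(): model.getCompartment(i).getSize()
            for i in range(model.getNumCompartments())
        }

        n_rxn = model.getNumReactions()
        N = np.zeros((n_sp, n_rxn))
        fluxes: list[sp.Expr] = []
        species_syms = [sp.Symbol(sid) for sid in species_ids]
        for j in range(n_rxn):
            rxn = model.getReaction(j)
            for k in range(rxn.getNumReactants()):
                ref = rxn.getReactant(k)
                N[sp_index[ref.getSpecies()], j] -= ref.getStoichiometry()
            for k in range(rxn.getNumProducts()):
                ref = rxn.getProduct(k)
                N[sp_index[ref.getSpecies()], j] += ref.getStoichiometry()
            kl = rxn.getKineticLaw()
            if kl is None or kl.getMath() is None:
                raise RhsError(f"reaction {rxn.getId()!r} has no kinetic law")
            expr = _l3_to_sympy(libsbml.formulaToL3String(kl.getMath()))
            local = {
                kl.getLocalParameter(k).getId(): kl.getLocalParameter(k).getValue()
                for k in range(kl.getNumLocalParameters())
            }
            subs = {sp.Symbol(n): sp.Float(v) for n, v in {**params, **comp_sizes, **local}.items()}
            expr = expr.subs(subs, simultaneous=True)
            free = {str(s) for s in expr.free_symbols}
            unknown = free - set(species_ids)
            if unknown:
                raise RhsError(
                    f"kinetic law of {rxn.getId()!r} has unresolved symbols {sorted(unknown)}"
                )
            fluxes.append(expr)
        N[boundary, :] = 0.0
        system = cls(
            species_ids=species_ids, y0=y0, boundary=boundary,
            substance_units=substance, stoichiometry=N, flux_exprs=fluxes,
            parameters=params,
        )
        system._compile(species_syms)
        return system

    def _compile(self, species_syms: list[sp.Symbol]) -> None:
        if self.flux_exprs:
            self._flux_fn = sp.lambdify(species_syms, self.flux_exprs, modules="numpy")
        else:
            self._flux_fn = None

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        if self._flux_fn is None:
            return np.zeros_like(y)
        flux = np.asarray(self._flux_fn(*y), dtype=float)
        return self.stoichiometry @ flux
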