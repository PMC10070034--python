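"""Gene-expression module: stochastic telegraph/birth-death kernel and its
deterministic mean-field counterpart.

Each gene carries ``total_alleles`` promoter copies switching between an
inactive and an active state with first-order rates ``k_on`` / ``k_off``
(the telegraph model).  Active alleles transcribe mRNA at ``k_tc`` molecules
per second; mRNA decays at ``k_deg``.  Over one communication interval
``dt`` (regulator concentrations frozen at step start), the stochastic
kernel samples the exact conditional marginals of the underlying
continuous-time process, in order:

1. allele switching — each allele's terminal state is drawn from the exact
   two-state Markov transition over ``dt`` (off->on probability
   ``(k_on/r)(1 - exp(-r dt))`` with ``r = k_on + k_off``, symmetrically
   for on->off), which reduces to the first-switch probability
   ``1 - exp(-k dt)`` whenever the opposing rate is zero;
2. transcription — ``Poisson(k_tc * g_active_start * tau_eff)`` new
   molecules, where ``tau_eff = (1 - exp(-k_deg dt)) / k_deg`` (-> ``dt``
   as ``k_deg -> 0``) accounts for decay of molecules born within the
   step;
3. degradation — binomial thinning of the step-start molecule count with
   survival probability ``exp(-k_deg dt)``.

For rates frozen over the step and allele counts held at their step-start
value in the transcription term, these are the exact marginals of the
telegraph/birth-death process sampled at the communication grid, so the
expectation of a step coincides with the mean-field update (up to the
within-step variation of the allele count, an O(dt^2) transient effect).
The mean-field variant propagates the linear ODE system

    d a/dt = k_on_eff (g_total - a) - k_off a
    d m/dt = k_tc a - k_deg m

exactly over the step (closed-form matrix exponential of a 2x2 triangular
system), so mean mode adds no solver error of its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_tables import GeneRecord, ModelDefinition, RegulationTerm

__all__ = [
    "UnitContext",
    "GeneState",
    "GeneMeanState",
    "effective_kon",
    "step_gene_stochastic",
    "step_gene_mean",
    "gene_mean_rhs",
    "counts_to_concentration",
    "concentration_to_counts",
    "initial_gene_state",
    "initial_gene_mean_state",
]


@dataclass(frozen=True)
class UnitContext:
    """Count <-> concentration bridge between the two modules.

    One mRNA molecule in a cell of volume ``cell_volume`` litres corresponds
    to ``1e9 / (avogadro * cell_volume)`` nM.
    """

    cell_volume: float = 1.0e-12  # L
    avogadro: float = 6.02214076e23  # 1/mol

    def __post_init__(self) -> None:
        if not self.cell_volume > 0:
            raise ValueError(f"cell_volume must be > 0, got {self.cell_volume}")

    @property
    def nM_per_molecule(self) -> float:
        return 1e9 / (self.avogadro * self.cell_volume)


@dataclass
class GeneState:
    """Integer allele-activity counts and mRNA copy numbers, gene-ordered."""

    active: np.ndarray  # int64, per gene
    mrna: np.ndarray  # int64, per gene

    def copy(self) -> "GeneState":
        return GeneState(self.active.copy(), self.mrna.copy())


@dataclass
class GeneMeanState:
    """Real-valued means of allele activity and mRNA copy number."""

    active_mean: np.ndarray  # float64, per gene
    mrna_mean: np.ndarray  # float64, per gene

    def copy(self) -> "GeneMeanState":
        return GeneMeanState(self.active_mean.copy(), self.mrna_mean.copy())


def initial_gene_state(model: ModelDefinition) -> GeneState:
    return GeneState(
        active=np.array([g.init_active for g in model.genes], dtype=np.int64),
        mrna=np.array([g.init_mrna_count for g in model.genes], dtype=np.int64),
    )


def initial_gene_mean_state(model: ModelDefinition) -> GeneMeanState:
    return GeneMeanState(
        active_mean=np.array([float(g.init_active) for g in model.genes]),
        mrna_mean=np.array([float(g.init_mrna_count) for g in model.genes]),
    )


def hill_occupancy(conc: float, term: RegulationTerm) -> float:
    """Weighted Hill occupancy a * c^h / (K^h + c^h) of one regulation term."""
    if conc < 0:
        raise ValueError(f"negative regulator concentration {conc}")
    if conc == 0.0:
        return 0.0
    ch = conc ** term.hill
    return term.weight * ch / (term.half_max_nM ** term.hill + ch)


def effective_kon(
    gene: GeneRecord,
    regulations: list[RegulationTerm],
    regulator_conc: dict[str, float],
) -> float:
    """Regulated activation rate: k_on scaled by Hill factors.

    Activators multiply by ``1 + occupancy``; repressors divide by it.  With
    no applicable terms this returns ``k_on`` unchanged.
    """
    k = gene.k_on
    for term in regulations:
        if term.gene_id != gene.id:
            continue
        occ = hill_occupancy(regulator_conc[term.regulator_species], term)
        if term.mode == "activator":
            k *= 1.0 + occ
        else:
            k /= 1.0 + occ
    return k


def switching_probabilities(kon: float, koff: float, dt: float) -> tuple[float, float]:
    """Exact two-state Markov transition probabilities over one interval.

    Returns (P(off -> on), P(on -> off)).  When the opposing rate is zero
    these reduce to the first-switch probability ``1 - exp(-k dt)``.
    """
    r = kon + koff
    if r <= 0:
        return 0.0, 0.0
    relax = -math.expm1(-r * dt)  # 1 - exp(-r dt)
    return kon / r * relax, koff / r * relax


def effective_exposure(kdeg: float, dt: float) -> float:
    """Expected survival-weighted exposure (1 - exp(-k_deg dt)) / k_deg.

    This is the integral of the end-of-step survival probability over birth
    times within the step; it tends to ``dt`` as ``k_deg -> 0``.
    """
    if kdeg <= 0:
        return dt
    return -math.expm1(-kdeg * dt) / kdeg


def step_gene_stochastic(
    state: GeneState,
    model: ModelDefinition,
    regulator_conc: dict[str, float],
    dt: float,
    rng: np.random.Generator,
) -> GeneState:
    """Advance all genes one communication interval stochastically.

    Regulator concentrations are frozen at step start (Lie splitting); the
    same seed and inputs always produce the same output state.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    active = state.active.copy()
    mrna = state.mrna.copy()
    for i, gene in enumerate(model.genes):
        kon = effective_kon(gene, list(model.regulations), regulator_conc)
        a0 = int(active[i])
        m0 = int(mrna[i])
        n_inactive = gene.total_alleles - a0
        p_on, p_off = switching_probabilities(kon, gene.k_off, dt)
        n_act = rng.binomial(n_inactive, p_on) if n_inactive > 0 and p_on > 0 else 0
        n_deact = rng.binomial(a0, p_off) if a0 > 0 and p_off > 0 else 0
        a1 = a0 - n_deact + n_act
        lam = gene.k_tc * a0 * effective_exposure(gene.k_deg, dt)
        n_new = rng.poisson(lam) if lam > 0 else 0
        p_die = -math.expm1(-gene.k_deg * dt)
        n_dead = rng.binomial(m0, p_die) if m0 > 0 and p_die > 0 else 0
        active[i] = a1
        mrna[i] = m0 + n_new - n_dead
    return GeneState(active, mrna)


def gene_mean_rhs(
    state: GeneMeanState,
    model: ModelDefinition,
    regulator_conc: dict[str, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-field time derivatives (d active_mean/dt, d mrna_mean/dt)."""
    d_active = np.empty(len(model.genes))
    d_mrna = np.empty(len(model.genes))
    for i, gene in enumerate(model.genes):
        kon = effective_kon(gene, list(model.regulations), regulator_conc)
        a = state.active_mean[i]
        m = state.mrna_mean[i]
        d_active[i] = kon * (gene.total_alleles - a) - gene.k_off * a
        d_mrna[i] = gene.k_tc * a - gene.k_deg * m
    return d_active, d_mrna


def _propagate_linear(
    a0: float, m0: float, kon: float, koff: float, ktc: float, kdeg: float,
    g_total: float, dt: float,
) -> tuple[float, float]:
    """Exact solution of the frozen-rate mean ODE after time dt.

    a(t) relaxes exponentially to kon*g/(kon+koff); m(t) is the forced
    first-order response to a(t).  Degenerate rate combinations (r = 0,
    kdeg = 0, kdeg = r) are handled by their analytic limits.
    """
    r = kon + koff
    if r > 0:
        a_inf = kon * g_total / r
        c = a0 - a_inf
        a1 = a_inf + c * math.exp(-r * dt)
    else:
        a_inf, c, a1 = a0, 0.0, a0
    if kdeg > 0:
        e_deg = math.exp(-kdeg * dt)
        m1 = m0 * e_deg + ktc * a_inf * -math.expm1(-kdeg * dt) / kdeg
        if c != 0.0:
            if abs(kdeg - r) > 1e-12 * max(kdeg, r):
                phi = (math.exp(-r * dt) - e_deg) / (kdeg - r)
            else:
                phi = dt * e_deg
            m1 += ktc * c * phi
    else:
        if r > 0:
            m1 = m0 + ktc * (a_inf * dt + c * -math.expm1(-r * dt) / r)
        else:
            m1 = m0 + ktc * a0 * dt
    return a1, m1


def step_gene_mean(
    state: GeneMeanState,
    model: ModelDefinition,
    regulator_conc: dict[str, float],
    dt: float,
) -> GeneMeanState:
    """Advance the mean-field gene state one interval (exact propagator)."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    active = state.active_mean.copy()
    mrna = state.mrna_mean.copy()
    for i, gene in enumerate(model.genes):
        kon = effective_kon(gene, list(model.regulations), regulator_conc)
        active[i], mrna[i] = _propagate_linear(
            active[i], mrna[i], kon, gene.k_off, gene.k_tc, gene.k_deg,
            gene.total_alleles, dt,
        )
    return GeneMeanState(active, mrna)


def counts_to_concentration(
    state: GeneState | GeneMeanState,
    model: ModelDefinition,
    units: UnitContext,
) -> dict[str, float]:
    """Map each gene's mRNA copy number (or mean) to nM."""
    mrna = state.mrna if isinstance(state, GeneState) else state.mrna_mean
    out: dict[str, float] = {}
    for i, gene in enumerate(model.genes):
        m = float(mrna[i])
        if m < 0:
            raise ValueError(f"negative mRNA count {m} for gene {gene.id}")
        out[gene.mrna_species] = m * units.nM_per_molecule
    return out


def concentration_to_counts(
    conc: dict[str, float],
    units: UnitContext,
    integer: bool = True,
) -> dict[str, float]:
    """Inverse conversion; rounds to the nearest integer for stochastic mode."""
    out: dict[str, float] = {}
    for sid, c in conc.items():
        if c < 0:
            raise ValueError(f"negative concentration {c} for species {sid}")
        m = c / units.nM_per_molecule
        out[sid] = float(round(m)) if integer else m
    return out
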