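"""Desk-scale fixture models: coupled gene expression + protein biochemistry.

The generated models reproduce, at 2-20 gene scale, the structure of the
large single-cell mechanistic models this framework targets: telegraph
genes transcribe mRNA; each mRNA drives synthesis of a protein; proteins
degrade; a small signaling cascade is stimulated by the first protein; and
(optionally) the terminal signal species feeds back onto gene 0's
activation rate, closing a loop across the module boundary.

Models are initialized at the unregulated mean-field steady state with a
stimulus bolus on the first signal species — the serum-starved-then-treated
pattern — so dynamics are a relaxation through the cascade rather than a
global start-up transient.  Rate ranges are chosen so 72 h dynamics are
non-trivial but non-stiff at the default solver tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gene_module import UnitContext
from .model_tables import (
    GeneRecord,
    ModelDefinition,
    ReactionRecord,
    RegulationTerm,
    SpeciesRecord,
)

__all__ = ["ToySpec", "make_toy", "make_constitutive_benchmark"]


@dataclass(frozen=True)
class ToySpec:
    n_genes: int = 2
    n_signal_species: int = 3
    with_regulation: bool = False
    seed: int = 0
    stimulus_factor: float = 5.0  # fold-elevation of S0 over its steady state
    # per-second rate ranges, sampled log-uniformly
    k_on_range: tuple[float, float] = (1e-4, 1e-2)
    k_off_range: tuple[float, float] = (1e-4, 1e-2)
    k_tc_range: tuple[float, float] = (0.01, 0.2)
    k_deg_range: tuple[float, float] = (1e-4, 1e-3)

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.n_signal_species < 1:
            raise ValueError("n_signal_species must be >= 1")


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))


def make_toy(spec: ToySpec, units: UnitContext = UnitContext()) -> ModelDefinition:
    """Deterministically generate a valid toy model from a :class:`ToySpec`."""
    rng = np.random.default_rng(spec.seed)
    conv = units.nM_per_molecule
    G, M = spec.n_genes, spec.n_signal_species

    genes: list[GeneRecord] = []
    species: list[SpeciesRecord] = []
    reactions: list[ReactionRecord] = []
    regulations: list[RegulationTerm] = []

    gene_params = []
    for i in range(G):
        gene_params.append(
            dict(
                k_on=_loguniform(rng, *spec.k_on_range),
                k_off=_loguniform(rng, *spec.k_off_range),
                k_tc=_loguniform(rng, *spec.k_tc_range),
                k_deg=_loguniform(rng, *spec.k_deg_range),
                k_syn=_loguniform(rng, 1e-4, 1e-3),
                k_pdeg=_loguniform(rng, 2e-5, 1e-4),
            )
        )
    k_in = _loguniform(rng, 1e-3, 5e-3)
    k_cas = [_loguniform(rng, 5e-4, 2e-3) for _ in range(max(M - 1, 0))]
    k_out = _loguniform(rng, 2e-4, 1e-3)

    # regulated gene 0 sees an elevated activation rate at baseline occupancy
    # (activator at its half-max: factor 1.5); fold that into its steady state
    kon_eff0 = 1.0
    total_alleles = 2

    def gene_steady(i: int, kon_factor: float) -> tuple[int, int]:
        p = gene_params[i]
        kon = p["k_on"] * kon_factor
        a_mean = total_alleles * kon / (kon + p["k_off"])
        m_mean = p["k_tc"] * a_mean / p["k_deg"]
        return int(round(a_mean)), int(round(m_mean))

    mrna_nM = []
    for i in range(G):
        factor = 1.5 if (spec.with_regulation and i == 0) else kon_eff0
        init_active, init_mrna = gene_steady(i, factor)
        p = gene_params[i]
        genes.append(
            GeneRecord(
                id=f"G{i}", total_alleles=total_alleles,
                k_on=p["k_on"], k_off=p["k_off"], k_tc=p["k_tc"], k_deg=p["k_deg"],
                mrna_species=f"mG{i}", init_active=init_active,
                init_mrna_count=init_mrna,
            )
        )
        mrna_nM.append(init_mrna * conv)
        species.append(
            SpeciesRecord(f"mG{i}", f"mRNA of gene {i}", "cell", init_mrna * conv, True)
        )

    protein_init = []
    for i in range(G):
        p = gene_params[i]
        p0 = p["k_syn"] * mrna_nM[i] / p["k_pdeg"]
        protein_init.append(p0)
        species.append(SpeciesRecord(f"P{i}", f"protein {i}", "cell", p0, False))
        reactions.append(
            ReactionRecord(
                id=f"syn{i}", reactants=(), products=((f"P{i}", 1),),
                rate_law=f"k_syn * mG{i}", parameters=(("k_syn", p["k_syn"]),),
            )
        )
        reactions.append(
            ReactionRecord(
                id=f"pdeg{i}", reactants=((f"P{i}", 1),), products=(),
                rate_law=f"k_pdeg * P{i}", parameters=(("k_pdeg", p["k_pdeg"]),),
            )
        )

    # signaling cascade S0 -> S1 -> ... stimulated by protein 0 when present
    if G >= 1 and protein_init[0] > 0:
        Ks = protein_init[0]  # half-max at baseline: influx factor 1.5
        influx = k_in * (1.0 + protein_init[0] / (Ks + protein_init[0]))
        in_law = f"k_in * (1 + P0 / (Ks + P0))"
        in_params = (("k_in", k_in), ("Ks", Ks))
    else:
        influx = k_in
        in_law = "k_in"
        in_params = (("k_in", k_in),)
    sig_steady = [influx / k_cas[j] for j in range(M - 1)] + [influx / k_out]
    for j in range(M):
        init = sig_steady[j] * (spec.stimulus_factor if j == 0 else 1.0)
        species.append(SpeciesRecord(f"S{j}", f"signal {j}", "cell", init, False))
    reactions.append(
        ReactionRecord(id="s_in", reactants=(), products=(("S0", 1),),
                       rate_law=in_law, parameters=in_params)
    )
    for j in range(M - 1):
        reactions.append(
            ReactionRecord(
                id=f"cas{j}", reactants=((f"S{j}", 1),), products=((f"S{j+1}", 1),),
                rate_law=f"k_cas * S{j}", parameters=(("k_cas", k_cas[j]),),
            )
        )
    reactions.append(
        ReactionRecord(
            id="s_out", reactants=((f"S{M-1}", 1),), products=(),
            rate_law=f"k_out * S{M-1}", parameters=(("k_out", k_out),),
        )
    )

    if spec.with_regulation and G >= 1:
        regulations.append(
            RegulationTerm(
                gene_id="G0", regulator_species=f"S{M-1}", mode="activator",
                half_max_nM=sig_steady[M - 1], hill=1.0, weight=1.0,
            )
        )

    return ModelDefinition(
        compartments=(("cell", units.cell_volume),),
        species=tuple(species),
        reactions=tuple(reactions),
        genes=tuple(genes),
        regulations=tuple(regulations),
    )


def make_constitutive_benchmark(
    init_mrna_count: int = 0,
    with_protein: bool = False,
    units: UnitContext = UnitContext(),
) -> ModelDefinition:
    """Closed-form oracle model: one always-active gene.

    With ``k_on = k_off = 0`` and both alleles initially active, the mean
    mRNA count follows m(t) = m0 e^(-k_deg t) + (k_tc g / k_deg)(1 - e^(-k_deg t)),
    and the stochastic mRNA count is a linear birth-death process with
    Poisson(k_tc g / k_deg) stationary law.  ``with_protein`` adds one
    mRNA-driven synthesis reaction and first-order protein decay, keeping
    every species analytically solvable.
    """
    k_tc, k_deg, g_total = 0.1, 5e-4, 2
    conv = units.nM_per_molecule
    species = [
        SpeciesRecord("mG0", "constitutive mRNA", "cell", init_mrna_count * conv, True)
    ]
    reactions: list[ReactionRecord] = []
    if with_protein:
        k_syn, k_pdeg = 1e-3, 5e-5
        p0 = k_syn * (init_mrna_count * conv) / k_pdeg
        species.append(SpeciesRecord("P0", "reporter protein", "cell", p0, False))
        reactions.append(
            ReactionRecord("syn0", (), (("P0", 1),), "k_syn * mG0",
                           (("k_syn", k_syn),))
        )
        reactions.append(
            ReactionRecord("pdeg0", (("P0", 1),), (), "k_pdeg * P0",
                           (("k_pdeg", k_pdeg),))
        )
    gene = GeneRecord(
        id="G0", total_alleles=g_total, k_on=0.0, k_off=0.0,
        k_tc=k_tc, k_deg=k_deg, mrna_species="mG0",
        init_active=g_total, init_mrna_count=init_mrna_count,
    )
    return ModelDefinition(
        compartments=(("cell", units.cell_volume),),
        species=tuple(species),
        reactions=tuple(reactions),
        genes=(gene,),
        regulations=(),
    )
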