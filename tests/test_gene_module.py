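import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

from cellforge.gene_module import (
    GeneMeanState,
    GeneState,
    UnitContext,
    concentration_to_counts,
    counts_to_concentration,
    effective_kon,
    effective_exposure,
    gene_mean_rhs,
    initial_gene_mean_state,
    initial_gene_state,
    step_gene_mean,
    step_gene_stochastic,
    switching_probabilities,
)
from cellforge.model_tables import (
    GeneRecord,
    ModelDefinition,
    RegulationTerm,
    SpeciesRecord,
)


def one_gene_model(**gene_kwargs) -> ModelDefinition:
    defaults = dict(id="G0", total_alleles=2, k_on=0.0, k_off=0.0, k_tc=0.0,
                    k_deg=0.0, mrna_species="mG0", init_active=0,
                    init_mrna_count=0)
    defaults.update(gene_kwargs)
    return ModelDefinition(
        compartments=(("cell", 1e-12),),
        species=(SpeciesRecord("mG0", "mRNA", "cell", 0.0, True),
                 SpeciesRecord("R", "regulator", "cell", 0.0, False)),
        reactions=(),
        genes=(GeneRecord(**defaults),),
    )


# ---------------------------------------------------------------------------
# effective_kon


def test_effective_kon_identity_without_regulation():
    m = one_gene_model(k_on=3e-3)
    assert effective_kon(m.genes[0], [], {"R": 10.0}) == 3e-3


def test_effective_kon_activator_half_max():
    m = one_gene_model(k_on=2e-3)
    term = RegulationTerm("G0", "R", "activator", half_max_nM=5.0, hill=1.0, weight=1.0)
    assert effective_kon(m.genes[0], [term], {"R": 5.0}) == pytest.approx(2e-3 * 1.5)


def test_effective_kon_repressor_saturation():
    m = one_gene_model(k_on=2e-3)
    term = RegulationTerm("G0", "R", "repressor", half_max_nM=5.0, hill=1.0, weight=1.0)
    assert effective_kon(m.genes[0], [term], {"R": 1e12}) == pytest.approx(1e-3, rel=1e-6)


def test_effective_kon_ignores_other_genes_terms():
    m = one_gene_model(k_on=2e-3)
    term = RegulationTerm("G9", "R", "activator", 5.0, 1.0, 1.0)
    assert effective_kon(m.genes[0], [term], {"R": 5.0}) == 2e-3


# ---------------------------------------------------------------------------
# stochastic kernel


def test_null_dynamics_returns_state_unchanged():
    m = one_gene_model(init_active=1, init_mrna_count=7)
    state = initial_gene_state(m)
    rng = np.random.default_rng(0)
    out = step_gene_stochastic(state, m, {}, dt=30.0, rng=rng)
    assert out.active.tolist() == [1] and out.mrna.tolist() == [7]


def test_step_rejects_nonpositive_dt():
    m = one_gene_model()
    with pytest.raises(ValueError):
        step_gene_stochastic(initial_gene_state(m), m, {}, 0.0, np.random.default_rng(0))
    with pytest.raises(ValueError):
        step_gene_mean(initial_gene_mean_state(m), m, {}, -1.0)


def test_same_seed_same_output():
    m = one_gene_model(k_on=5e-3, k_off=2e-3, k_tc=0.1, k_deg=5e-4,
                       init_active=1, init_mrna_count=50)
    s = initial_gene_state(m)
    a = step_gene_stochastic(s, m, {}, 30.0, np.random.default_rng(42))
    b = step_gene_stochastic(s, m, {}, 30.0, np.random.default_rng(42))
    assert np.array_equal(a.active, b.active) and np.array_equal(a.mrna, b.mrna)


def test_transcription_increment_poisson_moments():
    """Constitutive two-allele gene, no decay: increment ~ Poisson(k_tc*g*dt)=Poisson(6)."""
    m = one_gene_model(k_tc=0.1, init_active=2)
    rng = np.random.default_rng(123)
    n = 10_000
    state = initial_gene_state(m)
    draws = np.array([
        step_gene_stochastic(state, m, {}, 30.0, rng).mrna[0] for _ in range(n)
    ])
    lam = 6.0
    se_mean = math.sqrt(lam / n)
    assert abs(draws.mean() - lam) <= 3 * se_mean
    # Poisson: variance equals mean; sampling band from Var(s^2) ~ (mu4 - sigma^4)/n
    mu4 = lam * (1 + 3 * lam)
    se_var = math.sqrt((mu4 - lam**2) / n)
    assert abs(draws.var(ddof=1) - lam) <= 4 * se_var


def test_binomial_survival_half_life_mean():
    """k_deg*dt = ln 2 halves the population on average."""
    kdeg = math.log(2) / 30.0
    m = one_gene_model(k_deg=kdeg, init_mrna_count=1000)
    rng = np.random.default_rng(7)
    n = 10_000
    state = initial_gene_state(m)
    draws = np.array([
        step_gene_stochastic(state, m, {}, 30.0, rng).mrna[0] for _ in range(n)
    ])
    se = math.sqrt(1000 * 0.25 / n)
    assert abs(draws.mean() - 500.0) <= 3 * se


def _chisquare_pvalue(samples, pmf, lo, hi):
    """Chi-square GoF against a discrete law, tails aggregated to >=5 expected."""
    n = len(samples)
    ks = np.arange(lo, hi + 1)
    expected = pmf(ks) * n
    exp_bins = [n * pmf_below(pmf, lo)] + list(expected) + [n * pmf_above(pmf, hi)]
    obs_bins = (
        [np.sum(samples < lo)]
        + [np.sum(samples == k) for k in ks]
        + [np.sum(samples > hi)]
    )
    exp_arr, obs_arr = np.array(exp_bins), np.array(obs_bins, dtype=float)
    keep = exp_arr > 1e-9
    exp_arr, obs_arr = exp_arr[keep], obs_arr[keep]
    exp_arr *= obs_arr.sum() / exp_arr.sum()
    return stats.chisquare(obs_arr, exp_arr).pvalue


def pmf_below(pmf, lo):
    return float(sum(pmf(np.arange(0, lo)))) if lo > 0 else 0.0


def pmf_above(pmf, hi):
    return max(0.0, 1.0 - float(sum(pmf(np.arange(0, hi + 1)))))


def test_marginal_distributions_goodness_of_fit():
    """Per-substep marginals match their analytic laws (alpha = 0.001, n = 10000)."""
    rng = np.random.default_rng(2024)
    n = 10_000
    dt = 30.0

    # allele switching: exact two-state transition from the inactive state
    kon, koff = 5e-3, 2e-3
    m_sw = one_gene_model(k_on=kon, k_off=koff, total_alleles=1, init_active=0)
    state = initial_gene_state(m_sw)
    ons = np.array([
        step_gene_stochastic(state, m_sw, {}, dt, rng).active[0] for _ in range(n)
    ])
    p_on, _ = switching_probabilities(kon, koff, dt)
    p = stats.chisquare(
        [np.sum(ons == 1), np.sum(ons == 0)], [n * p_on, n * (1 - p_on)]
    ).pvalue
    assert p > 0.001

    # transcription with decay-corrected exposure: Poisson(k_tc*g*tau_eff)
    ktc, kdeg = 0.1, 2e-4
    m_tc = one_gene_model(k_tc=ktc, k_deg=kdeg, init_active=2)
    state = initial_gene_state(m_tc)  # m0 = 0, so no deaths: pure Poisson draw
    counts = np.array([
        step_gene_stochastic(state, m_tc, {}, dt, rng).mrna[0] for _ in range(n)
    ])
    lam = ktc * 2 * effective_exposure(kdeg, dt)
    p = _chisquare_pvalue(counts, lambda k: stats.poisson.pmf(k, lam), 1, 13)
    assert p > 0.001

    # degradation: survivors ~ Binomial(m0, exp(-k_deg dt))
    kdeg2 = math.log(2) / dt
    m_dg = one_gene_model(k_deg=kdeg2, init_mrna_count=1000)
    state = initial_gene_state(m_dg)
    surv = np.array([
        step_gene_stochastic(state, m_dg, {}, dt, rng).mrna[0] for _ in range(n)
    ])
    p = _chisquare_pvalue(
        surv, lambda k: stats.binom.pmf(k, 1000, 0.5), 450, 550
    )
    assert p > 0.001


def test_step_expectation_matches_mean_field_to_second_order():
    """Kernel expectation vs mean-field step discrepancy shrinks >=10x as dt 30 -> 3."""
    kon, koff, ktc, kdeg, g = 8e-3, 4e-3, 0.15, 8e-4, 2
    m = one_gene_model(k_on=kon, k_off=koff, k_tc=ktc, k_deg=kdeg,
                       init_active=0, init_mrna_count=100)

    def kernel_expectation(a0, m0, dt):
        p_on, p_off = switching_probabilities(kon, koff, dt)
        ea = a0 * (1 - p_off) + (g - a0) * p_on
        em = m0 * math.exp(-kdeg * dt) + ktc * a0 * effective_exposure(kdeg, dt)
        return ea, em

    def discrepancy(dt):
        mean1 = step_gene_mean(initial_gene_mean_state(m), m, {}, dt)
        ea, em = kernel_expectation(0.0, 100.0, dt)
        return abs(mean1.active_mean[0] - ea) + abs(mean1.mrna_mean[0] - em)

    d30, d3 = discrepancy(30.0), discrepancy(3.0)
    assert d3 <= d30 / 10


# ---------------------------------------------------------------------------
# mean field


def test_rhs_zero_at_fixed_point():
    kon, koff, ktc, kdeg, g = 5e-3, 2e-3, 0.1, 5e-4, 2
    m = one_gene_model(k_on=kon, k_off=koff, k_tc=ktc, k_deg=kdeg)
    a_star = g * kon / (kon + koff)
    state = GeneMeanState(np.array([a_star]), np.array([ktc * a_star / kdeg]))
    da, dm = gene_mean_rhs(state, m, {})
    assert abs(da[0]) < 1e-15 and abs(dm[0]) < 1e-12


def test_rhs_from_empty_state_is_activation_flux():
    m = one_gene_model(k_on=5e-3)
    da, dm = gene_mean_rhs(GeneMeanState(np.array([0.0]), np.array([0.0])), m, {})
    assert da[0] == pytest.approx(5e-3 * 2)
    assert dm[0] == 0.0


@pytest.mark.parametrize("kon,koff,ktc,kdeg", [
    (5e-3, 2e-3, 0.1, 5e-4),
    (0.0, 0.0, 0.1, 5e-4),     # constitutive with decay
    (0.0, 0.0, 0.1, 0.0),      # pure accumulation
    (5e-3, 2e-3, 0.1, 0.0),    # switching, no decay
    (1e-3, 1e-3, 0.05, 2e-3),  # k_deg near k_on + k_off regime
    (2e-3, 0.0, 0.08, 2e-3),   # k_deg == k_on + k_off (degenerate branch)
])
def test_exact_propagator_matches_rhs_integration(kon, koff, ktc, kdeg):
    """One mean step equals high-accuracy integration of gene_mean_rhs."""
    m = one_gene_model(k_on=kon, k_off=koff, k_tc=ktc, k_deg=kdeg,
                       init_active=1, init_mrna_count=40)

    def rhs(t, y):
        da, dm = gene_mean_rhs(GeneMeanState(y[:1], y[1:]), m, {})
        return np.concatenate([da, dm])

    dt = 500.0
    sol = solve_ivp(rhs, (0, dt), [1.0, 40.0], rtol=1e-11, atol=1e-12)
    stepped = step_gene_mean(initial_gene_mean_state(m), m, {}, dt)
    assert stepped.active_mean[0] == pytest.approx(sol.y[0, -1], rel=1e-7, abs=1e-9)
    assert stepped.mrna_mean[0] == pytest.approx(sol.y[1, -1], rel=1e-7, abs=1e-9)


def test_constitutive_mean_stepping_reproduces_closed_form():
    ktc, kdeg, g = 0.1, 5e-4, 2
    m = one_gene_model(k_tc=ktc, k_deg=kdeg, init_active=2)
    state = initial_gene_mean_state(m)
    t = 0.0
    for _ in range(120):
        state = step_gene_mean(state, m, {}, 30.0)
        t += 30.0
        expected = ktc * g / kdeg * -math.expm1(-kdeg * t)
        assert state.mrna_mean[0] == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# unit conversions


def test_counts_to_concentration_definitional():
    units = UnitContext()
    m = one_gene_model(init_mrna_count=0)
    assert counts_to_concentration(initial_gene_state(m), m, units)["mG0"] == 0.0
    one_nM_count = units.avogadro * units.cell_volume * 1e-9  # ~602 molecules
    state = GeneMeanState(np.array([2.0]), np.array([one_nM_count]))
    conc = counts_to_concentration(state, m, units)["mG0"]
    assert conc == pytest.approx(1.0, rel=1e-12)


def test_count_conc_round_trip_is_identity():
    units = UnitContext()
    for count in (0, 1, 17, 400, 123456):
        m = one_gene_model(init_mrna_count=count)
        conc = counts_to_concentration(initial_gene_state(m), m, units)
        back = concentration_to_counts(conc, units)
        assert back["mG0"] == count


def test_negative_concentration_rejected():
    with pytest.raises(ValueError):
        concentration_to_counts({"x": -1.0}, UnitContext())
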