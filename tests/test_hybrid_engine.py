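import math
from types import SimpleNamespace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cellforge.gene_module import UnitContext
from cellforge.hybrid_engine import (
    HandoffRecord,
    SimConfig,
    SimulationError,
    extract_terminal_state,
    run_ensemble,
    run_hybrid,
)
from cellforge.model_tables import ModelDefinition, SpeciesRecord
from cellforge.sbml_compile import build_biochem_sbml
from cellforge.toygen import ToySpec, make_constitutive_benchmark, make_toy


def test_config_invariants():
    with pytest.raises(ValueError):
        SimConfig(duration=100, dt=30)  # not an integer number of intervals
    with pytest.raises(ValueError):
        SimConfig(duration=-1)
    with pytest.raises(ValueError):
        SimConfig(mode="fancy")
    cfg = SimConfig(duration=259200, dt=30)
    assert cfg.n_steps == 8640


def test_null_model_constant_trajectory():
    m = ModelDefinition(
        compartments=(("cell", 1e-12),),
        species=(SpeciesRecord("A", "inert", "cell", 2.5, False),),
        reactions=(), genes=(),
    )
    traj = run_hybrid(build_biochem_sbml(m), m, SimConfig(duration=600, dt=30, mode="mean"))
    assert traj.states.shape == (21, 1)
    assert np.all(traj.states == 2.5)


def test_trajectory_grid_shape(toy2, toy2_biochem):
    cfg = SimConfig(duration=900, dt=30, mode="mean")
    traj = run_hybrid(toy2_biochem, toy2, cfg)
    assert traj.times.shape == (31,)
    assert np.allclose(np.diff(traj.times), 30.0)
    assert traj.states.shape[0] == cfg.n_steps + 1


def _monolithic_toy2_rhs(model, units: UnitContext):
    """Hand-written combined mean-field RHS for the 2-gene toy structure.

    Independent of the SBML compiler and engine code paths: reads rates
    straight from the table records and writes out the coupled ODEs.
    """
    conv = units.nM_per_molecule
    g0, g1 = model.genes
    p = {r.id: r.parameter_map() for r in model.reactions}

    def rhs(t, y):
        a0, m0, a1, m1, P0, P1, S0, S1, S2 = y
        da0 = g0.k_on * (g0.total_alleles - a0) - g0.k_off * a0
        dm0 = g0.k_tc * a0 - g0.k_deg * m0
        da1 = g1.k_on * (g1.total_alleles - a1) - g1.k_off * a1
        dm1 = g1.k_tc * a1 - g1.k_deg * m1
        dP0 = p["syn0"]["k_syn"] * m0 * conv - p["pdeg0"]["k_pdeg"] * P0
        dP1 = p["syn1"]["k_syn"] * m1 * conv - p["pdeg1"]["k_pdeg"] * P1
        influx = p["s_in"]["k_in"] * (1 + P0 / (p["s_in"]["Ks"] + P0))
        dS0 = influx - p["cas0"]["k_cas"] * S0
        dS1 = p["cas0"]["k_cas"] * S0 - p["cas1"]["k_cas"] * S1
        dS2 = p["cas1"]["k_cas"] * S1 - p["s_out"]["k_out"] * S2
        return [da0, dm0, da1, dm1, dP0, dP1, dS0, dS1, dS2]

    return rhs


def test_mean_mode_matches_monolithic_integration(toy2, toy2_biochem, toy2_mean_run):
    """Hybrid mean mode vs direct integration of the hand-written coupled ODEs."""
    units = UnitContext()
    rhs = _monolithic_toy2_rhs(toy2, units)
    g0, g1 = toy2.genes
    sidx = {s.id: i for i, s in enumerate(toy2.species)}
    y0 = [
        g0.init_active, g0.init_mrna_count, g1.init_active, g1.init_mrna_count,
        toy2.species[sidx["P0"]].initial_nM, toy2.species[sidx["P1"]].initial_nM,
        toy2.species[sidx["S0"]].initial_nM, toy2.species[sidx["S1"]].initial_nM,
        toy2.species[sidx["S2"]].initial_nM,
    ]
    traj = toy2_mean_run
    sol = solve_ivp(rhs, (0, traj.times[-1]), y0, method="LSODA",
                    rtol=1e-10, atol=1e-14, t_eval=traj.times)
    ref = {
        "G0__active": sol.y[0], "G0__mrna": sol.y[1],
        "G1__active": sol.y[2], "G1__mrna": sol.y[3],
        "P0": sol.y[4], "P1": sol.y[5],
        "S0": sol.y[6], "S1": sol.y[7], "S2": sol.y[8],
        "mG0": sol.y[1] * units.nM_per_molecule,
        "mG1": sol.y[3] * units.nM_per_molecule,
    }
    for label, expected in ref.items():
        got = traj.column(label)
        scale = np.abs(expected).max()
        assert np.abs(got - expected).max() <= 1e-4 * scale, label


def test_splitting_error_first_order_in_dt():
    """Max discrepancy vs the monolithic solution shrinks ~linearly with dt."""
    units = UnitContext()
    model = make_constitutive_benchmark(init_mrna_count=0, with_protein=True)
    gene = model.genes[0]
    pars = {r.id: r.parameter_map() for r in model.reactions}
    k_syn, k_pdeg = pars["syn0"]["k_syn"], pars["pdeg0"]["k_pdeg"]

    def rhs(t, y):
        m, P = y
        return [gene.k_tc * gene.total_alleles - gene.k_deg * m,
                k_syn * m * units.nM_per_molecule - k_pdeg * P]

    compiled = build_biochem_sbml(model)
    errs = {}
    for dt in (30.0, 3.0):
        cfg = SimConfig(duration=3600, dt=dt, mode="mean")
        traj = run_hybrid(compiled, model, cfg)
        sol = solve_ivp(rhs, (0, 3600), [0.0, 0.0], method="LSODA",
                        rtol=1e-11, atol=1e-14, t_eval=traj.times)
        ref_P = sol.y[1]
        err = np.abs(traj.column("P0") - ref_P).max() / np.abs(ref_P).max()
        errs[dt] = err
    assert errs[3.0] <= errs[30.0] / 5  # at least first-order decay


def test_extract_terminal_state_endpoint_invariance():
    one = SimpleNamespace(y=np.array([[1.0], [2.0], [3.0]]))
    many = SimpleNamespace(y=np.column_stack([np.zeros((3, 99)), [1.0, 2.0, 3.0]]))
    rec = HandoffRecord()
    assert np.array_equal(extract_terminal_state(one, rec),
                          extract_terminal_state(many, rec))
    assert rec.values_copied == [3, 3]
    assert rec.retrievals == [1, 1]
    with pytest.raises(SimulationError):
        extract_terminal_state(SimpleNamespace(y=np.empty((3, 0))))


def test_handoff_contract_independent_of_solver_density(toy2, toy2_biochem):
    """Values copied per step == n_species whatever the internal resolution."""
    n_species = len(toy2.species)
    for rtol in (1e-6, 1e-9):  # tighter tolerance -> denser internal stepping
        cfg = SimConfig(duration=600, dt=30, mode="mean", rel_tol=rtol)
        traj = run_hybrid(toy2_biochem, toy2, cfg)
        assert traj.handoff.values_per_step == {n_species}
        assert traj.handoff.n_steps == cfg.n_steps
        assert traj.handoff.total_values == n_species * cfg.n_steps


def test_stochastic_run_bitwise_reproducible(toy2, toy2_biochem):
    cfg = SimConfig(duration=900, dt=30, mode="stochastic", seed=5)
    a = run_hybrid(toy2_biochem, toy2, cfg)
    b = run_hybrid(toy2_biochem, toy2, cfg)
    assert np.array_equal(a.states, b.states)
    assert a.mode == "stochastic" and a.seed == 5


def test_ensemble_seeding_contract(toy2, toy2_biochem):
    cfg = SimConfig(duration=600, dt=30, mode="stochastic", seed=3)
    single = run_hybrid(toy2_biochem, toy2, cfg)
    ens = run_ensemble(toy2_biochem, toy2, cfg, 2)
    assert np.array_equal(ens[0].states, single.states)  # cell 0 uses base seed
    assert not np.array_equal(ens[0].states, ens[1].states)  # cells diverge
    again = run_ensemble(toy2_biochem, toy2, cfg, 2)
    for t1, t2 in zip(ens, again):
        assert np.array_equal(t1.states, t2.states)
    with pytest.raises(ValueError):
        run_ensemble(toy2_biochem, toy2, SimConfig(duration=600, dt=30, mode="mean"), 2)


def test_wrong_target_rejected(toy2, toy2_integrated):
    with pytest.raises(ValueError):
        run_hybrid(toy2_integrated, toy2, SimConfig(duration=600, dt=30, mode="mean"))


def test_trajectory_tsv_round_trip(tmp_path, toy2_mean_run):
    path = tmp_path / "traj.tsv"
    toy2_mean_run.write_tsv(path)
    from cellforge.hybrid_engine import Trajectory

    back = Trajectory.read_tsv(path)
    assert back.labels == toy2_mean_run.labels
    assert np.allclose(back.states, toy2_mean_run.states, rtol=1e-14, atol=0)
    assert np.allclose(back.times, toy2_mean_run.times)
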