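"""Engine: initialization, step ordering, reproducibility, run control."""

import dataclasses

import numpy as np
import pytest

import pubgoodsim as pg
from pubgoodsim.engine import (
    EMPTY,
    RESISTANT,
    SENSITIVE,
    _cell_pass_kernel,
    _cell_pass_python,
    initialize,
    run,
    snapshot_from_state,
    step,
)


def test_default_initialization_full_sensitive_lattice():
    state = initialize(pg.SimulationParams(seed=1))
    assert state.population_size == 2601
    assert np.all(state.occupancy == SENSITIVE)
    assert np.all((state.vitality > 0) & (state.vitality < 1))
    assert state.sensitive_field.concentrations.sum() == 0.0
    assert state.resistant_field.concentrations.sum() == 0.0
    assert state.first_mutation_step is None


def test_initialization_reproducible_bit_for_bit():
    p = pg.SimulationParams(seed=42)
    a, b = initialize(p), initialize(p)
    assert np.array_equal(a.occupancy, b.occupancy)
    assert np.array_equal(a.vitality, b.vitality)


def test_small_lattice_initialization():
    p = pg.SimulationParams(lattice=pg.LatticeConfig(width=3, height=3), seed=0)
    state = initialize(p)
    assert state.population_size == 9


def test_lone_resistant_cell_saturates_vitality():
    """On a 1x1 lattice at T=0 a resistant cell keeps its whole unit of
    product, so one step drives v to exactly 1 and it cannot die."""
    p = pg.SimulationParams(
        lattice=pg.LatticeConfig(width=1, height=1), transfer_coefficient=0.0, dose=1.0, seed=5
    )
    state = initialize(p)
    state.occupancy[0, 0] = RESISTANT
    state.vitality[0, 0] = 0.37
    step(state, p)
    assert state.occupancy[0, 0] == RESISTANT
    assert state.vitality[0, 0] == 1.0
    assert state.resistant_field.concentrations[0, 0] == 1.0


def test_lone_sensitive_cell_gets_no_product_at_full_dose():
    occ = np.array([[SENSITIVE]], dtype=np.int8)
    vit = np.array([[0.77]])
    psum = np.zeros((1, 1))  # full dose destroyed all sensitive product
    draws = np.array([[0.99, 0.0, 0.0, 0.0, 0.0]])  # survives its death trial
    _cell_pass_python(occ, vit, psum, np.array([0]), draws, 0.9, 1e-3, 0.0)
    assert vit[0, 0] == 0.77


def test_empty_lattice_step_is_noop():
    p = pg.SimulationParams(lattice=pg.LatticeConfig(width=4, height=4), seed=0)
    state = initialize(p)
    state.occupancy[:] = EMPTY
    state.vitality[:] = 0.0
    step(state, p)
    assert state.step_index == 1
    assert state.population_size == 0


@pytest.mark.parametrize("mut_p", [0.0, 0.5])
def test_kernel_matches_python_reference(rng, mut_p):
    """The compiled per-cell pass and the plain-Python twin produce
    bit-identical occupancy and vitality from the same draws."""
    h = w = 7
    for trial in range(20):
        occ = rng.integers(-1, 2, size=(h, w)).astype(np.int8)
        vit = np.where(occ >= 0, rng.random((h, w)), 0.0)
        psum = rng.random((h, w)) * 1.5
        alive = np.flatnonzero(occ.ravel() >= 0)
        order = rng.permutation(alive)
        draws = rng.random((order.size, 5))
        occ_a, vit_a = occ.copy(), vit.copy()
        occ_b, vit_b = occ.copy(), vit.copy()
        mut_a = _cell_pass_kernel(occ_a, vit_a, psum, order, draws, 0.9, mut_p, 0.0)
        mut_b = _cell_pass_python(occ_b, vit_b, psum, order, draws, 0.9, mut_p, 0.0)
        assert np.array_equal(occ_a, occ_b)
        assert np.array_equal(vit_a, vit_b)
        assert mut_a == mut_b


def assert_metrics_identical(ms_a, ms_b):
    """Step-metric equality treating NaN (undefined) as equal."""
    assert len(ms_a) == len(ms_b)
    for ma, mb in zip(ms_a, ms_b):
        for f in ma.__dataclass_fields__:
            va, vb = getattr(ma, f), getattr(mb, f)
            assert va == vb or (np.isnan(va) and np.isnan(vb))


def test_run_is_deterministic(small_params):
    a = run(small_params, collect_snapshots=True)
    b = run(small_params, collect_snapshots=True)
    assert a.status == b.status == "ok"
    assert a.first_mutation_step == b.first_mutation_step
    assert_metrics_identical(a.metrics, b.metrics)
    for sa, sb in zip(a.snapshots, b.snapshots):
        assert np.array_equal(sa.rows, sb.rows)
        assert np.array_equal(sa.vitality, sb.vitality)
        assert np.array_equal(sa.resistant, sb.resistant)


def test_run_records_exactly_the_window(small_params):
    result = run(small_params)
    assert result.status == "ok"
    assert len(result.metrics) == small_params.record_window
    assert result.first_mutation_step is not None


def test_occupancy_invariants_along_a_run(small_params):
    result = run(small_params, collect_snapshots=True)
    cap = small_params.lattice.n_locations
    for snap in result.snapshots:
        assert snap.rows.size <= cap
        locs = set(zip(snap.rows.tolist(), snap.cols.tolist()))
        assert len(locs) == snap.rows.size  # one cell per location


def test_zero_mutation_rate_reports_no_mutation(small_params):
    p = dataclasses.replace(
        small_params, rates=pg.CellRates(mutation_probability=0.0), max_burn_in=60
    )
    result = run(p)
    assert result.status == "no_mutation"
    assert result.first_mutation_step is None
    assert result.metrics == []


def test_mean_vitality_rises_without_drug():
    """With no drug every cell bathes in its neighbourhood's product,
    so population mean vitality climbs toward 1."""
    p = pg.SimulationParams(
        lattice=pg.LatticeConfig(width=15, height=15), transfer_coefficient=0.5, dose=0.0, seed=3
    )
    state = initialize(p)
    v0 = state.vitality.mean()
    for _ in range(5):
        step(state, p)
    alive = state.occupancy >= 0
    assert state.vitality[alive].mean() > v0
    assert state.vitality[alive].mean() > 0.95


def test_resistant_and_sensitive_exchangeable_without_drug():
    """At dose 0 with no resistance cost the two labels are dynamically
    interchangeable: swapping every label in the initial state yields
    the label-swapped trajectory, bit for bit, under the same seed."""

    def make_state(p, swap):
        state = initialize(p)
        lab = np.random.default_rng(99).integers(0, 2, size=state.occupancy.shape)
        state.occupancy[:] = np.where(lab == 1, RESISTANT, SENSITIVE)
        if swap:
            state.occupancy[:] = 1 - state.occupancy
        # carve some vacancies so deaths/divisions actually happen
        state.occupancy[::3, ::4] = EMPTY
        state.vitality[state.occupancy == EMPTY] = 0.0
        return state

    p = pg.SimulationParams(
        lattice=pg.LatticeConfig(width=12, height=12),
        transfer_coefficient=0.5,
        dose=0.0,
        rates=pg.CellRates(mutation_probability=0.01),
        seed=11,
    )
    a = make_state(p, swap=False)
    b = make_state(p, swap=True)
    for _ in range(30):
        step(a, p)
        step(b, p)
    occupied = a.occupancy >= 0
    assert np.array_equal(occupied, b.occupancy >= 0)
    assert np.array_equal(1 - a.occupancy[occupied], b.occupancy[occupied])
    assert np.array_equal(a.vitality, b.vitality)


def test_snapshot_matches_state(small_params):
    state = initialize(small_params)
    snap = snapshot_from_state(state)
    assert snap.rows.size == state.population_size
    assert not snap.resistant.any()
    assert np.array_equal(np.sort(snap.vitality), np.sort(state.vitality.ravel()))
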