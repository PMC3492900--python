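"""Simulation engine: time loop, event ordering, and data collection.

One time step:

1. product fields decay by the persistence factor (default 0: full
   per-step turnover);
2. every living cell releases product at its own location (sensitive
   product is degraded by the drug at release);
3. both fields diffuse once with the transfer coefficient;
4. living cells are visited in a fresh uniform-random permutation;
   each reads the post-diffusion local concentration, updates its
   vitality, runs its death trial, and — if it survives — may divide
   into a vacant neighbour (vacancies are consumed immediately and
   visible to later cells; daughters born this step are not updated
   until the next);
5. the first step in which any resistance mutation occurs starts the
   recording clock.

A run burns in until the first mutation arises, then records per-step
population statistics for ``record_window`` further steps. Everything
is driven by one seeded generator with a fixed consumption order (the
permutation, then a block of five uniforms per visited cell: death,
division, placement, and two mutation draws), so a (params, seed) pair
reproduces a trajectory bit for bit.

The per-cell pass is compiled with numba; ``_cell_pass_python`` is a
plain-Python twin kept for cross-checking the compiled kernel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from numba import njit

from .cells import CellRates, DrugDose
from .lattice import LatticeConfig, ProductField, ProductVariant, diffuse_array
from .metrics import StepMetrics, step_metrics

__all__ = [
    "SimulationParams",
    "SimulationState",
    "CellSnapshot",
    "RunResult",
    "initialize",
    "step",
    "run",
    "snapshot_from_state",
]

EMPTY = -1
SENSITIVE = 0
RESISTANT = 1


@dataclass(frozen=True)
class SimulationParams:
    """All model constants for a single run.

    ``time_step_minutes`` is documentation metadata (one step is
    nominally 40 min, a typical *P. aeruginosa* generation time at host
    body temperature) and does not enter the dynamics.
    """

    lattice: LatticeConfig = dc_field(default_factory=LatticeConfig)
    transfer_coefficient: float = 1.0
    dose: float = 1.0
    rates: CellRates = dc_field(default_factory=CellRates)
    record_window: int = 1000
    max_burn_in: int = 100_000
    field_persistence: float = 0.0
    seed: int = 0
    time_step_minutes: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.transfer_coefficient <= 1.0:
            raise ValueError("transfer_coefficient must be in [0, 1]")
        DrugDose(self.dose)  # range check
        if self.record_window < 1:
            raise ValueError("record_window must be >= 1")
        if self.max_burn_in < 1:
            raise ValueError("max_burn_in must be >= 1")
        if not 0.0 <= self.field_persistence <= 1.0:
            raise ValueError("field_persistence must be in [0, 1]")


@dataclass
class SimulationState:
    step_index: int
    occupancy: np.ndarray  # int8 grid: -1 empty, 0 sensitive, 1 resistant
    vitality: np.ndarray  # float64 grid; 0 where empty
    sensitive_field: ProductField
    resistant_field: ProductField
    first_mutation_step: Optional[int]
    rng: np.random.Generator

    @property
    def population_size(self) -> int:
        return int(np.count_nonzero(self.occupancy >= 0))


@dataclass(frozen=True)
class CellSnapshot:
    """Per-cell records (location, vitality, resistance) at one step."""

    step_index: int
    rows: np.ndarray
    cols: np.ndarray
    vitality: np.ndarray
    resistant: np.ndarray


@dataclass(frozen=True)
class RunResult:
    """Outcome of one run.

    ``status`` is ``"ok"`` when the recording window completed,
    ``"no_mutation"`` when no resistance mutation arose within the
    burn-in cap, and ``"extinct"`` when the population died out before
    any mutation arose.
    """

    status: str
    params: SimulationParams
    first_mutation_step: Optional[int]
    metrics: list[StepMetrics]
    snapshots: Optional[list[CellSnapshot]]
    extinct_during_window: bool

    def metadata(self) -> dict:
        return {
            "status": self.status,
            "seed": self.params.seed,
            "first_mutation_step": self.first_mutation_step,
            "extinct_during_window": self.extinct_during_window,
            "params": _params_dict(self.params),
        }


def _params_dict(params: SimulationParams) -> dict:
    d = dataclasses.asdict(params)
    return d


def initialize(params: SimulationParams) -> SimulationState:
    """Full lattice of drug-sensitive cells, vitality ~ Uniform(0, 1)."""
    shape = params.lattice.shape
    rng = np.random.default_rng(params.seed)
    occupancy = np.full(shape, SENSITIVE, dtype=np.int8)
    vitality = rng.random(shape)
    return SimulationState(
        step_index=0,
        occupancy=occupancy,
        vitality=vitality,
        sensitive_field=ProductField.zeros(params.lattice, ProductVariant.SENSITIVE),
        resistant_field=ProductField.zeros(params.lattice, ProductVariant.RESISTANT),
        first_mutation_step=None,
        rng=rng,
    )


def _cell_pass_python(occ, vit, psum, order, draws, repro_p, mut_p, res_cost):
    """Reference per-cell pass; semantics identical to the kernel."""
    h, w = occ.shape
    mutated = False
    for k in range(order.shape[0]):
        idx = order[k]
        r, c = idx // w, idx % w
        p = psum[r, c]
        if p > 1.0:
            p = 1.0
        v = vit[r, c] + p * (1.0 - vit[r, c])
        if occ[r, c] == RESISTANT:
            v -= res_cost
        v = min(max(v, 0.0), 1.0)
        vit[r, c] = v
        if draws[k, 0] < 1.0 - v:
            occ[r, c] = EMPTY
            vit[r, c] = 0.0
            continue
        vacancies = []
        if r > 0 and occ[r - 1, c] == EMPTY:
            vacancies.append((r - 1, c))
        if r < h - 1 and occ[r + 1, c] == EMPTY:
            vacancies.append((r + 1, c))
        if c > 0 and occ[r, c - 1] == EMPTY:
            vacancies.append((r, c - 1))
        if c < w - 1 and occ[r, c + 1] == EMPTY:
            vacancies.append((r, c + 1))
        if not vacancies:
            continue
        if draws[k, 1] >= repro_p:
            continue
        j = min(int(draws[k, 2] * len(vacancies)), len(vacancies) - 1)
        state = occ[r, c]
        s1, s2 = state, state
        if draws[k, 3] < mut_p:
            s1 = 1 - state
            mutated = True
        if draws[k, 4] < mut_p:
            s2 = 1 - state
            mutated = True
        dv = v * 0.5
        occ[r, c] = s1
        vit[r, c] = dv
        rr, cc = vacancies[j]
        occ[rr, cc] = s2
        vit[rr, cc] = dv
    return mutated


@njit(cache=True)
def _cell_pass_kernel(occ, vit, psum, order, draws, repro_p, mut_p, res_cost):
    h, w = occ.shape
    mutated = False
    vac_r = np.empty(4, np.int64)
    vac_c = np.empty(4, np.int64)
    for k in range(order.shape[0]):
        idx = order[k]
        r = idx // w
        c = idx % w
        p = psum[r, c]
        if p > 1.0:
            p = 1.0
        v = vit[r, c] + p * (1.0 - vit[r, c])
        if occ[r, c] == RESISTANT:
            v -= res_cost
        if v < 0.0:
            v = 0.0
        elif v > 1.0:
            v = 1.0
        vit[r, c] = v
        if draws[k, 0] < 1.0 - v:
            occ[r, c] = EMPTY
            vit[r, c] = 0.0
            continue
        nvac = 0
        if r > 0 and occ[r - 1, c] == EMPTY:
            vac_r[nvac] = r - 1
            vac_c[nvac] = c
            nvac += 1
        if r < h - 1 and occ[r + 1, c] == EMPTY:
            vac_r[nvac] = r + 1
            vac_c[nvac] = c
            nvac += 1
        if c > 0 and occ[r, c - 1] == EMPTY:
            vac_r[nvac] = r
            vac_c[nvac] = c - 1
            nvac += 1
        if c < w - 1 and occ[r, c + 1] == EMPTY:
            vac_r[nvac] = r
            vac_c[nvac] = c + 1
            nvac += 1
        if nvac == 0:
            continue
        if draws[k, 1] >= repro_p:
            continue
        j = int(draws[k, 2] * nvac)
        if j == nvac:
            j = nvac - 1
        state = occ[r, c]
        s1 = state
        s2 = state
        if draws[k, 3] < mut_p:
            s1 = 1 - state
            mutated = True
        if draws[k, 4] < mut_p:
            s2 = 1 - state
            mutated = True
        dv = v * 0.5
        occ[r, c] = s1
        vit[r, c] = dv
        occ[vac_r[j], vac_c[j]] = s2
        vit[vac_r[j], vac_c[j]] = dv
    return mutated


def step(
    state: SimulationState, params: SimulationParams, *, use_kernel: bool = True
) -> SimulationState:
    """Advance the state by one time step (in place; returns state)."""
    rates = params.rates
    sens = state.sensitive_field.concentrations
    res = state.resistant_field.concentrations
    lam = params.field_persistence
    if lam == 0.0:
        sens.fill(0.0)
        res.fill(0.0)
    else:
        sens *= lam
        res *= lam
    occ = state.occupancy
    sens[occ == SENSITIVE] += rates.release_amount * (1.0 - params.dose)
    res[occ == RESISTANT] += rates.release_amount
    sens = diffuse_array(sens, params.transfer_coefficient)
    res = diffuse_array(res, params.transfer_coefficient)
    state.sensitive_field.concentrations = sens
    state.resistant_field.concentrations = res
    alive = np.flatnonzero(occ.ravel() >= 0)
    if alive.size:
        order = state.rng.permutation(alive)
        draws = state.rng.random((order.size, 5))
        cell_pass = _cell_pass_kernel if use_kernel else _cell_pass_python
        mutated = cell_pass(
            occ,
            state.vitality,
            sens + res,
            order,
            draws,
            rates.reproduction_probability,
            rates.mutation_probability,
            rates.resistance_cost,
        )
        if mutated and state.first_mutation_step is None:
            state.first_mutation_step = state.step_index
    state.step_index += 1
    return state


def snapshot_from_state(state: SimulationState) -> CellSnapshot:
    mask = state.occupancy >= 0
    rows, cols = np.nonzero(mask)
    return CellSnapshot(
        step_index=state.step_index,
        rows=rows,
        cols=cols,
        vitality=state.vitality[mask].copy(),
        resistant=(state.occupancy[mask] == RESISTANT),
    )


def run(
    params: SimulationParams,
    *,
    collect_snapshots: bool = False,
    use_kernel: bool = True,
) -> RunResult:
    """Burn in to the first resistance mutation, then record a window.

    The burn-in runs the same dynamics as the window (the drug is on
    throughout). If the population dies out before any mutation arises
    the result is flagged ``"extinct"``; if no mutation arises within
    ``max_burn_in`` steps, ``"no_mutation"``. Extinction *during* the
    recording window is a valid outcome: later snapshots are empty and
    the result carries ``extinct_during_window=True``.
    """
    state = initialize(params)
    while state.first_mutation_step is None:
        if state.step_index >= params.max_burn_in:
            return RunResult(
                status="no_mutation",
                params=params,
                first_mutation_step=None,
                metrics=[],
                snapshots=None,
                extinct_during_window=False,
            )
        step(state, params, use_kernel=use_kernel)
        if state.first_mutation_step is None and state.population_size == 0:
            return RunResult(
                status="extinct",
                params=params,
                first_mutation_step=None,
                metrics=[],
                snapshots=None,
                extinct_during_window=False,
            )
    metrics_list: list[StepMetrics] = []
    snapshots: Optional[list[CellSnapshot]] = [] if collect_snapshots else None
    for _ in range(params.record_window):
        step(state, params, use_kernel=use_kernel)
        snap = snapshot_from_state(state)
        metrics_list.append(step_metrics(snap, state.step_index))
        if snapshots is not None:
            snapshots.append(snap)
    return RunResult(
        status="ok",
        params=params,
        first_mutation_step=state.first_mutation_step,
        metrics=metrics_list,
        snapshots=snapshots,
        extinct_during_window=metrics_list[-1].population_size == 0,
    )
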