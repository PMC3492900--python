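"""Selection statistics on per-step cell snapshots.

The per-generation change in mean resistance due to selection is the
covariance between the resistance trait (coded 0/1) and fitness. That
covariance factors as

    cov(r, v) = sd(r) * sd(v) * corr(r, v)

with population (divide-by-N) moments and the Pearson correlation, so
weak selection can be attributed to low trait variance, low fitness
variance, or a weak trait–fitness association. Vitality is the fitness
proxy throughout. Statistics are undefined (NaN) on empty snapshots,
and the correlation additionally whenever either variable has zero
variance (e.g. after resistance has fixed); undefined steps are
excluded from window averages rather than coerced to zero, which would
bias the average toward zero exactly when selection has completed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np

__all__ = [
    "StepMetrics",
    "RunSummary",
    "resistance_frequency",
    "resistance_vitality_correlation",
    "selection_decomposition",
    "step_metrics",
    "window_average",
]


class SnapshotLike(Protocol):
    vitality: np.ndarray
    resistant: np.ndarray


@dataclass(frozen=True)
class StepMetrics:
    """Population statistics for one recorded time step.

    Undefined quantities are NaN: ``resistant_frequency`` on an empty
    population; ``correlation`` with fewer than two cells or zero
    variance in either variable; the standard deviations and
    covariance with fewer than two cells.
    """

    step_index: int
    population_size: int
    resistant_frequency: float
    sd_resistance: float
    sd_vitality: float
    correlation: float
    covariance: float


@dataclass(frozen=True)
class RunSummary:
    """Window-averaged metrics for one simulation run.

    Each mean is taken over the steps where the quantity is defined;
    population size counts extinct steps as zero cells.
    """

    transfer: float
    dose: float
    seed: int
    mean_resistant_frequency: float
    mean_correlation: float
    mean_population_size: float
    n_defined_correlation_steps: int
    n_defined_frequency_steps: int
    n_steps: int
    last_population: int
    status: str = "ok"


def _as_arrays(snapshot: SnapshotLike) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(snapshot.resistant, dtype=np.float64)
    v = np.asarray(snapshot.vitality, dtype=np.float64)
    if r.shape != v.shape:
        raise ValueError("resistance and vitality arrays differ in length")
    return r, v


def resistance_frequency(snapshot: SnapshotLike) -> float:
    """Fraction of living cells that are resistant; NaN if none live."""
    r, _ = _as_arrays(snapshot)
    if r.size == 0:
        return float("nan")
    return float(r.mean())


def selection_decomposition(
    snapshot: SnapshotLike,
) -> tuple[float, float, float, float]:
    """(sd_resistance, sd_vitality, correlation, covariance).

    Population (divide-by-N) moments. With fewer than two cells every
    component is NaN; with zero variance in either variable the
    covariance is 0 and the correlation NaN.
    """
    r, v = _as_arrays(snapshot)
    if r.size < 2:
        nan = float("nan")
        return nan, nan, nan, nan
    # a mathematically constant variable gets an exact zero SD (and a
    # zero covariance) rather than rounding residue from the centering
    const_r = r.min() == r.max()
    const_v = v.min() == v.max()
    rc = r - r.mean()
    vc = v - v.mean()
    sd_r = 0.0 if const_r else float(np.sqrt(np.mean(rc * rc)))
    sd_v = 0.0 if const_v else float(np.sqrt(np.mean(vc * vc)))
    cov = 0.0 if (const_r or const_v) else float(np.mean(rc * vc))
    if sd_r == 0.0 or sd_v == 0.0:
        return sd_r, sd_v, float("nan"), cov
    return sd_r, sd_v, cov / (sd_r * sd_v), cov


def resistance_vitality_correlation(snapshot: SnapshotLike) -> float:
    """Pearson correlation between resistance (0/1) and vitality."""
    return selection_decomposition(snapshot)[2]


def step_metrics(snapshot: SnapshotLike, step_index: int = 0) -> StepMetrics:
    """All per-step statistics for one snapshot."""
    r, _ = _as_arrays(snapshot)
    sd_r, sd_v, corr, cov = selection_decomposition(snapshot)
    return StepMetrics(
        step_index=step_index,
        population_size=int(r.size),
        resistant_frequency=resistance_frequency(snapshot),
        sd_resistance=sd_r,
        sd_vitality=sd_v,
        correlation=corr,
        covariance=cov,
    )


def _nanmean(values: np.ndarray) -> tuple[float, int]:
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        return float("nan"), 0
    return float(defined.mean()), int(defined.size)


def window_average(
    series: Sequence[StepMetrics] | Iterable[StepMetrics],
    transfer: float,
    dose: float,
    seed: int,
    status: str = "ok",
) -> RunSummary:
    """Average per-step metrics over the recording window.

    Frequency and correlation are averaged over the steps where they
    are defined (and the counts of such steps reported); population
    size is averaged over all steps, counting extinct steps as zero.
    """
    series = list(series)
    if not series:
        raise ValueError("empty metric series")
    freq = np.array([m.resistant_frequency for m in series])
    corr = np.array([m.correlation for m in series])
    pop = np.array([m.population_size for m in series], dtype=np.float64)
    mean_freq, n_freq = _nanmean(freq)
    mean_corr, n_corr = _nanmean(corr)
    return RunSummary(
        transfer=transfer,
        dose=dose,
        seed=seed,
        mean_resistant_frequency=mean_freq,
        mean_correlation=mean_corr,
        mean_population_size=float(pop.mean()),
        n_defined_correlation_steps=n_corr,
        n_defined_frequency_steps=n_freq,
        n_steps=len(series),
        last_population=series[-1].population_size,
        status=status,
    )
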