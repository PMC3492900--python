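"""Factorial simulation experiments and replicate-level statistics.

Runs the transfer-coefficient x dose grid (defaults: T in {0, 0.5, 1},
dose in {1.0, 0.75, 0.5}, 10 replicate runs per condition), summarises
each condition as mean +/- standard error over replicates, and performs
the one-tailed Welch (unequal-variances) t-tests between transfer
coefficients at full dose: resistant frequency and population size at
T=1 versus each of T=0 and T=0.5 (alternative: lower/smaller at T=1),
and the resistance-vitality correlation for all three pairwise T
comparisons (alternative: lower at the higher T). Tests compare per-run
window means (one value per replicate), never pooled steps.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import RunResult, SimulationParams, run
from .metrics import window_average

__all__ = [
    "ExperimentDesign",
    "ConditionSummary",
    "ComparisonResult",
    "replicate_seed",
    "run_experiment",
    "summarize_condition",
    "summarize_conditions",
    "welch_one_tailed",
    "headline_comparisons",
    "HEADLINE_METRICS",
]

logger = logging.getLogger(__name__)

#: DataFrame columns holding the per-run window means under test.
HEADLINE_METRICS = {
    "resistant_frequency": "mean_resistant_frequency",
    "correlation": "mean_correlation",
    "population_size": "mean_population_size",
}


@dataclass(frozen=True)
class ExperimentDesign:
    transfer_values: tuple[float, ...] = (0.0, 0.5, 1.0)
    dose_values: tuple[float, ...] = (1.0, 0.75, 0.5)
    replicates: int = 10
    base_seed: int = 0
    params_template: SimulationParams = dc_field(default_factory=SimulationParams)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class ConditionSummary:
    """Replicate mean, standard error (sample SD / sqrt(n)) and n for
    each headline metric in one (transfer, dose) condition."""

    transfer: float
    dose: float
    means: dict
    standard_errors: dict
    n: dict
    n_aborted: int


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    condition_a: tuple[float, float]  # (transfer, dose)
    condition_b: tuple[float, float]
    alternative: str  # "a_less" or "a_greater"
    t_statistic: float
    df: float
    p_value: float
    computable: bool = True


def replicate_seed(base_seed: int, transfer: float, dose: float, replicate: int) -> int:
    """Stable injective seed for one run of one condition.

    Mixes (base_seed, transfer, dose, replicate) through a SeedSequence
    so every run has an independent stream and adding conditions never
    changes the seeds of existing ones. Kept below 2**31.
    """
    key = (int(base_seed), int(round(transfer * 1000)), int(round(dose * 1000)), int(replicate))
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def _summary_row(
    result: RunResult, transfer: float, dose: float, replicate: int, seed: int
) -> dict:
    row = {
        "transfer": transfer,
        "dose": dose,
        "replicate": replicate,
        "seed": seed,
        "status": result.status,
        "first_mutation_step": result.first_mutation_step,
        "extinct_during_window": result.extinct_during_window,
        "mean_resistant_frequency": np.nan,
        "mean_correlation": np.nan,
        "mean_population_size": np.nan,
        "n_defined_correlation_steps": 0,
        "n_defined_frequency_steps": 0,
        "last_population": np.nan,
    }
    if result.status == "ok":
        s = window_average(result.metrics, transfer, dose, seed, status=result.status)
        row.update(
            mean_resistant_frequency=s.mean_resistant_frequency,
            mean_correlation=s.mean_correlation,
            mean_population_size=s.mean_population_size,
            n_defined_correlation_steps=s.n_defined_correlation_steps,
            n_defined_frequency_steps=s.n_defined_frequency_steps,
            last_population=s.last_population,
        )
    return row


def run_experiment(design: ExperimentDesign) -> pd.DataFrame:
    """Run every (transfer, dose, replicate) cell; one row per run.

    Aborted runs (no mutation within the burn-in cap, or extinction
    before the first mutation) keep their row with NaN metrics and a
    non-"ok" status so they can be excluded listwise from tests and
    counted as diagnostics.
    """
    rows = []
    template = design.params_template
    for transfer in design.transfer_values:
        for dose in design.dose_values:
            for r in range(design.replicates):
                seed = replicate_seed(design.base_seed, transfer, dose, r)
                params = dataclasses.replace(
                    template, transfer_coefficient=transfer, dose=dose, seed=seed
                )
                result = run(params)
                if result.status != "ok":
                    logger.warning(
                        "run T=%s dose=%s replicate=%d aborted: %s",
                        transfer, dose, r, result.status,
                    )
                rows.append(_summary_row(result, transfer, dose, r, seed))
            logger.info("condition T=%s dose=%s done", transfer, dose)
    return pd.DataFrame(rows)


def summarize_condition(rows: pd.DataFrame) -> ConditionSummary:
    """Replicate mean and SE per metric for one (transfer, dose)."""
    if rows.empty:
        raise ValueError("no rows for condition")
    transfer = float(rows["transfer"].iloc[0])
    dose = float(rows["dose"].iloc[0])
    ok = rows[rows["status"] == "ok"]
    means, ses, ns = {}, {}, {}
    for name, col in HEADLINE_METRICS.items():
        vals = ok[col].dropna().to_numpy()
        ns[name] = int(vals.size)
        means[name] = float(vals.mean()) if vals.size else float("nan")
        ses[name] = (
            float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 else float("nan")
        )
    return ConditionSummary(
        transfer=transfer,
        dose=dose,
        means=means,
        standard_errors=ses,
        n=ns,
        n_aborted=int((rows["status"] != "ok").sum()),
    )


def summarize_conditions(table: pd.DataFrame) -> pd.DataFrame:
    """One row per (transfer, dose) with mean, SE and n per metric."""
    out = []
    for (transfer, dose), rows in table.groupby(["transfer", "dose"], sort=True):
        s = summarize_condition(rows)
        rec = {"transfer": transfer, "dose": dose, "n_aborted": s.n_aborted}
        for name in HEADLINE_METRICS:
            rec[f"{name}_mean"] = s.means[name]
            rec[f"{name}_se"] = s.standard_errors[name]
            rec[f"{name}_n"] = s.n[name]
        out.append(rec)
    return pd.DataFrame(out)


def welch_one_tailed(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str,
    metric: str = "",
    condition_a: tuple[float, float] = (np.nan, np.nan),
    condition_b: tuple[float, float] = (np.nan, np.nan),
) -> ComparisonResult:
    """One-tailed Welch t-test of mean(a) against mean(b).

    ``alternative="a_less"`` tests the alternative mean(a) < mean(b);
    ``"a_greater"`` the reverse. Uses sample (ddof=1) variances and
    Welch-Satterthwaite degrees of freedom. When both samples have zero
    variance the statistic is undefined and the result is flagged
    non-computable rather than assigned a p-value.
    """
    if alternative not in ("a_less", "a_greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample must contain at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    denom = va / na + vb / nb
    if denom == 0.0:
        return ComparisonResult(
            metric, condition_a, condition_b, alternative,
            float("nan"), float("nan"), float("nan"), computable=False,
        )
    t = (a.mean() - b.mean()) / np.sqrt(denom)
    df = denom**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    if alternative == "a_less":
        p = float(stats.t.cdf(t, df))
    else:
        p = float(stats.t.sf(t, df))
    return ComparisonResult(
        metric, condition_a, condition_b, alternative, float(t), float(df), p
    )


def _metric_sample(table: pd.DataFrame, transfer: float, dose: float, col: str) -> np.ndarray:
    mask = (
        np.isclose(table["transfer"], transfer)
        & np.isclose(table["dose"], dose)
        & (table["status"] == "ok")
    )
    return table.loc[mask, col].dropna().to_numpy()


def headline_comparisons(table: pd.DataFrame, dose: float = 1.0) -> list[ComparisonResult]:
    """The seven directional tests between transfer coefficients at
    full dose.

    Resistant frequency and population size: T=1 vs T=0 and T=1 vs
    T=0.5 (alternative: lower at T=1). Correlation: all three pairwise
    comparisons (alternative: lower at the higher T).
    """
    required = (0.0, 0.5, 1.0)
    present = {
        t for t in required
        if ((np.isclose(table["transfer"], t)) & np.isclose(table["dose"], dose)).any()
    }
    missing = [t for t in required if t not in present]
    if missing:
        raise ValueError(
            f"missing conditions at dose {dose}: transfer values {missing}"
        )
    pairs = {
        "resistant_frequency": [(1.0, 0.0), (1.0, 0.5)],
        "correlation": [(0.5, 0.0), (1.0, 0.0), (1.0, 0.5)],
        "population_size": [(1.0, 0.0), (1.0, 0.5)],
    }
    results = []
    for metric, metric_pairs in pairs.items():
        col = HEADLINE_METRICS[metric]
        for t_a, t_b in metric_pairs:
            a = _metric_sample(table, t_a, dose, col)
            b = _metric_sample(table, t_b, dose, col)
            if a.size < 2 or b.size < 2:
                results.append(
                    ComparisonResult(
                        metric, (t_a, dose), (t_b, dose), "a_less",
                        float("nan"), float("nan"), float("nan"), computable=False,
                    )
                )
                continue
            results.append(
                welch_one_tailed(
                    a, b, "a_less",
                    metric=metric,
                    condition_a=(t_a, dose),
                    condition_b=(t_b, dose),
                )
            )
    return results


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metric": r.metric,
            "transfer_a": r.condition_a[0],
            "dose_a": r.condition_a[1],
            "transfer_b": r.condition_b[0],
            "dose_b": r.condition_b[1],
            "alternative": r.alternative,
            "t_statistic": r.t_statistic,
            "df": r.df,
            "p_value": r.p_value,
            "computable": r.computable,
        }
        for r in results
    )
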