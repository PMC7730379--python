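"""Reliability statistics: R² versus number of samples, quantile classification
accuracy, and the one-way ANOVA intraclass correlation coefficient.

All statistics operate on the natural-log scale (R² and rank-based
classification are invariant to the base; the ICC on logs is base-invariant
too).  The "true exposure" for each individual is the area under their
internal amount curve (AUC) over the exposure window; urinary estimates are
the equal-volume pooled mean concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ReliabilityReport", "MetricsError", "r2_curve", "quantile_accuracy_curve", "quantile_accuracy", "anova_icc", "build_report"]


class MetricsError(ValueError):
    """Raised when a reliability statistic cannot be computed."""


def _check_positive(name: str, x: np.ndarray) -> None:
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise MetricsError(
            f"{name} contains non-positive values; lengthen the accumulation period "
            "or check the exposure pattern before log-transforming"
        )


def r2_curve(aucs: np.ndarray, pools: dict[int, np.ndarray]) -> dict[int, float]:
    """R² of log(AUC) against log(pooled concentration), for each pool size n.

    R² is the squared Pearson correlation across individuals (identical to
    the coefficient of determination of the simple linear regression in
    either direction).  Zero variance in either variable leaves that entry
    missing (NaN) with a warning.
    """
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size < 3:
        raise MetricsError("need at least 3 individuals for a regression R²")
    _check_positive("AUC", aucs)
    log_auc = np.log(aucs)
    out: dict[int, float] = {}
    for n, conc in sorted(pools.items()):
        _check_positive(f"pooled concentration (n={n})", conc)
        log_c = np.log(conc)
        if np.ptp(log_auc) == 0 or np.ptp(log_c) == 0:
            warnings.warn(f"zero variance at n={n}; R² undefined", stacklevel=2)
            out[n] = float("nan")
            continue
        r = np.corrcoef(log_auc, log_c)[0, 1]
        out[n] = float(r * r)
    return out


def _equal_count_groups(values: np.ndarray, n_groups: int) -> np.ndarray:
    """Rank-based group label (0..n_groups-1) per individual.

    Groups have equal counts; any remainder goes to the *lower* groups.  Ties
    are broken by the stable original index (stable argsort).
    """
    n = values.size
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    base, rem = divmod(n, n_groups)
    sizes = np.array([base + 1] * rem + [base] * (n_groups - rem))
    boundaries = np.cumsum(sizes)
    return np.searchsorted(boundaries, ranks, side="right")


def quantile_accuracy(aucs: np.ndarray, conc: np.ndarray, n_quantiles: int) -> float:
    """Percent of individuals placed in the same tertile/quartile by both rankings."""
    aucs = np.asarray(aucs, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if aucs.size < n_quantiles:
        raise MetricsError("need at least n_quantiles individuals")
    true_group = _equal_count_groups(aucs, n_quantiles)
    est_group = _equal_count_groups(conc, n_quantiles)
    return float(100.0 * np.mean(true_group == est_group))


def quantile_accuracy_curve(
    aucs: np.ndarray, pools: dict[int, np.ndarray], n_quantiles: int
) -> dict[int, float]:
    return {n: quantile_accuracy(aucs, conc, n_quantiles) for n, conc in sorted(pools.items())}


def anova_icc(samples: np.ndarray, log_scale: bool = True) -> tuple[float, float]:
    """One-way random-effects ANOVA ICC from a balanced (N, k) sample matrix.

    ICC = (MSB − MSW) / (MSB + (k − 1)·MSW) on log-transformed concentrations
    (the conventional scale for log-normal biomarkers).  Returns
    ``(icc, raw_icc)``: negative estimates are clipped to 0 with a warning,
    the raw value is kept for verbose reporting.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise MetricsError("samples must be a balanced (n_individuals, k) matrix")
    n, k = x.shape
    if k < 2:
        raise MetricsError("ICC needs at least k = 2 samples per individual")
    if n < 2:
        raise MetricsError("ICC needs at least 2 individuals")
    if log_scale:
        _check_positive("ICC samples", x)
        x = np.log(x)
    row_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - row_means[:, None]) ** 2) / (n * (k - 1))
    raw = (msb - msw) / (msb + (k - 1) * msw)
    icc = raw
    if raw < 0:
        warnings.warn(f"negative ANOVA ICC ({raw:.4g}) clipped to 0", stacklevel=2)
        icc = 0.0
    return float(icc), float(raw)


@dataclass
class ReliabilityReport:
    """The three output surfaces of a simulation run.

    ``r2_by_n`` and the accuracy maps are keyed by the number of pooled
    samples n = 1..max_samples; ``icc`` is the single-sample ICC at
    k = max_samples repeated collections (None when max_samples < 2);
    ``scatter_max_n`` holds the per-individual (AUC, pooled mean at max n)
    pairs behind the regression scatter plot.
    """

    r2_by_n: dict[int, float]
    tertile_accuracy_by_n: dict[int, float]
    quartile_accuracy_by_n: dict[int, float]
    icc: float | None
    icc_raw: float | None
    scatter_max_n: pd.DataFrame = field(repr=False)

    def r2_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_samples": list(self.r2_by_n), "r_squared": list(self.r2_by_n.values())}
        )

    def accuracy_table(self) -> pd.DataFrame:
        ns = sorted(self.tertile_accuracy_by_n)
        return pd.DataFrame(
            {
                "n_samples": ns,
                "tertile_pct_correct": [self.tertile_accuracy_by_n[n] for n in ns],
                "quartile_pct_correct": [self.quartile_accuracy_by_n[n] for n in ns],
            }
        )


def build_report(aucs: np.ndarray, pools: dict[int, np.ndarray], sample_matrix: np.ndarray) -> ReliabilityReport:
    """Assemble the full reliability report from simulation outputs.

    ``sample_matrix`` is the (n_individuals, max_samples) matrix of collected
    single-sample concentrations; the ICC uses all k = max_samples columns.
    """
    aucs = np.asarray(aucs, dtype=float)
    max_n = max(pools)
    r2 = r2_curve(aucs, pools)
    tert = quantile_accuracy_curve(aucs, pools, 3)
    quart = quantile_accuracy_curve(aucs, pools, 4)
    if sample_matrix.shape[1] >= 2:
        icc, icc_raw = anova_icc(sample_matrix)
    else:
        icc = icc_raw = None
    scatter = pd.DataFrame({"auc_window": aucs, "pooled_concentration": pools[max_n]})
    return ReliabilityReport(
        r2_by_n=r2,
        tertile_accuracy_by_n=tert,
        quartile_accuracy_by_n=quart,
        icc=icc,
        icc_raw=icc_raw,
        scatter_max_n=scatter,
    )
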