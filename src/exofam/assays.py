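"""Functional-assay quantification.

Comparative-Ct qPCR fold changes (2^-ddCt against a reference gene and a
control group), Renilla-normalised dual-luciferase activation, calcium
standard-curve calibration by ordinary least squares, and Welch two-group
comparisons reported as mean +/- SEM with significance stars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats.models import FormatError

__all__ = [
    "QpcrResult",
    "LuciferaseSummary",
    "CalciumCalibration",
    "CalciumSample",
    "GroupComparison",
    "delta_delta_ct",
    "normalize_luciferase",
    "calcium_from_standard_curve",
    "pool_size_linearity",
    "compare_groups",
    "sem",
]


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean, sd/sqrt(n) with sample sd (ddof=1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return float("nan")
    return float(arr.std(ddof=1) / math.sqrt(arr.size))


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class QpcrResult:
    group: str
    target: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float
    percent_change: float

    @property
    def percent_knockdown(self) -> Optional[float]:
        """Knockdown magnitude in percent when expression decreased."""
        return -self.percent_change if self.fold_change < 1.0 else None


def delta_delta_ct(
    assay_table: pd.DataFrame,
    reference_target: str,
    control_group: str,
) -> list[QpcrResult]:
    """Comparative-Ct quantification.

    Per group, dCt(target) = mean Ct(target) - mean Ct(reference); ddCt is
    taken against the control group and fold change is 2^-ddCt, so the
    control group's fold change is exactly 1.  Aggregation uses per-group
    mean Ct (replicates are not paired).
    """
    df = assay_table
    groups = list(dict.fromkeys(df["group"]))
    if control_group not in groups:
        raise FormatError(f"control group {control_group!r} not in table")
    mean_ct = df.groupby(["group", "target"])["value"].mean()
    targets = [t for t in dict.fromkeys(df["target"]) if t != reference_target]
    delta: dict[tuple, float] = {}
    for g in groups:
        if (g, reference_target) not in mean_ct.index:
            raise FormatError(
                f"group {g!r} has no Ct values for reference "
                f"{reference_target!r}"
            )
        for t in targets:
            if (g, t) in mean_ct.index:
                delta[(g, t)] = float(
                    mean_ct[(g, t)] - mean_ct[(g, reference_target)]
                )
    results = []
    for (g, t), dct in delta.items():
        if (control_group, t) not in delta:
            raise FormatError(
                f"control group {control_group!r} has no Ct values for "
                f"target {t!r}"
            )
        ddct = dct - delta[(control_group, t)]
        fold = 2.0 ** (-ddct)
        results.append(
            QpcrResult(
                group=g,
                target=t,
                delta_ct=dct,
                delta_delta_ct=ddct,
                fold_change=fold,
                percent_change=(fold - 1.0) * 100.0,
            )
        )
    return results


# ---------------------------------------------------------------------------
# dual luciferase


@dataclass(frozen=True)
class LuciferaseSummary:
    group: str
    n: int
    mean_ratio: float
    sem_ratio: float
    fold_activation: float


def normalize_luciferase(
    assay_table: pd.DataFrame,
    control_group: Optional[str] = None,
    firefly_target: str = "firefly",
    renilla_target: str = "renilla",
) -> tuple[pd.DataFrame, list[LuciferaseSummary]]:
    """Per-well firefly/Renilla ratios plus group mean +/- SEM and fold
    activation relative to the control group (first group when omitted)."""
    df = assay_table
    wide = df.pivot_table(
        index=["group", "replicate"],
        columns="target",
        values="value",
        aggfunc="first",
    )
    for col in (firefly_target, renilla_target):
        if col not in wide.columns or wide[col].isna().any():
            raise FormatError(
                f"every well needs paired {firefly_target!r} and "
                f"{renilla_target!r} readings"
            )
    zero = wide[wide[renilla_target] == 0]
    if len(zero):
        g, r = zero.index[0]
        raise FormatError(
            f"Renilla reading is zero in group {g!r} replicate {r!r}"
        )
    wide = wide.reset_index()
    wide["ratio"] = wide[firefly_target] / wide[renilla_target]

    groups = list(dict.fromkeys(df["group"]))
    if control_group is None:
        control_group = groups[0]
    if control_group not in groups:
        raise FormatError(f"control group {control_group!r} not in table")
    control_mean = float(
        wide.loc[wide["group"] == control_group, "ratio"].mean()
    )
    summaries = []
    for g in groups:
        ratios = wide.loc[wide["group"] == g, "ratio"].tolist()
        summaries.append(
            LuciferaseSummary(
                group=g,
                n=len(ratios),
                mean_ratio=float(np.mean(ratios)),
                sem_ratio=sem(ratios),
                fold_activation=float(np.mean(ratios)) / control_mean,
            )
        )
    return wide[["group", "replicate", "ratio"]], summaries


# ---------------------------------------------------------------------------
# calcium calibration


@dataclass(frozen=True)
class CalciumCalibration:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class CalciumSample:
    label: str
    reading: float
    pool_concentration: float
    per_embryo: float
    extrapolated: bool


def calcium_from_standard_curve(
    standards: Sequence[Tuple[float, float]],
    samples: Sequence[Tuple[str, float]],
    n_embryos_per_pool: int = 20,
) -> tuple[CalciumCalibration, list[CalciumSample]]:
    """Calibrate sample readings against a CaCl2 standard series.

    Standards are (concentration, reading) pairs fitted by OLS
    reading = slope * concentration + intercept; sample concentrations are
    obtained by inversion and divided by the pool size for the per-embryo
    value.  Readings outside the standard reading range are flagged as
    extrapolated.
    """
    if len(standards) < 3:
        raise FormatError("need at least 3 standard points")
    conc = np.array([s[0] for s in standards], dtype=float)
    reading = np.array([s[1] for s in standards], dtype=float)
    fit = stats.linregress(conc, reading)
    if fit.slope == 0:
        raise FormatError("degenerate standard curve (zero slope)")
    calib = CalciumCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
    lo, hi = float(reading.min()), float(reading.max())
    out = []
    import logging

    log = logging.getLogger(__name__)
    for label, y in samples:
        extrapolated = not (lo <= y <= hi)
        if extrapolated:
            log.warning(
                "sample %r reading %.4g outside standard range [%.4g, %.4g]; "
                "extrapolating",
                label,
                y,
                lo,
                hi,
            )
        pool = (y - calib.intercept) / calib.slope
        out.append(
            CalciumSample(
                label=label,
                reading=float(y),
                pool_concentration=float(pool),
                per_embryo=float(pool / n_embryos_per_pool),
                extrapolated=extrapolated,
            )
        )
    return calib, out


def pool_size_linearity(
    pool_sizes: Sequence[float], totals: Sequence[float]
) -> CalciumCalibration:
    """Linearity check of total calcium against the number of pooled
    embryos; returns the OLS fit with its R^2."""
    if len(pool_sizes) != len(totals) or len(pool_sizes) < 3:
        raise FormatError("need >= 3 matched (pool size, total) points")
    fit = stats.linregress(np.asarray(pool_sizes, float), np.asarray(totals, float))
    return CalciumCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    stars: str


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    method: str = "welch",
    n_permutations: int = 10000,
    seed: Optional[int] = None,
) -> GroupComparison:
    """Two-sided two-sample comparison; Welch's t-test by default, with a
    permutation test on the difference in means as alternative.

    Identical degenerate groups (zero variance, zero difference) report
    p = 1 rather than NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if method == "welch":
        if a.std(ddof=0) == 0 and b.std(ddof=0) == 0 and a.mean() == b.mean():
            statistic, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        observed = abs(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        hits = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            diff = abs(pooled[: a.size].mean() - pooled[a.size :].mean())
            if diff >= observed - 1e-12:
                hits += 1
        statistic = float(a.mean() - b.mean())
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=sem(a),
        sem_b=sem(b),
        n_a=int(a.size),
        n_b=int(b.size),
        statistic=statistic,
        p_value=float(p),
        stars=_stars(float(p)),
    )
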