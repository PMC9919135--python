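"""Two-factor ANOVA with interaction, assumption checks, and LSD subsets.

Factor A is the pump suction flow (r levels), factor B the sampling-gas
concentration (s levels), with t repeated observations per cell.  The
total sum of squares decomposes exactly as

    SST = SSA + SSB + SSAB + SSE

with SSA = s*t * sum_i (Ai_mean - grand)^2, SSB = r*t * sum_j
(Bj_mean - grand)^2, SSAB = t * sum_ij (cell_ij - Ai - Bj + grand)^2 and
SSE the within-cell sum of squares.  F statistics divide each mean square
by the error mean square; p-values come from the F distribution.

The least-significant-difference (LSD) comparison groups the factor levels
into homogeneous subsets: levels sorted by mean, maximal contiguous runs
whose extreme means differ by less than the LSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CalibrationSample

__all__ = [
    "FactorialTable",
    "AnovaResult",
    "LsdResult",
    "two_way_anova",
    "lsd_subsets",
    "variance_homogeneity_test",
    "normality_test",
]


@dataclass
class FactorialTable:
    """Balanced r x s x t response array with its factor level labels.

    ``responses[i, j, k]`` is the k-th repeated observation at flow level
    ``levels_a[i]`` and concentration level ``levels_b[j]``.
    """

    responses: np.ndarray
    levels_a: np.ndarray
    levels_b: np.ndarray

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.levels_a = np.asarray(self.levels_a)
        self.levels_b = np.asarray(self.levels_b)
        if self.responses.ndim != 3:
            raise ValueError("responses must be a 3-D (r, s, t) array")
        r, s, _ = self.responses.shape
        if self.levels_a.shape != (r,) or self.levels_b.shape != (s,):
            raise ValueError("level labels must match the response array shape")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must all be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.responses.shape

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        factor_a: str = "flow_set_sccm",
        factor_b: str = "concentration_ppb",
        response: str = "x1_volts",
    ) -> "FactorialTable":
        """Build a balanced table from a long-format feature table.

        Every (factor_a, factor_b) cell must hold the same number of rows;
        an unbalanced table is rejected.
        """
        for col in (factor_a, factor_b, response):
            if col not in frame.columns:
                raise ValueError(f"missing column {col!r}")
        la = np.sort(frame[factor_a].unique())
        lb = np.sort(frame[factor_b].unique())
        counts = frame.groupby([factor_a, factor_b]).size()
        if len(counts) != len(la) * len(lb) or counts.nunique() != 1:
            raise ValueError("unbalanced design: every cell needs the same number of observations")
        t = int(counts.iloc[0])
        resp = np.empty((len(la), len(lb), t))
        grouped = frame.groupby([factor_a, factor_b])[response]
        for i, a in enumerate(la):
            for j, b in enumerate(lb):
                resp[i, j, :] = grouped.get_group((a, b)).to_numpy()
        return cls(resp, la, lb)

    @classmethod
    def from_samples(cls, samples: Sequence[CalibrationSample]) -> "FactorialTable":
        """Table of NO-channel eigenvalues; the five kinds (times any
        replicates) act as the repeated observations per cell."""
        from .preprocess import samples_to_frame

        return cls.from_frame(samples_to_frame(samples))


@dataclass
class AnovaResult:
    """Sums of squares, degrees of freedom, F statistics and p-values."""

    ss_total: float
    ss_a: float
    ss_b: float
    ss_ab: float
    ss_e: float
    df_a: int
    df_b: int
    df_ab: int
    df_e: int
    f_a: float
    f_b: float
    f_ab: float
    p_a: float
    p_b: float
    p_ab: float

    def to_frame(self) -> pd.DataFrame:
        """ANOVA table with one row per effect (p printed as <0.001 when tiny)."""

        def fmt_p(p: float) -> str:
            return "<0.001" if p < 1e-3 else f"{p:.3f}"

        rows = [
            ("flow (A)", self.ss_a, self.df_a, self.ss_a / self.df_a, self.f_a, self.p_a, fmt_p(self.p_a)),
            ("concentration (B)", self.ss_b, self.df_b, self.ss_b / self.df_b, self.f_b, self.p_b, fmt_p(self.p_b)),
            ("A x B", self.ss_ab, self.df_ab, self.ss_ab / self.df_ab, self.f_ab, self.p_ab, fmt_p(self.p_ab)),
            ("error", self.ss_e, self.df_e, self.ss_e / self.df_e, np.nan, np.nan, ""),
        ]
        return pd.DataFrame(rows, columns=["effect", "ss", "df", "ms", "F", "p", "p_printed"])


def two_way_anova(table: FactorialTable) -> AnovaResult:
    """Decompose a balanced two-factor table with interaction.

    Requires r, s >= 2 and t >= 2 (with a single observation per cell the
    interaction cannot be separated from error).
    """
    x = table.responses
    r, s, t = x.shape
    if r < 2 or s < 2:
        raise ValueError("need at least 2 levels per factor")
    if t < 2:
        raise ValueError("interaction inestimable: need t >= 2 repeats per cell")

    grand = x.mean()
    a_means = x.mean(axis=(1, 2))
    b_means = x.mean(axis=(0, 2))
    cell_means = x.mean(axis=2)

    ss_a = s * t * float(np.sum((a_means - grand) ** 2))
    ss_b = r * t * float(np.sum((b_means - grand) ** 2))
    ss_ab = t * float(np.sum((cell_means - a_means[:, None] - b_means[None, :] + grand) ** 2))
    ss_e = float(np.sum((x - cell_means[:, :, None]) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))

    df_a, df_b = r - 1, s - 1
    df_ab = (r - 1) * (s - 1)
    df_e = r * s * (t - 1)
    mse = ss_e / df_e

    def f_and_p(ss: float, df: int) -> tuple[float, float]:
        if mse == 0.0:
            f = np.inf if ss > 0 else 0.0
            return f, 0.0 if ss > 0 else 1.0
        f = (ss / df) / mse
        return f, float(stats.f.sf(f, df, df_e))

    f_a, p_a = f_and_p(ss_a, df_a)
    f_b, p_b = f_and_p(ss_b, df_b)
    f_ab, p_ab = f_and_p(ss_ab, df_ab)

    return AnovaResult(
        ss_total=ss_total, ss_a=ss_a, ss_b=ss_b, ss_ab=ss_ab, ss_e=ss_e,
        df_a=df_a, df_b=df_b, df_ab=df_ab, df_e=df_e,
        f_a=f_a, f_b=f_b, f_ab=f_ab, p_a=p_a, p_b=p_b, p_ab=p_ab,
    )


@dataclass
class LsdResult:
    """Homogeneous-subset summary of one factor's level means."""

    levels: np.ndarray          # sorted by ascending mean
    means: np.ndarray           # matching means
    n_per_level: int
    lsd: float
    subsets: list[list]         # maximal homogeneous subsets, ascending
    p_values: list[float]       # extreme-pair p-value per subset

    def to_frame(self) -> pd.DataFrame:
        """Wide subset table: one row per level, one column per subset."""
        data = {"level": self.levels, "n": self.n_per_level, "mean": self.means}
        frame = pd.DataFrame(data)
        for si, subset in enumerate(self.subsets, start=1):
            col = [m if lv in subset else np.nan for lv, m in zip(self.levels, self.means)]
            frame[f"subset_{si}"] = col
        return frame


def lsd_subsets(table: FactorialTable, factor: str = "a", alpha: float = 0.05) -> LsdResult:
    """LSD comparison of one factor's level means after the two-way ANOVA.

    LSD = t_{1-alpha/2, df_e} * sqrt(2 * MSE / n_per_level).  Levels are
    sorted by mean and grouped into maximal contiguous subsets whose
    extreme means differ by less than the LSD; each subset is annotated
    with the p-value of its extreme-pair comparison (1.0 for singletons).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if factor not in ("a", "b"):
        raise ValueError("factor must be 'a' or 'b'")
    result = two_way_anova(table)
    x = table.responses
    r, s, t = x.shape
    if factor == "a":
        levels = table.levels_a
        means = x.mean(axis=(1, 2))
        n_per = s * t
    else:
        levels = table.levels_b
        means = x.mean(axis=(0, 2))
        n_per = r * t
    mse = result.ss_e / result.df_e
    se = np.sqrt(2.0 * mse / n_per)
    lsd = float(stats.t.ppf(1 - alpha / 2, result.df_e) * se)

    order = np.argsort(means)
    levels_sorted = levels[order]
    means_sorted = means[order]
    m = len(means_sorted)

    # Maximal contiguous runs within one LSD of their own minimum; runs
    # contained in a longer run are dropped (SPSS-style overlapping subsets).
    runs: list[tuple[int, int]] = []
    for i in range(m):
        j = i
        while j + 1 < m and means_sorted[j + 1] - means_sorted[i] < lsd:
            j += 1
        runs.append((i, j))
    maximal = [(i, j) for (i, j) in runs if not any(a <= i and j <= b and (a, b) != (i, j) for a, b in runs)]
    maximal.sort()

    subsets, p_values = [], []
    for i, j in maximal:
        subsets.append(list(levels_sorted[i : j + 1]))
        if i == j or se == 0:
            p_values.append(1.0)
        else:
            tstat = (means_sorted[j] - means_sorted[i]) / se
            p_values.append(float(2 * stats.t.sf(abs(tstat), result.df_e)))
    return LsdResult(levels_sorted, means_sorted, n_per, lsd, subsets, p_values)


def variance_homogeneity_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Brown-Forsythe homogeneity of variances (Levene on deviations from
    the group medians); returns (statistic, p-value)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    deviations = np.concatenate([np.abs(a - np.median(a)) for a in arrays])
    if np.all(deviations == 0):
        return 0.0, 1.0  # no spread anywhere: Levene's F is exactly 0
    stat, p = stats.levene(*arrays, center="median")
    return float(stat), float(p)


def normality_test(residuals: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality check on the ANOVA residuals."""
    res = np.asarray(residuals, dtype=float)
    if res.size < 3:
        raise ValueError("need at least 3 residuals")
    stat, p = stats.shapiro(res)
    return float(stat), float(p)
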