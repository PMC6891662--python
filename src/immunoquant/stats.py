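"""Classical statistics used to compare assay groups.

One-way ANOVA with Tukey's HSD post-hoc test (for encapsulation indices and
relative fluorescence intensities) and the Pearson chi-square test on 2x2
contingency tables (for spreading and phagocytosis ratios).  The sums of
squares, F and q statistics, and the chi-square statistic are computed from
first principles; only the reference-distribution tails (F, studentized
range, chi-square) come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sps

from .errors import DomainError


@dataclass(frozen=True)
class TukeyPair:
    """One pairwise Tukey-Kramer comparison at the chosen alpha."""

    group_a: str
    group_b: str
    difference: float  # mean(a) - mean(b)
    q: float  # studentized-range statistic
    p: float
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict
    ss_between: float
    ss_within: float
    tukey_pairs: list = field(default_factory=list)
    levene_W: float = float("nan")
    levene_p: float = float("nan")
    degenerate: bool = False  # zero within-group variance with unequal means


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    table: np.ndarray
    yates: bool = False


@lru_cache(maxsize=64)
def _tukey_critical(alpha: float, k: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1 - alpha, k, df))


def one_way_anova(
    groups,
    labels: "list[str] | None" = None,
    alpha: float = 0.05,
    posthoc: bool = True,
) -> AnovaResult:
    """Fixed-effects one-way ANOVA with Tukey-Kramer pairwise comparisons.

    Parameters
    ----------
    groups : sequence of 1-D numeric samples
        At least two groups with at least two observations each.
    labels : list of str, optional
        Group names for the Tukey table; defaults to ``g0, g1, ...``.
    alpha : float
        Familywise significance level for the Tukey flags (default 0.05).
    posthoc : bool
        Compute the Tukey-Kramer pairwise table (default).  Disable when
        only the omnibus F test is needed, e.g. in large simulations; the
        studentized-range quantiles dominate the runtime otherwise.

    Notes
    -----
    Between- and within-group sums of squares are accumulated directly from
    the decomposition SS_total = SS_between + SS_within; the p-value is the
    upper tail of F(k-1, N-k).  Levene's statistic (on absolute deviations
    from group means) is reported alongside but never gates the ANOVA.
    Degenerate inputs with zero within-group variance but unequal means yield
    an infinite F; p is reported as the smallest positive float and flagged.
    """
    samples = [np.asarray(g, dtype=float).ravel() for g in groups]
    k = len(samples)
    if k < 2:
        raise DomainError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in samples):
        raise DomainError("each group needs at least two observations")
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    if len(labels) != k:
        raise DomainError("labels length must match number of groups")

    ns = np.array([len(g) for g in samples])
    means = np.array([g.mean() for g in samples])
    N = int(ns.sum())
    grand = float(np.concatenate(samples).mean())

    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(samples, means)))
    df_between = k - 1
    df_within = N - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    degenerate = False
    if ms_within == 0.0:
        if ss_between == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), float(np.finfo(float).tiny)
            degenerate = True
    else:
        F = ms_between / ms_within
        p = float(sps.f.sf(F, df_between, df_within))

    # Tukey-Kramer: q_ij = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)).
    pairs = []
    if posthoc and ms_within > 0:
        q_crit = _tukey_critical(alpha, k, df_within)
        for i in range(k):
            for j in range(i + 1, k):
                diff = float(means[i] - means[j])
                se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(diff) / se
                p_pair = float(sps.studentized_range.sf(q, k, df_within))
                pairs.append(
                    TukeyPair(
                        labels[i], labels[j], diff, float(q), p_pair, bool(q > q_crit)
                    )
                )

    with np.errstate(invalid="ignore", divide="ignore"):
        try:
            levene_W, levene_p = sps.levene(*samples, center="mean")
        except Exception:  # pragma: no cover - constant groups
            levene_W, levene_p = float("nan"), float("nan")

    return AnovaResult(
        F=float(F),
        df_between=df_between,
        df_within=df_within,
        p=p,
        group_means=dict(zip(labels, means.tolist())),
        ss_between=ss_between,
        ss_within=ss_within,
        tukey_pairs=pairs,
        levene_W=float(levene_W),
        levene_p=float(levene_p),
        degenerate=degenerate,
    )


def chi_square_2x2(table, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on a 2x2 count table.

    ``yates=True`` applies the continuity correction; the default is the
    uncorrected Pearson statistic, appropriate for the large cell counts
    these assays produce (hundreds to thousands of cells per arm).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise DomainError("expected a 2x2 table")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise DomainError("counts must be nonnegative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DomainError("all row and column margins must be positive")
    expected = np.outer(row, col) / obs.sum()
    correction = 0.5 if yates else 0.0
    dev = np.abs(obs - expected) - correction
    if yates:
        dev = np.maximum(dev, 0.0)
    chi2 = float((dev**2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    return ChiSquareResult(chi2=chi2, df=1, p=p, table=obs.astype(int), yates=yates)
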