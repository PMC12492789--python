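"""Repeated-measures comparison of cut-point methods.

Every subject contributes one value per cut-point method for each outcome
(adjusted daily minutes of SB, LPA, MVPA or TPA), giving a complete n × k
within-subject design.  The omnibus test is a one-within-factor
repeated-measures ANOVA by sums-of-squares decomposition::

    SS_total   = Σ (y_ij − ȳ)²
    SS_subject = k Σ_i (ȳ_i· − ȳ)²
    SS_method  = n Σ_j (ȳ_·j − ȳ)²
    SS_error   = SS_total − SS_subject − SS_method
    F = (SS_method / (k−1)) / (SS_error / ((n−1)(k−1)))

For a single balanced within-subject factor the estimated marginal means
are the simple per-method means, and their pairwise contrasts reduce to
paired contrasts: the estimate is the mean within-subject difference, its
standard error sd(diff)/√n with n−1 degrees of freedom.  Pairwise p-values
and confidence intervals are Bonferroni-corrected over the k(k−1)/2 pairs.
No sphericity correction is applied; a Greenhouse–Geisser epsilon is
reported as a diagnostic only.

Guideline-adherence proportions under two methods are paired binary data,
compared with an exact McNemar test (binomial test on the discordant
pairs).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RmAnovaResult",
    "PairwiseContrast",
    "McNemarResult",
    "rm_anova",
    "emm_pairwise",
    "paired_t",
    "compare_adherence",
]


class DegenerateDataError(ValueError):
    """Raised when the design carries no residual information."""


@dataclass(frozen=True)
class RmAnovaResult:
    f_stat: float
    df_method: int
    df_error: int
    p_value: float
    ss_method: float
    ss_subject: float
    ss_error: float
    gg_epsilon: float  # Greenhouse–Geisser sphericity diagnostic


@dataclass(frozen=True)
class PairwiseContrast:
    pair: tuple[str, str]  # estimate is mean(a) − mean(b)
    estimate: float
    se: float
    t_value: float
    df: int
    p_bonf: float
    ci_low: float
    ci_high: float
    degenerate: bool = False  # zero variance of the differences


@dataclass(frozen=True)
class McNemarResult:
    n_a_only: int  # adherent under a, not under b
    n_b_only: int
    prop_a: float
    prop_b: float
    p_value: float
    note: str = ""


def _as_matrix(values) -> np.ndarray:
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected an n x k matrix (subjects x methods)")
    if not np.isfinite(m).all():
        raise ValueError("matrix must be complete (no missing cells)")
    return m


def _gg_epsilon(m: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the double-centred covariance."""
    k = m.shape[1]
    S = np.cov(m, rowvar=False, ddof=1)
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    denom = (k - 1) * float((Sc * Sc).sum())
    if denom <= 0:
        return 1.0
    return float(np.trace(Sc) ** 2 / denom)


def rm_anova(values) -> RmAnovaResult:
    """One-within-factor repeated-measures ANOVA on an n × k matrix."""
    m = _as_matrix(values)
    n, k = m.shape
    if n < 2 or k < 2:
        raise DegenerateDataError("need at least 2 subjects and 2 methods")
    grand = m.mean()
    ss_total = float(((m - grand) ** 2).sum())
    ss_subject = float(k * ((m.mean(axis=1) - grand) ** 2).sum())
    ss_method = float(n * ((m.mean(axis=0) - grand) ** 2).sum())
    ss_error = max(ss_total - ss_subject - ss_method, 0.0)
    df_method = k - 1
    df_error = (n - 1) * (k - 1)
    if ss_error <= 0:
        if ss_total == 0:
            raise DegenerateDataError("matrix is constant across subjects and methods")
        if ss_method == 0:
            # methods identical within every subject: no effect, by fiat
            return RmAnovaResult(0.0, df_method, df_error, 1.0, 0.0, ss_subject, 0.0, 1.0)
        raise DegenerateDataError(
            "zero residual variance (perfectly additive matrix); F undefined"
        )
    f = (ss_method / df_method) / (ss_error / df_error)
    p = float(sps.f.sf(f, df_method, df_error))
    return RmAnovaResult(
        float(f), df_method, df_error, p, ss_method, ss_subject, ss_error, _gg_epsilon(m)
    )


def paired_t(a, b) -> tuple[float, int, float]:
    """Classical paired t-test; returns ``(t, df, p)``.

    Zero-variance differences are guarded: t = 0 and p = 1 when the samples
    are identical, t = ±inf and p = 0 for a constant non-zero shift.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-d and equally long")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if mean == 0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, mean), df, 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), df, p


def emm_pairwise(values, method_names: list[str], alpha: float = 0.05) -> list[PairwiseContrast]:
    """Bonferroni-corrected pairwise contrasts of the per-method means.

    For each unordered pair (a, b), in ``method_names`` order, the estimate
    is ``mean(a − b)`` over subjects, tested with a paired t statistic; the
    p-value is ``min(1, n_pairs · p_raw)`` and the confidence interval is a
    two-sided interval at level ``1 − alpha/n_pairs``.
    """
    m = _as_matrix(values)
    n, k = m.shape
    if k != len(method_names):
        raise ValueError("method_names must match the number of columns")
    pairs = list(itertools.combinations(range(k), 2))
    n_pairs = len(pairs)
    out: list[PairwiseContrast] = []
    for i, j in pairs:
        d = m[:, i] - m[:, j]
        est = float(d.mean())
        sd = float(d.std(ddof=1))
        df = n - 1
        se = sd / math.sqrt(n)
        if se == 0:
            out.append(
                PairwiseContrast(
                    (method_names[i], method_names[j]),
                    est,
                    0.0,
                    0.0 if est == 0 else math.copysign(math.inf, est),
                    df,
                    1.0 if est == 0 else 0.0,
                    est,
                    est,
                    degenerate=True,
                )
            )
            continue
        t = est / se
        p_raw = 2.0 * float(sps.t.sf(abs(t), df))
        p_bonf = min(1.0, n_pairs * p_raw)
        tcrit = float(sps.t.ppf(1.0 - (alpha / n_pairs) / 2.0, df))
        out.append(
            PairwiseContrast(
                (method_names[i], method_names[j]),
                est,
                float(se),
                float(t),
                df,
                p_bonf,
                est - tcrit * se,
                est + tcrit * se,
            )
        )
    return out


def compare_adherence(flags_a, flags_b) -> McNemarResult:
    """Exact McNemar test on paired adherence flags from two methods.

    The test statistic is the smaller discordant count against
    Binomial(n_discordant, ½), two-sided.  With no discordant pairs the
    methods agree everywhere and p = 1 by convention.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("adherence vectors must be 1-d and equally long")
    n_a_only = int(np.sum(a & ~b))
    n_b_only = int(np.sum(~a & b))
    prop_a = float(a.mean()) if len(a) else float("nan")
    prop_b = float(b.mean()) if len(b) else float("nan")
    n_disc = n_a_only + n_b_only
    if n_disc == 0:
        return McNemarResult(0, 0, prop_a, prop_b, 1.0, note="no discordant pairs")
    p = float(sps.binomtest(min(n_a_only, n_b_only), n_disc, 0.5).pvalue)
    return McNemarResult(n_a_only, n_b_only, prop_a, prop_b, p)
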