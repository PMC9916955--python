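"""Group comparison tests and the relative-expression helper.

The comparisons used throughout the phenotyping figures are the classical
Student's t test (pooled variance; Welch available as an option), the
paired t test, and the Mann-Whitney U test (exact p for small tie-free
samples, normal approximation with tie correction otherwise). One-tailed
directions are never inferred from the data: the favored direction must be
declared per hypothesis.

Computation is delegated to :mod:`scipy.stats`; this module fixes the
conventions (which statistic, which p-values, degenerate-input handling)
and returns a uniform :class:`ComparisonResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, DataError

#: exact Mann-Whitney p by enumeration is used up to this combined sample size
MW_EXACT_MAX_N = 16


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-group (or paired) comparison.

    ``p_one`` is the one-sided p in the *declared* direction
    (``direction`` = "greater" means the alternative x > y).
    ``degenerate`` flags zero-variance input, for which the t statistic is
    undefined.
    """

    method: str
    statistic: float
    df: float | None
    p_one: float
    p_two: float
    n_x: int
    n_y: int
    direction: str
    effect_direction: str  # sign of the observed x-vs-y difference
    degenerate: bool = False


def _effect_direction(x: np.ndarray, y: np.ndarray, paired: bool) -> str:
    d = float(np.mean(x) - np.mean(y)) if not paired else float(np.mean(x - y))
    return "greater" if d > 0 else ("less" if d < 0 else "equal")


def t_test(x, y, paired: bool = False, tails: int = 1,
           direction: str = "greater", welch: bool = False) -> ComparisonResult:
    """Student's t test (pooled-variance unpaired, or paired difference test).

    Parameters
    ----------
    x, y
        Samples; for ``paired=True`` they must be equal-length pairs.
    tails
        1 or 2; recorded for reporting, both p-values are always computed.
    direction
        Declared one-sided alternative: ``"greater"`` (x > y) or ``"less"``.
    welch
        Use the Welch (unequal-variance) statistic instead of pooled.
    """
    if tails not in (1, 2):
        raise ConfigError("tails must be 1 or 2")
    if direction not in ("greater", "less"):
        raise ConfigError("direction must be 'greater' or 'less'")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired:
        if len(x) != len(y):
            raise DataError("paired test needs equal-length samples")
        if len(x) < 2:
            raise DataError("paired test needs at least 2 pairs")
        method = "paired t"
        diffs = x - y
        degenerate = float(np.std(diffs, ddof=1)) == 0.0
        if degenerate:
            return ComparisonResult(method, math.nan, float(len(x) - 1), math.nan,
                                    math.nan, len(x), len(y), direction,
                                    _effect_direction(x, y, True), degenerate=True)
        res_one = sps.ttest_rel(x, y, alternative=direction)
        res_two = sps.ttest_rel(x, y)
        df = float(len(x) - 1)
    else:
        if len(x) < 2 or len(y) < 2:
            raise DataError("unpaired test needs n >= 2 per group")
        method = "Welch t" if welch else "Student t"
        degenerate = float(np.std(x, ddof=1)) == 0.0 and float(np.std(y, ddof=1)) == 0.0
        if degenerate:
            return ComparisonResult(method, math.nan, math.nan, math.nan, math.nan,
                                    len(x), len(y), direction,
                                    _effect_direction(x, y, False), degenerate=True)
        res_one = sps.ttest_ind(x, y, equal_var=not welch, alternative=direction)
        res_two = sps.ttest_ind(x, y, equal_var=not welch)
        df = float(res_two.df)
    return ComparisonResult(
        method=method,
        statistic=float(res_two.statistic),
        df=df,
        p_one=float(res_one.pvalue),
        p_two=float(res_two.pvalue),
        n_x=len(x),
        n_y=len(y),
        direction=direction,
        effect_direction=_effect_direction(x, y, paired),
    )


def mann_whitney(x, y, tails: int = 1, direction: str = "greater") -> ComparisonResult:
    """Mann-Whitney U test with midranks for ties.

    The p-value is exact (enumeration over orderings) when the combined
    sample size is at most :data:`MW_EXACT_MAX_N` and there are no ties;
    otherwise the normal approximation with tie correction and continuity
    correction is used. The reported statistic is U for sample x.
    """
    if tails not in (1, 2):
        raise ConfigError("tails must be 1 or 2")
    if direction not in ("greater", "less"):
        raise ConfigError("direction must be 'greater' or 'less'")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 1 or len(y) < 1:
        raise DataError("Mann-Whitney needs n >= 1 per group")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    exact = (len(combined) <= MW_EXACT_MAX_N) and not has_ties
    method_kw = "exact" if exact else "asymptotic"
    res_one = sps.mannwhitneyu(x, y, alternative=direction, method=method_kw)
    res_two = sps.mannwhitneyu(x, y, alternative="two-sided", method=method_kw)
    label = "Mann-Whitney (exact)" if exact else "Mann-Whitney (normal approx.)"
    return ComparisonResult(
        method=label,
        statistic=float(res_one.statistic),
        df=None,
        p_one=float(res_one.pvalue),
        p_two=float(min(res_two.pvalue, 1.0)),
        n_x=len(x),
        n_y=len(y),
        direction=direction,
        effect_direction=_effect_direction(x, y, False),
    )


def delta_ct(ct_target: float, ct_ref: float,
             calibrator_dct: float | None = None) -> tuple[float, float]:
    """Relative qPCR expression by the delta-Ct method.

    Returns ``(dct, expression)`` where ``dct = ct_target - ct_ref`` and
    ``expression = 2**(-dct)``. When ``calibrator_dct`` (the delta-Ct of the
    calibrator sample) is given, the delta-delta-Ct fold change
    ``2**(-(dct - calibrator_dct))`` is returned instead.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_ref)):
        raise DataError("Ct values must be finite")
    dct = ct_target - ct_ref
    if calibrator_dct is None:
        return dct, 2.0 ** (-dct)
    ddct = dct - calibrator_dct
    return ddct, 2.0 ** (-ddct)
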