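"""Nested-model comparison and replicate statistics.

The central tool is the extra-sum-of-squares F-test for comparing two nested
least-squares fits of the same data::

    F = ((SS_null - SS_alt) / (df_null - df_alt)) / (SS_alt / df_alt)

with the p-value from the upper tail of F(df_null - df_alt, df_alt). It is
used for three hypotheses: a single Kd for both conditions (binding), a
single proofreading rate kp for both conditions (signaling), and a single
maximal response (logistic top). Two-tailed paired/unpaired t-tests cover
the simple replicate comparisons, and :func:`calibrate_test` measures
empirical type-I error and power of any such test by simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .binding_models import fit_binding
from .datasets import DoseResponseDataset

__all__ = [
    "FTestResult",
    "ess_f_test",
    "compare_max_response",
    "t_test",
    "TTestResult",
    "calibrate_test",
    "CalibrationResult",
]

#: relative tolerance absorbing optimizer jitter when SS_null < SS_alt
_SS_REL_TOL = 1e-8


@dataclass(frozen=True)
class FTestResult:
    """Extra-sum-of-squares F-test between two nested fits."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    null_label: str = "null"
    alt_label: str = "alternative"

    def __str__(self) -> str:  # key-value report form
        return (
            f"null={self.null_label} alt={self.alt_label} "
            f"F({self.df_num},{self.df_den})={self.f_stat:.6g} p={self.p_value:.6g}"
        )


def _ss_df(fit) -> tuple[float, int, str]:
    return float(fit.ss_resid), int(fit.df), getattr(fit, "data_fingerprint", "")


def ess_f_test(fit_null, fit_alt, null_label: str = "null", alt_label: str = "alternative") -> FTestResult:
    """Extra-sum-of-squares F-test of a null fit against a nested alternative.

    Both fits must have been computed on identical data (enforced through the
    dataset fingerprint each fit carries) and the null must have strictly
    more residual degrees of freedom. If the optimizer left the null with a
    marginally *smaller* SS than the alternative (within a relative tolerance
    of 1e-8), F is clamped to 0 with a warning; a larger violation raises.
    """
    ss0, df0, fp0 = _ss_df(fit_null)
    ss1, df1, fp1 = _ss_df(fit_alt)
    if fp0 and fp1 and fp0 != fp1:
        raise ValueError("fits were computed on different data (fingerprint mismatch)")
    if df0 <= df1:
        raise ValueError(f"fits are not nested: df_null={df0} must exceed df_alt={df1}")
    if ss0 < ss1 * (1.0 - _SS_REL_TOL) - _SS_REL_TOL:
        if ss1 - ss0 > max(ss1, 1.0) * 1e-3:
            raise ValueError(
                f"null SS ({ss0:.6g}) is substantially below alternative SS ({ss1:.6g}); "
                "the alternative fit has not converged"
            )
        warnings.warn("SS_null marginally below SS_alt (optimizer jitter); clamping F to 0", stacklevel=2)
        ss0 = ss1
    df_num = df0 - df1
    f = max((ss0 - ss1) / df_num, 0.0) / (ss1 / df1) if ss1 > 0 else (np.inf if ss0 > ss1 else 0.0)
    p = float(stats.f.sf(f, df_num, df1)) if np.isfinite(f) else 0.0
    return FTestResult(f_stat=float(f), df_num=df_num, df_den=df1, p_value=p, null_label=null_label, alt_label=alt_label)


def compare_max_response(
    wt_data: DoseResponseDataset,
    mut_data: DoseResponseDataset,
    family: str = "logistic4",
    n_starts: int = 8,
) -> FTestResult:
    """F-test of equal maximal response between two dose-response datasets.

    Fits the pair jointly with the logistic ``top`` shared (null) versus free
    per condition (alternative); bottom, EC50 and Hill slope stay free per
    condition in both fits.
    """
    if family not in ("logistic3", "logistic4"):
        raise ValueError("compare_max_response requires a logistic family")
    null = fit_binding([wt_data, mut_data], family=family, share={"top"}, n_starts=n_starts)
    warm = {k: v for k, v in null.params[wt_data.condition_label].items()}
    alt = fit_binding([wt_data, mut_data], family=family, share=set(), n_starts=n_starts, extra_starts=(warm,))
    return ess_f_test(null, alt, null_label="shared top", alt_label="per-condition top")


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_value: float
    paired: bool
    pooled: bool = False


def t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    paired: bool = False,
    pooled: bool = False,
) -> TTestResult:
    """Two-tailed t-test between two groups of replicate measurements.

    Unpaired comparisons use the Welch (unequal-variance) form by default;
    ``pooled=True`` selects the classical equal-variance Student form.
    Degenerate inputs (zero variance everywhere) yield ``p = NaN``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        d = a - b
        if np.ptp(d) == 0 and d[0] == 0:
            # all differences exactly zero: t = 0, but with zero variance the
            # p-value is undefined and flagged as NaN
            return TTestResult(0.0, float(a.size - 1), float("nan"), True)
        res = stats.ttest_rel(a, b)
        return TTestResult(float(res.statistic), float(a.size - 1), float(res.pvalue), True)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return TTestResult(float("nan"), float("nan"), float("nan"), False, pooled)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=pooled)
    df = a.size + b.size - 2 if pooled else float(getattr(res, "df", np.nan))
    return TTestResult(float(res.statistic), float(df), float(res.pvalue), False, pooled)


@dataclass(frozen=True)
class CalibrationResult:
    """Empirical rejection rate of a test over simulated datasets."""

    rejection_rate: float
    se: float  # binomial standard error
    n_sims: int
    alpha: float
    n_failed: int = 0


def calibrate_test(
    p_value_fn: Callable[[int], float],
    n_sims: int,
    alpha: float,
    seed: int,
) -> CalibrationResult:
    """Monte-Carlo rejection rate of a test at level ``alpha``.

    Parameters
    ----------
    p_value_fn
        Maps an integer sub-seed to the p-value of one simulated experiment
        (generate data under the scenario, run the test, return p). Raising
        or returning NaN counts the replicate as failed and excludes it.
    n_sims
        Number of simulated experiments, >= 100.
    alpha
        Rejection threshold in (0, 1].
    seed
        Base seed; replicate i uses sub-seed drawn from a seeded sequence.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for a meaningful rate")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_sims)
    rejected = 0
    failed = 0
    for s in sub_seeds:
        try:
            p = p_value_fn(int(s))
        except Exception:
            failed += 1
            continue
        if not np.isfinite(p):
            failed += 1
            continue
        if p < alpha or alpha == 1.0:
            rejected += 1
    n_ok = n_sims - failed
    rate = rejected / n_ok if n_ok else float("nan")
    se = float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else float("nan")
    return CalibrationResult(rejection_rate=rate, se=se, n_sims=n_ok, alpha=alpha, n_failed=failed)
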