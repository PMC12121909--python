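"""Learning-curve fits, plateau detection, outcome contrasts, correlations.

The adaptation time course of any per-trial measure is summarised by an
exponential a*exp(-x/b) + c fitted by nonlinear least squares; the time
constant b is the learning rate and the plateau trial is where the curve has
covered 95 % of its asymptotic change, i.e. x = b*ln(20).  Outcome-dependent
adaptation is quantified by the per-run sums of metric changes between
consecutive successes (S-S) and between successes separated by at least one
failure (S-F-S); de-adaptation by the relative-reduction index
RD = 1 - (A_D1 - A_B)/(A_C - A_B).  A simulated cohort is compared against
reference trial series by all-pairs Pearson correlation on a common
normalized trial grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ExpFitResult",
    "ContrastResult",
    "fit_learning_curve",
    "plateau_trial",
    "outcome_contrasts",
    "relative_reduction",
    "run_reference_correlations",
    "paired_t",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class ExpFitResult:
    a: float
    b: float
    c: float
    plateau_trial: float | None
    converged: bool
    excluded_reason: str | None  # None | "negative_b" | "linear_fit"
    sse: float = float("nan")


def _exp_model(x, a, b, c):
    with np.errstate(over="ignore"):
        return a * np.exp(np.clip(-x / b, -700, 700)) + c


def fit_learning_curve(
    series: Sequence[float],
    x: Sequence[float] | None = None,
    linear_b_factor: float = 10.0,
) -> ExpFitResult:
    """Fit a*exp(-x/b)+c by multi-start nonlinear least squares.

    Fits with b of either sign are allowed so that runaway time constants
    can be recognised: a negative best-fit b is flagged ``negative_b`` and a
    time constant exceeding ``linear_b_factor`` times the x span (the
    exponential is indistinguishable from a straight line on the window) is
    flagged ``linear_fit``; both flags exclude the plateau estimate.
    """
    y = np.asarray(series, dtype=float)
    if x is None:
        x = np.arange(1, len(y) + 1, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 points")
    span = x.max() - x.min()
    a0 = y[0] - y[-1]
    if a0 == 0:
        a0 = max(1e-8, np.std(y))
    c0 = y[-1]
    b0 = span / 3.0
    best = None
    for jitter in (1.0, 0.5, 2.0, 0.25, 4.0, -1.0):
        try:
            popt, _ = optimize.curve_fit(
                _exp_model, x, y, p0=(a0, b0 * jitter, c0), maxfev=5000
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        sse = float(np.sum((_exp_model(x, *popt) - y) ** 2))
        if best is None or sse < best[1] - 1e-12:
            best = (popt, sse)
    if best is None:
        return ExpFitResult(
            a=float("nan"), b=float("nan"), c=float("nan"),
            plateau_trial=None, converged=False, excluded_reason=None,
        )
    (a, b, c), sse = best
    reason = None
    if b < 0:
        reason = "negative_b"
    elif b > linear_b_factor * span:
        reason = "linear_fit"
    plateau = b * np.log(20.0) if reason is None else None
    return ExpFitResult(
        a=float(a), b=float(b), c=float(c),
        plateau_trial=plateau, converged=True, excluded_reason=reason,
        sse=sse,
    )


def plateau_trial(fit: ExpFitResult) -> float:
    """Trial index at which the fitted exponential reaches 95 % of its change.

    |a| e^(-x/b) <= 0.05 |a|  =>  x = b ln 20 (0 for a degenerate flat fit).
    """
    if not fit.converged or fit.excluded_reason is not None or fit.b <= 0:
        raise ValueError("plateau undefined for unconverged or excluded fits")
    if fit.a == 0:
        return 0.0
    return fit.b * float(np.log(20.0))


@dataclass(frozen=True)
class ContrastResult:
    mean_delta_ss: float
    mean_delta_sfs: float
    per_run_ss: np.ndarray
    per_run_sfs: np.ndarray
    t_statistic: float
    p_value: float
    n: int


def _run_contrast_sums(
    outcomes: Sequence[str], values: Sequence[float]
) -> tuple[float, float, int, int]:
    """Per-run sums of metric deltas over S-S and S-F-S trial pairs.

    A pair is two successes; it is S-S when adjacent and S-F-S when at least
    one failure lies between them.  Pairs whose intervening failures include
    a forward failure are excluded (forward steps are atypical events).
    """
    ss = sfs = 0.0
    n_ss = n_sfs = 0
    prev_idx = None
    for i, (oc, v) in enumerate(zip(outcomes, values)):
        if oc != "success":
            continue
        if prev_idx is not None:
            between = outcomes[prev_idx + 1 : i]
            delta = v - values[prev_idx]
            if not between:
                ss += delta
                n_ss += 1
            elif "failure_forward" not in between:
                sfs += delta
                n_sfs += 1
        prev_idx = i
    return ss, sfs, n_ss, n_sfs


def outcome_contrasts(
    runs: Sequence, metric_name: str, block: str = "perturbed"
) -> ContrastResult:
    """Population contrast of S-S versus S-F-S metric changes.

    ``runs`` are RunResult objects; per-run sums of the metric deltas are
    compared across runs with a paired t-test.
    """
    per_ss, per_sfs = [], []
    for run in runs:
        recs = [t for t in run.trials if t.block == block]
        outcomes = [t.outcome for t in recs]
        values = [getattr(t.metrics, metric_name) for t in recs]
        ss, sfs, n_ss, n_sfs = _run_contrast_sums(outcomes, values)
        if n_ss == 0 and n_sfs == 0:
            continue
        per_ss.append(ss)
        per_sfs.append(sfs)
    if len(per_ss) < 2:
        raise ValueError("no qualifying runs for the contrast")
    per_ss = np.array(per_ss)
    per_sfs = np.array(per_sfs)
    t, p = paired_t(per_sfs, per_ss)
    return ContrastResult(
        mean_delta_ss=float(per_ss.mean()),
        mean_delta_sfs=float(per_sfs.mean()),
        per_run_ss=per_ss,
        per_run_sfs=per_sfs,
        t_statistic=t,
        p_value=p,
        n=len(per_ss),
    )


def relative_reduction(a_d1: float, a_c: float, a_b: float) -> float:
    """De-adaptation index RD = 1 - (A_D1 - A_B)/(A_C - A_B).

    1 when the first de-adaptation trial returns fully to baseline, 0 when
    it retains the full catch-trial aftereffect.
    """
    if a_c == a_b:
        raise ZeroDivisionError("undefined when catch equals baseline")
    return 1.0 - (a_d1 - a_b) / (a_c - a_b)


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Paired t statistic and two-sided p for equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need equal-length samples, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        raise ZeroDivisionError("zero variance of non-zero differences")
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2 * stats.t.sf(abs(t), len(d) - 1)
    return float(t), float(p)


def run_reference_correlations(
    sim: np.ndarray, ref: np.ndarray, alpha: float = 0.05
) -> dict:
    """All-pairs Pearson correlation between simulated and reference series.

    ``sim`` (n_sim x m) and ``ref`` (n_ref x m) hold per-trial metric series
    aligned on a common normalized trial grid.  Returns the full r and p
    matrices (n_ref x n_sim) plus a per-reference summary (min/mean/max r
    and the count of non-significant pairs at ``alpha``), mirroring how a
    cohort of reference runs is scored against a simulated population.
    Constant series yield NaN r and are counted as non-significant.
    """
    sim = np.atleast_2d(np.asarray(sim, dtype=float))
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    if sim.shape[1] != ref.shape[1]:
        raise ValueError("series must share the trial grid length")
    n_ref, n_sim = ref.shape[0], sim.shape[0]
    r = np.full((n_ref, n_sim), np.nan)
    p = np.full((n_ref, n_sim), np.nan)
    for i in range(n_ref):
        for j in range(n_sim):
            if np.std(ref[i]) == 0 or np.std(sim[j]) == 0:
                continue
            res = stats.pearsonr(ref[i], sim[j])
            r[i, j] = res.statistic
            p[i, j] = res.pvalue
    significant = (p < alpha) & (r > 0)
    r_min = np.full(n_ref, np.nan)
    r_mean = np.full(n_ref, np.nan)
    r_max = np.full(n_ref, np.nan)
    for i in range(n_ref):
        row = r[i][~np.isnan(r[i])]
        if len(row):
            r_min[i], r_mean[i], r_max[i] = row.min(), row.mean(), row.max()
    summary = pd.DataFrame(
        {
            "r_min": r_min,
            "r_mean": r_mean,
            "r_max": r_max,
            "n_nonsignificant": (~significant).sum(axis=1),
        }
    )
    return {
        "r": r,
        "p": p,
        "summary": summary,
        "n_pairs": n_ref * n_sim,
        "n_significant_positive": int(significant.sum()),
    }


def adjust_pvalues(pvals: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg or Bonferroni."""
    p = np.asarray(pvals, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method != "bh":
        raise ValueError("method must be 'bh' or 'bonferroni'")
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.minimum(ranked, 1.0)
    return out
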