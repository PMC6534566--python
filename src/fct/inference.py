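"""Delete-1 jackknife inference on variance explained, and FDR control.

For a statistic compared between two model variants A and B, let
M_hat_{-i} be the A-minus-B difference re-estimated without subject i.
The jackknife point estimate and variance are

    M_jack = (1/N) sum_i M_hat_{-i}
    V_jack = ((N-1)/N) sum_i (M_hat_{-i} - M_jack)^2

and z = M_jack / sqrt(V_jack) is referred to a standard normal under the
null (two-tailed). Leave-one-out refits of the moment estimator are
computed by exact algebraic downdates of the cached cross-products
(Gram entries and quadratic forms), so each refit equals the direct fit
on the N-1 remaining subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from fct.vcm import (
    MAX_GRAM_COND,
    ModelIdentifiabilityError,
    _as_kernel_arrays,
    projected_system,
)

TASK, SELF, UNCLASSIFIED = "task", "self", "unclassified"


@dataclass
class JackknifeResult:
    """Point estimate, variance, z and two-tailed p of one jackknifed statistic."""

    estimate: float
    variance: float
    z: float
    p: float
    leaveouts: np.ndarray

    @property
    def n(self) -> int:
        return self.leaveouts.size

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def jackknife_from_leaveouts(values: np.ndarray):
    """Aggregate per-leave-out statistic values into jackknife results.

    ``values`` is (N,) for a scalar statistic or (N, S) for S statistics
    jackknifed jointly; returns one ``JackknifeResult`` or a list.
    """
    values = np.asarray(values, dtype=float)
    scalar = values.ndim == 1
    v = values[:, None] if scalar else values
    n = v.shape[0]
    est = v.mean(axis=0)
    var = (n - 1) / n * ((v - est) ** 2).sum(axis=0)

    results = []
    for j in range(v.shape[1]):
        if var[j] > 0:
            z = est[j] / np.sqrt(var[j])
            p = 2.0 * norm.sf(abs(z))
        elif est[j] == 0.0:
            z, p = 0.0, 1.0
        else:
            z, p = np.sign(est[j]) * np.inf, 0.0
        results.append(
            JackknifeResult(
                estimate=float(est[j]),
                variance=float(var[j]),
                z=float(z),
                p=float(p),
                leaveouts=v[:, j].copy(),
            )
        )
    return results[0] if scalar else results


def jackknife(data: np.ndarray, stat_fn):
    """Delete-1 jackknife of an arbitrary statistic of the sample.

    ``stat_fn`` maps a data array (with axis 0 indexing subjects) to a
    scalar; the engine computes the N leave-one-out values and
    aggregates them. For ``stat_fn = mean`` this reproduces the
    closed-form variance s^2 / n exactly.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    loo = np.array([stat_fn(np.delete(data, i, axis=0)) for i in range(n)])
    return jackknife_from_leaveouts(loo)


@dataclass
class _LooFit:
    """Per-leave-out variance-explained quantities for one model."""

    M: np.ndarray          # (N,)
    M_i: np.ndarray        # (N, Q)
    shares: np.ndarray     # (N, K)
    trace_c: np.ndarray    # (N, K) explained trace per kernel
    trace_e: np.ndarray    # (N,)


def loo_variance_explained(
    y: np.ndarray, kernels, center: bool = True, truncate: bool = True
) -> _LooFit:
    """All N delete-1 refits of the moment estimator, exactly and at once.

    Y is centered once on the full sample; deleting subject i then only
    downdates the cached Gram entries <F_a, F_b> and quadratic forms
    y_p^T F_a y_p, giving the same numbers as a direct refit on the
    deleted data (without re-centering, whose effect is O(1/N)).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, q = y.shape
    f_only = _as_kernel_arrays(kernels)
    k = len(f_only)
    for f in f_only:
        if f.shape[0] != n:
            raise ValueError("kernel dimension does not match subject count")
    if center:
        y = y - y.mean(axis=0)

    # projection (like centering) is applied once at the full-sample
    # level; the per-subject downdates below are then exact
    f_stack = np.stack(projected_system(f_only, n, center))   # (K+1, N, N)
    k1 = k + 1
    g = np.einsum("aij,bij->ab", f_stack, f_stack)
    if np.linalg.cond(g) > MAX_GRAM_COND:
        raise ModelIdentifiabilityError("moment system ill-conditioned")

    d = np.array([np.diag(f) for f in f_stack])        # (K+1, N)
    rowdot = np.einsum("aij,bij->iab", f_stack, f_stack)   # (N, K+1, K+1)
    g_loo = g[None] - 2.0 * rowdot + d.T[:, :, None] * d.T[:, None, :]

    w = np.einsum("aij,jp->aip", f_stack, y)           # (K+1, N, Q)
    b_full = np.einsum("aip,ip->ap", w, y)             # (K+1, Q)
    wt = w.transpose(1, 0, 2)                          # (N, K+1, Q)
    b_loo = (
        b_full[None]
        - 2.0 * y[:, None, :] * wt
        + d.T[:, :, None] * (y ** 2)[:, None, :]
    )

    try:
        sig = np.linalg.solve(g_loo, b_loo)            # (N, K+1, Q)
    except np.linalg.LinAlgError:
        for i in range(n):
            try:
                np.linalg.solve(g_loo[i], b_loo[i])
            except np.linalg.LinAlgError:
                raise ModelIdentifiabilityError(
                    f"leave-one-out refit failed for subject index {i}"
                ) from None
        raise

    if truncate:
        dc = np.clip(sig[:, :k, :], 0.0, None)         # (N, K, Q)
        de = np.clip(sig[:, k, :], 0.0, None)          # (N, Q)
    else:
        # raw components: used for statistics whose null distribution
        # should stay centered at zero (e.g. block contribution shares)
        dc = sig[:, :k, :]
        de = sig[:, k, :]
    num_i = dc.sum(axis=1)
    denom_i = num_i + de
    total = denom_i.sum(axis=1)
    if truncate and np.any(total <= 0):
        raise ModelIdentifiabilityError("all-zero total variance in a leave-one-out fit")
    with np.errstate(invalid="ignore", divide="ignore"):
        m_i = np.where(denom_i > 0, num_i / np.where(denom_i > 0, denom_i, 1.0), 0.0)
        m = num_i.sum(axis=1) / np.where(total != 0, total, 1.0)
        shares = dc.sum(axis=2) / np.where(total != 0, total, 1.0)[:, None]
    return _LooFit(
        M=m, M_i=m_i, shares=shares, trace_c=dc.sum(axis=2), trace_e=de.sum(axis=1)
    )


def _category_masks(categories, q: int):
    cats = np.asarray(list(categories))
    if cats.size != q:
        raise ValueError("one category label per measure required")
    task = cats == TASK
    self_ = cats == SELF
    if not task.any() or not self_.any():
        raise ValueError("category contrast needs task and self measures")
    return task, self_


def jackknife_compare(
    y: np.ndarray,
    kernels_a,
    kernels_b,
    statistic: str = "overall_m",
    categories=None,
):
    """Jackknife comparison of variance explained between two models.

    ``kernels_a`` / ``kernels_b`` each define a (possibly multi-kernel)
    variance-component model on the same subjects. Statistics:

    - ``overall_m``: difference of overall M (scalar result).
    - ``per_measure``: per-measure M_i differences (list of results);
      the per-measure z is the T statistic used for ranking, positive
      when model A explains more variance.
    - ``category_mean``: dict with the mean per-measure difference over
      task-performance and over self-reported measures (unclassified
      measures are excluded).
    - ``interaction``: (mean over task) - (mean over self) of the
      per-measure differences.

    The leave-one-out refits use the raw (untruncated) variance
    components: truncation at zero inflates each model's M by an amount
    that depends on its kernel count, so differences of truncated
    estimates are biased and their null distribution is off-center,
    whereas raw component differences are unbiased. Reported point
    estimates of M elsewhere remain truncated.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    if n < 30:
        import warnings

        warnings.warn(
            f"N={n} < 30: the normal approximation for the jackknife z may be poor",
            stacklevel=2,
        )
    loo_a = loo_variance_explained(y, kernels_a, truncate=False)
    loo_b = loo_variance_explained(y, kernels_b, truncate=False)

    if statistic == "overall_m":
        return jackknife_from_leaveouts(loo_a.M - loo_b.M)
    diff = loo_a.M_i - loo_b.M_i                      # (N, Q)
    if statistic == "per_measure":
        return jackknife_from_leaveouts(diff)
    task, self_ = _category_masks(categories, y.shape[1])
    if statistic == "category_mean":
        return {
            TASK: jackknife_from_leaveouts(diff[:, task].mean(axis=1)),
            SELF: jackknife_from_leaveouts(diff[:, self_].mean(axis=1)),
        }
    if statistic == "interaction":
        return jackknife_from_leaveouts(
            diff[:, task].mean(axis=1) - diff[:, self_].mean(axis=1)
        )
    raise ValueError(f"unknown statistic: {statistic!r}")


def rank_measures(results, names, categories):
    """Rank measures by T (descending), ties broken by measure name.

    ``results`` are per-measure ``JackknifeResult`` objects whose z is
    the T statistic (model A minus model B, positive = A explains more).
    """
    import pandas as pd

    if len(results) != len(names):
        raise ValueError("one result per measure required")
    df = pd.DataFrame(
        {
            "measure": list(names),
            "T": [r.z for r in results],
            "estimate": [r.estimate for r in results],
            "sd": [r.sd for r in results],
            "p": [r.p for r in results],
            "category": list(categories),
        }
    )
    df = df.sort_values(["measure"], kind="mergesort")
    df = df.sort_values(["T"], ascending=False, kind="mergesort")
    return df.reset_index(drop=True)


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level q."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(pvals)) or np.any(pvals < 0) or np.any(pvals > 1):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return rejected
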