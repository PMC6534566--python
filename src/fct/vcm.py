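"""Multivariate variance-component model linking FC similarity to behavior.

Model: Y = C + E for a subjects x measures matrix Y, with
Vec(C) ~ N(0, Sigma_c (x) F) and Vec(E) ~ N(0, Sigma_e (x) I), where F
is a subjects x subjects FC-similarity kernel. The fraction of
inter-subject behavioral variance explained by FC variability is

    M = Tr(Sigma_c) / (Tr(Sigma_c) + Tr(Sigma_e)),

and per measure i, M_i = Sigma_c(i,i) / (Sigma_c(i,i) + Sigma_e(i,i)).
With K kernels, C = sum_k C_k with Vec(C_k) ~ N(0, Sigma_c^k (x) F_k)
and the numerator of M sums the K explained traces.

Estimation is by method of moments (Haseman-Elston / MINQUE style): for
each ordered measure pair (p, q),

    E[y_p^T F_k y_q] = sum_l Sigma_c^l(p, q) <F_k, F_l> + Sigma_e(p, q) Tr(F_k)

so the (K+1)-vector of components solves the linear system with Gram
matrix G_{kl} = <F_k, F_l>_Frobenius (F_{K+1} = I). The estimator is
deterministic and unbiased; negative diagonal components are truncated
to zero when computing M (raw values are retained for diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fct.similarity import SimilarityKernel


class ModelIdentifiabilityError(ValueError):
    """The kernel set cannot separate signal from noise (e.g. F = I)."""


MAX_GRAM_COND = 1e10


def projected_system(f_only: list[np.ndarray], n: int, center: bool) -> list[np.ndarray]:
    """Kernel basis for the moment equations, including the noise kernel.

    With centering, Y loses its grand-mean component, so the model for
    the centered data is Cov(Py_p) = Sigma_c P F P + Sigma_e P with
    P = I - 11^T/n. Using the projected basis {PFP, P} keeps the moment
    estimator consistent when the kernel has non-zero row sums (as
    FC-similarity kernels, with their large shared component, always
    do); the unprojected basis {F, I} would be biased there.
    """
    if not center:
        return list(f_only) + [np.eye(n)]
    p = np.eye(n) - np.full((n, n), 1.0 / n)
    return [p @ f @ p for f in f_only] + [p]


def _as_kernel_arrays(kernels) -> list[np.ndarray]:
    if isinstance(kernels, (SimilarityKernel, np.ndarray)):
        kernels = [kernels]
    out = []
    for k in kernels:
        f = k.F if isinstance(k, SimilarityKernel) else np.asarray(k, dtype=float)
        if f.ndim != 2 or f.shape[0] != f.shape[1]:
            raise ValueError("kernel must be square")
        if not np.allclose(f, f.T, atol=1e-10):
            raise ValueError("kernel must be symmetric")
        out.append((f + f.T) / 2.0)
    if not out:
        raise ValueError("at least one kernel required")
    return out


@dataclass
class VCMFit:
    """Estimated variance components and derived variance-explained.

    ``sigma_c_list`` holds one measures x measures matrix per kernel;
    raw (untruncated) estimates are kept alongside the truncated
    quantities that enter M and M_i.
    """

    sigma_c_list: list[np.ndarray]
    sigma_e: np.ndarray
    M: float
    M_i: np.ndarray
    kernel_shares: np.ndarray      # Tr+(Sigma_c^k) / total trace; sums to M
    gram_cond: float
    measures: list[str] = field(default_factory=list)

    @property
    def n_kernels(self) -> int:
        return len(self.sigma_c_list)


def moment_system(f_list: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Gram matrix of the kernels (identity appended) and its condition."""
    k1 = len(f_list)
    g = np.empty((k1, k1))
    for a in range(k1):
        for b in range(a, k1):
            g[a, b] = g[b, a] = float(np.sum(f_list[a] * f_list[b]))
    return g, float(np.linalg.cond(g))


def fit_vcm(
    y: np.ndarray,
    kernels,
    center: bool = True,
    measures: list[str] | None = None,
) -> VCMFit:
    """Method-of-moments fit of the (multi-kernel) variance-component model.

    Parameters
    ----------
    y
        (subjects, measures) behavioral matrix; columns are centered by
        default (the model has zero mean).
    kernels
        One kernel or a list (``SimilarityKernel`` or plain arrays),
        each subjects x subjects symmetric.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, q = y.shape
    f_only = _as_kernel_arrays(kernels)
    for f in f_only:
        if f.shape[0] != n:
            raise ValueError("kernel dimension does not match subject count")
    if center:
        y = y - y.mean(axis=0)

    f_list = projected_system(f_only, n, center)
    g, cond = moment_system(f_list)
    if cond > MAX_GRAM_COND:
        raise ModelIdentifiabilityError(
            f"moment system condition number {cond:.2e} exceeds {MAX_GRAM_COND:.0e}"
        )

    # b_k = Y^T F_k Y for each kernel, flattened over measure pairs
    b = np.stack([y.T @ f @ y for f in f_list])
    sol = np.linalg.solve(g, b.reshape(len(f_list), -1)).reshape(b.shape)
    sigmas = [(s + s.T) / 2.0 for s in sol]
    sigma_c_list, sigma_e = sigmas[:-1], sigmas[-1]

    m, m_i, shares = variance_explained(sigma_c_list, sigma_e)
    return VCMFit(
        sigma_c_list=sigma_c_list,
        sigma_e=sigma_e,
        M=m,
        M_i=m_i,
        kernel_shares=shares,
        gram_cond=cond,
        measures=list(measures) if measures is not None else [],
    )


def variance_explained(
    sigma_c_list: list[np.ndarray] | "VCMFit",
    sigma_e: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Trace-ratio variance explained, overall and per measure.

    Negative diagonal entries are truncated to zero first, keeping M and
    every M_i inside [0, 1]. Returns ``(M, M_i, kernel_shares)`` where
    ``kernel_shares[k]`` is kernel k's contribution Tr+(Sigma_c^k)
    divided by the total trace, so the shares sum to M.
    """
    if sigma_e is None:  # called with a VCMFit
        fit = sigma_c_list
        sigma_c_list, sigma_e = fit.sigma_c_list, fit.sigma_e
    dc = np.stack([np.clip(np.diag(s), 0.0, None) for s in sigma_c_list])
    de = np.clip(np.diag(sigma_e), 0.0, None)
    num_i = dc.sum(axis=0)
    denom_i = num_i + de
    total = float(denom_i.sum())
    if total <= 0:
        raise ValueError("all-zero total variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        m_i = np.where(denom_i > 0, num_i / np.where(denom_i > 0, denom_i, 1.0), 0.0)
    m = float(num_i.sum() / total)
    shares = dc.sum(axis=1) / total
    return m, m_i, shares
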