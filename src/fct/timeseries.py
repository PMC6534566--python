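"""Motion censoring, nuisance regression, and static/dynamic FC estimation.

Static functional connectivity (FC) is the Pearson correlation matrix of
the ROI time series, computed per run on uncensored frames, Fisher
z-transformed, averaged over runs, and mapped back to r-space.

Dynamic FC is the coefficient matrix ``A`` of a first-order
autoregressive (AR-1) model ``x_t = A x_{t-1} + eps_t`` identified by
least squares over all frame pairs (t-1, t) that are consecutive, both
uncensored, and do not straddle a censored gap or a run boundary. The
model's goodness of fit is summarized by

    R^2 = 1 - ||Cov(eps)||_F / ||Cov(x)||_F,

the multivariate analogue of the univariate AR R-squared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateDataError(ValueError):
    """Raised when the input time series cannot support the estimator."""


@dataclass
class RunTimeSeries:
    """One run's ROI time series with its per-frame motion traces.

    Attributes
    ----------
    data
        Array of shape (frames, ROIs).
    fd
        Framewise displacement per frame, in mm.
    dvars
        Frame-to-frame signal change per frame (unitless here).
    run_id
        Identifier used in error messages and serialization.
    """

    data: np.ndarray
    fd: np.ndarray
    dvars: np.ndarray
    run_id: str = "run-1"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        n = self.data.shape[0]
        if self.fd.shape != (n,) or self.dvars.shape != (n,):
            raise ValueError(
                f"{self.run_id}: fd/dvars length must equal frame count {n}"
            )
        if not (np.isfinite(self.data).all() and np.isfinite(self.fd).all()
                and np.isfinite(self.dvars).all()):
            raise ValueError(f"{self.run_id}: non-finite values in input")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]


@dataclass
class CensorMask:
    """Boolean keep-flag per frame plus the derived segment list.

    ``segments`` are the maximal runs of consecutive kept frames, as
    half-open ``(start, stop)`` index pairs; after cleanup every segment
    has length >= the minimum segment length used to build the mask.
    """

    keep: np.ndarray
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)
        if not self.segments:
            self.segments = _segments_of(self.keep)

    @property
    def n_frames(self) -> int:
        return self.keep.size

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def censored_fraction(self) -> float:
        return 1.0 - self.n_kept / self.n_frames


def _segments_of(keep: np.ndarray) -> list[tuple[int, int]]:
    segs = []
    n = keep.size
    t = 0
    while t < n:
        if keep[t]:
            start = t
            while t < n and keep[t]:
                t += 1
            segs.append((start, t))
        else:
            t += 1
    return segs


def compute_censor_mask(
    fd: np.ndarray,
    dvars: np.ndarray,
    fd_thresh: float = 0.2,
    dvars_thresh: float = 75.0,
    n_before: int = 1,
    n_after: int = 2,
    min_segment: int = 5,
) -> CensorMask:
    """Build the motion-censoring mask from FD and DVARS traces.

    A frame is flagged when FD strictly exceeds ``fd_thresh`` (mm) or
    DVARS strictly exceeds ``dvars_thresh``; ``n_before`` frames before
    and ``n_after`` frames after each flagged frame are also removed
    (clipped at run boundaries). Surviving segments shorter than
    ``min_segment`` frames are then removed entirely.
    """
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    if fd.size == 0 or dvars.size == 0:
        raise ValueError("empty motion traces")
    if fd.shape != dvars.shape:
        raise ValueError("fd and dvars must have equal length")
    n = fd.size

    bad = (fd > fd_thresh) | (dvars > dvars_thresh)
    censor = np.zeros(n, dtype=bool)
    for t in np.flatnonzero(bad):
        censor[max(0, t - n_before): min(n, t + n_after + 1)] = True
    keep = ~censor

    segs = _segments_of(keep)
    for start, stop in segs:
        if stop - start < min_segment:
            keep[start:stop] = False
    return CensorMask(keep=keep)


def run_passes_qc(mask: CensorMask, max_censored_fraction: float = 0.5) -> bool:
    """A run is kept iff its censored fraction does not strictly exceed 50%."""
    return mask.censored_fraction <= max_censored_fraction


def regress_nuisance(
    run: RunTimeSeries,
    mask: CensorMask,
    regress_global: bool = True,
) -> RunTimeSeries:
    """Regress intercept, linear trend, and the global mean signal.

    Coefficients are fit per ROI by OLS on kept frames only; residuals
    are computed at every frame so the mask stays applicable downstream.
    The global regressor approximates the mean cortical signal at ROI
    level by the mean across ROIs; each ROI is regressed on the mean of
    the *other* ROIs (leave-one-out), which keeps the interpretation
    while avoiding an exact linear collapse of the residuals (regressing
    every ROI on the all-ROI mean would force the residual columns to
    sum to zero on kept frames, making the AR design exactly singular —
    a degeneracy the grayordinate-level operation on real data does not
    have). Pass ``regress_global=False`` to disable it.
    """
    keep = mask.keep
    if keep.size != run.n_frames:
        raise ValueError("mask length does not match run")
    if keep.sum() < 3:
        raise DegenerateDataError(f"{run.run_id}: fewer than 3 kept frames")

    n = run.n_frames
    base = np.column_stack([np.ones(n), np.linspace(-1.0, 1.0, n)])
    if not regress_global:
        dk = base[keep]
        if np.linalg.matrix_rank(dk) < dk.shape[1]:
            raise DegenerateDataError(f"{run.run_id}: rank-deficient nuisance regressors")
        beta, *_ = np.linalg.lstsq(dk, run.data[keep], rcond=None)
        resid = run.data - base @ beta
        return RunTimeSeries(data=resid, fd=run.fd, dvars=run.dvars, run_id=run.run_id)

    r = run.n_roi
    total = run.data.sum(axis=1)
    resid = np.empty_like(run.data)
    for j in range(r):
        g = (total - run.data[:, j]) / (r - 1)
        design = np.column_stack([base, g])
        dk = design[keep]
        if np.linalg.matrix_rank(dk) < dk.shape[1]:
            raise DegenerateDataError(f"{run.run_id}: rank-deficient nuisance regressors")
        beta, *_ = np.linalg.lstsq(dk, run.data[keep][:, j], rcond=None)
        resid[:, j] = run.data[:, j] - design @ beta
    return RunTimeSeries(data=resid, fd=run.fd, dvars=run.dvars, run_id=run.run_id)


@dataclass
class StaticFC:
    """Symmetric ROI x ROI correlation matrix with unit diagonal."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("static FC must be square")

    @property
    def n_roi(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DynamicFC:
    """AR-1 coefficient matrix with residual covariance and fit R^2.

    ``A`` is generally non-symmetric: entry (i, j) is the lag-1 influence
    of ROI j on ROI i. ``n_pairs`` counts the (t-1, t) frame pairs used.
    """

    A: np.ndarray
    resid_cov: np.ndarray
    r2: float
    n_pairs: int

    @property
    def n_roi(self) -> int:
        return self.A.shape[0]


# correlations are clipped away from +/-1 before atanh; the diagonal is
# excluded from averaging and reset to 1 afterwards
_ATANH_CLIP = 1.0 - 1e-12


def static_fc(runs: list[tuple[RunTimeSeries, CensorMask]]) -> StaticFC:
    """Static FC: per-run Pearson correlation on kept frames, Fisher-averaged.

    Each run's correlation matrix is computed from its uncensored frames,
    Fisher z-transformed (off-diagonal only), averaged across runs, and
    transformed back to r-space; the diagonal is forced to 1.
    """
    if not runs:
        raise ValueError("at least one run required")
    zs = []
    for run, mask in runs:
        kept = run.data[mask.keep]
        if kept.shape[0] < 3:
            raise DegenerateDataError(f"{run.run_id}: fewer than 3 kept frames")
        sd = kept.std(axis=0)
        if np.any(sd == 0):
            raise DegenerateDataError(
                f"{run.run_id}: constant ROI signal, correlation undefined"
            )
        corr = np.corrcoef(kept, rowvar=False)
        z = np.arctanh(np.clip(corr, -_ATANH_CLIP, _ATANH_CLIP))
        np.fill_diagonal(z, 0.0)
        zs.append(z)
    mean_z = np.mean(zs, axis=0)
    out = np.tanh(mean_z)
    np.fill_diagonal(out, 1.0)
    out = (out + out.T) / 2.0
    return StaticFC(matrix=out)


def ar_pairs(runs: list[tuple[RunTimeSeries, CensorMask]]) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate valid AR frame pairs: (x_{t-1} rows, x_t rows).

    A pair is valid when both frames are kept, consecutive, and inside
    one censoring segment of one run, so transitions across censored
    gaps and across run boundaries are never used.
    """
    prev_rows, next_rows = [], []
    for run, mask in runs:
        for start, stop in mask.segments:
            if stop - start >= 2:
                prev_rows.append(run.data[start:stop - 1])
                next_rows.append(run.data[start + 1:stop])
    if not prev_rows:
        raise DegenerateDataError("no valid consecutive frame pairs")
    return np.vstack(prev_rows), np.vstack(next_rows)


def dynamic_fc(runs: list[tuple[RunTimeSeries, CensorMask]]) -> DynamicFC:
    """Fit the AR-1 model on the concatenated uncensored sections.

    ``A`` solves min ||X_next - X_prev A^T||_F over the valid pair list
    (no intercept: the series are detrended/demeaned upstream). The
    residual covariance and the covariance of the kept frames yield
    R^2 = 1 - ||Cov(eps)||_F / ||Cov(x)||_F.
    """
    x_prev, x_next = ar_pairs(runs)
    n_pairs, n_roi = x_prev.shape
    if n_pairs <= n_roi:
        raise DegenerateDataError(
            f"{n_pairs} valid pairs <= {n_roi} ROIs: AR model unidentifiable"
        )
    at, _, rank, _ = np.linalg.lstsq(x_prev, x_next, rcond=None)
    if rank < n_roi:
        raise DegenerateDataError("singular normal equations in AR fit")
    resid = x_next - x_prev @ at
    resid_cov = np.cov(resid, rowvar=False)

    kept = np.vstack([run.data[mask.keep] for run, mask in runs])
    x_cov = np.cov(kept, rowvar=False)
    denom = np.linalg.norm(x_cov, "fro")
    if denom == 0:
        raise DegenerateDataError("zero-variance input")
    r2 = 1.0 - np.linalg.norm(resid_cov, "fro") / denom
    return DynamicFC(A=at.T, resid_cov=resid_cov, r2=float(r2), n_pairs=n_pairs)
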