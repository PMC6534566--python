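"""Synthetic cohort generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: each subject's resting-state dynamics follow a stable AR-1
model whose coefficient matrix shares a common backbone across subjects
plus an individual perturbation (so inter-subject FC similarity kernels
are non-degenerate); motion traces produce realistic censoring
fractions under the standard FD/DVARS scrubbing rules; and behavioral
measures are drawn exactly from the matrix-normal variance-component
model given the similarity kernels computed from the simulated time
series, so every true variance-explained value is known by construction.

Generation is two-stage: time series first, then behavior conditional on
the empirically computed kernels. This makes the recorded true M exact
rather than approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from fct.parcellation import Parcellation, make_parcellation
from fct.timeseries import (
    RunTimeSeries,
    compute_censor_mask,
    run_passes_qc,
    regress_nuisance,
    static_fc,
    dynamic_fc,
)
from fct.similarity import kernel_from_fc, SimilarityKernel

PSD_TOL = -1e-10


def spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(a))))


def make_base_ar(
    parcellation: Parcellation,
    seed: int,
    diag: float = 0.7,
    within_scale: float = 0.25,
    between_scale: float = 0.06,
    target_radius: float = 0.9,
) -> np.ndarray:
    """Network-structured base AR matrix shared across subjects.

    A dominant positive diagonal mimics hemodynamic autocorrelation;
    within-network couplings are stronger than between-network ones.
    The matrix is rescaled to the requested spectral radius.
    """
    rng = np.random.default_rng(seed)
    r = parcellation.n_roi
    labels = np.asarray(parcellation.networks)
    same = labels[:, None] == labels[None, :]
    scale = np.where(same, within_scale, between_scale)
    a = rng.standard_normal((r, r)) * scale / np.sqrt(r)
    a[np.diag_indices(r)] = diag * (1.0 + 0.1 * rng.standard_normal(r))
    return a * (target_radius / spectral_radius(a))


def make_ar_modes(
    parcellation: Parcellation,
    n_modes: int,
    seed: int,
    within_scale: float = 1.0,
    between_scale: float = 0.25,
) -> list[np.ndarray]:
    """Shared modes of inter-subject AR variability (unit Frobenius norm).

    Subjects differ along a small number of shared connectivity modes
    (plus idiosyncratic noise); this low-dimensional structure is what
    makes some subject pairs genuinely more similar than others and
    hence the similarity kernel informative. A purely i.i.d.
    perturbation per subject would produce a kernel with constant
    off-diagonal (every pair equally dissimilar), which carries no
    usable structure for the variance-component model.
    """
    rng = np.random.default_rng(seed)
    r = parcellation.n_roi
    labels = np.asarray(parcellation.networks)
    same = labels[:, None] == labels[None, :]
    scale = np.where(same, within_scale, between_scale)
    modes = []
    for _ in range(n_modes):
        m = rng.standard_normal((r, r)) * scale
        modes.append(m / np.linalg.norm(m))
    return modes


def sample_subject_ar(
    base_A: np.ndarray,
    individual_scale: float,
    target_radius: float,
    seed: int,
) -> np.ndarray:
    """Subject-specific AR matrix: base + scaled perturbation, radius fixed.

    The perturbation has i.i.d. normal entries with standard deviation
    ``individual_scale / sqrt(R)`` (so its own spectral radius is about
    ``individual_scale``); the sum is rescaled so its spectral radius is
    exactly ``target_radius``, keeping every subject stationary.
    """
    base_A = np.asarray(base_A, dtype=float)
    if base_A.ndim != 2 or base_A.shape[0] != base_A.shape[1]:
        raise ValueError("base_A must be square")
    if individual_scale < 0:
        raise ValueError("individual_scale must be non-negative")
    if not 0.0 < target_radius < 1.0:
        raise ValueError("target_radius must lie in (0, 1) for stationarity")
    rng = np.random.default_rng(seed)
    r = base_A.shape[0]
    a = base_A + rng.standard_normal((r, r)) * individual_scale / np.sqrt(r)
    rad = spectral_radius(a)
    if rad == 0:
        raise ValueError("degenerate zero matrix")
    return a * (target_radius / rad)


def _psd_sqrt(mat: np.ndarray, name: str) -> np.ndarray:
    """Symmetric PSD square root with eigen-clipping at the -1e-10 tolerance."""
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    lam, vec = np.linalg.eigh((mat + mat.T) / 2.0)
    scale = max(1.0, float(np.abs(lam).max()))
    if lam.min() < PSD_TOL * scale:
        raise ValueError(f"{name} is not PSD (min eigenvalue {lam.min():.3e})")
    lam = np.clip(lam, 0.0, None)
    return vec * np.sqrt(lam) @ vec.T


def simulate_run(
    A: np.ndarray,
    innovation_cov: np.ndarray | float,
    n_frames: int,
    burn_in: int = 200,
    seed: int | None = None,
    x0: np.ndarray | None = None,
    fd: np.ndarray | None = None,
    dvars: np.ndarray | None = None,
    run_id: str = "run-1",
) -> RunTimeSeries:
    """Forward-simulate x_t = A x_{t-1} + eps_t and return a run.

    The chain starts at ``x0`` (zero by default) and the first
    ``burn_in`` frames are discarded so the retained sample is
    (approximately) stationary. With ``innovation_cov = 0`` the
    recursion is exactly deterministic. FD/DVARS traces default to
    zeros (a motion-free run) and can be supplied by the caller.
    """
    A = np.asarray(A, dtype=float)
    r = A.shape[0]
    if spectral_radius(A) >= 1.0:
        raise ValueError("unstable AR matrix (spectral radius >= 1)")
    if np.isscalar(innovation_cov):
        cov = float(innovation_cov) * np.eye(r)
    else:
        cov = np.asarray(innovation_cov, dtype=float)
    l_eps = _psd_sqrt(cov, "innovation_cov")

    rng = np.random.default_rng(seed)
    total = n_frames + burn_in
    if np.all(l_eps == 0):
        eps = np.zeros((total, r))
    else:
        eps = rng.standard_normal((total, r)) @ l_eps.T
    x = np.zeros(r) if x0 is None else np.asarray(x0, dtype=float)
    out = np.empty((total, r))
    for t in range(total):
        x = A @ x + eps[t]
        out[t] = x
    data = out[burn_in:]
    n = data.shape[0]
    return RunTimeSeries(
        data=data,
        fd=np.zeros(n) if fd is None else fd,
        dvars=np.zeros(n) if dvars is None else dvars,
        run_id=run_id,
    )


def simulate_motion(
    n_frames: int,
    censor_fraction_target: float,
    seed: int | None = None,
    tol: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """FD/DVARS traces whose rule-based censoring hits a target fraction.

    Baseline FD sits well below the 0.2 mm threshold and baseline DVARS
    below 75 (the generator calibrates the unitless DVARS scale to the
    standard threshold). Motion spikes exceeding both thresholds are
    inserted at random frames; the spike count is searched so that the
    fraction censored by ``compute_censor_mask`` at default thresholds
    lands within ``tol`` of the target. Raises if the target is
    infeasible at this run length (frame expansion and the minimum
    segment rule quantize the achievable fractions).
    """
    if not 0.0 <= censor_fraction_target < 1.0:
        raise ValueError("censor target must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    fd = 0.04 + 0.08 * rng.random(n_frames)
    dvars = 40.0 + 15.0 * rng.random(n_frames)
    if censor_fraction_target == 0.0:
        return fd, dvars

    positions = rng.permutation(n_frames)
    fd_spikes = 0.25 + 0.25 * rng.random(n_frames)
    dv_spikes = 80.0 + 25.0 * rng.random(n_frames)

    def frac_for(k: int) -> float:
        f, d = fd.copy(), dvars.copy()
        pos = positions[:k]
        f[pos] = fd_spikes[pos]
        d[pos] = dv_spikes[pos]
        return compute_censor_mask(f, d).censored_fraction

    lo, hi = 0, n_frames
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if frac_for(mid) < censor_fraction_target:
            lo = mid
        else:
            hi = mid
    # local scan around the bisection point (the map k -> fraction is
    # only approximately monotone near the segment-removal rule)
    best_k, best_err = None, np.inf
    for k in range(max(0, lo - 3), min(n_frames, hi + 3) + 1):
        err = abs(frac_for(k) - censor_fraction_target)
        if err < best_err:
            best_k, best_err = k, err
    if best_err > tol:
        raise ValueError(
            f"censor target {censor_fraction_target} infeasible at {n_frames} frames "
            f"(closest achievable deviates by {best_err:.3f})"
        )
    pos = positions[:best_k]
    fd[pos] = fd_spikes[pos]
    dvars[pos] = dv_spikes[pos]
    return fd, dvars


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    subject_A: list[np.ndarray]
    innovation_cov: np.ndarray
    sigma_c_list: list[np.ndarray]
    sigma_e: np.ndarray
    M: float
    M_i: np.ndarray
    kernel_names: list[str]
    seed: int

    def to_jsonable(self) -> dict:
        return {
            "subject_A": [a.tolist() for a in self.subject_A],
            "innovation_cov": self.innovation_cov.tolist(),
            "sigma_c_list": [s.tolist() for s in self.sigma_c_list],
            "sigma_e": self.sigma_e.tolist(),
            "M": self.M,
            "M_i": self.M_i.tolist(),
            "kernel_names": self.kernel_names,
            "seed": self.seed,
        }


def true_variance_explained(
    sigma_c_list: list[np.ndarray], sigma_e: np.ndarray
) -> tuple[float, np.ndarray]:
    """Trace-ratio M implied by chosen component matrices (no truncation)."""
    num_i = np.sum([np.diag(s) for s in sigma_c_list], axis=0)
    denom_i = num_i + np.diag(sigma_e)
    return float(num_i.sum() / denom_i.sum()), num_i / denom_i


def simulate_behavior(
    kernels: list[SimilarityKernel] | list[np.ndarray],
    sigma_c_list: list[np.ndarray],
    sigma_e: np.ndarray,
    seed: int | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Exact matrix-normal draw from the variance-component model.

    Y = sum_k C_k + E with C_k = L_{F_k} U_k L_{c,k}^T (U_k i.i.d.
    standard normal) so Vec(C_k) ~ N(0, Sigma_c^k (x) F_k), and E drawn
    analogously with the identity kernel. Returns (Y, true M, true M_i)
    with the truths evaluated from the chosen component traces.
    """
    f_list = [k.F if isinstance(k, SimilarityKernel) else np.asarray(k, float) for k in kernels]
    if len(f_list) != len(sigma_c_list):
        raise ValueError("one Sigma_c per kernel required")
    n = f_list[0].shape[0]
    q = np.asarray(sigma_e).shape[0]
    for f in f_list:
        if f.shape != (n, n):
            raise ValueError("kernels must share one dimension")
    for s in sigma_c_list:
        if np.asarray(s).shape != (q, q):
            raise ValueError("Sigma matrices must match the measure count")

    rng = np.random.default_rng(seed)
    y = np.zeros((n, q))
    for f, sc in zip(f_list, sigma_c_list):
        l_f = _psd_sqrt(f, "kernel")
        l_c = _psd_sqrt(np.asarray(sc, float), "Sigma_c")
        y += l_f @ rng.standard_normal((n, q)) @ l_c.T
    l_e = _psd_sqrt(np.asarray(sigma_e, float), "Sigma_e")
    y += rng.standard_normal((n, q)) @ l_e.T
    m, m_i = true_variance_explained(
        [np.asarray(s, float) for s in sigma_c_list], np.asarray(sigma_e, float)
    )
    return y, m, m_i


def sample_similarity_kernel(
    n_subjects: int,
    seed: int | None = None,
    n_features: int = 400,
    shared_scale: float = 1.0,
    noise_scale: float = 1.0,
    n_factors: int = 8,
    factor_scale: float = 1.2,
) -> np.ndarray:
    """Draw a similarity kernel with FC-like structure, without time series.

    Each subject gets a feature vector = shared component +
    low-dimensional factor structure (decaying loadings) + individual
    noise; the kernel is the subjects' Pearson correlation matrix. The
    shared backbone raises the off-diagonal level and the factors make
    some subject pairs genuinely more alike than others, emulating
    empirical FC-similarity matrices at a fraction of the cost of
    simulating full cohorts. Useful for estimator-level studies where
    only (F, Y) matter.
    """
    rng = np.random.default_rng(seed)
    vecs = shared_scale * rng.standard_normal(n_features) \
        + noise_scale * rng.standard_normal((n_subjects, n_features))
    if n_factors > 0:
        load = rng.standard_normal((n_subjects, n_factors)) * (
            factor_scale / np.arange(1, n_factors + 1) ** 0.5
        )
        vecs += load @ rng.standard_normal((n_factors, n_features))
    f = np.corrcoef(vecs)
    np.fill_diagonal(f, 1.0)
    return (f + f.T) / 2.0


def default_network_sizes() -> dict[str, int]:
    # 8 networks (7 cortical + subcortex) over 40 ROIs, mirroring the
    # usual resting-state partition at desk scale
    return {
        "VIS": 6, "SM": 6, "D-Att": 5, "Sal": 5,
        "Lim": 4, "FP": 5, "DMN": 5, "Sub": 4,
    }


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults preserve the structure of a large single-site resting-state
    study at roughly 1/10 scale per axis: 120 subjects, 40 ROIs in 8
    networks, 2 runs of 600 frames, 24 behavioral measures (10
    task-performance, 10 self-reported, 4 unclassified). Task measures
    load preferentially on the dynamic-FC kernel; self-reported measures
    load equally on both kernels.
    """

    n_subjects: int = 120
    network_sizes: dict[str, int] = field(default_factory=default_network_sizes)
    subnetworks_per_network: int = 2
    n_runs: int = 2
    n_frames: int = 600
    burn_in: int = 200
    target_radius: float = 0.9
    n_ar_modes: int = 5
    ar_mode_scale: float = 1.25
    individual_scale: float = 0.05
    base_diag: float = 0.7
    base_within_scale: float = 0.25
    base_between_scale: float = 0.06
    innovation_scale: float = 1.0
    censor_fraction_target: float = 0.10
    n_task: int = 10
    n_self: int = 10
    n_unclassified: int = 4
    load_task_static: float = 0.0
    load_task_dynamic: float = 0.5
    load_self_static: float = 0.25
    load_self_dynamic: float = 0.25
    covariate_effect: float = 0.25
    regress_global: bool = True
    apply_censoring: bool = True
    seed: int = 0

    @property
    def n_roi(self) -> int:
        return sum(self.network_sizes.values())

    @property
    def n_measures(self) -> int:
        return self.n_task + self.n_self + self.n_unclassified

    def categories(self) -> list[str]:
        return (
            ["task"] * self.n_task
            + ["self"] * self.n_self
            + ["unclassified"] * self.n_unclassified
        )

    def measure_names(self) -> list[str]:
        names = [f"task_{i + 1:02d}" for i in range(self.n_task)]
        names += [f"self_{i + 1:02d}" for i in range(self.n_self)]
        names += [f"uncl_{i + 1:02d}" for i in range(self.n_unclassified)]
        return names


@dataclass
class Cohort:
    """In-memory cohort bundle: inputs to the pipeline plus ground truth."""

    config: CohortConfig
    parcellation: Parcellation
    runs: dict[str, list[RunTimeSeries]]       # subject id -> runs
    behavior: "object"                          # pandas DataFrame (subjects x measures)
    covariates: "object"                        # pandas DataFrame
    categories: list[str]
    ground_truth: GroundTruth
    kernels: list[SimilarityKernel] = field(default_factory=list)
    mean_r2: float = float("nan")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.runs.keys())


def _stage_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def build_cohort(config: CohortConfig | None = None, out_dir: str | Path | None = None) -> Cohort:
    """Generate a full synthetic cohort; optionally write the disk bundle.

    Stage 1 simulates per-subject AR time series and motion, runs the
    standard preprocessing (censoring, nuisance regression) and computes
    the static and dynamic whole-brain similarity kernels. Stage 2 draws
    the behavioral matrix exactly from the variance-component model
    conditional on those kernels, then adds covariate effects so the
    behavioral preparation step has real work to do. Fully reproducible
    from the config seed via named substreams.
    """
    import pandas as pd

    cfg = config or CohortConfig()
    if cfg.n_subjects <= 0:
        raise ValueError("cohort needs at least one subject")
    if cfg.n_measures <= 0:
        raise ValueError("cohort needs at least one behavioral measure")

    ss_base, ss_subj, ss_motion, ss_behav, ss_cov = _stage_seeds(cfg.seed, 5)
    parc = make_parcellation(
        cfg.n_roi, cfg.network_sizes, subnetworks_per_network=cfg.subnetworks_per_network
    )
    base_a = make_base_ar(
        parc,
        seed=ss_base.generate_state(1)[0] % (2**31),
        diag=cfg.base_diag,
        within_scale=cfg.base_within_scale,
        between_scale=cfg.base_between_scale,
        target_radius=cfg.target_radius,
    )
    innovation = cfg.innovation_scale * np.eye(cfg.n_roi)
    modes = make_ar_modes(
        parc,
        cfg.n_ar_modes,
        seed=ss_base.generate_state(2)[1] % (2**31),
        within_scale=cfg.base_within_scale,
        between_scale=cfg.base_between_scale,
    )

    subj_seeds = ss_subj.spawn(cfg.n_subjects)
    motion_seeds = ss_motion.spawn(cfg.n_subjects)
    runs: dict[str, list[RunTimeSeries]] = {}
    subject_a = []
    static_stack, dynamic_stack, r2s, mean_fd = [], [], [], []
    for s in range(cfg.n_subjects):
        sid = f"sub-{s + 1:03d}"
        s_children = subj_seeds[s].spawn(cfg.n_runs + 1)
        rng_s = np.random.default_rng(s_children[0].generate_state(1)[0] % (2**31))
        loadings = rng_s.standard_normal(cfg.n_ar_modes) if modes else np.zeros(0)
        subject_base = base_a + cfg.ar_mode_scale * sum(
            lam * m for lam, m in zip(loadings, modes)
        )
        a_s = sample_subject_ar(
            subject_base,
            cfg.individual_scale,
            cfg.target_radius,
            seed=int(rng_s.integers(2**31)),
        )
        subject_a.append(a_s)
        m_children = motion_seeds[s].spawn(cfg.n_runs)
        subj_runs = []
        for r in range(cfg.n_runs):
            fd, dvars = simulate_motion(
                cfg.n_frames,
                cfg.censor_fraction_target,
                seed=m_children[r].generate_state(1)[0] % (2**31),
            )
            run = simulate_run(
                a_s,
                innovation,
                cfg.n_frames,
                burn_in=cfg.burn_in,
                seed=s_children[r + 1].generate_state(1)[0] % (2**31),
                fd=fd,
                dvars=dvars,
                run_id=f"run-{r + 1}",
            )
            subj_runs.append(run)
        runs[sid] = subj_runs
        fc_s, fc_d, fd_bar = preprocess_subject(
            subj_runs,
            regress_global=cfg.regress_global,
            apply_censoring=cfg.apply_censoring,
        )
        static_stack.append(fc_s.matrix)
        dynamic_stack.append(fc_d.A)
        r2s.append(fc_d.r2)
        mean_fd.append(fd_bar)

    k_static = kernel_from_fc(np.stack(static_stack), "static")
    k_dynamic = kernel_from_fc(np.stack(dynamic_stack), "dynamic")

    # stage 2: behavior conditional on the empirical kernels
    cats = cfg.categories()
    load_s = np.array(
        [cfg.load_task_static] * cfg.n_task
        + [cfg.load_self_static] * cfg.n_self
        + [0.0] * cfg.n_unclassified
    )
    load_d = np.array(
        [cfg.load_task_dynamic] * cfg.n_task
        + [cfg.load_self_dynamic] * cfg.n_self
        + [0.0] * cfg.n_unclassified
    )
    if np.any(load_s + load_d > 1.0):
        raise ValueError("per-measure loadings exceed unit total variance")
    sigma_c_list = [np.diag(load_s), np.diag(load_d)]
    sigma_e = np.diag(1.0 - load_s - load_d)
    behav_seed = ss_behav.generate_state(1)[0] % (2**31)
    y_model, m_true, m_i_true = simulate_behavior(
        [k_static, k_dynamic], sigma_c_list, sigma_e, seed=behav_seed
    )

    # covariates and their (removable) effects on the raw measures
    rng_cov = np.random.default_rng(ss_cov.generate_state(1)[0] % (2**31))
    n = cfg.n_subjects
    covariates = pd.DataFrame(
        {
            "age": rng_cov.integers(22, 36, size=n),
            "gender": rng_cov.choice(["F", "M"], size=n),
            "race": rng_cov.choice(["g1", "g2", "g3"], size=n),
            "education": rng_cov.integers(11, 18, size=n),
            "mean_fd": np.asarray(mean_fd),
        },
        index=[f"sub-{i + 1:03d}" for i in range(n)],
    )
    from fct.behavior import encode_covariates

    x = encode_covariates(covariates)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    beta = cfg.covariate_effect * rng_cov.standard_normal((x.shape[1], cfg.n_measures))
    y_raw = y_model + x @ beta

    behavior = pd.DataFrame(y_raw, index=covariates.index, columns=cfg.measure_names())
    truth = GroundTruth(
        subject_A=subject_a,
        innovation_cov=innovation,
        sigma_c_list=sigma_c_list,
        sigma_e=sigma_e,
        M=m_true,
        M_i=m_i_true,
        kernel_names=["static", "dynamic"],
        seed=cfg.seed,
    )
    cohort = Cohort(
        config=cfg,
        parcellation=parc,
        runs=runs,
        behavior=behavior,
        covariates=covariates,
        categories=cats,
        ground_truth=truth,
        kernels=[k_static, k_dynamic],
        mean_r2=float(np.mean(r2s)),
    )
    if out_dir is not None:
        from fct.io import write_cohort

        write_cohort(cohort, out_dir)
    return cohort


def preprocess_subject(
    subj_runs: list[RunTimeSeries],
    regress_global: bool = True,
    apply_censoring: bool = True,
):
    """Censor, QC-filter, regress nuisance, and estimate both FC types.

    Returns (StaticFC, DynamicFC, mean FD over all frames of all runs).
    With ``apply_censoring=False`` the full time series are used (the
    all-kept mask), mirroring the uncensored control analysis.
    """
    from fct.timeseries import CensorMask

    pairs = []
    fds = []
    for run in subj_runs:
        fds.append(run.fd)
        if apply_censoring:
            mask = compute_censor_mask(run.fd, run.dvars)
            if not run_passes_qc(mask):
                continue
        else:
            mask = CensorMask(keep=np.ones(run.n_frames, dtype=bool))
        clean = regress_nuisance(run, mask, regress_global=regress_global)
        pairs.append((clean, mask))
    if not pairs:
        raise ValueError("no run passed quality control")
    return (
        static_fc(pairs),
        dynamic_fc(pairs),
        float(np.concatenate(fds).mean()),
    )


def config_to_jsonable(cfg: CohortConfig) -> dict:
    return asdict(cfg)


def config_from_dict(d: dict) -> CohortConfig:
    return CohortConfig(**d)
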