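"""Disk layout for cohort bundles, FC estimates, and kernels (plain text)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fct.parcellation import Parcellation
from fct.similarity import SimilarityKernel
from fct.synthdata import Cohort, CohortConfig, GroundTruth, config_to_jsonable, config_from_dict
from fct.timeseries import DynamicFC, RunTimeSeries, StaticFC


def _write_matrix(path: Path, mat: np.ndarray, columns) -> None:
    pd.DataFrame(mat, columns=columns).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "motion").mkdir(exist_ok=True)
    roi_ids = list(cohort.parcellation.roi_ids)
    for sid, runs in cohort.runs.items():
        for run in runs:
            _write_matrix(out / "timeseries" / f"{sid}_{run.run_id}.tsv", run.data, roi_ids)
            pd.DataFrame({"FD": run.fd, "DVARS": run.dvars}).to_csv(
                out / "motion" / f"{sid}_{run.run_id}.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
    cohort.parcellation.to_frame().to_csv(out / "parcellation.tsv", sep="\t", index=False)
    cohort.behavior.to_csv(out / "behavior.csv", index_label="subject", float_format="%.10g")
    cohort.covariates.to_csv(out / "covariates.csv", index_label="subject", float_format="%.10g")
    pd.DataFrame(
        {"measure": cohort.behavior.columns, "category": cohort.categories}
    ).to_csv(out / "categories.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(json.dumps(cohort.ground_truth.to_jsonable()))
    manifest = {"config": config_to_jsonable(cohort.config), "mean_r2": cohort.mean_r2}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_cohort(path: str | Path) -> Cohort:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    cfg = config_from_dict(manifest["config"])
    parc = Parcellation.from_frame(pd.read_csv(path / "parcellation.tsv", sep="\t"))
    behavior = pd.read_csv(path / "behavior.csv", index_col="subject")
    covariates = pd.read_csv(path / "covariates.csv", index_col="subject")
    categories = list(pd.read_csv(path / "categories.tsv", sep="\t")["category"])
    gt = json.loads((path / "ground_truth.json").read_text())
    truth = GroundTruth(
        subject_A=[np.asarray(a) for a in gt["subject_A"]],
        innovation_cov=np.asarray(gt["innovation_cov"]),
        sigma_c_list=[np.asarray(s) for s in gt["sigma_c_list"]],
        sigma_e=np.asarray(gt["sigma_e"]),
        M=gt["M"],
        M_i=np.asarray(gt["M_i"]),
        kernel_names=gt["kernel_names"],
        seed=gt["seed"],
    )
    runs: dict[str, list[RunTimeSeries]] = {}
    for sid in behavior.index:
        subj_runs = []
        for r in range(1, cfg.n_runs + 1):
            data = pd.read_csv(path / "timeseries" / f"{sid}_run-{r}.tsv", sep="\t").to_numpy()
            mot = pd.read_csv(path / "motion" / f"{sid}_run-{r}.tsv", sep="\t")
            subj_runs.append(
                RunTimeSeries(
                    data=data,
                    fd=mot["FD"].to_numpy(),
                    dvars=mot["DVARS"].to_numpy(),
                    run_id=f"run-{r}",
                )
            )
        runs[sid] = subj_runs
    return Cohort(
        config=cfg,
        parcellation=parc,
        runs=runs,
        behavior=behavior,
        covariates=covariates,
        categories=categories,
        ground_truth=truth,
        mean_r2=manifest.get("mean_r2", float("nan")),
    )


def write_fc(out_dir: str | Path, sid: str, fc_static: StaticFC, fc_dynamic: DynamicFC, roi_ids) -> None:
    out = Path(out_dir) / sid
    out.mkdir(parents=True, exist_ok=True)
    _write_matrix(out / "static_fc.tsv", fc_static.matrix, roi_ids)
    _write_matrix(out / "A.tsv", fc_dynamic.A, roi_ids)
    _write_matrix(out / "resid_cov.tsv", fc_dynamic.resid_cov, roi_ids)
    (out / "stats.json").write_text(
        json.dumps({"r2": fc_dynamic.r2, "n_pairs": fc_dynamic.n_pairs})
    )


def load_fc(fc_dir: str | Path, sid: str) -> tuple[StaticFC, DynamicFC]:
    d = Path(fc_dir) / sid
    stats = json.loads((d / "stats.json").read_text())
    return (
        StaticFC(matrix=pd.read_csv(d / "static_fc.tsv", sep="\t").to_numpy()),
        DynamicFC(
            A=pd.read_csv(d / "A.tsv", sep="\t").to_numpy(),
            resid_cov=pd.read_csv(d / "resid_cov.tsv", sep="\t").to_numpy(),
            r2=stats["r2"],
            n_pairs=stats["n_pairs"],
        ),
    )


def write_kernel(out_dir: str | Path, name: str, kernel: SimilarityKernel, subjects) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(kernel.F, index=subjects, columns=subjects).to_csv(
        out / f"K_{name}.tsv", sep="\t", float_format="%.10g"
    )
    (out / f"K_{name}.json").write_text(
        json.dumps({"mode": kernel.mode, "block": kernel.block, "p": kernel.p})
    )


def load_kernel(out_dir: str | Path, name: str) -> SimilarityKernel:
    out = Path(out_dir)
    f = pd.read_csv(out / f"K_{name}.tsv", sep="\t", index_col=0).to_numpy()
    meta = json.loads((out / f"K_{name}.json").read_text())
    return SimilarityKernel(F=f, mode=meta["mode"], block=meta["block"], p=meta["p"])
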