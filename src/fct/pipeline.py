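"""End-to-end orchestration: simulate -> preprocess -> FC -> kernels ->
variance components -> jackknife inference -> machine-readable report.

The report mirrors the analysis sequence of the study design: overall
static/dynamic/combined variance explained, the per-measure T ranking
with category contrasts and the interaction test, the network-block M
table, and the block-pair contribution decomposition with FDR flags.
All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fct.behavior import prepare_behavior
from fct.inference import (
    fdr_bh,
    jackknife_compare,
    jackknife_from_leaveouts,
    loo_variance_explained,
    rank_measures,
)
from fct.similarity import block_decomposition_kernels, kernel_from_fc
from fct.synthdata import Cohort, CohortConfig, build_cohort, config_to_jsonable, preprocess_subject
from fct.vcm import fit_vcm


def load_config(path: str | Path) -> CohortConfig:
    """Cohort/pipeline configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return CohortConfig(**raw)


def _jr_dict(jr) -> dict:
    return {"estimate": jr.estimate, "sd": jr.sd, "z": jr.z, "p": jr.p}


def compute_fc(cohort: Cohort):
    """Per-subject static and dynamic FC (stage shared by CLI and pipeline)."""
    cfg = cohort.config
    static_stack, dynamic_stack, r2s = [], [], []
    for sid in cohort.subject_ids:
        fc_s, fc_d, _ = preprocess_subject(
            cohort.runs[sid],
            regress_global=cfg.regress_global,
            apply_censoring=cfg.apply_censoring,
        )
        static_stack.append(fc_s.matrix)
        dynamic_stack.append(fc_d.A)
        r2s.append(fc_d.r2)
    return np.stack(static_stack), np.stack(dynamic_stack), np.asarray(r2s)


def run_all(
    config: CohortConfig | None = None,
    cohort: Cohort | None = None,
    out_dir: str | Path | None = None,
    measure_subset: list[str] | None = None,
    save_intermediates: bool = False,
) -> dict:
    """Run the full analysis and return the report dictionary.

    Either pass a ``CohortConfig`` (a cohort is synthesized) or a
    ``Cohort`` already built/loaded. ``measure_subset`` restricts the
    behavioral measures (the measure-count control analysis). When
    ``out_dir`` is given, ``report.json``, the flat tables, and a run
    manifest are written there.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if cohort is None:
        cohort = build_cohort(config or CohortConfig())
    cfg = cohort.config
    timings["cohort"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    static_stack, dynamic_stack, r2s = compute_fc(cohort)
    timings["fc"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    parc = cohort.parcellation
    k_static = kernel_from_fc(static_stack, "static")
    k_dynamic = kernel_from_fc(dynamic_stack, "dynamic")
    timings["kernels"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    y_df = prepare_behavior(cohort.behavior, cohort.covariates)
    categories = list(cohort.categories)
    if measure_subset is not None:
        keep = [m for m in y_df.columns if m in set(measure_subset)]
        categories = [c for m, c in zip(y_df.columns, categories) if m in set(measure_subset)]
        y_df = y_df[keep]
    y = y_df.to_numpy()
    measures = list(y_df.columns)
    timings["behavior"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fits = {
        "static": fit_vcm(y, [k_static], measures=measures),
        "dynamic": fit_vcm(y, [k_dynamic], measures=measures),
        "combined": fit_vcm(y, [k_static, k_dynamic], measures=measures),
    }
    timings["fit"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    models = {
        "static": [k_static],
        "dynamic": [k_dynamic],
        "combined": [k_static, k_dynamic],
    }
    m_sd = {
        name: jackknife_from_leaveouts(loo_variance_explained(y, ks).M).sd
        for name, ks in models.items()
    }
    overall = {
        "dynamic_vs_static": _jr_dict(
            jackknife_compare(y, [k_dynamic], [k_static], "overall_m")
        ),
        "combined_vs_static": _jr_dict(
            jackknife_compare(y, models["combined"], [k_static], "overall_m")
        ),
        "combined_vs_dynamic": _jr_dict(
            jackknife_compare(y, models["combined"], [k_dynamic], "overall_m")
        ),
    }
    per_measure = jackknife_compare(y, [k_dynamic], [k_static], "per_measure")
    ranking = rank_measures(per_measure, measures, categories)
    ranking["p_fdr_significant"] = fdr_bh(ranking["p"].to_numpy())
    idx = {m: j for j, m in enumerate(measures)}
    ranking["m_static"] = [fits["static"].M_i[idx[m]] for m in ranking["measure"]]
    ranking["m_dynamic"] = [fits["dynamic"].M_i[idx[m]] for m in ranking["measure"]]
    ranking["m_combined"] = [fits["combined"].M_i[idx[m]] for m in ranking["measure"]]

    cat_res = jackknife_compare(y, [k_dynamic], [k_static], "category_mean", categories)
    interaction = jackknife_compare(y, [k_dynamic], [k_static], "interaction", categories)
    timings["inference"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    blocks_table = network_block_table(static_stack, dynamic_stack, parc, y)
    contributions = block_contributions(
        dynamic_stack, parc, y, categories, level="network"
    )
    timings["blocks"] = time.perf_counter() - t0

    report = {
        "config": config_to_jsonable(cfg),
        "n_subjects": len(cohort.subject_ids),
        "n_measures": len(measures),
        "ar_r2_mean": float(r2s.mean()),
        "ar_r2_sd": float(r2s.std(ddof=1)),
        "true_m": cohort.ground_truth.M if cohort.ground_truth is not None else None,
        "m": {name: fit.M for name, fit in fits.items()},
        "m_sd": m_sd,
        "overall": overall,
        "categories": {
            "task": _jr_dict(cat_res["task"]),
            "self": _jr_dict(cat_res["self"]),
            "interaction": _jr_dict(interaction),
        },
        "ranking": ranking.to_dict(orient="records"),
        "blocks": blocks_table.to_dict(orient="records"),
        "contributions": contributions.to_dict(orient="records"),
    }
    if out_dir is not None:
        out = Path(out_dir)
        (out / "report").mkdir(parents=True, exist_ok=True)
        (out / "report" / "report.json").write_text(json.dumps(report, indent=1, default=float))
        report_tables(report, out / "report")
        manifest = {
            "config": config_to_jsonable(cfg),
            "timings_s": timings,
            "version": _version(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        if save_intermediates:
            from fct.io import write_cohort, write_kernel

            write_cohort(cohort, out / "cohort")
            write_kernel(out / "kernels", "static", k_static, cohort.subject_ids)
            write_kernel(out / "kernels", "dynamic", k_dynamic, cohort.subject_ids)
    return report


def _version() -> str:
    from fct import __version__

    return __version__


def network_block_table(
    static_stack: np.ndarray,
    dynamic_stack: np.ndarray,
    parc,
    y: np.ndarray,
) -> pd.DataFrame:
    """Variance explained by block-restricted FC, per network pair.

    For every unordered network pair (within pairs included) the static
    and dynamic FC entries of that block are vectorized, correlated into
    a kernel, and a single-kernel variance-component model is fit.
    """
    order = parc.label_order("network")
    rows = []
    for ai, a in enumerate(order):
        for b in order[ai:]:
            block = ("within", a) if a == b else ("between", a, b)
            row = {"net_a": a, "net_b": b, "kind": "within" if a == b else "between"}
            for mode, stack in (("static", static_stack), ("dynamic", dynamic_stack)):
                k = kernel_from_fc(stack, mode, parc, block)
                row[f"m_{mode}"] = fit_vcm(y, [k]).M
            rows.append(row)
    return pd.DataFrame(rows)


def block_contributions(
    dynamic_stack: np.ndarray,
    parc,
    y: np.ndarray,
    categories: list[str],
    level: str = "network",
    q_fdr: float = 0.05,
) -> pd.DataFrame:
    """Block-pair contributions to the dynamic-FC association with task scores.

    The entry-standardized whole-matrix kernel is decomposed additively
    over (sub)network block pairs, F_std = sum_b w_b F_b, and a
    multi-kernel variance-component model with the weighted block
    kernels is fit on the task-performance measures. Each block's
    reported contribution is its truncated explained-trace share; the
    jackknife test uses the *raw* (untruncated) explained trace of the
    block, whose null distribution stays centered at zero and which
    avoids the weakly identified total-variance denominator, and the
    two-tailed p-values are flagged by BH-FDR across blocks.
    """
    task_cols = [j for j, c in enumerate(categories) if c == "task"]
    if not task_cols:
        raise ValueError("no task-performance measures for the contribution analysis")
    y_task = np.asarray(y, dtype=float)[:, task_cols]

    blocks, _ = block_decomposition_kernels(dynamic_stack, parc, "dynamic", level)
    kernels = [b.weight * b.F for b in blocks]
    fit = fit_vcm(y_task, kernels)
    # contribution of block b to per-subject variance scales with the
    # mean diagonal of its (weighted) kernel
    diag_means = np.array([np.mean(np.diag(k)) for k in kernels])
    contrib = np.clip([np.trace(s) for s in fit.sigma_c_list], 0, None) * diag_means
    total = contrib.sum()
    shares = contrib / total if total > 0 else np.zeros_like(contrib)

    loo = loo_variance_explained(y_task, kernels, truncate=False)
    results = jackknife_from_leaveouts(loo.trace_c * diag_means)
    pvals = np.array([r.p for r in results])
    rejected = fdr_bh(pvals, q=q_fdr)
    return pd.DataFrame(
        {
            "net_a": [b.pair[0] for b in blocks],
            "net_b": [b.pair[1] for b in blocks],
            "weight": [b.weight for b in blocks],
            "share": shares,
            "z": [r.z for r in results],
            "p": pvals,
            "fdr_significant": rejected,
        }
    )


def report_tables(report: dict, out_dir: str | Path) -> list[Path]:
    """Flat TSV tables matching the report's figure-style content."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    overall = pd.DataFrame(
        {
            "model": list(report["m"].keys()),
            "m": list(report["m"].values()),
            "sd": [report["m_sd"][k] for k in report["m"]],
        }
    )
    written.append(out / "overall_m.tsv")
    overall.to_csv(written[-1], sep="\t", index=False)

    ranking = pd.DataFrame(report["ranking"])
    written.append(out / "ranking.tsv")
    ranking.to_csv(written[-1], sep="\t", index=False)

    blocks = pd.DataFrame(report["blocks"])
    written.append(out / "block_table.tsv")
    blocks.to_csv(written[-1], sep="\t", index=False)

    contrib = pd.DataFrame(report["contributions"])
    edges = contrib[contrib["fdr_significant"]]
    written.append(out / "contribution_edges.tsv")
    edges.to_csv(written[-1], sep="\t", index=False)

    contrasts = pd.DataFrame(report["categories"]).T
    written.append(out / "category_contrasts.tsv")
    contrasts.to_csv(written[-1], sep="\t", index_label="contrast")
    return written
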