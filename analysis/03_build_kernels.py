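"""Build the whole-brain static and dynamic FC-similarity kernels.

Each subject's static FC (upper triangle) and dynamic FC (all entries
of the AR coefficient matrix) are vectorized and correlated between
subjects. Writes K_static / K_dynamic under scratch/kernels/ and a
kernel summary under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fct.io import load_cohort, load_fc, write_kernel
from fct.similarity import kernel_from_fc

ROOT = Path(__file__).resolve().parent.parent

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohort")
    ap.add_argument("--fc", type=Path, default=ROOT / "scratch" / "fc")
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "kernels")
    args = ap.parse_args()

    cohort = load_cohort(args.cohort)
    statics, dynamics = [], []
    for sid in cohort.subject_ids:
        fc_s, fc_d = load_fc(args.fc, sid)
        statics.append(fc_s.matrix)
        dynamics.append(fc_d.A)
    rows = []
    for name, stack, mode in (("static", statics, "static"), ("dynamic", dynamics, "dynamic")):
        k = kernel_from_fc(np.stack(stack), mode)
        write_kernel(args.out, name, k, cohort.subject_ids)
        tri = k.F[np.triu_indices(k.n_subjects, 1)]
        rows.append({"kernel": name, "p": k.p, "offdiag_mean": tri.mean(),
                     "offdiag_sd": tri.std()})
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "kernel_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
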