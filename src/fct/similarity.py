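"""Inter-subject FC similarity kernels.

A kernel F is a subjects x subjects matrix whose (i, j) entry is the
Pearson correlation between the two subjects' vectorized FC patterns
(whole-brain or restricted to a network block). Static FC matrices are
symmetric so only the strict upper triangle carries information
(R(R-1)/2 free entries); dynamic AR coefficient matrices are
non-symmetric so all R^2 entries are used, diagonal included.

For the additive block-pair contribution analysis a second kernel family
is provided: each FC entry is standardized across subjects and the Gram
kernel of each block pair b is F_b = Z_b Z_b^T / P_b with weight
w_b = P_b / P, which guarantees sum_b w_b F_b equals the
entry-standardized whole-matrix kernel exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from fct.parcellation import Parcellation

logger = logging.getLogger(__name__)

Block = tuple  # ("whole",) | ("within", net) | ("between", netA, netB)


@dataclass
class SimilarityKernel:
    """Subjects x subjects FC-similarity matrix with provenance."""

    F: np.ndarray
    mode: str = "static"            # "static" | "dynamic"
    block: str = "whole"
    p: int = 0                      # vector length behind each correlation

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2 or self.F.shape[0] != self.F.shape[1]:
            raise ValueError("kernel must be square")

    @property
    def n_subjects(self) -> int:
        return self.F.shape[0]


def _block_indices(parcellation: Parcellation, block: Block, level: str = "network"):
    kind = block[0]
    if kind == "whole":
        idx = np.arange(parcellation.n_roi)
        return idx, idx
    if kind == "within":
        idx = parcellation.indices(block[1], level)
        return idx, idx
    if kind == "between":
        return (
            parcellation.indices(block[1], level),
            parcellation.indices(block[2], level),
        )
    raise ValueError(f"unknown block spec: {block!r}")


def vectorize_fc(
    fc: np.ndarray,
    mode: str,
    parcellation: Parcellation | None = None,
    block: Block = ("whole",),
    level: str = "network",
) -> np.ndarray:
    """Vectorize an FC matrix, whole-brain or block-restricted.

    static/whole: strict upper triangle, length R(R-1)/2.
    dynamic/whole: all R^2 entries, diagonal included.
    static/within(net): strict upper triangle of the diagonal block.
    dynamic/within(net): all entries of the square block.
    static/between(a, b): the rectangular off-diagonal block.
    dynamic/between(a, b): both directed blocks a->b and b->a concatenated
    (the asymmetry of the AR matrix is preserved).
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError("fc must be square")
    if mode not in ("static", "dynamic"):
        raise ValueError(f"unknown mode: {mode!r}")
    if block[0] != "whole":
        if parcellation is None:
            raise ValueError("block restriction requires a parcellation")
        if parcellation.n_roi != fc.shape[0]:
            raise ValueError("fc dimension does not match parcellation")

    if block[0] == "between":
        rows, cols = _block_indices(parcellation, block, level)
        ab = fc[np.ix_(rows, cols)].ravel()
        if mode == "static":
            return ab
        ba = fc[np.ix_(cols, rows)].ravel()
        return np.concatenate([ab, ba])

    if block[0] == "whole":
        sub = fc
    else:
        idx, _ = _block_indices(parcellation, block, level)
        sub = fc[np.ix_(idx, idx)]
    if sub.size == 0:
        raise ValueError(f"empty block: {block!r}")
    if mode == "dynamic":
        return sub.ravel()
    iu = np.triu_indices(sub.shape[0], k=1)
    return sub[iu]


def build_kernel(
    vectors: np.ndarray,
    mode: str = "static",
    block: str = "whole",
) -> SimilarityKernel:
    """Pearson-correlation kernel from one FC vector per subject."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2:
        raise ValueError("vectors must be (subjects, P)")
    n, p = vectors.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.any(vectors.std(axis=1) == 0):
        raise ValueError("constant FC vector: correlation undefined")
    f = np.corrcoef(vectors)
    f = (f + f.T) / 2.0
    np.fill_diagonal(f, 1.0)
    return SimilarityKernel(F=f, mode=mode, block=block, p=p)


def kernel_from_fc(
    fc_stack: np.ndarray,
    mode: str,
    parcellation: Parcellation | None = None,
    block: Block = ("whole",),
    level: str = "network",
) -> SimilarityKernel:
    """Convenience: vectorize a (subjects, R, R) FC stack and correlate."""
    vecs = np.stack(
        [vectorize_fc(fc, mode, parcellation, block, level) for fc in fc_stack]
    )
    name = "whole" if block[0] == "whole" else "-".join(map(str, block))
    return build_kernel(vecs, mode=mode, block=name)


@dataclass
class BlockKernel:
    """One additive component of the entry-standardized kernel."""

    pair: tuple[str, str]       # unordered (sub)network pair
    F: np.ndarray
    weight: float
    p: int


def block_decomposition_kernels(
    fc_stack: np.ndarray,
    parcellation: Parcellation,
    mode: str,
    level: str = "network",
) -> tuple[list[BlockKernel], np.ndarray]:
    """Additive block-pair decomposition of the whole-matrix kernel.

    Every vectorized FC entry is standardized across subjects (mean 0,
    variance 1); entries constant across subjects are excluded (their
    count is logged). Each entry belongs to exactly one unordered
    (sub)network pair; the pair's Gram kernel F_b = Z_b Z_b^T / P_b with
    weight w_b = P_b / P satisfies sum_b w_b F_b = F_std exactly, where
    F_std is the standardized whole-matrix Gram kernel (second return).
    """
    fc_stack = np.asarray(fc_stack, dtype=float)
    if fc_stack.ndim != 3 or fc_stack.shape[0] < 2:
        raise ValueError("need a (subjects>=2, R, R) FC stack")
    r = fc_stack.shape[1]
    if parcellation.n_roi != r:
        raise ValueError("fc dimension does not match parcellation")

    labels = np.asarray(parcellation.labels(level))
    if mode == "dynamic":
        rows, cols = np.meshgrid(np.arange(r), np.arange(r), indexing="ij")
        rows, cols = rows.ravel(), cols.ravel()
        vecs = fc_stack.reshape(fc_stack.shape[0], -1)
    elif mode == "static":
        rows, cols = np.triu_indices(r, k=1)
        vecs = fc_stack[:, rows, cols]
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    sd = vecs.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("block decomposition: dropped %d constant FC entries", n_dropped)
    vecs, rows, cols = vecs[:, keep], rows[keep], cols[keep]
    z = (vecs - vecs.mean(axis=0)) / vecs.std(axis=0, ddof=1)
    p_total = z.shape[1]

    # unordered pair id per entry (canonicalized by parcellation label
    # order); within-pairs have a == b
    order = parcellation.label_order(level)
    rank = {lab: i for i, lab in enumerate(order)}

    def canon(a: str, b: str) -> tuple[str, str]:
        return (a, b) if rank[a] <= rank[b] else (b, a)

    pair_of = [canon(labels[i], labels[j]) for i, j in zip(rows, cols)]
    pairs = [
        (a, b)
        for ai, a in enumerate(order)
        for b in order[ai:]
    ]
    blocks: list[BlockKernel] = []
    pair_arr = np.array([f"{a}|{b}" for a, b in pair_of])
    for a, b in pairs:
        sel = pair_arr == f"{a}|{b}"
        p_b = int(sel.sum())
        if p_b == 0:
            continue
        zb = z[:, sel]
        blocks.append(
            BlockKernel(pair=(a, b), F=zb @ zb.T / p_b, weight=p_b / p_total, p=p_b)
        )
    f_std = z @ z.T / p_total
    return blocks, f_std
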