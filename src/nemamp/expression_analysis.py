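"""Life-stage expression calls and heatmap matrices.

A gene is called expressed when any life stage reaches the TPM threshold
(default >= 2 TPM, inclusive).  For heatmaps, TPM values are transformed
as log2(TPM + 1) and converted to per-row Z scores (sample sd, n-1);
rows are ordered by agglomerative average-linkage clustering on Euclidean
distances between Z rows, with a deterministic lowest-index tie-break.
Only the linkage tree and leaf order are produced; rendering is left to
the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import ExpressionMatrix

__all__ = [
    "ExpressionSummary",
    "HeatmapResult",
    "call_expressed",
    "heatmap_matrix",
    "summarize_expression",
    "TPM_EXPRESSION_THRESHOLD",
]

#: Expression call cut-off in Transcripts Per Million (inclusive).
TPM_EXPRESSION_THRESHOLD = 2.0


@dataclass(frozen=True)
class ExpressionSummary:
    """Expressed fraction of AMP candidate genes for one species."""

    species: str
    n_amp_genes: int
    n_expressed: int

    @property
    def fraction_expressed(self) -> float:
        return self.n_expressed / self.n_amp_genes


@dataclass
class HeatmapResult:
    """Row-standardised matrix with clustering order.

    ``z`` rows have mean 0 and sd 1 except for constant input rows, which
    are set to all-zero and flagged; ``row_order`` is the dendrogram leaf
    permutation; ``linkage`` lists merge steps (a, b, height, size) with
    cluster indices following the usual convention (leaves first).
    """

    z: np.ndarray
    row_order: list[int]
    linkage: list[tuple[int, int, float, int]]
    constant_rows: list[bool]


def call_expressed(
    mat: ExpressionMatrix, threshold: float = TPM_EXPRESSION_THRESHOLD
) -> dict[str, bool]:
    """Per-gene expression flags: max TPM over stages >= threshold."""
    flags = mat.tpm.max(axis=1) >= threshold
    return dict(zip(mat.gene_ids, (bool(f) for f in flags)))


def _average_linkage(z: np.ndarray) -> tuple[list[tuple[int, int, float, int]], list[int]]:
    """Agglomerative average-linkage on Euclidean distances.

    Ties merge the lowest-index cluster pair (indices in creation order:
    leaves 0..n-1, then merged clusters n, n+1, ...), making the leaf
    order fully deterministic.
    """
    n = z.shape[0]
    # distances between active clusters, keyed by creation index
    active: dict[int, np.ndarray | None] = {i: None for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    sizes = {i: 1 for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(np.linalg.norm(z[i] - z[j]))
    linkage: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best_pair, best_d = None, np.inf
        for pair in sorted(dist):
            d = dist[pair]
            if d < best_d - 1e-12:
                best_pair, best_d = pair, d
        a, b = best_pair
        na, nb = sizes[a], sizes[b]
        new = next_id
        next_id += 1
        sizes[new] = na + nb
        members[new] = members[a] + members[b]
        linkage.append((a, b, best_d, na + nb))
        del active[a], active[b]
        new_dist = {}
        for k in active:
            da = dist[(min(a, k), max(a, k))]
            db = dist[(min(b, k), max(b, k))]
            new_dist[(k, new)] = (na * da + nb * db) / (na + nb)
        dist = {
            (i, j): d
            for (i, j), d in dist.items()
            if i not in (a, b) and j not in (a, b)
        }
        dist.update(new_dist)
        active[new] = None
    root = next(iter(active))
    return linkage, members[root]


def heatmap_matrix(mat: ExpressionMatrix) -> HeatmapResult:
    """log2(TPM+1) -> per-row Z -> average-linkage row clustering."""
    if len(mat.gene_ids) < 2 or len(mat.stage_ids) < 2:
        raise ValueError("heatmap_matrix: need >= 2 genes and >= 2 stages")
    x = np.log2(mat.tpm + 1.0)
    means = x.mean(axis=1, keepdims=True)
    sds = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sds[:, 0] < 1e-12)
    safe_sds = np.where(sds < 1e-12, 1.0, sds)
    z = (x - means) / safe_sds
    z[constant] = 0.0
    linkage, row_order = _average_linkage(z)
    return HeatmapResult(
        z=z,
        row_order=row_order,
        linkage=linkage,
        constant_rows=[bool(c) for c in constant],
    )


def summarize_expression(
    matrices: Mapping[str, ExpressionMatrix],
    candidate_ids: Mapping[str, Sequence[str]],
    threshold: float = TPM_EXPRESSION_THRESHOLD,
) -> tuple[list[ExpressionSummary], float]:
    """Per-species expressed fractions of AMP candidates, plus the pooled
    fraction over the whole corpus.

    Candidate ids missing from a species' TPM table are counted as
    unexpressed with a warning; species with zero AMP candidates are
    excluded with a note.
    """
    import logging

    logger = logging.getLogger("nemamp")
    summaries: list[ExpressionSummary] = []
    pooled_n, pooled_expr = 0, 0
    for species in sorted(candidate_ids):
        ids = list(candidate_ids[species])
        if not ids:
            logger.info("species %s has zero AMP candidates; excluded", species)
            continue
        mat = matrices.get(species)
        flags = call_expressed(mat, threshold) if mat is not None else {}
        n_expr = 0
        for gid in ids:
            if gid not in flags:
                logger.warning(
                    "candidate %s missing from %s TPM table; counted unexpressed",
                    gid, species,
                )
            elif flags[gid]:
                n_expr += 1
        summaries.append(
            ExpressionSummary(species=species, n_amp_genes=len(ids), n_expressed=n_expr)
        )
        pooled_n += len(ids)
        pooled_expr += n_expr
    pooled = pooled_expr / pooled_n if pooled_n else float("nan")
    return summaries, pooled
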