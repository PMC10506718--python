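"""Repertoire statistics: per-genome tallies, relative abundance,
lifestyle/clade aggregation, and the nonparametric tests used to compare
them.

Relative abundance is the percentage of AMP candidate genes relative to
the genome's total protein-coding gene (PCG) count.  Group comparisons use
a Lilliefors-corrected Kolmogorov–Smirnov normality check and the
Kruskal–Wallis test with Dunn's multiple-comparison z statistics
(Bonferroni-adjusted by default; configurable to none or Sidak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import AMP_GROUPS, SpeciesMeta

__all__ = [
    "GenomeProfile",
    "GroupSummary",
    "tally",
    "summarize",
    "ks_normality",
    "kruskal_dunn",
    "group_shares",
]


@dataclass(frozen=True)
class GenomeProfile:
    """Per-genome candidate counts and relative abundance."""

    genome_id: str
    counts: tuple[int, ...]  # one per AMP group, in AMP_GROUPS order
    pcg_count: int

    @property
    def total_amp(self) -> int:
        return sum(self.counts)

    @property
    def rel_abundance(self) -> float:
        """Percentage of AMP genes relative to protein-coding genes."""
        return 100.0 * self.total_amp / self.pcg_count


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SEM of repertoire size for one lifestyle or clade."""

    label: str
    n_genomes: int
    mean_amp: float
    sem_amp: float
    mean_rel_abundance: float
    sem_rel_abundance: float
    single_genome: bool = False  # SEM reported as 0 with this flag when n=1


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def tally(
    candidates: Sequence[object], meta: Sequence[SpeciesMeta]
) -> list[GenomeProfile]:
    """Per-genome candidate counts (complete and incomplete alike).

    Every genome in *meta* appears, with zeros when it has no candidates;
    a candidate in an unknown genome is an error.  Candidates may be
    ``AMPCandidate`` objects or anything exposing ``group`` and a record
    (or row) with ``genome_id``.
    """
    known = {m.genome_id for m in meta}
    counts: dict[str, list[int]] = {m.genome_id: [0] * len(AMP_GROUPS) for m in meta}
    gi = {g: i for i, g in enumerate(AMP_GROUPS)}
    for cand in candidates:
        genome = getattr(getattr(cand, "record", cand), "genome_id")
        group = cand.group
        if genome not in known:
            raise ValueError(f"candidate in unknown genome {genome!r}")
        counts[genome][gi[group]] += 1
    return [
        GenomeProfile(
            genome_id=m.genome_id,
            counts=tuple(counts[m.genome_id]),
            pcg_count=m.pcg_count,
        )
        for m in meta
    ]


def summarize(
    profiles: Sequence[GenomeProfile],
    meta: Sequence[SpeciesMeta],
    grouping: str = "lifestyle",
) -> list[GroupSummary]:
    """Mean +/- SEM of repertoire size per lifestyle or clade.

    Single-genome groups report SEM 0 with an explicit flag rather than
    being dropped.
    """
    if grouping not in ("lifestyle", "clade"):
        raise ValueError("grouping must be 'lifestyle' or 'clade'")
    label_of = {m.genome_id: getattr(m, grouping) for m in meta}
    groups: dict[str, list[GenomeProfile]] = {}
    for p in profiles:
        groups.setdefault(label_of[p.genome_id], []).append(p)
    out = []
    for label in sorted(groups):
        members = groups[label]
        totals = np.array([p.total_amp for p in members], dtype=float)
        rels = np.array([p.rel_abundance for p in members], dtype=float)
        out.append(
            GroupSummary(
                label=label,
                n_genomes=len(members),
                mean_amp=float(totals.mean()),
                sem_amp=_sem(totals),
                mean_rel_abundance=float(rels.mean()),
                sem_rel_abundance=_sem(rels),
                single_genome=len(members) == 1,
            )
        )
    return out


def ks_normality(
    values: Sequence[float],
    rng: np.random.Generator | None = None,
    n_mc: int = 10_000,
) -> float:
    """Lilliefors-corrected one-sample KS test against a fitted normal.

    The KS statistic is computed against N(mean, sd) with both parameters
    estimated from the data, so the classical KS null distribution does
    not apply; the p-value is obtained by Monte Carlo (*n_mc* simulated
    samples of the same size, re-estimating the parameters each time).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("ks_normality: need n >= 5")
    sd = x.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("ks_normality: zero variance")
    rng = rng if rng is not None else np.random.default_rng(0)
    n = len(x)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n

    def lilliefors_stat(samples: np.ndarray) -> np.ndarray:
        """Row-wise KS statistic against the row-fitted normal."""
        m = samples.mean(axis=1, keepdims=True)
        s = samples.std(ddof=1, axis=1, keepdims=True)
        z = np.sort((samples - m) / s, axis=1)
        cdf = stats.norm.cdf(z)
        return np.maximum(ecdf_hi - cdf, cdf - ecdf_lo).max(axis=1)

    d_obs = float(lilliefors_stat(x[None, :])[0])
    d_null = lilliefors_stat(rng.standard_normal((n_mc, n)))
    return float((np.sum(d_null >= d_obs) + 1) / (n_mc + 1))


def kruskal_dunn(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjustment: str = "bonferroni",
) -> dict:
    """Kruskal–Wallis H (tie-corrected) with Dunn's pairwise z tests.

    Returns ``{"H", "p_overall", "df", "pairwise"}`` where pairwise maps
    (label_i, label_j) to the adjusted p-value.  ``adjustment`` is
    'bonferroni' (default), 'sidak' or 'none'.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("kruskal_dunn: need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise ValueError("kruskal_dunn: each group needs n >= 2")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ValueError("kruskal_dunn: all values identical")
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]

    H, p_overall = stats.kruskal(*arrays)

    # Dunn: z on mean ranks with tie correction
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    n_pairs = k * (k - 1) // 2
    pairwise: dict[tuple[str, str], float] = {}
    for i, j in combinations(range(k), 2):
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        if adjustment == "bonferroni":
            p = min(1.0, p * n_pairs)
        elif adjustment == "sidak":
            p = 1.0 - (1.0 - p) ** n_pairs
        elif adjustment != "none":
            raise ValueError(f"unknown adjustment {adjustment!r}")
        pairwise[(labels[i], labels[j])] = float(p)
    return {
        "H": float(H),
        "p_overall": float(p_overall),
        "df": k - 1,
        "adjustment": adjustment,
        "pairwise": pairwise,
    }


def group_shares(counts: Sequence[int]) -> dict:
    """Percentage share of each AMP group in the phylum-wide totals.

    ``counts`` follows :data:`AMP_GROUPS` order; shares are rounded to two
    decimals, with the grand total included.
    """
    if len(counts) != len(AMP_GROUPS):
        raise ValueError(f"need {len(AMP_GROUPS)} counts in AMP_GROUPS order")
    total = int(sum(counts))
    if total < 1:
        raise ValueError("group_shares: all counts are zero")
    return {
        "total": total,
        "shares": {
            g: round(100.0 * c / total, 2) for g, c in zip(AMP_GROUPS, counts)
        },
    }
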