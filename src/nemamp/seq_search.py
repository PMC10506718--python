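"""Similarity engines: profile-model scoring, local pairwise alignment,
E-value calibration, iterative query expansion and the GRSP reciprocal check.

The in-repo engines are the defaults so the whole pipeline runs at desk
scale without external binaries; users with HMMER/BLAST installed can feed
their tabular output through :func:`read_hits_tsv` instead (same
:class:`SearchHit` schema).

Scores are in bits throughout.  E-values follow the classical extreme-value
model ``E(s) = K * db_size * exp(-lambda * s)`` with (lambda, K) fitted by
the method of moments on scores of random decoy sequences drawn from the
background composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import AMINO_ACIDS, ProteinRecord, SeedSet, read_tsv

__all__ = [
    "ProfileModel",
    "SearchHit",
    "EvalueModel",
    "build_profile",
    "score_profile",
    "score_profile_full",
    "calibrate_evalue",
    "calibrate_pairwise",
    "align_local",
    "iterative_expand",
    "reciprocal_top5",
    "search_profile",
    "shuffle_sequence",
    "read_hits_tsv",
]

_EULER_GAMMA = 0.5772156649015329

#: Robinson & Robinson amino-acid background frequencies.
BACKGROUND_FREQS = {
    "A": 0.0781, "R": 0.0512, "N": 0.0449, "D": 0.0536, "C": 0.0192,
    "Q": 0.0426, "E": 0.0624, "G": 0.0737, "H": 0.0219, "I": 0.0514,
    "L": 0.0901, "K": 0.0574, "M": 0.0225, "F": 0.0386, "P": 0.0520,
    "S": 0.0712, "T": 0.0584, "W": 0.0132, "Y": 0.0321, "V": 0.0644,
}

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_X_INDEX = len(AMINO_ACIDS)
_X_EMISSION_BITS = -1.0  # 'X' never rewards a match state

# Fixed transition scheme for the lightweight profile model (bits).
INSERT_SCORE = -2.0
DELETE_SCORE = -2.5

MATCH_GAP_MAX_FRACTION = 0.5
# one pseudo-observation per column, distributed as the background — a
# flat +1 per residue would hand rare residues (W, C) spurious log-odds
# with small seed sets
PSEUDOCOUNT_MASS = 1.0


def encode_sequence(seq: str) -> np.ndarray:
    return np.fromiter(
        (_AA_INDEX.get(aa, _X_INDEX) for aa in seq), dtype=np.int64, count=len(seq)
    )


# ---------------------------------------------------------------------------
# Profile model
# ---------------------------------------------------------------------------

@dataclass
class ProfileModel:
    """Position-specific log-odds profile built from a seed alignment.

    ``emissions`` has shape (M, 21): per-match-state log-odds in bits over
    the 20 amino acids plus a fixed penalty column for 'X'.
    """

    group: str
    emissions: np.ndarray
    match_columns: tuple[int, ...]
    subgroup: str | None = None
    insert_score: float = INSERT_SCORE
    delete_score: float = DELETE_SCORE
    background: dict[str, float] = field(default_factory=lambda: dict(BACKGROUND_FREQS))

    @property
    def n_states(self) -> int:
        return self.emissions.shape[0]


@dataclass(frozen=True)
class SearchHit:
    """One similarity hit (internal coordinates 0-based half-open)."""

    query_ref: str
    target_id: str
    bits: float
    evalue: float
    tstart: int
    tend: int
    coverage: float = float("nan")  # fraction of profile/query length aligned

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("SearchHit: evalue must be > 0")
        if self.tstart < 0 or self.tend < self.tstart:
            raise ValueError("SearchHit: invalid target interval")


def build_profile(seed: SeedSet) -> ProfileModel:
    """Construct a profile from a seed alignment.

    Match states are the alignment columns with gap fraction below 0.5;
    emissions are observed counts plus one background-distributed
    pseudo-observation, expressed as log-odds (bits) against the
    background frequencies.
    """
    if len(seed.sequences) < 2:
        raise ValueError("build_profile: need at least 2 aligned seed sequences")
    rows = seed.alignment
    n_rows = len(rows)
    n_cols = seed.n_columns
    bg = np.array([BACKGROUND_FREQS[aa] for aa in AMINO_ACIDS])
    match_cols: list[int] = []
    emission_rows: list[np.ndarray] = []
    for c in range(n_cols):
        column = [row[c] for row in rows]
        if column.count("-") / n_rows >= MATCH_GAP_MAX_FRACTION:
            continue
        counts = PSEUDOCOUNT_MASS * bg.copy()
        for aa in column:
            if aa in _AA_INDEX:
                counts[_AA_INDEX[aa]] += 1
        probs = counts / counts.sum()
        emission_rows.append(np.log2(probs / bg))
        match_cols.append(c)
    if len(match_cols) < 5:
        raise ValueError(
            f"build_profile: only {len(match_cols)} match states (need >= 5)"
        )
    emissions = np.column_stack(
        [np.vstack(emission_rows), np.full(len(match_cols), _X_EMISSION_BITS)]
    )
    return ProfileModel(
        group=seed.group,
        subgroup=seed.subgroup,
        emissions=emissions,
        match_columns=tuple(match_cols),
    )


def score_profile(model: ProfileModel, seq: str | np.ndarray) -> float:
    """Best local log-odds score (bits) of *seq* against the profile.

    Smith–Waterman-style dynamic programme over the profile match states
    with the fixed insert/delete scheme; the empty alignment scores 0.
    """
    encoded = seq if isinstance(seq, np.ndarray) else encode_sequence(seq)
    L = len(encoded)
    if L == 0:
        return 0.0
    ins, dele = model.insert_score, model.delete_score
    idx = np.arange(1, L + 1, dtype=float)
    prev = np.zeros(L + 1)
    best = 0.0
    for state_scores in model.emissions:
        e = state_scores[encoded]
        base = np.maximum(prev[:-1] + e, prev[1:] + dele)
        base = np.maximum(base, 0.0)
        # fold in insertions (stay in this state, consume residues):
        # cur[j] = max_{k<=j} base[k] + ins*(j-k)
        shifted = np.maximum.accumulate(base - ins * idx)
        cur_body = ins * idx + shifted
        best = max(best, float(cur_body.max()))
        cur = np.empty(L + 1)
        cur[0] = 0.0
        cur[1:] = np.maximum(cur_body, 0.0)
        prev = cur
    return best


def score_profile_full(model: ProfileModel, seq: str) -> tuple[float, tuple[int, int], int]:
    """Like :func:`score_profile` but with traceback.

    Returns (score, target interval 0-based half-open, number of match
    states consumed).  Used only on gate-passing hits, so the plain-Python
    dynamic programme is fine.
    """
    encoded = encode_sequence(seq)
    L = len(encoded)
    M = model.n_states
    ins, dele = model.insert_score, model.delete_score
    NEG = float("-inf")
    H = np.zeros((M + 1, L + 1))
    ptr = np.zeros((M + 1, L + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    best, bi, bj = 0.0, 0, 0
    for i in range(1, M + 1):
        e_row = model.emissions[i - 1]
        for j in range(1, L + 1):
            diag = H[i - 1][j - 1] + e_row[encoded[j - 1]]
            up = H[i - 1][j] + dele
            left = H[i][j - 1] + ins
            val, move = 0.0, 0
            if diag > val:
                val, move = diag, 1
            if up > val:
                val, move = up, 2
            if left > val:
                val, move = left, 3
            H[i][j] = val
            ptr[i][j] = move
            if val > best:
                best, bi, bj = val, i, j
    if best <= 0:
        return 0.0, (0, 0), 0
    i, j = bi, bj
    n_states = 0
    while ptr[i][j] != 0:
        move = ptr[i][j]
        if move == 1:
            n_states += 1
            i, j = i - 1, j - 1
        elif move == 2:
            n_states += 1
            i -= 1
        else:
            j -= 1
    return float(best), (j, bj), n_states


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Composition-preserving Fisher–Yates shuffle."""
    arr = list(seq)
    rng.shuffle(arr)
    return "".join(arr)


def random_background_sequence(length: int, rng: np.random.Generator) -> str:
    aas = list(BACKGROUND_FREQS)
    probs = np.array(list(BACKGROUND_FREQS.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(aas, size=length, p=probs))


# ---------------------------------------------------------------------------
# E-value calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalueModel:
    """Gumbel tail calibration: E(s) = K * db_size * exp(-lambda * s)."""

    lam: float
    K: float
    db_size: int  # database size in residues

    def evalue(self, score: float, db_size: int | None = None) -> float:
        n = self.db_size if db_size is None else db_size
        return self.K * n * math.exp(-self.lam * score)

    def score_at(self, evalue: float, db_size: int | None = None) -> float:
        n = self.db_size if db_size is None else db_size
        return -math.log(evalue / (self.K * n)) / self.lam


def _gumbel_moments(scores: np.ndarray) -> tuple[float, float]:
    sd = float(np.std(scores, ddof=1))
    if sd < 1e-9:
        raise ValueError("calibration: degenerate score variance")
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = float(np.mean(scores)) - _EULER_GAMMA / lam
    return lam, mu


def calibrate_evalue(
    model: ProfileModel,
    db_size: int,
    rng: np.random.Generator,
    n_decoys: int = 200,
    decoy_length: int = 150,
) -> EvalueModel:
    """Fit the Gumbel tail of the profile's null score distribution.

    Null scores come from random decoy sequences of the background
    composition; lambda and mu are fitted by moments, and K is scaled so
    that db_size counts residues.
    """
    scores = np.array(
        [
            score_profile(model, random_background_sequence(decoy_length, rng))
            for _ in range(n_decoys)
        ]
    )
    lam, mu = _gumbel_moments(scores)
    K = math.exp(lam * mu) / decoy_length
    return EvalueModel(lam=lam, K=K, db_size=db_size)


def calibrate_pairwise(
    rng: np.random.Generator,
    n_pairs: int = 200,
    length: int = 150,
) -> EvalueModel:
    """Gumbel calibration for pairwise local-alignment bit scores.

    ``db_size`` here counts target residues; :meth:`EvalueModel.evalue`
    treats the stored db_size as the m*n search-space normalisation.
    """
    scores = np.array(
        [
            align_local(
                random_background_sequence(length, rng),
                random_background_sequence(length, rng),
            ).score
            for _ in range(n_pairs)
        ],
        dtype=float,
    )
    lam, mu = _gumbel_moments(scores)
    K = math.exp(lam * mu) / (length * length)
    return EvalueModel(lam=lam, K=K, db_size=length * length)


# ---------------------------------------------------------------------------
# Pairwise local alignment (Smith–Waterman, BLOSUM62, affine 11/1)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalAlignment:
    score: int
    a_interval: tuple[int, int]  # 0-based half-open on sequence a
    b_interval: tuple[int, int]


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    # BLAST affine convention: a gap of length k costs 11 + k
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    aligner.mode = "local"
    return aligner


_ALIGNER = _make_aligner()


def align_local(a: str, b: str) -> LocalAlignment:
    """Local pairwise alignment with BLOSUM62 and affine gaps (open 11,
    extend 1, BLAST convention).  Empty input aligns with score 0."""
    if not a or not b:
        return LocalAlignment(score=0, a_interval=(0, 0), b_interval=(0, 0))
    score = _ALIGNER.score(a, b)
    if score <= 0:
        return LocalAlignment(score=int(score), a_interval=(0, 0), b_interval=(0, 0))
    aln = _ALIGNER.align(a, b)[0]
    a_blocks, b_blocks = aln.aligned
    return LocalAlignment(
        score=int(score),
        a_interval=(int(a_blocks[0][0]), int(a_blocks[-1][1])),
        b_interval=(int(b_blocks[0][0]), int(b_blocks[-1][1])),
    )


def align_score(a: str, b: str) -> int:
    """Score-only fast path of :func:`align_local`."""
    if not a or not b:
        return 0
    return int(_ALIGNER.score(a, b))


# ---------------------------------------------------------------------------
# Database search, iterative expansion, reciprocal check
# ---------------------------------------------------------------------------

def search_profile(
    model: ProfileModel,
    db: Sequence[ProteinRecord],
    calibration: EvalueModel,
    e_gate: float,
    query_ref: str | None = None,
) -> list[SearchHit]:
    """Score every database protein against the profile; keep hits under
    the E-value gate, with aligned interval and profile coverage."""
    ref = query_ref or f"profile:{model.group}" + (f"/{model.subgroup}" if model.subgroup else "")
    gate_score = calibration.score_at(e_gate)
    hits: list[SearchHit] = []
    for rec in db:
        s = score_profile(model, rec.sequence)
        if s < gate_score:
            continue
        full_score, (tstart, tend), n_states = score_profile_full(model, rec.sequence)
        ev = calibration.evalue(full_score)
        if ev >= e_gate:
            continue
        hits.append(
            SearchHit(
                query_ref=ref,
                target_id=rec.id,
                bits=full_score,
                evalue=ev,
                tstart=tstart,
                tend=tend,
                coverage=n_states / model.n_states,
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.bits, h.target_id))
    return hits


def iterative_expand(
    seeds: set[str],
    db: Sequence[ProteinRecord],
    accept: Callable[[ProteinRecord], bool],
    search_fn: Callable[[ProteinRecord, Sequence[ProteinRecord]], Iterable[str]],
    max_rounds: int = 20,
) -> tuple[set[str], int, bool]:
    """Iterate similarity search from an accepted set until it stops growing.

    Each round uses the members added in the previous round as queries;
    any database protein they hit (per *search_fn*) that passes the pure
    *accept* predicate joins the set.  The result is the monotone fixed
    point {S U accepted-hits-of(S)} and is independent of database order.

    Returns (converged set, rounds used, converged flag); the flag is False
    when ``max_rounds`` was exhausted before convergence.
    """
    by_id = {rec.id: rec for rec in db}
    current = set(seeds)
    frontier = {i for i in current if i in by_id}
    rounds = 0
    while frontier and rounds < max_rounds:
        hit_ids: set[str] = set()
        for qid in sorted(frontier):
            hit_ids.update(search_fn(by_id[qid], db))
        new = {
            tid
            for tid in hit_ids
            if tid in by_id and tid not in current and accept(by_id[tid])
        }
        if not new:
            return current, rounds, True
        current |= new
        frontier = new
        rounds += 1
    return current, rounds, not frontier


def reciprocal_top5(
    candidate: ProteinRecord,
    reference_db: Sequence[ProteinRecord],
    known_grsp_ids: set[str],
    pairwise_cal: EvalueModel,
    top_n: int = 5,
) -> bool:
    """GRSP plausibility check against a labelled reference database.

    Aligns the candidate to every reference entry, ranks by E-value
    ascending (ties: higher bit score, then lexicographic id), and passes
    iff at least one known GRSP appears within the first *top_n* entries.
    """
    if not reference_db:
        raise ValueError("reciprocal_top5: empty reference database")
    ranked = []
    for ref in reference_db:
        s = align_score(candidate.sequence, ref.sequence)
        ev = pairwise_cal.evalue(
            float(s), len(candidate.sequence) * len(ref.sequence)
        )
        ranked.append((ev, -float(s), ref.id))
    ranked.sort()
    return any(rid in known_grsp_ids for _, _, rid in ranked[:top_n])


def read_hits_tsv(path: str | Path) -> list[SearchHit]:
    """Adapter for external search-engine output.

    Columns: query_ref, target_id, bits, evalue, tstart, tend with 1-based
    inclusive target coordinates (converted to the internal convention).
    """
    df = read_tsv(path)
    needed = ["query_ref", "target_id", "bits", "evalue", "tstart", "tend"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing hit columns {missing}")
    return [
        SearchHit(
            query_ref=row.query_ref,
            target_id=row.target_id,
            bits=float(row.bits),
            evalue=float(row.evalue),
            tstart=int(row.tstart) - 1,
            tend=int(row.tend),
        )
        for row in df.itertuples(index=False)
    ]
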