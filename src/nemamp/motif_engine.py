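"""Cysteine-array motif definitions and matching.

The cysteine-stabilised AMP groups (Diapausin, the CSab subgroups, and the
Saposin B domain of Nemapores) are recognised by ordered arrays of cysteine
residues with constrained spacing.  A :class:`MotifDefinition` lists the
number of cysteines, an inclusive (min, max) range for the number of
residues between each consecutive pair, and the putative disulfide
connectivity (metadata only; matching never uses it).

Matching semantics: spacers are runs of non-cysteine residues, so a match
always uses consecutive cysteines of the sequence (an array never "skips"
a cysteine — in the reference diagrams the dashes between the C symbols
stand for any *other* amino acid).  All matches are non-overlapping and
leftmost-greedy — candidate placements are ordered by first-cysteine
position, then span end, then lexicographic cysteine tuple; after a
match, scanning resumes after its last cysteine.  'X' residues are
allowed inside spacer windows but can never stand for a cysteine.

The shipped reference arrays are data, not code: they are loaded from the
package's ``data/motifs.json`` and derive from the curated seed alignments
(minimum/maximum observed inter-cysteine gaps with +/-2 residues of slack).
Every result file records the motif-definition checksum so analyses remain
auditable against the array file actually used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path

__all__ = [
    "MotifDefinition",
    "MotifMatch",
    "CsabCall",
    "find_motif",
    "brute_force_motif_oracle",
    "classify_csab",
    "count_saposin_domains",
    "load_motifs",
    "default_motifs",
    "motif_checksum",
]


@dataclass(frozen=True)
class MotifDefinition:
    """An ordered cysteine array with spacing ranges and connectivity."""

    name: str
    n_cys: int
    spacers: tuple[tuple[int, int], ...]
    connectivity: tuple[tuple[int, int], ...] = ()
    min_before: int = 0   # minimum residues before the first cysteine
    min_after: int = 0    # minimum residues after the last cysteine

    def __post_init__(self) -> None:
        if self.n_cys < 2:
            raise ValueError(f"{self.name}: n_cys must be >= 2")
        if len(self.spacers) != self.n_cys - 1:
            raise ValueError(
                f"{self.name}: need {self.n_cys - 1} spacer ranges, "
                f"got {len(self.spacers)}"
            )
        for lo, hi in self.spacers:
            if lo < 0 or lo > hi:
                raise ValueError(f"{self.name}: invalid spacer range ({lo}, {hi})")
        seen: set[int] = set()
        for i, j in self.connectivity:
            if not (1 <= i <= self.n_cys and 1 <= j <= self.n_cys) or i == j:
                raise ValueError(f"{self.name}: invalid connectivity pair ({i}, {j})")
            if i in seen or j in seen:
                raise ValueError(f"{self.name}: connectivity pairs must be disjoint")
            seen.update((i, j))


@dataclass(frozen=True)
class MotifMatch:
    """One placement of a cysteine array on a sequence (0-based positions)."""

    motif: str
    positions: tuple[int, ...]
    sequence_id: str = ""

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        """Half-open end of the motif span (one past the last cysteine)."""
        return self.positions[-1] + 1

    def validate(self, seq: str, definition: MotifDefinition) -> None:
        """Re-check that this match literally satisfies its definition."""
        if len(self.positions) != definition.n_cys:
            raise AssertionError(f"{self.motif}: wrong cysteine count")
        for p in self.positions:
            if seq[p] != "C":
                raise AssertionError(f"{self.motif}: position {p} is not 'C'")
        for (lo, hi), a, b in zip(
            definition.spacers, self.positions, self.positions[1:]
        ):
            gap = b - a - 1
            if not lo <= gap <= hi:
                raise AssertionError(
                    f"{self.motif}: spacer {gap} outside [{lo}, {hi}]"
                )
            if "C" in seq[a + 1 : b]:
                raise AssertionError(
                    f"{self.motif}: cysteine inside spacer window ({a}, {b})"
                )


def _cys_positions(seq: str) -> list[int]:
    return [i for i, aa in enumerate(seq) if aa == "C"]


def _window_ok(seq_len: int, window: list[int], m: MotifDefinition) -> bool:
    if window[0] < m.min_before:
        return False
    if seq_len - window[-1] - 1 < m.min_after:
        return False
    for (lo, hi), a, b in zip(m.spacers, window, window[1:]):
        if not lo <= (b - a - 1) <= hi:
            return False
    return True


def find_motif(seq: str, m: MotifDefinition, sequence_id: str = "") -> list[MotifMatch]:
    """All non-overlapping, leftmost-greedy placements of the array on *seq*.

    Because spacers contain no cysteines, every placement is a run of
    ``n_cys`` consecutive cysteines; the scan walks those runs left to
    right and resumes after the last cysteine of each accepted match.
    """
    cys = _cys_positions(seq)
    matches: list[MotifMatch] = []
    j = 0
    while j + m.n_cys <= len(cys):
        window = cys[j : j + m.n_cys]
        if _window_ok(len(seq), window, m):
            matches.append(
                MotifMatch(motif=m.name, positions=tuple(window), sequence_id=sequence_id)
            )
            j += m.n_cys
        else:
            j += 1
    return matches


def brute_force_motif_oracle(
    seq: str, m: MotifDefinition, sequence_id: str = "", max_cys: int = 20
) -> list[MotifMatch]:
    """Exhaustive-enumeration reference for :func:`find_motif`.

    Enumerates every strictly increasing ``n_cys``-tuple of cysteine
    positions, keeps the tuples satisfying all spacer and flank
    constraints whose spacer windows are cysteine-free, and reduces them
    to the non-overlapping leftmost-greedy set by the (start, end, tuple)
    ordering.
    """
    cys = _cys_positions(seq)
    if len(cys) > max_cys:
        raise ValueError(
            f"combinatorial guard: {len(cys)} cysteines exceeds {max_cys}"
        )
    valid: list[tuple[int, ...]] = []
    for tup in combinations(cys, m.n_cys):
        if tup[0] < m.min_before:
            continue
        if len(seq) - tup[-1] - 1 < m.min_after:
            continue
        ok = True
        for (lo, hi), a, b in zip(m.spacers, tup, tup[1:]):
            if not lo <= (b - a - 1) <= hi or "C" in seq[a + 1 : b]:
                ok = False
                break
        if ok:
            valid.append(tup)
    valid.sort(key=lambda t: (t[0], t[-1], t))
    chosen: list[tuple[int, ...]] = []
    boundary = -1
    for tup in valid:
        if tup[0] > boundary:
            chosen.append(tup)
            boundary = tup[-1]
    return [MotifMatch(motif=m.name, positions=t, sequence_id=sequence_id) for t in chosen]


# ---------------------------------------------------------------------------
# CSab subgroup classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CsabCall:
    """Outcome of matching a sequence against the CSab reference arrays.

    ``subgroup`` is one of MND, TID, Macin, Drosomycin, MND_6Cys when exactly
    one array matches; ``ambiguous`` lists all matching arrays when more than
    one does (never silently tie-broken); both empty means no call.
    """

    subgroup: str | None
    match: MotifMatch | None
    ambiguous: tuple[str, ...] = ()

    @property
    def is_ambiguous(self) -> bool:
        return len(self.ambiguous) > 1


def classify_csab(
    seq: str, reference_arrays: dict[str, MotifDefinition], sequence_id: str = ""
) -> CsabCall:
    """Assign a CSab subgroup by literal cysteine-array matching."""
    hits: list[tuple[str, MotifMatch]] = []
    for name, definition in reference_arrays.items():
        found = find_motif(seq, definition, sequence_id)
        if found:
            hits.append((name, found[0]))
    if not hits:
        return CsabCall(subgroup=None, match=None)
    if len(hits) == 1:
        return CsabCall(subgroup=hits[0][0], match=hits[0][1])
    return CsabCall(
        subgroup=None, match=None, ambiguous=tuple(sorted(name for name, _ in hits))
    )


def count_saposin_domains(
    seq: str, saposin_def: MotifDefinition, sequence_id: str = ""
) -> int:
    """Number of non-overlapping Saposin B cysteine arrays in *seq*."""
    return len(find_motif(seq, saposin_def, sequence_id))


# ---------------------------------------------------------------------------
# Reference arrays (shipped as data)
# ---------------------------------------------------------------------------

def _definitions_from_payload(payload: dict) -> dict[str, MotifDefinition]:
    out: dict[str, MotifDefinition] = {}
    for entry in payload["motifs"]:
        out[entry["name"]] = MotifDefinition(
            name=entry["name"],
            n_cys=entry["n_cys"],
            spacers=tuple((lo, hi) for lo, hi in entry["spacers"]),
            connectivity=tuple((i, j) for i, j in entry.get("connectivity", [])),
            min_before=entry.get("min_before", 0),
            min_after=entry.get("min_after", 0),
        )
    return out


def load_motifs(path: str | Path) -> dict[str, MotifDefinition]:
    """Load motif definitions from a JSON file (see ``data/motifs.json``)."""
    with open(path, encoding="utf-8") as fh:
        return _definitions_from_payload(json.load(fh))


def default_motifs() -> dict[str, MotifDefinition]:
    """The packaged reference arrays."""
    text = resources.files("nemamp.data").joinpath("motifs.json").read_text("utf-8")
    return _definitions_from_payload(json.loads(text))


def motif_checksum(motifs: dict[str, MotifDefinition]) -> str:
    """Stable sha256 fingerprint of a motif-definition set."""
    payload = [
        {
            "name": m.name,
            "n_cys": m.n_cys,
            "spacers": [list(s) for s in m.spacers],
            "connectivity": [list(c) for c in m.connectivity],
            "min_before": m.min_before,
            "min_after": m.min_after,
        }
        for m in sorted(motifs.values(), key=lambda d: d.name)
    ]
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


#: CSab subgroup array names (keys into the motif set).
CSAB_ARRAY_NAMES = ("MND", "TID", "Macin", "Drosomycin", "MND_6Cys")


def csab_arrays(motifs: dict[str, MotifDefinition]) -> dict[str, MotifDefinition]:
    return {name: motifs[name] for name in CSAB_ARRAY_NAMES}
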