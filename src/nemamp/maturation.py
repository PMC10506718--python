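"""Signal-peptide and propeptide processing of AMP precursors.

The external neural-network predictors used in large-scale annotation
(Sec/SPI signal-peptide and furin-site predictors) are deliberately not
reimplemented.  The defaults here are transparent sequence rules so the
pipeline is self-contained and testable, and an adapter TSV lets users
inject real predictor output instead; every maturation result records which
mode produced it.

Signal-peptide rule (classical tripartite architecture, searched within the
first 35 residues):

* n-region — at least one K/R among the first five residues;
* h-region — a window of >= 7 residues with mean Kyte–Doolittle
  hydropathy >= 1.6;
* c-region — an Ala-X-Ala-style cleavage site ``[AGSTC]-X-[AGST]`` whose
  last residue lies after the h-region; cleavage occurs after that residue.

Propeptides are delimited by furin sites ``R-X-[KR]-R`` (cleavage after the
final arginine).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

from .io_formats import read_tsv

logger = logging.getLogger("nemamp")

#: Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

SP_SEARCH_WINDOW = 35
H_REGION_LENGTH = 7
H_REGION_MIN_HYDROPATHY = 1.6
_CLEAVAGE_M3 = set("AGSTC")   # position -3 relative to cleavage
_CLEAVAGE_M1 = set("AGST")    # position -1 relative to cleavage

_FURIN_RE = re.compile(r"(?=R.[KR]R)")


@dataclass(frozen=True)
class MaturationResult:
    """Predicted processing of one precursor.

    ``sp_cleavage`` is the 1-based position of the last signal-peptide
    residue (None when no signal peptide was found); ``mature_seq`` is the
    predicted mature peptide (for precursors without a signal peptide it is
    the whole sequence, retained for reporting only, with
    ``complete=False``).
    """

    sp_cleavage: int | None
    furin_sites: tuple[int, ...]
    mature_seq: str
    mature_glycine_pct: float
    complete: bool
    mode: str = "heuristic"


def predict_signal_peptide(seq: str) -> int | None:
    """Rule-based Sec/SPI signal-peptide call.

    Returns the 1-based position of the last signal-peptide residue, or
    None when the tripartite architecture is not found.
    """
    head = seq[:SP_SEARCH_WINDOW]
    if not any(aa in "KR" for aa in head[:5]):
        return None
    h_end = None  # 1-based end of the leftmost qualifying hydrophobic window
    for start in range(0, len(head) - H_REGION_LENGTH + 1):
        window = head[start : start + H_REGION_LENGTH]
        mean_kd = sum(KYTE_DOOLITTLE.get(aa, 0.0) for aa in window) / H_REGION_LENGTH
        if mean_kd >= H_REGION_MIN_HYDROPATHY:
            h_end = start + H_REGION_LENGTH
            break
    if h_end is None:
        return None
    for p in range(max(h_end + 1, 3), min(SP_SEARCH_WINDOW, len(seq) - 1) + 1):
        if seq[p - 3] in _CLEAVAGE_M3 and seq[p - 1] in _CLEAVAGE_M1:
            return p
    return None


def predict_furin_sites(seq: str) -> list[int]:
    """1-based end positions of all R-X-[KR]-R furin sites, ascending.

    Cleavage occurs after the final arginine of each site; overlapping
    sites are all reported.
    """
    return [m.start() + 4 for m in _FURIN_RE.finditer(seq)]


def glycine_fraction(mature: str) -> float:
    """Glycine content of a mature peptide as a percentage (2 decimals)."""
    if len(mature) < 1:
        raise ValueError("glycine_fraction: empty mature peptide")
    return round(100.0 * mature.count("G") / len(mature), 2)


def derive_mature(
    seq: str,
    sp: int | None,
    furin_sites: list[int] | tuple[int, ...] = (),
    motif_start: int | None = None,
    mode: str = "heuristic",
) -> MaturationResult:
    """Derive the mature peptide after signal-peptide and propeptide removal.

    With a signal peptide ending at 1-based position *sp*, the mature region
    starts after the last furin site that follows the signal peptide and —
    when the 0-based start of the group's defining motif is given — precedes
    it.  Furin sites inside the signal peptide are ignored with a warning.
    Without a signal peptide the whole sequence is retained for reporting
    and the result is flagged incomplete.
    """
    furin_sites = tuple(furin_sites)
    if sp is None:
        return MaturationResult(
            sp_cleavage=None,
            furin_sites=furin_sites,
            mature_seq=seq,
            mature_glycine_pct=glycine_fraction(seq),
            complete=False,
            mode=mode,
        )
    usable = []
    for f in furin_sites:
        if f <= sp:
            logger.warning("furin site at %d precedes signal-peptide cleavage %d; ignored", f, sp)
            continue
        if motif_start is not None and f > motif_start:
            continue
        usable.append(f)
    cut = max(usable) if usable else sp
    mature = seq[cut:]
    if not mature:  # cleavage at the very end: fall back to SP removal only
        mature = seq[sp:]
    return MaturationResult(
        sp_cleavage=sp,
        furin_sites=furin_sites,
        mature_seq=mature,
        mature_glycine_pct=glycine_fraction(mature) if mature else 0.0,
        complete=True,
        mode=mode,
    )


def mature_precursor(
    seq: str,
    motif_start: int | None = None,
    sp_override: int | None = None,
    use_override: bool = False,
) -> MaturationResult:
    """Full maturation of one precursor (heuristic or adapter override).

    ``use_override=True`` forces the adapter value (``sp_override``; 0 or
    None meaning "no signal peptide") regardless of the heuristic.
    """
    if use_override:
        sp = sp_override if sp_override else None
        mode = "adapter"
    else:
        sp = predict_signal_peptide(seq)
        mode = "heuristic"
    return derive_mature(seq, sp, predict_furin_sites(seq), motif_start, mode=mode)


def read_sp_adapter(path: str | Path) -> dict[str, int]:
    """Read an external signal-peptide prediction TSV: id, sp_position.

    ``sp_position`` 0 means no signal peptide.
    """
    df = read_tsv(path)
    for col in ("id", "sp_position"):
        if col not in df.columns:
            raise ValueError(f"{path}: adapter TSV must have columns id, sp_position")
    return {row.id: int(row.sp_position) for row in df.itertuples(index=False)}
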