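"""Shared domain types and readers/writers for the standard file formats.

All tabular files are UTF-8, tab-delimited, with a single ``#``-prefixed
header line naming the columns.  Sequence coordinates are 0-based half-open
internally; every serialized coordinate is 1-based inclusive (stated in the
file headers written here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("nemamp")

#: The five antimicrobial-peptide groups profiled across the phylum.
AMP_GROUPS = ("Cecropin", "Diapausin", "CSab", "Nemapore", "GRSP")

#: CSab (cysteine-stabilised alpha/beta fold) subgroups.
CSAB_SUBGROUPS = ("MND", "TID", "Macin", "Drosomycin", "MND_6Cys")

#: Closed set of nematode lifestyle labels: free-living, animal-parasitic,
#: plant-parasitic and entomopathogenic nematodes.
LIFESTYLES = ("FLN", "APN", "PPN", "EPN")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
_REMAPPED_RESIDUES = {"U": "X", "B": "X", "Z": "X"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein with species provenance."""

    id: str
    sequence: str
    species: str = ""
    genome_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpeciesMeta:
    """Per-genome metadata carried through the repertoire statistics.

    ``busco_complete`` is a completeness percentage in [0, 100];
    ``pcg_count`` is the genome's total number of protein-coding genes.
    """

    genome_id: str
    species: str
    clade: str
    lifestyle: str
    pcg_count: int
    busco_complete: float

    def __post_init__(self) -> None:
        if self.lifestyle not in LIFESTYLES:
            raise FormatError(
                f"genome {self.genome_id!r}: unknown lifestyle "
                f"{self.lifestyle!r} (expected one of {LIFESTYLES})"
            )
        if self.pcg_count < 1:
            raise FormatError(f"genome {self.genome_id!r}: pcg_count must be >= 1")
        if not 0.0 <= self.busco_complete <= 100.0:
            raise FormatError(
                f"genome {self.genome_id!r}: busco_complete must be in [0, 100]"
            )


@dataclass(frozen=True)
class SeedSet:
    """Curated seed sequences for one AMP group with their multiple alignment.

    The alignment rows are gapped with '-'; ungapping row *i* must recover
    ``sequences[i].sequence``.
    """

    group: str
    sequences: tuple[ProteinRecord, ...]
    alignment: tuple[str, ...]
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.group not in AMP_GROUPS:
            raise FormatError(f"unknown AMP group {self.group!r}")
        if len(self.alignment) != len(self.sequences):
            raise FormatError("alignment must have one row per seed sequence")
        widths = {len(row) for row in self.alignment}
        if len(widths) > 1:
            raise FormatError("alignment rows have unequal lengths")
        for rec, row in zip(self.sequences, self.alignment):
            if row.replace("-", "") != rec.sequence:
                raise FormatError(
                    f"alignment row for {rec.id!r} does not match its sequence"
                )

    @property
    def n_columns(self) -> int:
        return len(self.alignment[0]) if self.alignment else 0


@dataclass
class ExpressionMatrix:
    """Gene-by-life-stage expression in Transcripts Per Million (TPM)."""

    gene_ids: list[str]
    stage_ids: list[str]
    tpm: np.ndarray

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        if self.tpm.shape != (len(self.gene_ids), len(self.stage_ids)):
            raise FormatError(
                f"TPM shape {self.tpm.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.stage_ids)} stages"
            )
        if np.any(self.tpm < 0):
            raise FormatError("TPM values must be non-negative")


# ---------------------------------------------------------------------------
# Tab-separated helpers ('#'-prefixed header line)
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path, comment_lines: bool = True) -> pd.DataFrame:
    """Read a tab-delimited file whose header line starts with '#'.

    Extra '#'-prefixed lines before the header are treated as comments.
    """
    path = Path(path)
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            rows.append(line.split("\t"))
    if header is None:
        raise FormatError(f"{path}: no '#'-prefixed header line found")
    for r in rows:
        if len(r) != len(header):
            raise FormatError(
                f"{path}: ragged row with {len(r)} fields (expected {len(header)})"
            )
    return pd.DataFrame(rows, columns=header)


def write_tsv(df: pd.DataFrame, path: str | Path, comments: Sequence[str] = ()) -> None:
    """Write a DataFrame with a '#'-prefixed header, preceded by comments."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(f"## {c}\n")
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase, strip one terminal '*', and map U/B/Z ambiguity codes to X."""
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if any(c in seq for c in _REMAPPED_RESIDUES):
        logger.warning(
            "record %s: mapping selenocysteine/ambiguity codes (U/B/Z) to X",
            record_id,
        )
        for src, dst in _REMAPPED_RESIDUES.items():
            seq = seq.replace(src, dst)
    return seq


def read_fasta(
    path: str | Path, species: str = "", genome_id: str = ""
) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The header token before the first whitespace is the record id.  Sequences
    are uppercased, a single terminal stop ('*') is stripped, and U/B/Z are
    mapped to 'X' with a logged warning.  Duplicate ids and empty sequences
    are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise FormatError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        seq = normalize_sequence(str(entry.seq), rid)
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rid!r}")
        records.append(
            ProteinRecord(id=rid, sequence=seq, species=species, genome_id=genome_id)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Species metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = ["genome_id", "species", "clade", "lifestyle", "pcg_count", "busco_complete"]


def read_species_meta(path: str | Path) -> list[SpeciesMeta]:
    """Read and validate the per-genome metadata table."""
    df = read_tsv(path)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        try:
            pcg = int(row.pcg_count)
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-numeric pcg_count {row.pcg_count!r} "
                f"for genome {row.genome_id!r}"
            ) from exc
        out.append(
            SpeciesMeta(
                genome_id=row.genome_id,
                species=row.species,
                clade=row.clade,
                lifestyle=row.lifestyle,
                pcg_count=pcg,
                busco_complete=float(row.busco_complete),
            )
        )
    return out


def write_species_meta(meta: Iterable[SpeciesMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (m.genome_id, m.species, m.clade, m.lifestyle, m.pcg_count, m.busco_complete)
            for m in meta
        ],
        columns=_META_COLUMNS,
    )
    write_tsv(df, path)


# ---------------------------------------------------------------------------
# TPM tables
# ---------------------------------------------------------------------------

def read_tpm(path: str | Path) -> ExpressionMatrix:
    """Read a gene x stage TPM table; first column is the gene id."""
    df = read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: TPM table needs a gene column and >=1 stage")
    gene_ids = df.iloc[:, 0].tolist()
    stage_ids = list(df.columns[1:])
    try:
        tpm = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric TPM value") from exc
    if np.any(tpm < 0):
        raise FormatError(f"{path}: negative TPM value")
    return ExpressionMatrix(gene_ids=gene_ids, stage_ids=stage_ids, tpm=tpm)


def write_tpm(mat: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(mat.tpm, columns=mat.stage_ids)
    df.insert(0, "gene_id", mat.gene_ids)
    write_tsv(df, path)


# ---------------------------------------------------------------------------
# Candidate tables
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "id",
    "genome_id",
    "species",
    "group",
    "subgroup",
    "complete",
    "evalue",
    "bits",
    "evidence_source",
    "motif_name",
    "motif_span",       # 1-based inclusive "start-end", or ""
    "cys_positions",    # 1-based, comma-separated, or ""
    "n_saposin_domains",
    "sp_cleavage",      # 1-based last signal-peptide residue, 0 = none
    "mature_seq",
    "mature_glycine_pct",
    "accepted_by",
    "cross_flag",
    "rescued",
]

_CANDIDATE_HEADER_COMMENTS = (
    "AMP candidate table; coordinates are 1-based inclusive",
)


def write_candidates(candidates: Iterable[object], path: str | Path,
                     comments: Sequence[str] = ()) -> None:
    """Serialize classified candidates to TSV (one row per candidate).

    Accepts any objects exposing a ``to_row()`` method returning a dict with
    the :data:`CANDIDATE_COLUMNS` keys (see ``amp_pipeline.AMPCandidate``).
    Internal 0-based half-open coordinates become 1-based inclusive here.
    """
    rows = [c.to_row() for c in candidates]
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    write_tsv(df, path, comments=tuple(_CANDIDATE_HEADER_COMMENTS) + tuple(comments))


def read_candidates(path: str | Path) -> pd.DataFrame:
    """Read a candidate TSV back into a typed DataFrame."""
    df = read_tsv(path)
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing candidate columns {missing}")
    df["complete"] = df["complete"].map({"True": True, "False": False})
    df["cross_flag"] = df["cross_flag"].map({"True": True, "False": False})
    df["rescued"] = df["rescued"].map({"True": True, "False": False})
    for col in ("evalue", "bits", "mature_glycine_pct"):
        df[col] = df[col].replace("", "nan").astype(float)
    for col in ("n_saposin_domains", "sp_cleavage"):
        df[col] = df[col].replace("", "0").astype(int)
    return df


def interval_to_1based(start: int, end: int) -> str:
    """Render an internal 0-based half-open interval as 1-based inclusive."""
    return f"{start + 1}-{end}"


def parse_1based_interval(text: str) -> tuple[int, int]:
    """Parse "start-end" (1-based inclusive) to 0-based half-open."""
    a, b = text.split("-")
    return int(a) - 1, int(b)
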