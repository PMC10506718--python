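"""Synthetic proteome benchmark with planted AMPs and known ground truth.

The generator emulates the statistical structure the discovery pipeline
assumes: per-genome predicted proteomes that are mostly decoy proteins,
with planted members of the five AMP groups (Cecropin, Diapausin, CSab
with its subgroups, Nemapore, GRSP) built the way authentic precursors
look — a canonical Sec signal peptide, an optional furin-cleaved
propeptide, and a mature region carrying the group's defining feature.

Planted sequences are anchored on the curated seed sets: a randomly chosen
seed mature region is substituted per-residue at ``mutation_rate`` with a
BLOSUM62-conditional model (cysteine skeleton and signal/propeptide
boundaries never mutated) and its inter-cysteine spacers are resized to
values drawn uniformly within the configured spacing ranges.  This keeps
every planted AMP inside the similarity basin of its seed profile while
still satisfying its group's acceptance rules by construction.

Hard decoys each violate exactly one named acceptance rule, so a checker
disagreement localises the broken rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    AMINO_ACIDS,
    AMP_GROUPS,
    CSAB_SUBGROUPS,
    ExpressionMatrix,
    ProteinRecord,
    SeedSet,
    SpeciesMeta,
    read_tsv,
    write_fasta,
    write_species_meta,
    write_tpm,
    write_tsv,
)
from .maturation import glycine_fraction
from .motif_engine import MotifDefinition, default_motifs
from .seq_search import BACKGROUND_FREQS

__all__ = [
    "SimConfig",
    "TruthRecord",
    "StudyData",
    "default_seed_sets",
    "default_grsp_reference",
    "plant_amp",
    "make_decoy",
    "generate_study",
    "grsp_gate_fixture",
    "simulate_lifestyle_counts",
    "HARD_DECOY_KINDS",
    "HARD_DECOY_TARGET_RULE",
]

# canonical signal peptide: n-region (M + K/R + 3 polar), 8-residue
# hydrophobic h-region, A-X-A c-region => cleavage after residue 16
SP_LENGTH = 16
_H_RESIDUES = "LIVF"
_POLAR = "NQDEST"
_NON_CYS = AMINO_ACIDS.replace("C", "")
_NON_CYS_NON_GLY = _NON_CYS.replace("G", "")

HARD_DECOY_KINDS = (
    "glycine_rich_long",
    "glycine_rich_no_sp",
    "saplip_extra_domain",
    "cys_rich_wrong_spacing",
)

#: The single acceptance rule each hard decoy class is built to violate.
HARD_DECOY_TARGET_RULE = {
    "glycine_rich_long": "grsp_length",
    "glycine_rich_no_sp": "grsp_signal_peptide",
    "saplip_extra_domain": "nemapore_no_extra_domain",
    "cys_rich_wrong_spacing": "diapausin_motif",
}

_STAGES = ("egg", "L1", "L3", "adult")
_CLADES = ("9/V", "10/IV", "8/III", "2/I", "12/IV", "9/V")
_LIFESTYLES = ("FLN", "FLN", "APN", "APN", "PPN", "EPN")

# inter-domain / inter-motif linker lengths chosen so that no cysteine
# window spanning a domain boundary can satisfy any reference array
_LINKER_RANGE = (16, 24)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one synthetic protein."""

    id: str
    genome_id: str
    planted_group: str            # AMP group, "decoy", or "hard_decoy"
    planted_subgroup: str = ""    # CSab subgroup, or the decoy kind
    n_saposin_domains: int = 0
    has_signal_peptide: bool = False
    mature_glycine_pct: float = 0.0
    sp_cleavage: int = 0          # 1-based last SP residue; 0 = none

    def __post_init__(self) -> None:
        if self.planted_group == "GRSP":
            assert self.has_signal_peptide and self.mature_glycine_pct > 17
        if self.planted_group == "Nemapore":
            assert self.n_saposin_domains >= 1


@dataclass
class SimConfig:
    """Study-generator configuration (defaults are the benchmark corpus)."""

    seed: int = 7
    n_genomes: int = 6
    n_decoys_per_genome: int = 500
    planted_per_group: int | dict[str, int] = 10
    mutation_rate: float = 0.10
    hard_decoy_fractions: dict[str, float] = field(
        default_factory=lambda: {k: 0.01 for k in HARD_DECOY_KINDS}
    )
    expressed_fraction: float = 0.86
    furin_fraction: float = 0.5
    truncate_fraction: float = 0.0  # drop SP from this fraction of plants

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5]")
        counts = [self.n_genomes, self.n_decoys_per_genome]
        if isinstance(self.planted_per_group, dict):
            counts += list(self.planted_per_group.values())
        else:
            counts.append(self.planted_per_group)
        if min(counts) < 0:
            raise ValueError("counts must be >= 0")
        for k in self.hard_decoy_fractions:
            if k not in HARD_DECOY_KINDS:
                raise ValueError(f"unknown hard decoy kind {k!r}")

    def planted_count(self, group: str) -> int:
        if isinstance(self.planted_per_group, dict):
            return self.planted_per_group.get(group, 0)
        return self.planted_per_group


@dataclass
class StudyData:
    """In-memory view of one generated study corpus."""

    proteomes: dict[str, list[ProteinRecord]]
    meta: list[SpeciesMeta]
    truth: list[TruthRecord]
    domains: pd.DataFrame          # columns: id, domain, start, end (1-based)
    tpm: dict[str, ExpressionMatrix]

    def all_proteins(self) -> list[ProteinRecord]:
        return [rec for gid in sorted(self.proteomes) for rec in self.proteomes[gid]]

    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {t.id: t for t in self.truth}


# ---------------------------------------------------------------------------
# Residue-level helpers
# ---------------------------------------------------------------------------

def _random_residues(rng: np.random.Generator, n: int, alphabet: str = _NON_CYS) -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n > 0 else ""


def _background_sequence(rng: np.random.Generator, n: int) -> str:
    aas = list(BACKGROUND_FREQS)
    p = np.array(list(BACKGROUND_FREQS.values()))
    return "".join(rng.choice(aas, size=n, p=p / p.sum()))


def _blosum_conditionals() -> dict[str, tuple[list[str], np.ndarray]]:
    """P(b | a) proportional to bg(b) * 2^(S(a,b)/2), b != a, b != C."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out: dict[str, tuple[list[str], np.ndarray]] = {}
    for a in AMINO_ACIDS:
        targets = [b for b in AMINO_ACIDS if b not in (a, "C")]
        weights = np.array(
            [BACKGROUND_FREQS[b] * 2.0 ** (mat[a][b] / 2.0) for b in targets]
        )
        out[a] = (targets, weights / weights.sum())
    return out


_CONDITIONALS = _blosum_conditionals()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-residue BLOSUM62-conditional substitution; cysteines are fixed."""
    out = []
    for aa in seq:
        if aa != "C" and rng.random() < rate:
            targets, probs = _CONDITIONALS[aa]
            out.append(rng.choice(targets, p=probs))
        else:
            out.append(aa)
    return "".join(out)


def _signal_peptide(rng: np.random.Generator) -> str:
    """n-region (>=1 K/R in the first 5), 8 hydrophobic residues, A-X-A."""
    n_region = "M" + rng.choice(["K", "R"]) + _random_residues(rng, 3, _POLAR)
    h_region = _random_residues(rng, 8, _H_RESIDUES)
    c_region = "A" + rng.choice(list("NQDE")) + "A"
    return n_region + h_region + c_region


def _propeptide(rng: np.random.Generator) -> str:
    """Short pro-region ending in an R-X-K-R furin site."""
    return _random_residues(rng, 5, _NON_CYS_NON_GLY) + "R" + rng.choice(list(_POLAR)) + "KR"


# ---------------------------------------------------------------------------
# Curated seed sets (deterministic fixtures)
# ---------------------------------------------------------------------------

_SEED_FIXTURE_RNG = 941042          # fixed: seeds are fixtures, not run data
_N_SEEDS = 6
_SEED_DIVERGENCE = 0.25

# amphipathic alpha-helical consensus for the Cecropin seeds
_CECROPIN_CONSENSUS = "SWLSKTAKKLENSAKKRISEGIAIAIQGGPR"

#: groups whose mature region is defined by a cysteine array, mapped to the
#: reference array that defines it
MOTIF_BY_GROUP = {
    "Diapausin": "Diapausin",
    "Nemapore": "SaposinB",
}


def _canonical_spacers(m: MotifDefinition) -> list[int]:
    return [(lo + hi) // 2 for lo, hi in m.spacers]


def _array_segments(
    m: MotifDefinition, spacers: list[int], rng: np.random.Generator
) -> list[str]:
    """[pre-flank, spacer_1, ..., spacer_{n-1}, post-flank] random filler."""
    segs = [_random_residues(rng, 3)]
    segs += [_random_residues(rng, s) for s in spacers]
    segs.append(_random_residues(rng, 3))
    return segs


def _assemble(segments: list[str]) -> str:
    """Join filler segments with the cysteines of the array."""
    pre, *spacers, post = segments
    return pre + "C" + "C".join(spacers) + "C" + post


def _grsp_consensus() -> str:
    non_g = "YNQFSRLPWH"
    units = []
    for i in range(20):
        units.append("GG" + non_g[i % 10] + non_g[(3 * i + 1) % 10])
    return "".join(units)  # length 80, 50% glycine


def default_seed_sets() -> list[SeedSet]:
    """The packaged seed alignments: one per group, one per CSab subgroup.

    Six seeds per set, derived from a consensus mature region by 25%
    BLOSUM62-conditional divergence; alignments are ungapped (all seeds in
    a set share the canonical inter-cysteine spacing), so the observed
    spacer range that the reference arrays extend by +/-2 is the canonical
    value itself.
    """
    rng = np.random.default_rng(_SEED_FIXTURE_RNG)
    motifs = default_motifs()
    seed_sets: list[SeedSet] = []

    def finish(group: str, subgroup: str | None, consensus: str) -> None:
        label = subgroup or group
        records, rows = [], []
        for i in range(_N_SEEDS):
            seq = _mutate(consensus, _SEED_DIVERGENCE, rng)
            records.append(ProteinRecord(id=f"{label}_seed{i + 1}", sequence=seq))
            rows.append(seq)
        seed_sets.append(
            SeedSet(
                group=group,
                subgroup=subgroup,
                sequences=tuple(records),
                alignment=tuple(rows),
            )
        )

    finish("Cecropin", None, _CECROPIN_CONSENSUS)
    dia = motifs["Diapausin"]
    finish("Diapausin", None, _assemble(_array_segments(dia, _canonical_spacers(dia), rng)))
    for sub in CSAB_SUBGROUPS:
        m = motifs[sub]
        finish("CSab", sub, _assemble(_array_segments(m, _canonical_spacers(m), rng)))
    sap = motifs["SaposinB"]
    finish("Nemapore", None, _assemble(_array_segments(sap, _canonical_spacers(sap), rng)))
    finish("GRSP", None, _grsp_consensus())
    return seed_sets


_HOUSEKEEPING_CONSENSUS_LEN = 120
_HOUSEKEEPING_FAMILY = 5


def default_grsp_reference() -> tuple[list[ProteinRecord], set[str]]:
    """Labelled reference database for the GRSP reciprocal top-5 check.

    Known GRSPs are the GRSP seeds; the rest are the other groups' seeds
    plus a five-member housekeeping-like family, so that a candidate whose
    best matches are all non-GRSP fails the check.
    """
    rng = np.random.default_rng(_SEED_FIXTURE_RNG + 1)
    records: list[ProteinRecord] = []
    known: set[str] = set()
    for seed in default_seed_sets():
        for rec in seed.sequences:
            records.append(rec)
            if seed.group == "GRSP":
                known.add(rec.id)
    consensus = _random_residues(rng, _HOUSEKEEPING_CONSENSUS_LEN, _NON_CYS_NON_GLY)
    for i in range(_HOUSEKEEPING_FAMILY):
        records.append(
            ProteinRecord(id=f"hk_fam{i + 1}", sequence=_mutate(consensus, 0.10, rng))
        )
    return records, known


def housekeeping_consensus() -> str:
    rng = np.random.default_rng(_SEED_FIXTURE_RNG + 1)
    return _random_residues(rng, _HOUSEKEEPING_CONSENSUS_LEN, _NON_CYS_NON_GLY)


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def _seed_for(group: str, subgroup: str | None, seed_sets: list[SeedSet]) -> SeedSet:
    for s in seed_sets:
        if s.group == group and (subgroup is None or s.subgroup == subgroup):
            return s
    raise ValueError(f"no seed set for {group}/{subgroup}")


def _planted_array_mature(
    seed_mature: str,
    m: MotifDefinition,
    mutation_rate: float,
    rng: np.random.Generator,
) -> str:
    """Mutate a seed mature region and re-draw its spacers within range."""
    spacers = _canonical_spacers(m)
    parts = seed_mature.split("C")
    assert len(parts) == m.n_cys + 1, "seed mature must carry the canonical array"
    drawn = [int(rng.integers(lo, hi + 1)) for lo, hi in m.spacers]
    new_parts = [_mutate(parts[0], mutation_rate, rng)]
    for seg, want in zip(parts[1:-1], drawn):
        seg = _mutate(seg, mutation_rate, rng)
        if len(seg) < want:
            pad = _random_residues(rng, want - len(seg))
            cut = int(rng.integers(0, len(seg) + 1))
            seg = seg[:cut] + pad + seg[cut:]
        elif len(seg) > want:
            if want == 0:
                seg = ""
            else:
                cut = int(rng.integers(0, want + 1))
                seg = seg[:cut] + seg[len(seg) - (want - cut):]
        new_parts.append(seg)
    new_parts.append(_mutate(parts[-1], mutation_rate, rng))
    return "C".join(new_parts)


def _grsp_mature(rng: np.random.Generator, length: int | None = None,
                 fraction: float | None = None) -> str:
    """Glycine-rich mature region; glycine fraction drawn U(0.20, 0.60)."""
    L = int(rng.integers(40, 151)) if length is None else length
    g = float(rng.uniform(0.20, 0.60)) if fraction is None else fraction
    n_g = int(round(g * L))
    positions = rng.choice(L, size=n_g, replace=False)
    out = list(_random_residues(rng, L, _NON_CYS_NON_GLY))
    for p in positions:
        out[p] = "G"
    return "".join(out)


def plant_amp(
    group: str,
    subgroup: str | None,
    rng: np.random.Generator,
    seed_sets: list[SeedSet] | None = None,
    motifs: dict[str, MotifDefinition] | None = None,
    mutation_rate: float = 0.10,
    n_domains: int = 1,
    with_furin: bool = False,
    truncate_sp: bool = False,
    record_id: str = "planted",
    genome_id: str = "",
) -> tuple[ProteinRecord, TruthRecord]:
    """Build one planted AMP precursor and its ground-truth row."""
    if group not in AMP_GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if group == "CSab" and subgroup not in CSAB_SUBGROUPS:
        raise ValueError(f"unknown CSab subgroup {subgroup!r}")
    seed_sets = seed_sets if seed_sets is not None else default_seed_sets()
    motifs = motifs if motifs is not None else default_motifs()

    seed_set = _seed_for(group, subgroup, seed_sets)
    seed_mature = str(rng.choice([r.sequence for r in seed_set.sequences]))
    n_sap = 0
    if group == "Cecropin":
        mature = _mutate(seed_mature, mutation_rate, rng)
    elif group == "GRSP":
        mature = _grsp_mature(rng)
        with_furin = False
    elif group == "Nemapore":
        sap = motifs["SaposinB"]
        domains = [
            _planted_array_mature(
                str(rng.choice([r.sequence for r in seed_set.sequences])),
                sap, mutation_rate, rng,
            )
            for _ in range(n_domains)
        ]
        linkers = [
            _random_residues(rng, int(rng.integers(*_LINKER_RANGE)))
            for _ in range(n_domains - 1)
        ]
        mature = domains[0]
        for i in range(1, n_domains):
            mature += linkers[i - 1] + domains[i]
        n_sap = n_domains
    else:  # Diapausin or a CSab subgroup
        array_name = subgroup if group == "CSab" else "Diapausin"
        mature = _planted_array_mature(seed_mature, motifs[array_name], mutation_rate, rng)

    sp = "" if truncate_sp else _signal_peptide(rng)
    pro = _propeptide(rng) if with_furin else ""
    sequence = sp + pro + mature
    if group == "GRSP" and len(sequence) > 200:
        mature = mature[: 200 - len(sp)]
        sequence = sp + mature
    truth = TruthRecord(
        id=record_id,
        genome_id=genome_id,
        planted_group=group,
        planted_subgroup=subgroup or "",
        n_saposin_domains=n_sap,
        has_signal_peptide=not truncate_sp,
        mature_glycine_pct=glycine_fraction(mature),
        sp_cleavage=0 if truncate_sp else SP_LENGTH,
    )
    return (
        ProteinRecord(id=record_id, sequence=sequence, genome_id=genome_id),
        truth,
    )


def make_decoy(
    kind: str,
    rng: np.random.Generator,
    seed_sets: list[SeedSet] | None = None,
    motifs: dict[str, MotifDefinition] | None = None,
    record_id: str = "decoy",
    genome_id: str = "",
) -> tuple[ProteinRecord, TruthRecord]:
    """Build a negative-control protein.

    ``kind='random'`` is a background-composition decoy; the four hard
    kinds each violate exactly one acceptance rule (see
    :data:`HARD_DECOY_TARGET_RULE`) and satisfy the rest.
    """
    motifs = motifs if motifs is not None else default_motifs()
    seed_sets = seed_sets if seed_sets is not None else default_seed_sets()
    group = "decoy" if kind == "random" else "hard_decoy"
    glycine = 0.0
    has_sp = False
    sp_pos = 0
    n_sap = 0

    if kind == "random":
        seq = "M" + _background_sequence(rng, int(rng.integers(79, 400)))
    elif kind == "glycine_rich_long":
        sp = _signal_peptide(rng)
        mature = _grsp_mature(rng, length=250 - len(sp), fraction=0.35)
        seq = sp + mature
        glycine, has_sp, sp_pos = glycine_fraction(mature), True, SP_LENGTH
    elif kind == "glycine_rich_no_sp":
        mature = _grsp_mature(rng, length=int(rng.integers(60, 150)), fraction=0.35)
        seq = "MDD" + mature  # no basic residue / h-region: no signal peptide
        glycine = glycine_fraction(mature)
    elif kind == "saplip_extra_domain":
        sap = motifs["SaposinB"]
        seed_set = _seed_for("Nemapore", None, seed_sets)
        dom = _planted_array_mature(
            str(rng.choice([r.sequence for r in seed_set.sequences])), sap, 0.10, rng
        )
        extra = _random_residues(rng, 60, _NON_CYS)
        seq = _signal_peptide(rng) + dom + _random_residues(
            rng, int(rng.integers(*_LINKER_RANGE))
        ) + extra
        has_sp, sp_pos, n_sap = True, SP_LENGTH, 1
    elif kind == "cys_rich_wrong_spacing":
        dia = motifs["Diapausin"]
        seed_set = _seed_for("Diapausin", None, seed_sets)
        mature = _planted_array_mature(
            str(rng.choice([r.sequence for r in seed_set.sequences])), dia, 0.10, rng
        )
        # stretch the third spacer 3 beyond its maximum: no array matches
        parts = mature.split("C")
        lo, hi = dia.spacers[2]
        parts[3] = parts[3] + _random_residues(rng, (hi + 3) - len(parts[3]))
        seq = _signal_peptide(rng) + "C".join(parts)
        has_sp, sp_pos = True, SP_LENGTH
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")

    truth = TruthRecord(
        id=record_id,
        genome_id=genome_id,
        planted_group=group,
        planted_subgroup="" if kind == "random" else kind,
        n_saposin_domains=n_sap,
        has_signal_peptide=has_sp,
        mature_glycine_pct=glycine,
        sp_cleavage=sp_pos,
    )
    return ProteinRecord(id=record_id, sequence=seq, genome_id=genome_id), truth


# ---------------------------------------------------------------------------
# Full study generation
# ---------------------------------------------------------------------------

def _nemapore_domain_counts(n: int, rng: np.random.Generator) -> list[int]:
    """Mostly single-domain genes plus a multi-domain tail (up to seven)."""
    pattern = [1, 1, 1, 1, 1, 1, 2, 2, 3, 7]
    if n <= len(pattern):
        return pattern[:n]
    return pattern + [int(rng.choice([1, 1, 2, 3]))] * (n - len(pattern))


def generate_study(cfg: SimConfig, out_dir: str | Path | None = None) -> StudyData:
    """Generate the full benchmark corpus; deterministic given ``cfg.seed``.

    Writes, when *out_dir* is given: one proteome FASTA and one TPM table
    per genome, plus ``meta.tsv``, ``truth.tsv`` and ``domains.tsv``.
    """
    seed_sets = default_seed_sets()
    motifs = default_motifs()
    proteomes: dict[str, list[ProteinRecord]] = {}
    truth: list[TruthRecord] = []
    domain_rows: list[tuple[str, str, int, int]] = []
    sap = motifs["SaposinB"]

    csab_cycle = list(CSAB_SUBGROUPS)
    for g in range(cfg.n_genomes):
        gid = f"g{g + 1:02d}"
        rng = np.random.default_rng([cfg.seed, g])
        records: list[ProteinRecord] = []
        idx = 0
        dom_counts = _nemapore_domain_counts(cfg.planted_count("Nemapore"), rng)
        for group in AMP_GROUPS:
            for k in range(cfg.planted_count(group)):
                idx += 1
                subgroup = csab_cycle[k % len(csab_cycle)] if group == "CSab" else None
                rec, tr = plant_amp(
                    group,
                    subgroup,
                    rng,
                    seed_sets=seed_sets,
                    motifs=motifs,
                    mutation_rate=cfg.mutation_rate,
                    n_domains=dom_counts[k] if group == "Nemapore" else 1,
                    with_furin=(
                        group in ("Cecropin", "Diapausin", "CSab", "Nemapore")
                        and rng.random() < cfg.furin_fraction
                    ),
                    truncate_sp=rng.random() < cfg.truncate_fraction,
                    record_id=f"{gid}_{group.lower()}{k + 1:03d}",
                    genome_id=gid,
                )
                records.append(rec)
                truth.append(tr)
                if group == "Nemapore":
                    from .motif_engine import find_motif

                    for match in find_motif(rec.sequence, sap, rec.id):
                        domain_rows.append(
                            (rec.id, "SaposinB", match.start + 1, match.end)
                        )
        # decoys: hard kinds first (counts from fractions), then random
        n_dec = cfg.n_decoys_per_genome
        hard_counts = {
            k: int(round(cfg.hard_decoy_fractions.get(k, 0.0) * n_dec))
            for k in HARD_DECOY_KINDS
        }
        kinds = [k for k in HARD_DECOY_KINDS for _ in range(hard_counts[k])]
        kinds += ["random"] * (n_dec - len(kinds))
        for j, kind in enumerate(kinds):
            rec, tr = make_decoy(
                kind,
                rng,
                seed_sets=seed_sets,
                motifs=motifs,
                record_id=f"{gid}_dec{j + 1:04d}",
                genome_id=gid,
            )
            records.append(rec)
            truth.append(tr)
            if kind == "saplip_extra_domain":
                from .motif_engine import find_motif

                for match in find_motif(rec.sequence, sap, rec.id):
                    domain_rows.append((rec.id, "SaposinB", match.start + 1, match.end))
                domain_rows.append(
                    (rec.id, "Kunitz", len(rec.sequence) - 59, len(rec.sequence))
                )
        proteomes[gid] = records

    meta = [
        SpeciesMeta(
            genome_id=f"g{g + 1:02d}",
            species=f"Simulus_species_{g + 1:02d}",
            clade=_CLADES[g % len(_CLADES)],
            lifestyle=_LIFESTYLES[g % len(_LIFESTYLES)],
            pcg_count=len(proteomes[f"g{g + 1:02d}"]),
            busco_complete=round(
                float(np.random.default_rng([cfg.seed, 1000 + g]).uniform(85, 100)), 1
            ),
        )
        for g in range(cfg.n_genomes)
    ]

    # expression: exactly round(fraction * n_planted) planted genes get at
    # least one stage >= 2 TPM (exact counting, not per-gene sampling)
    planted_ids = [t.id for t in truth if t.planted_group in AMP_GROUPS]
    rng_expr = np.random.default_rng([cfg.seed, 999999])
    n_expressed = int(round(cfg.expressed_fraction * len(planted_ids)))
    expressed = set(
        rng_expr.choice(planted_ids, size=n_expressed, replace=False)
    ) if planted_ids else set()
    tpm: dict[str, ExpressionMatrix] = {}
    for g in range(cfg.n_genomes):
        gid = f"g{g + 1:02d}"
        gene_ids = [t.id for t in truth if t.genome_id == gid and t.planted_group in AMP_GROUPS]
        gene_ids += [f"{gid}_dec{j + 1:04d}" for j in range(min(50, cfg.n_decoys_per_genome))]
        rows = []
        for gene in gene_ids:
            if gene in expressed:
                profile = rng_expr.uniform(0.0, 1.9, size=len(_STAGES))
                profile[rng_expr.integers(len(_STAGES))] = rng_expr.uniform(5.0, 200.0)
            elif gene in planted_ids:
                profile = rng_expr.uniform(0.0, 1.9, size=len(_STAGES))
            else:  # decoy genes: unconstrained housekeeping-like expression
                profile = rng_expr.uniform(0.0, 50.0, size=len(_STAGES))
            rows.append(np.round(profile, 3))
        tpm[gid] = ExpressionMatrix(
            gene_ids=gene_ids, stage_ids=list(_STAGES), tpm=np.array(rows)
        )

    domains = pd.DataFrame(domain_rows, columns=["id", "domain", "start", "end"])
    study = StudyData(proteomes=proteomes, meta=meta, truth=truth, domains=domains, tpm=tpm)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gid in sorted(proteomes):
            write_fasta(proteomes[gid], out / f"{gid}.fasta")
            write_tpm(tpm[gid], out / f"{gid}.tpm.tsv")
        write_species_meta(meta, out / "meta.tsv")
        truth_df = pd.DataFrame(
            [
                (
                    t.id, t.genome_id, t.planted_group, t.planted_subgroup,
                    t.n_saposin_domains, t.has_signal_peptide,
                    t.mature_glycine_pct, t.sp_cleavage,
                )
                for t in truth
            ],
            columns=[
                "id", "genome_id", "planted_group", "planted_subgroup",
                "n_saposin_domains", "has_signal_peptide",
                "mature_glycine_pct", "sp_cleavage",
            ],
        )
        write_tsv(truth_df, out / "truth.tsv")
        write_tsv(domains, out / "domains.tsv")
    return study


def read_truth(path: str | Path) -> list[TruthRecord]:
    df = read_tsv(path)
    return [
        TruthRecord(
            id=r.id,
            genome_id=r.genome_id,
            planted_group=r.planted_group,
            planted_subgroup=r.planted_subgroup,
            n_saposin_domains=int(r.n_saposin_domains),
            has_signal_peptide=r.has_signal_peptide == "True",
            mature_glycine_pct=float(r.mature_glycine_pct),
            sp_cleavage=int(r.sp_cleavage),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Purpose-built fixtures
# ---------------------------------------------------------------------------

def grsp_gate_fixture() -> list[tuple[ProteinRecord, bool, str]]:
    """Eight constructed precursors probing the GRSP acceptance gate.

    Returns (record, should_accept, description) triples: three designed
    accepts (clear pass, pass at exactly 200 aa, pass just above 17%
    glycine), four single-rule failures (length, signal peptide, glycine at
    exactly 17.00%, reciprocal top-5) and one incomplete sequence that is
    retained in output but never accepted as authentic.
    """
    rng = np.random.default_rng(_SEED_FIXTURE_RNG + 2)
    sp = _signal_peptide(rng)
    out: list[tuple[ProteinRecord, bool, str]] = []

    mature = _grsp_mature(rng, length=120, fraction=0.40)
    out.append((ProteinRecord(id="grsp_pass", sequence=sp + mature), True, "clear pass"))

    long_mature = _grsp_mature(rng, length=250 - len(sp), fraction=0.40)
    out.append(
        (ProteinRecord(id="grsp_fail_length", sequence=sp + long_mature), False,
         "precursor 250 aa > 200")
    )

    out.append(
        (ProteinRecord(id="grsp_fail_sp", sequence="MDD" + mature), False,
         "no signal peptide")
    )

    m17 = _grsp_mature(rng, length=100, fraction=0.17)  # exactly 17.00%
    out.append(
        (ProteinRecord(id="grsp_fail_glycine_17", sequence=sp + m17), False,
         "glycine exactly 17.00% fails the strict >17 gate")
    )

    hk = housekeeping_consensus()  # best hits: the 5-member non-GRSP family
    hk_mature = list(hk)
    n_g = int(round(0.18 * len(hk_mature)))
    for p in rng.choice(len(hk_mature), size=n_g, replace=False):
        hk_mature[p] = "G"
    out.append(
        (ProteinRecord(id="grsp_fail_reciprocal", sequence=sp + "".join(hk_mature)),
         False, "top-5 reference hits are all non-GRSP")
    )

    m200 = _grsp_mature(rng, length=200 - len(sp), fraction=0.40)
    out.append(
        (ProteinRecord(id="grsp_pass_200aa", sequence=sp + m200), True,
         "precursor exactly 200 aa passes the <=200 rule")
    )

    m_just = _grsp_mature(rng, length=182, fraction=31 / 182)  # 17.03%
    out.append(
        (ProteinRecord(id="grsp_pass_just_above_17", sequence=sp + m_just), True,
         "glycine just above 17% passes the strict gate")
    )

    out.append(
        (ProteinRecord(id="grsp_incomplete_retained", sequence="M" + mature[:80]),
         False, "incomplete (no SP): retained with complete=False, not accepted")
    )
    return out


def simulate_lifestyle_counts(
    rng: np.random.Generator,
    n_per_group: int = 15,
    base_rate: float = 25.0,
    fln_effect: float = 4.0,
) -> dict[str, np.ndarray]:
    """Per-genome AMP counts with a planted lifestyle effect.

    Free-living genomes draw from a Poisson with ``fln_effect`` times the
    parasitic rate, mirroring the enriched free-living repertoires.
    """
    return {
        "FLN": rng.poisson(base_rate * fln_effect, size=n_per_group).astype(float),
        "APN": rng.poisson(base_rate, size=n_per_group).astype(float),
        "PPN": rng.poisson(base_rate, size=n_per_group).astype(float),
    }
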