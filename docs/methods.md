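# Methods

This note documents the models and procedures implemented in `nemamp`,
the parameters that matter, the synthetic benchmark's scope, and the
design choices made where the design was genuinely open.

## Similarity engines

**Profile models.** A seed set per AMP group (and per CSαβ subgroup) is a
small multiple alignment of curated mature peptides. Match states are the
alignment columns with gap fraction below 0.5. Emissions are observed
residue counts plus one pseudo-observation distributed as the background
amino-acid frequencies (Robinson–Robinson), converted to log-odds in
bits. A flat +1-per-residue pseudocount was rejected: with half a dozen
seeds it hands rare residues (W, C) larger log-odds than the observed
consensus. Transitions use a fixed scheme — insertion −2.0 bits,
deletion −2.5 bits — rather than estimated probabilities; at seed-set
sizes of six there is nothing to estimate them from.

Scoring is local (Smith–Waterman over match states with the linear
insert/delete scheme); the empty alignment scores 0, and an `X` residue
can never reward a match state (fixed −1-bit emission). The row-wise
dynamic programme is vectorised with a max-plus prefix scan for the
in-row insertion recurrence; a plain traceback version supplies aligned
intervals and state coverage for gate-passing hits only.

**E-values.** The null score distribution is modelled as a Gumbel tail,
`E(s) = K · N · exp(−λ·s)` with N in database residues. λ and the
location are fitted by the method of moments on the scores of 200 random
decoy sequences (length 150) drawn from the background composition; K is
scaled so N counts residues. Degenerate score variance is an error. The
same machinery calibrates raw pairwise BLOSUM62 scores, with the search
space for a pairwise hit taken as query length × total database residues
— database-wide semantics, as in a protein-vs-database search. Per-pair
E-values were tried and rejected: they are hundreds of times too
permissive and let chance hits seed expansion cascades.

**Pairwise alignment.** Local BLOSUM62 alignment with affine gaps, gap of
length k costing 11 + k. The production path is Biopython's
`PairwiseAligner`; the test suite holds it to exact integer equality
against an independent three-matrix Gotoh dynamic programme on random
pairs.

## Motif engine

A cysteine array is data: name, cysteine count, inclusive (min, max)
spacer ranges between consecutive cysteines, and putative disulfide
connectivity (metadata only; matching never consults it). The shipped
`data/motifs.json` arrays derive from the packaged seed alignments — the
canonical observed inter-cysteine gaps widened by ±2 residues, floored at
0 — and were additionally designed to be *mutually exclusive*: every
array has at least one spacer range disjoint from every aligned window of
every other array, so a planted subgroup can never legitimately match two
arrays. Every pipeline report records the motif-set checksum.

Matching semantics, fixed after an explicit failure mode: spacer windows
are cysteine-free, i.e. an array occupies a run of *consecutive*
cysteines. Allowing arrays to skip interior cysteines lets a 10-cysteine
Macin satisfy the 6-cysteine Diapausin or Saposin B definitions through
its own interior cysteines, producing systematic cross-group calls.
Matches are non-overlapping and leftmost-greedy (ordered by first
cysteine, then span end, then lexicographic tuple; scanning resumes after
an accepted match's last cysteine) because domains are counted as
discrete units per gene. `X` may appear inside a spacer but never stands
for a cysteine. A brute-force enumerator over all increasing cysteine
tuples (guarded at ≤ 20 cysteines) is the oracle the scanner is tested
against, and every reported match re-validates literally against its
definition during the pipeline audit.

CSαβ classification evaluates all five reference arrays; exactly one
match gives the subgroup, several give an explicit `ambiguous` call
(never silently tie-broken), none gives no call. The nematode Macin array
is fixed at ten cysteines (configurable in the motif file; other phyla
show eight to twelve).

## Maturation

The external neural-network predictors used for signal peptides and
propeptides are not reimplemented. The defaults are transparent rules —
n-region with ≥ 1 K/R in the first five residues, a ≥ 7-residue window of
mean Kyte–Doolittle hydropathy ≥ 1.6, and an `[AGSTC]-X-[AGST]` cleavage
triplet after the h-region, searched within the first 35 residues; furin
sites are `R-X-[KR]-R` with cleavage after the final arginine. Adapter
TSVs override the heuristic with real predictor output, and every result
records which mode produced it. The mature peptide starts after the last
furin site between the signal peptide and the group's motif; sequences
without a signal peptide are retained whole with `complete=False`.

GRSP gate semantics: precursor length ≤ 200 amino acids applies to the
full predicted protein; glycine content is strictly greater than 17%
(exactly 17.00% fails) and is computed after signal-peptide removal only
— propeptides are rarely annotated in GRSPs, so no propeptide step is
applied there (configurable point left as a single code path).

## Pipeline

Per group: profile search → E-gate (`E < 0.01`; GRSPs assessed up to
`E = 10`) → group rule → iterative expansion → CSαβ subgroup call →
maturation → candidate table. "High peptide similarity" is
operationalised as alignment coverage ≥ 60% of the profile (or pairwise
query) length; this threshold is a config default and is echoed in the
run report as an interpretation, not a published cutoff.

Expansion uses each accepted candidate's *mature* region as the pairwise
query. Full precursors were tried first and chained unrelated proteins
through signal-peptide-only similarity (canonical signal peptides are
generically hydrophobic and score 50–65 raw against each other). Targets
are pre-screened to proteins whose profile score comes within 15 bits of
the intake gate (`prescreen_margin_bits`); this two-stage gate keeps
near-miss homologs searchable while cutting the all-vs-all cost roughly
tenfold. Expansion is a monotone fixed point — accept verdicts are pure
and memoized — and terminates either at convergence or at `max_rounds`
with an explicit flag.

A protein accepted by two groups is reported once per group with a
cross-flag (no precedence rule exists). The run report carries per-stage
counts, convergence rounds, the motif checksum, a config echo, and an
audit that re-validates every accepted candidate's stored evidence
against its rule set. The relatives re-scan is protein-level only: for a
(genome, group) with zero candidates, neighbours' accepted candidates are
re-used as queries; hits must still pass the group rule to be flagged
`rescued`, otherwise the genome is marked `confirmed_null`.

## Synthetic benchmark

The generator defines the study conditions: 6 genomes × (500 decoys + 10
planted per group), mutation rate 0.10, four hard-decoy classes at 1% of
decoys each, expressed fraction 0.86, furin propeptides on half the
cysteine-motif plants. Planted precursors are a canonical tripartite
signal peptide (cleavage after residue 16), an optional `R-X-K-R`
propeptide, and a mature region that is a seed mature mutated per-residue
under a BLOSUM62-conditional substitution model (cysteines and
signal/propeptide boundaries never mutated) with inter-cysteine spacers
re-drawn uniformly within the configured ranges. Anchoring plants on
seeds is deliberate: a mature region random everywhere except its
cysteine skeleton is not retrievable by profile search at any sane gate,
and planted AMPs must sit in the similarity basin of their group — the
same reasoning that applies to Cecropins, which are accepted on
similarity alone. GRSP matures draw their glycine fraction from
U(0.20, 0.60) by exact count placement. Multi-domain Nemapores join
Saposin B domains with 16–24-residue linkers, chosen so no cysteine
window spanning a boundary can satisfy any reference array.

Each hard-decoy class violates exactly one rule: glycine-rich at 250 aa
(length), glycine-rich without a signal peptide (SP), a Saposin domain
plus an annotated extra domain (SAPLIP exclusion), and a Diapausin-like
array with one spacer three residues beyond its maximum (motif). The
expressed fraction is planted by exact counting — `round(0.86·n)` genes
get one stage ≥ 2 TPM — not by per-gene sampling.

What the generator does **not** emulate: real per-clade abundance
distributions, genome mis-annotation beyond an optional
signal-peptide-truncation flag, nucleotide-level structure, and the
compositional quirks of real proteomes (decoys are i.i.d. background).
Passing the recovery tests therefore demonstrates that the rules,
engines and bookkeeping are implemented correctly under the stated
generative model — not that the pipeline would achieve the same
sensitivity on real predicted proteomes, where annotation errors and
divergent homologs dominate.

All randomness flows from one master seed; per-genome streams are derived
with fixed offsets, so corpora are byte-identical across runs and
platforms.

## Statistics and expression

Kruskal–Wallis uses the tie-corrected H with a χ² reference (df = k−1);
Dunn's pairwise z statistics share the tie correction and are
Bonferroni-adjusted by default (Šidák and unadjusted are config options,
and the flavour is recorded in outputs since conventions differ across
software). Normality testing is a Lilliefors-corrected one-sample KS
against a normal with estimated parameters; because that null is not the
classical KS distribution, p-values come from seeded Monte Carlo (10⁴
samples re-estimating parameters each time, vectorised). SEM uses the
sample standard deviation (n−1); single-genome groups report SEM 0 with
an explicit flag rather than being dropped. Statistics are computed per
genome; a species-collapse mode would take the highest-BUSCO assembly.

Expression calls use the inclusive threshold ≥ 2 TPM in at least one life
stage (a caption elsewhere reads "> 2"; the Methods wording "≥ 2" is
treated as normative and the discrepancy noted here). Heatmap matrices
are log2(TPM+1), per-row Z with sample sd; constant rows are flagged and
zeroed rather than dropped. Row order comes from an in-package
agglomerative average-linkage clustering on Euclidean distances with a
deterministic lowest-index tie-break (library linkage functions do not
pin tie behaviour); clustering operates on the Z rows, and only the
linkage table and leaf order are emitted — rendering is out of scope.

## Problem sizes and tolerances

The shipped benchmark (6 × 550 proteins) runs the full pipeline in about
two minutes on one CPU; the test suite uses a 2-genome corpus for
behavioural tests and shares a single full-corpus run session-wide.
Oracle comparisons demand exact equality (integer alignment scores, motif
position tuples); floating checks use 1e-9 for row standardisation and
0.5 percentage points for glycine-content agreement with generator
truth. Calibration bands: Kruskal–Wallis empirical type-I error in
[0.04, 0.06] over 2000 simulations at α = 0.05.

## Known limitations

- The profile scorer is a lightweight PSSM with fixed gap scores, not a
  full profile HMM; no Forward-algorithm E-values, no glocal mode.
- E-value calibration by moments on 200 decoys carries sampling noise of
  a few percent in λ; gates sit far from the planted score distribution,
  so this does not affect recovery under the benchmark conditions.
- Orthology assignment, translated (genome-level) searches, cluster-map
  layout, domain scanning and antimicrobial-propensity scoring are out of
  scope; the last two enter only through user-supplied TSVs.
- Real seed sequences are not distributed; the packaged seed sets are
  synthetic fixtures generated deterministically, and users can substitute
  their own curated FASTA/alignments.
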