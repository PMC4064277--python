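# Methods

## Model

`runalign` computes optimal pairwise alignments of nucleotide sequences
under a scoring model in which a run of *n* consecutive matching bases
contributes *f(n)* for an arbitrary non-decreasing contiguity function
*f* with *f(0) = 0*, while mismatches and gaps carry the usual fixed
penalties (ρ_m per mismatch column; ρ_o + k·ρ_e for a k-column affine
gap, or k·ρ_e under the linear gap model). Because *f* need not be
linear, the dynamic program cannot collapse a match run into per-column
increments: the edit graph carries a third dimension of *depth nodes*,
one per possible trailing-run length at each cell. Depth at cell (i,j)
equals the matching-suffix length d(i,j) and nodes are allocated on
demand, so memory and time grow over the classic scheme only by the
average contiguity of the data (a small constant for diverged DNA). With
a linear *f* the increment is constant, a single depth node suffices,
and the recurrence is *exactly* classic Smith–Waterman (linear gaps) or
Gotoh (affine gaps) — the test suite asserts bit-identical scores
against independently written textbook implementations.

Local mode includes a restart-at-zero alternative in the cell maximum
and traces back from the matrix argmax; global mode removes that
alternative and charges boundary rows/columns as gaps
(−(ρ_o + k·ρ_e) affine, −k·ρ_e linear).

### Interpretation choices the recurrence leaves open

Three points are underdetermined by the recurrence as usually written
and are fixed here as follows:

* **Match after gap/mismatch.** A fresh run (depth node n = 1) is seeded
  from the predecessor cell's *zero-contiguity* value — the best arrival
  there via mismatch, either gap state, or local restart. A literal
  reading that seeds n = 1 only from the mismatch state would forbid a
  match directly following a gap, which cannot be right for an optimal
  aligner.
* **Gap anchoring.** Gap openings depart from the cell-best (so a gap
  may open immediately after a match run of any depth), not from the
  zero-depth state only.
* **Gap-open accounting.** Opening costs ρ_o + ρ_e for the first gap
  column; extension costs ρ_e per further column. The linear gap model
  is the same machinery with ρ_o treated as 0.

### Determinism

Traceback tie-breaks prefer, in order: deeper match node, mismatch,
vertical gap, horizontal gap, local restart; gap traceback prefers
extending an existing gap over re-opening when scores tie; among
equal-scoring local maxima the cell with smallest row, then column,
wins; a local optimum of exactly 0 returns the empty alignment. All
scores are exact Python integers whenever *f* and the penalties are
integral; otherwise floats compared with absolute tolerance 1e-9.
`N` never matches anything, including another `N` (masking convention);
lowercase input is uppercased; IUPAC ambiguity codes other than `N` are
rejected because partial-match semantics are undefined in this model.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| f | contiguity function | cubic n³ | steep enough to favour compact motifs, shallower than exponential; presets: `linear:c`, `quadratic`, `cubic`, `exp:b`, tabulated |
| ρ_m | mismatch penalty | 8 | with cubic f, two consecutive matches equal one mismatch |
| ρ_o | gap open | 200 | gaps are rare, costly events |
| ρ_e | gap extend | 20 | three consecutive matches outscore one extension |
| c | linear match reward in `sw`/`swga` presets | 1 | the conventional unit reward; the classic schemes' original constant is not dictated by the model, so this is a package default, flagged as such |
| band_width | diagonal band half-width | unbanded | band is centred on the resampled diagonal joining (0,0)–(N,M); off-band cells are never created |
| depth_cap | cap C on depth nodes | unbounded | when set, Δf(n) = Δf(C) for n > C and deeper nodes merge; bounds memory against pathological perfect runs |
| checkpoint_interval | linear-space row stride | ceil(√N) | balances recompute passes against retained rows |

Tabulated contiguity functions extend past their last entry with the
final increment. `f(0) = 0` is fixed by definition so that a run of
length n scores exactly f(n).

## Linear-space traceback

The check-pointing variant stores a full-state row (all depth nodes,
both gap states, the zero state and depth) every `checkpoint_interval`
rows during the forward pass, keeping otherwise only the previous row.
Traceback recomputes the block between the current row and the nearest
checkpoint below, traces through it, and moves down block by block.
Because checkpoints hold complete state, recomputation is exact and the
output is bitwise identical to the full matrix; peak retained rows are
bounded by 2 + ceil(N/interval) checkpoints plus one working block of
`interval` rows (instrumented and asserted in the tests). Storing
reduced (cell-best only) checkpoints would shrink the constant further
at the cost of re-deriving depth state; completeness was chosen over
the smaller constant.

## Consistency metrics

Given one reference and per-genome pairwise alignments to it, a
`MatchMatrix` records, per genome, which reference positions are
*covered* (inside the reported alignment; deletion columns in the genome
still cover) and *matched* (aligned and identical). Derived measures:

* **agreement profile** — fraction of genomes matching at each position.
  The denominator defaults to *covered genomes* (a literal reading of
  agreement "among the aligned genomes"); all-genomes is available. A
  position covered by no genome is undefined (NaN) and excluded from
  histograms and elements.
* **agreement histogram** — normalised position counts per agreement
  bin; counts are divided by total covered positions before any
  baseline subtraction, so two histograms over the same denominator
  subtract to zero-sum differences.
* **conserved elements** — maximal runs of ≥ `min_len` positions with
  agreement ≥ `min_frac` (boundary-equal positions are inside; defaults
  6 and 0.9, the poly-adenylation-signal setting).
* **k-mer tallies** — overlapping windows fully inside elements, on the
  reference strand only (no reverse complement).
* **method summary** — matched nucleotides (summed over genome ×
  position cells), element count, sequence in elements and a focal
  k-mer count per method, computed after intersecting every genome's
  coverage across all compared methods so that methods are judged on
  common ground.

## Synthetic families and oracles

The generator emulates an ortholog family around a reference that
carries planted conserved motifs: uniform random reference, `n_motifs`
copies of the motif written at non-overlapping positions at least one
motif length apart, and per-genome divergence by independent
substitutions (rate `flank_sub_rate` in flanks, `motif_sub_rate` inside
motifs) and flank-only indels (per-position rate `flank_indel_rate`,
geometric lengths). Defaults (300 bp reference, 10 genomes, 3 × AATAAA,
rates 0.3 / 0.02 / 0.01) describe the regime the consistency metrics
target: flanks near the twilight zone for linear scoring, motifs almost
always intact. Divergence is star-shaped and indels never touch motif
positions, so the planted truth (motif intervals plus per-genome
substitution-free flags) is exact. The generator does **not** model
phylogenetic correlation between genomes, rate heterogeneity along the
sequence, or realistic indel-length mixtures — passing tests show the
metrics and engine behave as designed under this controlled regime, not
that any scheme is superior on real genomes.

Two independent oracles validate the engine. The enumerator walks every
monotone edit-graph path (from every start cell, in local mode) scoring
them by the run-length semantics of `rescore`; it is exponential and
used exhaustively at sequence lengths ≤ 4. The path-state DP tracks
(exact trailing-run length, last operation) per cell — polynomial, no
depth-node machinery — and is cross-validated against the enumerator on
the exhaustive small set before standing in for it at lengths up to 8.
The engine must agree with both, for all four presets, local and
global.

## Problem sizes in the shipped checks

The test suite and acceptance script run at desk scale, chosen to
exercise every code path while keeping runs quick: exhaustive oracle
comparison over all pairs of length ≤ 4 (deduplicated by match matrix,
which fully determines the score), 500 random pairs ≤ 8 against the
path-state oracle, 1000 random pairs ≤ 60 for SW/SWGA bit-compatibility,
200 pairs for banded/linear-space bitwise equivalence, and 50 simulated
families (banded at half-width 60, generous against the ±~12 expected
indel drift) for the directional motif-recovery comparison between the
cubic-affine and SW pipelines.

## Known limitations

* The engine is pure Python; throughput is a few hundred thousand cells
  per second. Fine for motif-scale and gene-scale sequences, not for
  chromosome-scale alignment without banding.
* Nucleotide match/mismatch only; no substitution matrices, protein or
  translated alignment, and no seed-and-extend heuristics (the engine is
  a back-end for optimal alignment, not a seeder).
* The consistency histogram CLI output currently supports a single
  reference record per run; the library handles arbitrary sets.
* Whether "matched nucleotides" should sum over genome × position cells
  or distinct reference positions is ambiguous in general; the summary
  sums over cells, documented here.
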