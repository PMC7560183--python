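# Methods

This note documents the models and procedures implemented in `oacgh`,
the parameter defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical decisions that
affect results.

## Coordinates

Internal coordinates are 0-based half-open everywhere; file I/O and
printed reports use 1-based inclusive coordinates, the convention of
genome browsers and published positional statements. The printed span
of an interval is `end_1based − start_1based`. Conversion happens only
at the I/O border, so internal arithmetic never mixes conventions.

## Thermodynamic model

Melting temperature uses nearest-neighbor thermodynamics with the
unified SantaLucia parameter set (via Biopython's `Tm_NN`), with the
entropic salt correction `ΔS += 0.368·(N−1)·ln[Na+]`. Defaults:

| parameter | default | rationale |
|---|---|---|
| Na+ | 300 mM | a high-salt hybridization condition; places AT-rich (~36% GC) 60-mers in the 71–85 °C band characteristic of long-oligo aCGH designs |
| strand concentrations | 25 nM each | conventional oligo duplex assumption |
| Tm tolerance | 2.0 °C | "consistent with the template" operationalized; configurable |
| GC tolerance | 0.05 | five percentage points; configurable |
| probe length bounds | 45–75 nt | a window around the ~60-mer design length |

GC content is the G+C fraction of the probe; sequences containing N are
not designable and are rejected. Both quantities are invariant under
reverse complement (the NN table is symmetric for Watson–Crick
duplexes), which the test suite verifies numerically.

**Probe adjustment** searches all windows that overlap the orthologous
core, lie within the available flanking context and the length bounds,
and contain no N. GC prefix sums prune GC-infeasible windows before any
Tm evaluation. A core already within both tolerances is returned
unchanged. Otherwise the feasible window minimizing |ΔTm| wins, ties
broken by |ΔGC|, then by least positional shift from the core — a
deterministic rule that keeps probes centered on their ortholog. On
contexts ≤ 200 nt the search is exhaustive by construction, and the
test suite checks it against an independent brute-force enumeration.

## Migration pipeline

Per template probe:

1. **Extension**: the probe interval plus 100 nt per side (clipped at
   chromosome ends), giving ≈260 nt contexts for 60-mers.
2. **Ortholog search**: a k-mer seeded (k = 11) search over all target
   scaffolds. Seed hits on one scaffold within a query length of each
   other form a candidate locus; each locus window is aligned with
   exact affine-gap local dynamic programming (match +2, mismatch −3,
   gap open −7 for the first gapped base, −2 per further base —
   blastn-style values suited to ~75% nucleotide identity). A hit
   requires identity ≥ 0.75, an alignment spanning ≥ 50% of the query,
   and a best score ≥ 1.1× the runner-up on a distinct locus; otherwise
   the probe fails as `no_alignment` or `ambiguous_map`. Only the plus
   strand is searched: template probes are treated as plus-strand
   sequences and the synthetic divergence model has no inversions.
3. **Core extraction**: target positions aligned to the template
   probe's columns define the target core (gaps drop out, so indels
   shrink or stretch it); fewer than 80% of core columns aligned is a
   failure.
4. **Classification**: an identical core is `exact_match`; a core
   already within both tolerances is `direct_ortholog`; otherwise the
   adjustment search runs with 100 nt target flanks (`adjusted` /
   `failed_adjust`).
5. **Uniqueness remap**: every successful candidate is re-searched
   against the whole target with k = 8 seeds. A locus counts as a near
   match at ≥ 90% identity over the candidate's full length; anything
   other than exactly one such locus demotes the record to
   `ambiguous_map`. For a 60-mer within 10% divergence, a preserved
   exact run of ≥ 8 nt is guaranteed by pigeonhole, so k = 8 cannot
   miss a near-duplicate.

The `Ledger` follows design-accounting semantics: the five pipeline
classes (`no_alignment`, `exact_match`, `direct_ortholog`, `adjusted`,
`failed_adjust`) partition the input, and `ambiguous_map` counts the
candidates excluded by the remap, so `final = exact + direct + adjusted
− ambiguous`. A probe whose *primary* search was ambiguous is counted
under `no_alignment` (no robust unambiguous alignment) at ledger level
while its per-probe record still says `ambiguous_map`.

The alignment engine is a pluggable strategy; the identity, coverage
and margin thresholds are explicit configuration, not a claim about any
particular published pipeline's internal settings.

## Design QC

Spacing is the start-to-start distance between consecutive probes, so N
probes yield N−1 intervals and mean spacing ≈ chromosome span/(N−1) —
the common array convention. `probes_per_mb = round(count/(size/1e6))`.
Outlier intervals exceed the Tukey fence Q3 + 1.5·IQR with
linear-interpolation quartiles (configurable in principle; the common
"type 7" definition). Totals rows report mean spacing and probes/Mb
both as the unweighted mean of per-chromosome values (the convention of
the published design summary, labelled "paper-style") and as pooled
genome-wide values. Coverage fractions are strict (`< threshold`), and
the count above the largest threshold is strict as well.

## Segmentation and calling

Chromosomes are segmented independently by least-squares binary
segmentation: recursively accept the split that most reduces the
residual sum of squares while the reduction exceeds a BIC-style penalty
`2·σ²·ln(n)`, with σ estimated robustly per chromosome from the median
absolute successive difference (`MAD_diff/(0.954·√2)`). A small floor
(1e−8) on the penalty absorbs floating-point dust so noise-free
piecewise-constant tracks are recovered exactly. The engine is a named,
swappable strategy (`segment_track(..., strategy=...)`).

Calling applies inclusive thresholds exactly as printed — gain ≥ 0.201,
loss ≤ −0.234, high-amplitude ≥ 1.14 and ≤ −1.1, with the high
thresholds taking precedence — and a minimum window of 3 consecutive
probes. Runs shorter than the minimum are merged into the neighboring
segment with the closer mean (tie → left). The state of a merged
segment is decided by its *core* probes — those belonging to a
legitimate ≥ min-window run — so a 2-probe spike can contribute to a
segment's reported mean but can never drive its call across a
threshold. Two sub-minimum runs that coalesce into a window-sized run
become callable as a unit. A whole chromosome shorter than the minimum
window is reported as a single uncalled (balanced) segment.

Gene annotation reports a gene for a segment iff their intervals
overlap by ≥ 1 bp in half-open arithmetic; a shared boundary with zero
overlap does not count.

## Sex-mismatch analysis

Chromosome means are plain arithmetic means over probes, with optional
exclusion of one interval (the PAR, when summarizing X-specific
dosage). On noise-free simulated data the X-specific mean equals
log2(2/1) = 1 and the autosomal mean 0 exactly.

**PAR boundary.** The boundary is reported as the open window between
the last probe of the balanced head and the first probe of the first
sustained gained run — the resolution probe spacing allows — rather
than a point estimate. The default detector works on the segmented
track: the first gain-called segment of ≥ k probes (k defaults to the
calling minimum window, 3) whose following `max(2k, 6)`-probe window
also clears the gain threshold marks the transition. The confirmation
window matters at realistic noise (sd 0.15): without it, an isolated
3-probe noise cluster in a ~300-probe balanced head occasionally passes
as the boundary, while a genuine transition to a log2 = 1 region always
confirms. A literal consecutive-probes rule (`strategy="runs"`) is
available and agrees on noise-free data. A coarse, segment-level
containing interval and the fine flanking-probe window are two views of
the same transition; both are derivable from the returned boundary and
the segmentation.

Discordant autosomal regions are simply the non-balanced called
segments of the autosomal track, reported with probe counts and spans.

## Profile comparison

Comparison is on the probe grid, not on base pairs, so unequal segment
boundaries need no interval algebra: each probe takes its called state
under each profile (positions not covered by a segment count as
balanced), concordance is the fraction of probes with identical state,
and maximal runs of probes with the same disagreeing state pair form
discordant regions, annotated with the mean difference of the two
segment means over the region. A bp-weighted concordance (each probe
weighted by half the spacing to its neighbors) is also reported, and a
3-level option collapses high-amplitude calls into gain/loss for
qualitative comparisons. Concordance is symmetric, and swapping the
profiles swaps region states and negates amplitude differences.

## Synthetic data: what it emulates, and what not

* **Genome pairs**: i.i.d. uniform template sequence; uniform per-base
  substitutions (default 2–3% in tests), indels at per-base rate
  0.1–0.2% with geometric(0.5) lengths, and whole 4 kb blocks deleted
  or duplicated. Duplicated blocks place a verbatim copy of their
  *target* sequence on a decoy scaffold (N-spaced), so migrated probes
  from them are guaranteed ambiguous. The truth object records per-base
  edit positions and the block orthology map, and derives each probe's
  expected fate (missing / duplicated / conserved / diverged). Fate
  agreement is asserted at ≥ 95%, not 100%: indel-placement ambiguity
  at core edges and probes straddling block boundaries make a few
  probes' fates genuinely ambiguous.
* **Probe tiling**: start-to-start gaps Uniform(0.5, 1.5)×spacing, so
  the realized mean converges to the target; N windows skipped. Test
  genomes use ~1.5–2 kb spacing to keep probe counts near 50–100 per
  run; the array-scale default is the design's 22.6 kb.
* **CGH tracks**: per-probe log2 = truth level + i.i.d. Gaussian noise,
  default sd 0.15 (stated in every test). Real array noise is heavier
  tailed, spatially correlated (wave artifacts) and intensity
  dependent; passing tests therefore demonstrate the calling contract
  and estimator behavior under the stated noise model, not robustness
  to every artifact of scanner data.
* **Sex-mismatch**: X of 20 Mb with a 7 Mb balanced PAR head and two
  10 Mb autosomes at 23 kb spacing — the real chromosome's geometry
  scaled to desk size; no centromere gap, no repeat structure, no
  intensity-level physics.

These sizes keep the full test suite around ten seconds on one CPU
while leaving every statistical margin wide (e.g. boundary-recovery
probability, segment-mean standard errors).

## Reference constants

The published per-chromosome probe-distribution table of the feline
110,456-probe design and the migration stage counts of its derivation
from the 171,534-probe canine template are embedded as constants
(`designqc.FELINE_ARRAY_TABLE`, `designqc.FELINE_DESIGN_LEDGER`). They
are inputs to the report arithmetic — the package recomputes every
derived figure (totals, percentages, stage identities) from them and
asserts the reproductions in the acceptance tests.

## Known limitations

* Plus-strand-only ortholog search; inversions between template and
  target are not handled.
* No secondary-structure or cross-hybridization screening of candidate
  probes; no repeat library (repeat masking is the caller's
  responsibility).
* The seeded aligner is exhaustive only over loci sharing an exact
  k-mer with the query; homology below ~70% identity with no conserved
  11-mer can be missed, which is the intended "no robust alignment"
  regime.
* Segmentation assumes independent Gaussian noise per probe; no wave
  correction, recentering beyond the autosomal median, or tumor
  purity/ploidy modeling.
* Concordance of paired profiles is a formalization for which no
  published numeric counterpart exists; it is not a reproduction.
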