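# Methods

## Flank segments and leaflet assignment

The lipid-water interface is operationalized purely from a transmembrane
topology table: for each TM span `(s, e)` (1-based inclusive) the N-side
flank is `[s-flank_len, s-1]` and the C-side flank `[e+1, e+flank_len]`,
clamped at the sequence termini but **never** truncated at loop
boundaries — when a loop is shorter than `flank_len` the flank simply runs
into the neighbouring helix (rat TRPV1's 2-residue TM3–TM4 loop makes the
TM3 C-flank and TM4 N-flank share positions 533–534, which is why the
12 × 5 = 60 multiset positions reduce to 58 unique ones). Keeping the
topology table as the single normative input makes the pipeline
structure-free: alternative boundary sets derived from membrane-embedded
structures are supplied as different topology files, not computed here.

Leaflet labels follow strand directionality: the chain starts on the
`n_term_side` of the membrane and alternates with each crossing, so for a
cytoplasmic N-terminus the inner-leaflet set is {TM1N, TM2C, TM3N, TM4C,
TM5N, TM6C} and the outer set its complement; flipping `n_term_side` flips
every label (an involution, property-tested).

Residues of orthologs are taken by **alignment-column projection**: the
segment's reference positions are mapped to the columns where the reference
row is ungapped, and every sequence contributes its residues at those
columns (gaps stripped and counted). Pooling is `multiset` by default
(overlapping flank positions count once per segment, giving the 60-residue
pool per sequence); `dedup` keeps each reference position once and serves
single-sequence composition statements.

## Divergence

Pairwise divergence is the uncorrected p-distance with pairwise deletion:
`d(a,b) = #{i : a_i ≠ b_i} / #{i : a_i, b_i both standard}`, where columns
containing `-` are skipped per pair. `X` (unknown residue) is treated like
a gap — it is excluded from distance denominators and from all frequency
denominators; the alternative (counting `X` as always-mismatching) would
conflate missing data with divergence. A pair with zero comparable sites
raises rather than returning 0. No model-based corrections (Poisson, JTT)
are offered: at the within-vertebrate divergences involved, p-distance is
the measure of record for this analysis style.

Bootstrap variance resamples alignment columns with replacement to the
original length, within the analysed region only (each region is its own
alignment for resampling purposes), and reports per-pair variance/SE over
replicates; results are bit-reproducible given `(reps, seed)` via
`numpy.random.default_rng`. Boxplot summaries use numpy's linear-
interpolation quartiles with Tukey 1.5×IQR outliers and whiskers at the
most extreme non-outlier values.

Per-column position frequency matrices count standard residues only
(gap and `X` tallied separately), and information content is
`IC = log2(20) − H` bits with no small-sample correction — the plain
logo-height convention; empty columns yield NaN, flagged. PFM/IC are
exported as TSV for external logo renderers; no rendering is done here.

Rank tests (Kruskal–Wallis with tie correction and chi-square p on k−1 df;
Mann–Whitney with tie-corrected normal approximation) and one-way ANOVA
delegate to scipy.stats behind this package's interface; the test suite
checks them against hand-computed rank-sum, pair-count and sum-of-squares
oracles. Two conventions are fixed here: Mann–Whitney reports
`min(U1, U2)` (the classic tables convention, so perfectly separated
groups give U = 0), and the all-observations-tied Kruskal–Wallis case
returns H = 0, p = 1 instead of an error. ANOVA on groups with zero
within-group variance is undefined (0/0) when the means are also equal and
is flagged as an error; with unequal means it reports F = ∞, p = 0.
"Nonparametric two-group comparison" is interpreted as Mann–Whitney U
throughout.

## Composition and snorkeling profiles

Composition tables report `100 × count/total` over the 20 standard amino
acids. Cross-species LWI composition pools all species' LWI residues into
one multiset before computing percentages (a per-species-then-average mode
is available via the per-species tables). The TM-core region is defined
*exclusive* of flank positions that fall inside TMs, so LWI and TM-core
never double-count a position. Enrichment classification is a three-way
threshold rule — above / below / equal (±1e-9) to the threshold, default
5% — applied per amino acid per region. Snorkeling profiles compute each
species' %Arg, %Tyr, %(Arg+Tyr) over its own LWI pool; group figures
average per-species values within a phylum or thermal class.

## Motif scanning

CRAC (`{L,V}–X(1..5)–{Y}–X(1..5)–{R,K}`) and CARC (strict inversion;
optionally `{Y,F}` center) are matched as anchor triples `(a1, c, a3)` on
ungapped sequences. The spacer minimum is 1, reading `X(1–5)` literally; a
zero-minimum variant is available as a custom pattern for users following
other CRAC conventions. Because the elastic spacers make single regions
satisfy many triples, the default report merges overlapping triple spans
into maximal intervals (one representative triple each), which is how such
motifs are conventionally quoted as residue ranges; `all_triples` exposes
the raw enumeration. CCM has no sequence consensus and is supported only
as a named-region annotation. Cross-species motif comparison goes through
alignment projection of motif intervals, not rescanning of gapped rows.

## Synthetic cohorts

`simulate_orthologs` draws a **star phylogeny**: every taxon descends
independently from one common ancestor (uniform-random over the 20
residues, or a supplied reference), each site substituting with its
region-class probability, uniformly among the other 19 residues, no
indels. The expected tip-to-tip p-distance at per-site rate `p` is the
closed form `E[d] = 1 − [(1−p)² + p²/19]`, which the parameter-recovery
tests check at rates 0.02–0.2. Region classes (inner flank, outer flank,
TM core, elsewhere) come from the same topology object the analyser
consumes, so generator and pipeline agree on coordinates by construction;
flank positions claim TM-core positions on overlap, inner claims shared
inner/outer positions.

Defaults state a vertebrate-like world: 38 taxa (4 fish, 2 amphibians,
14 reptiles, 4 birds, 14 mammals — a typical ortholog panel for this kind
of channel survey) and rates inner 0.05 < outer 0.10 = TM-core 0.10 <
elsewhere 0.20, encoding the inner-leaflet-most-conserved, LWI-more-
conserved-than-elsewhere structure the analysis is designed to detect.
Group `flank_composition` biases redraw the affected taxa's ancestral
flank residues from a biased distribution (e.g. Arg-rich flanks in
cold-blooded groups) before divergence is applied. Planted motifs are
written into every tip **after** divergence, so they are invariant across
taxa — the scanner always recovers them at the planted coordinates and
their anchor columns carry full information content.

What the generator does *not* emulate: indels (projection with gaps is
exercised by hand-built fixtures instead), phylogenetic tree structure
(internal branches, rate heterogeneity, exchangeability matrices), and
residue-dependent substitution preferences. A green synthetic test
therefore establishes that the pipeline measures what the model puts in —
not that real ortholog sets satisfy the model.

`simulate_pool_composition` draws i.i.d. residues from a 20-way target
distribution for composition-table tests. Targets must sum to 100 within
1e-6; `renormalize=True` accepts printed tables whose 1-decimal rounding
sums to 99.9/100.1.

## Numerical and interface choices

- Coordinates are 1-based inclusive everywhere outside function bodies.
- Distance matrices are computed vectorized over numpy int8 codes; the
  naive double loop lives only in the tests as the oracle.
- Enrichment equality tolerance is 1e-9; composition percentage sums are
  checked to 1e-6.
- Exported TSVs carry full precision (`%.10g`); 1-decimal rounding is a
  presentation concern left to the consumer.
- `export_report` refuses a non-empty existing directory without `force`.
- Bootstrap output has no external numeric anchor (published analyses of
  this kind show only box plots), so it is validated by its invariants:
  zero variance on identical sequences, bit-reproducibility, and closeness
  to the binomial closed form on two-sequence alignments.

## Known limitations

- Flank extraction trusts the topology table; boundary sets derived from
  embedded structures can differ from printed domain tables, and such
  differences (e.g. residues discussed as interface-proximal despite lying
  inside a printed TM span) are out of scope — supply an alternative
  topology file instead.
- The degenerate CRAC/CARC consensus is permissive; genome-wide scans
  yield more maximal intervals than curated motif lists, which typically
  restrict attention to TM-proximal hits. Use the overlap report with the
  LWI segments or named regions to filter.
- Group comparisons are plain rank/variance tests without phylogenetic
  correction; closely related taxa are treated as independent samples.
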