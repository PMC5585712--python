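# Methods

`tnseqfit` implements conditional-fitness analysis for mariner (Himar1)
transposon-insertion sequencing (Tn-Seq), together with a fully seeded
synthetic-experiment generator used to validate every stage against known
ground truth. This note records the model, the conventions the
implementation fixes where the protocol leaves room, the numerical choices,
and what the synthetic validation does and does not demonstrate.

## The experimental design being modelled

A pooled library of mariner insertion mutants is selected on a permissive
acceptor (fumarate) — mutants disrupting genes required for that growth
never form colonies — then split into two arms: a test arm grown on a
poised electrode for G_p = 6 generations (generations counted on the
parent clock, doubling time td_p = 10 h), and a parallel fumarate control
arm grown for the same 6 generations. Because electrode biofilms yield
little free biomass, both arms then receive an identical fumarate
outgrowth (another 6 generations) before DNA extraction; being common to
both arms and neutral for electrode-specific phenotypes, this outgrowth
cancels in the read ratio. Each mutant's abundance is read out by
sequencing the ~20-bp genomic fragment adjacent to the transposon end
released by the type IIS enzyme MmeI.

## Growth model and doubling-time conversion

Over elapsed time T = G_p × td_p, a clone with doubling time x grows by
2^(T/x). Its log2 read ratio against the neutral population is therefore
L = T/x − G_p, inverted as

    x = T / (G_p + L),   defined for G_p + L > 0.

With the defaults (T = 60 h) L = −2 gives x = 15 h, a 50% increase in
apparent doubling time; this anchor is tested exactly. The conversion is
undefined when G_p + L ≤ 0: such a mutant declined in absolute terms and
no finite doubling time reproduces its ratio. These features keep their
L-based growth class (a deeply depleted gene is still "defective") and
carry a separate `declining` flag instead of a fabricated doubling time.

A note on the time base: the description this model follows quotes a 72-h
experiment duration in its printed equation, but its two worked
interpretations (6 generations at a 10-h doubling; −2 ↔ ~15 h) are only
mutually consistent with T = G_p × td_p = 60 h. The implementation uses
T = G_p × td_p, which reproduces the worked value exactly; both td_p and
G_p are parameters, so an absolute T can be obtained by adjusting them.

The percent change reported (`percent_td_change`) is time-based: +50% at
L = −2. A "50% reduction in growth *rate*" phrasing describes the same
cutoff viewed as rate = 1/td; the package reports the time-based number
and leaves the rate view to the reader, since both cross 50% at the same
L = −2 under this model only approximately (rate falls by 1/3 at L = −2).

## Site model and the first-5% rule

Mariner inserts only at TA dinucleotides. A site is keyed by the 0-based
offset of its forward-strand 'T'; TA is palindromic, so one key serves
both junction orientations. Insertions in the first 5% of a feature's
length (measured from the strand-aware 5′ end) are discounted because they
frequently fail to produce a knockout. Conventions fixed here:

- The exclusion window is floor(0.05 × length) bases — deterministic and
  conservative.
- Membership of a boundary-straddling TA in a feature, and its 5′ offset,
  are resolved by the site's first base *as read on the feature's strand*
  (the forward 'T' for +, the base at p+1 for −). This is the unique
  convention under which reverse-complementing the genome and flipping
  strands leaves every feature's available-site count unchanged, which the
  test suite asserts exactly.
- Feature aggregation sums reads over available (beyond-window) sites
  only; insertion density is unique sites hit per kb of *full* feature
  length, matching how the thresholds were derived.

## Read processing rules

Reads are demultiplexed by exact barcode match (no mismatches, barcodes
validated distinct and equal length), the transposon tag is trimmed, and
the remaining genomic junction is kept only if ≥ 16 bp; remainders longer
than 21 bp are truncated from the junction end (MmeI fragments are
20 ± 1 bp; longer remainders indicate adaptor read-through). Mapping is
full-length exact matching over both strands of every replicon via a
16-mer seed index with full-length verification — 16 being the minimum
read length, every retained read has a seed. A read matching exactly one
locus is unique; two or more, ambiguous; none, unmapped. Ambiguous reads
(e.g. from tandemly duplicated gene clusters) are excluded from site
assignment but retained in the totals used for depth normalization, and
any feature whose available sites were implicated in ambiguous matches is
flagged, since ambiguity can depress its apparent insertion density.

Two tallies exist beyond the canonical five (unique, ambiguous, unmapped,
too-short, undemultiplexed): `no_tag` (tag absent after demultiplexing —
only possible with sequencing errors or malformed input) and `off_ta`
(a unique alignment whose implied insertion position is not a TA). Both
are zero on error-free data; keeping them separate preserves the exact
read-accounting invariant that every input read lands in exactly one
category.

## Normalization and essentiality

Counts are scaled to a 40M-read reference depth by
reference_total / (unique + ambiguous). A feature is called essential
when, in the permissive-condition library, it has fewer than 300
reads (threshold defined at the 40M reference and scaled linearly with the
chosen reference depth) **and** fewer than 4 insertion sites per kb. The
conjunction is the default because each criterion alone has a failure
mode: small genes have few TA sites regardless of fitness, and large genes
tolerate insertions between domains. An "either" mode (union) is provided
and reported as well; its essential set is a superset of the default's.
The density threshold is not depth-scaled — site saturation, not read
depth, limits it. Features with fewer than 3 available sites, or with
ambiguity flags, are demoted to "low-confidence" whenever a criterion
fires, rather than being called essential.

Fitness ratios use a pseudocount of 1 normalized read in numerator and
denominator — the minimal shrinkage that keeps zero-read features finite.
L is reported to one decimal in exports; classification uses unrounded
values. No p-values are computed: the method uses fixed thresholds, with
an optional replicate-consistency filter (defect called only if L ≤ cutoff
in every replicate) applied when two or more replicate pairs exist.

## The synthetic-data generator

The generator emulates the study conditions end to end with defaults
chosen once:

| parameter | default | why |
|---|---|---|
| genome_length | 500 kb | large enough for ~20k TA sites; tractable on one CPU |
| gc_content | 0.60 | GC-rich host (~61%); sets TA density ≈ 0.04/bp |
| n_features | 400 | mean feature ≈ 1 kb at 85% genic coverage |
| target_unique_insertions | 5,000 | ~25% TA-site saturation, scaled-down analogue of a 33k-insertion library |
| sequencing_depth | 2M reads/sample | scaled with library size to keep ~1,200 reads/insertion-equivalent feature resolution |
| parent_doubling_time, generations | 10 h, 6 + 6 | the two-arm design's stated values |
| fraction_lethal_fumarate | 0.10 | minority lethal class, ~40 features |
| fraction_electrode_defective | 0.05 | ≥ 20 defective features while keeping defective clones a small abundance share (see below) |
| electrode_defective_doubling_time | 15 h | the L = −2 anchor |
| read_length | 20 nt | MmeI junction; optional 19–21 jitter, default off |
| substitution_error_rate | 0 | zero-mismatch mapping makes any error a lost read; the expected loss is exposed for error-mode tests |

Clone abundances after pooling are equal — the protocol does not measure
the post-pooling distribution, and equal abundance is the simplest null.
Intergenic insertions are always neutral. Lethal-gene clones are removed
at library construction (plating selection), not during propagation.
Sequencing is multinomial over clone abundances with a fair coin for
junction orientation; the junction geometry (+: read_length bases
rightward from the 'T'; −: read_length bases leftward ending at the 'A',
reverse-complemented) is a concrete invertible convention, and the mapper
inverts exactly it. Sites too close to a replicon end to supply full
flanking junctions are excluded from library sampling.

What the generator does *not* model: PCR duplicates, GC amplification
bias, realistic quality scores, bottleneck drift beyond multinomial
sampling, or fitness effects of intergenic insertions. Passing the
recovery tests therefore shows the estimator chain is correct under the
stated growth model and multinomial sampling — not that it is robust to
amplification artefacts or abundance skew in real libraries.

A composition caveat bounds the recovery tolerances: normalization forces
each sample to a fixed total, so when defective clones shrink, neutral
clones' normalized counts rise by −log2(1 − 0.75·f) (f = defective
abundance fraction at inoculation). With f ≈ 5% this biases defective L
upward by ≈ +0.05 and neutral L by the same amount — second-order effects
the recovery bands (±0.3 on L, ±1.5 h on td, mean |L| < 0.1 for neutrals)
absorb by design. The acceptance checks run at exactly these defaults
(seeded), where measured values land at L ≈ −1.96, td ≈ 14.8 h, neutral
mean |L| ≈ 0.05, and essentiality precision/recall of 1.0.

## Numerical and degenerate-input choices

- Ambiguity codes in a genome are a hard error by default ('mask' policy
  replaces them with N, which can neither form a TA nor match a read).
- Zero normalization denominator, empty populations, K exceeding the
  usable TA-site count, negative generations, infeasible feature layouts:
  all hard errors with explanatory messages.
- A feature with zero reads in both samples of a ratio is "no-data", not
  L = 0.
- td → ∞ in the simulator means a static clone (growth factor 1).
- All randomness flows from one integer seed through named, stable
  substreams; identical config + seed reproduces byte-identical FASTQ.

## Known limitations

- The mapper is exact-match only (by design: the protocol discards any
  mismatched read); there is no indel or quality-aware mode, and no
  SAM/BAM emission — per-site count tables, BED and wiggle tracks are the
  products.
- Essentiality is threshold-based, not model-based (no HMM/Bayesian
  smoothing across adjacent sites).
- Replicate correlation on real library replicates depends on the actual
  data; the simulation-based check (two sequencing draws of one library,
  r > 0.95) validates the computation, not the reproducibility of any
  particular wet-lab protocol.
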