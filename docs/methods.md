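# Methods

This note documents the models implemented by `hifisim`, the defaults and
why they were chosen, what the synthetic fixtures do and do not emulate,
and the numerical conventions that matter for reproducibility.

## Abundance model

Genome molarities are relative abundances summing to 1. Supported
distributions: `uniform` (1/n each, the classic "even" mock community
design), `lognormal` (normalized `exp(Normal(mu, sigma))`, defaults mu=0,
sigma=1), `powerlaw` (normalized `rank^-alpha`, default alpha=1, a
"staggered" design), and `empirical` (a user profile, normalized).

Counts arise from the intensity + variability contract used by sparse
microbiome count simulators:

- **Intensity** — the expected relative abundance of a feature (genome, or
  ASV after copy-number expansion).
- **Variability** — the squared coefficient of variation (CV²) of the
  feature's abundance between replicate samples.

The mean CV² is modeled log-linearly in intensity,
`E[CV²](x) = b0 + b1·ln(x)` with defaults `b0 = -0.25`, `b1 = -0.18`
(CV² ≈ 1.0 at 0.1% relative abundance, ≈ 0.17 at 10%, the canonical
"rarer features are noisier" overdispersion shape). Around a positive
mean, a CV² draw comes from a Gamma with shape `nb_size` (default 4), the
continuous mixing analog of a negative binomial; `nb_size → ∞` collapses
to the mean curve. When the predicted mean CV² is ≤ 0 — which happens for
the most abundant features under the default curve — the draw is exactly
0 and all replicates receive identical abundance values before technical
sampling. This reproduces, as an explicit rule, the behavior of upstream
count simulators that convert failed (NA) variability estimates to zero.
The three curve parameters are deliberately user-settable and a
least-squares helper (`VariabilityModel.fit`) estimates them from any
(intensity, CV²) table; published fit coefficients for specific presets
are not bundled.

Per sample, counts are drawn in two stages: a biological stage draws each
feature's realized intensity from a Gamma with mean = intensity and
CV² = variability (variability 0 ⇒ the intensity is used unchanged), and
a technical stage allocates the configured depth by a multinomial over
the renormalized realized intensities. Column sums therefore always equal
the configured depth. Multinomial rather than hypergeometric sampling is
used because sequencing depth is far below library complexity in amplicon
settings; the sampler is a single function and is documented as the
swap-in point. Variability is drawn per feature × sample by default
(switchable to once per feature).

Copy-number expansion: each ASV's expected intensity is its genome's
molarity times the ASV's copy multiplicity within that genome,
renormalized over all ASVs. Identical operon copies collapse into one ASV
with summed multiplicity.

## In-silico PCR

A genome position matches a primer position iff the genome base is in the
IUPAC degeneracy set of the primer code; an `N` in the genome matches
only a primer `N` (an ambiguous genome base is never claimed as a hit).
Sites with at most `max_primer_mismatch` mismatches (default 2) are
primer sites. Every (forward site, downstream reverse-complement reverse
site) pair on each strand is a product; nested and overlapping candidates
are all reported, so a product-length window (`min/max_product_len`)
should be set for multi-operon genomes — length filtering is off by
default and the window is a run-level choice (e.g. 1000–2000 for 16S
primer pairs). Products are stored primer-inclusive (both annealing
footprints retained) for length filtering and reference comparison, with
the primer-exclusive insert kept separately for template construction.
Coordinates are 0-based half-open on the forward strand; minus-strand
products carry a strand flag and 5'→3' product orientation. No polymerase
thermodynamics: a 3'-terminal mismatch costs the same as any other
(documented limitation).

## Templates

`A + FwdBarcode + FwdPrimer + insert + rc(RevPrimer) + rc(RevBarcode) + A`,
with the flanking `A` bases literal and every segment's span recorded.
Templates must be concrete DNA. Degenerate primer positions are resolved
in "oligo mode" by default — a random concrete base from the degeneracy
set per template, reflecting that the amplicon physically carries the
primer oligo at its 5' ends — with a "genomic mode" switch that instead
uses the sequence found at the binding site.

## Pass numbers

`np` (the number of CCS passes) is drawn either from an empirical
histogram TSV (out-of-range rows dropped, the rest normalized; the raw
histogram is used without smoothing) or from a lognormal on the log scale
(defaults mu=2.3, sigma=0.5, i.e. a median of ~10 passes, typical of HiFi
amplicon runs), rounded to the nearest integer and rejection-sampled into
`[np_min, np_max]` (default [2, 59]). Rejection rather than renormalized
truncation keeps the in-range shape unbiased. `fit_lognormal` uses the
MLE convention: mean and population (ddof = 0) standard deviation of
log(np). Insert-length dependence of the pass-number distribution is not
modeled in v1; per-length-bin histograms can be supplied as separate runs.

## Subread error model

Each pass walks the template base by base. With probability `accuracy`
(default 0.65) the base is emitted unchanged; otherwise the error type is
chosen by the substitution:insertion:deletion ratio (default 6:55:39, the
published PacBio RSII ratio, retained because no Sequel II-specific
defaults are published). A substitution emits a uniformly random
different base; an insertion emits a uniformly random base and
*re-processes* the same template base, so insertion run lengths are
geometric; a deletion skips the base. Even passes operate on the reverse
complement of the template (strand alternation).

Because every walk step emits exactly one alignment column, the expected
fraction of match columns equals `accuracy` and the composition of error
columns equals the normalized ratio — the configured parameters are
recovered exactly as realized statistics, which is what the acceptance
suite verifies at 10⁶ bases. (Note that matches per *template base* is
`accuracy/(1 - p_ins)` ≈ 0.805 at defaults, not 0.65; "subread accuracy"
here is aligned identity over alignment columns.) An optional homopolymer
multiplier (≥ 1, default 1 = off) scales the ins+del mass inside runs of
≥ 3 identical bases with per-position renormalization, as a hook for the
elevated homopolymer indel rates seen in real data.

## Consensus

Consensus is hierarchical plurality voting, entirely re-implemented (the
vendor CCS algorithm is deliberately not replicated bit-for-bit):

1. subreads are oriented to the forward strand;
2. for ≥ 6 passes, round-robin groups of ~3 build group drafts (medoid
   backbone, two voting rounds); the drafts vote among themselves to
   produce a backbone; for < 6 passes the medoid subread seeds the
   backbone directly;
3. all subreads are globally aligned (edlib, unit costs) to the backbone;
   each backbone column takes the plurality of {A, C, G, T, gap}
   (gap-winning columns are dropped), and insertion columns supported by
   ≥ 40% of subreads are emitted with the plurality inserted base;
4. per-base quality is the Phred-scaled column agreement
   `min(93, round(-10·log10(max(1e-10, 1 - k/n))))` for k winning votes
   among n subreads. With ≤ 2 passes no plurality exists and the first
   pass is returned unchanged at a fixed single-coverage quality
   (default Q20, a parameter).

The hierarchy exists because a single medoid backbone's errors are
correlated with the voters that produced them, which leaves a fixed-point
error floor under iteration; splitting voters into groups weakens that
correlation. Measured on 350 bp templates at default accuracy, median
consensus edit distance falls from ~96 (np=3) to ~48 (np=15) to ~29
(np=59). This is substantially noisier than vendor CCS at the same pass
numbers — backbone-based plurality voting discards phase information that
a partial-order-alignment or HMM consensus would keep — and is the main
known limitation; POA is the documented upgrade path. The acceptance
suite relies only on relative properties (monotone improvement with np,
zero misassignment on well-separated references), which hold with wide
margins.

## Evaluation and calibration

- **Edit-distance profiles** — unit-cost global (NW) distance from each
  read to every reference; minimum taken, ties broken by lexicographically
  smallest ASV id. Histograms use unit bins on [0, d_max] plus an
  overflow bin. Reads outside a configured length window are excluded
  before any metric.
- **Misassignment** — fraction of reads whose nearest reference is not
  their true source ASV; ties that include the truth count as correct.
- **KL calibration** — `KL(target ‖ simulated)` in nats over identical
  binning; the simulated histogram is smoothed by adding 1e-9 mass per
  bin and renormalizing (an un-smoothed zero where the target has mass is
  an error, forcing the smoothing choice to be explicit). The grid search
  returns the accuracy minimizing KL, ties to the lower accuracy.
  Against real data the target would be the real read profile; the test
  suite uses simulated-vs-simulated self-recovery.
- **Abundance R²** — squared Pearson correlation on linear counts by
  default, with a log10 option (both conventions are in use in the
  field).
- **Positional error profiles** — reads are globally aligned to their
  true templates; per template column the match/sub/ins/del event
  proportions are reported (insertions counted at the template position
  they precede; proportions per column sum to 1).

## Determinism and parallelism

All randomness flows from `numpy.random.Generator` seeded via
`SeedSequence` with hierarchical keys (run seed → module → unit), so
adding samples never perturbs earlier samples' draws. Pass numbers are
drawn up front and each ZMW gets its own derived seed, so outputs are
byte-identical for any worker count; multiprocessing is opt-in
(`workers > 1`).

## Fixtures and what passing tests do (and do not) show

The synthetic mock genomes are random intergenic spacers interleaved with
operons built as concrete-primer-realization + random core +
rc(concrete reverse primer realization); copies 2..k mutate the core by
substitutions at the configured divergence. Degenerate primer positions
are instantiated randomly per operon so extraction must genuinely handle
IUPAC matching. Fixture cores are uniform random DNA: they carry no rRNA
secondary structure, conserved regions, taxonomy, or homopolymer
statistics of real operons, so passing tests demonstrate the machinery's
correctness and calibration, not sequence-level realism on real genomes.
Test problem sizes (250–350 bp cores, 2 000-read misassignment and
calibration runs, 10⁶-base error calibration) were chosen as the smallest
sizes at which the checked statistics are stable.

PCR bias, chimera formation, and adapter artifacts are intentionally not
modeled.
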