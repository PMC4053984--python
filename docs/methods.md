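# Methods

## Scope and model

`zfbind` reimplements, as a tested pipeline, the quantitative analysis
behind in-vitro binding-site mapping of long zinc-finger (ZF) array
proteins such as PRDM9. The package covers the arithmetic from raw
instrument readouts to normalized binding quantities, the statistics used
to compare observed sites to predicted motifs and to each other, a
mutagenesis-derived position weight matrix (PWM) with exact p-value
scanning, ZF-array bookkeeping, and a simulation of the experimental
localization strategy. Wet-lab protocols, ZF recognition-model prediction
algorithms, and genome-wide hotspot catalogs are out of scope; predicted
motifs are consumed as input files.

## Assay quantitation

* Gel lanes: shifted fraction `S/(S+U)`. Densities are arbitrary units
  taken as scored; no background subtraction is attempted, since only
  ratios are meaningful and band-boxing conventions differ by instrument.
* Haplotype binding ratios use the ratio of arithmetic means across
  replicate lanes; the single-lane alternative is a degenerate case of the
  same estimator. Only this convention is implemented because the assay
  reports no titration model.
* Dot-blot methyltransferase activity:
  `(S_ind − S_un)/(S_H3K4me3 − S_H3K4me2)`; equal standards are an invalid
  calibration and raise.
* ChIP-qPCR: percent bound `2^(Ct_input − Ct_ChIP) × 100`. Failed
  (or missing) reactions are imputed to Ct 35 before triplicate Ct values
  are averaged arithmetically.

## Competition mutagenesis

The minimal 31-bp site sits at positions 3–33 of the 36-mer competitor
(2 extra bases 5', 3 extra 3'). For each substitution,
`B_mut = (S_un − S_mut)/(S_scr − S_un)`; the scrambled control must leave
more labeled signal than the unmutated competitor or the measurement has
no dynamic range.

Per-position specificity is the standard deviation of binding changes at
that position. The default (frozen) mode takes the **sample SD (ddof 1)
over four values** — the reference pinned at 0 plus the three substitution
indices. This mode was chosen a priori because it is the only candidate
whose range matches the observed group ranges: complete loss at all three
substitutions gives SD exactly 0.5, inside the observed high band
(0.45–0.52), whereas the three-value population SD collapses that case to
0. The alternative (`three_population`) remains available behind a flag
for sensitivity analysis.

Class boundaries are the midpoints of the gaps between the observed group
ranges: low < 0.14 ≤ moderate < 0.405 ≤ high. The three classes always
partition the site.

## Motif and site statistics

A motif position is *defined* when one base exceeds 60% frequency; strong
matches are counted only at defined positions against a uniform 0.25
chance rate (15 defined positions → 3.75 expected matches). Significance
is the exact binomial upper tail `P(X ≥ k)` by pmf summation — no normal
approximation.

Site-to-site comparisons use ungapped sliding alignment (sites are
30–33 bp and were aligned without gaps), maximizing identities with ties
broken toward larger overlap, then smaller |offset|. The pairwise binomial
test takes n = overlap length; because the choice of n is not dictated by
the assay and materially changes p-values, n is explicit in the API and
reported alongside. The three-way test scores each aligned column as
triple / one-pair / no-pair and runs a 2-df goodness-of-fit χ² against
the uniform-independence expectations 1/16, 9/16, 6/16 (upper-tail p).
Published headline p-values for such comparisons are sensitive to the
unstated n, sidedness and expected model; this package reports its own
computed values and does not attempt to force agreement.

## PWM construction and exact scanning

From a specificity profile, relative affinities are `1` for the reference
base and `max(1 + B_mut, floor)` otherwise, floor 0.01 (a config knob) so
complete-loss positions keep finite log-odds. Per-position probabilities
are `affinity^β` normalized; weights are log₂(p/background). Background
defaults to uniform and can be estimated 0th-order from the scanned
sequence.

β is calibrated on the matrix's source hotspot: over a grid (default
0.25–4.0 in steps of 0.25) pick the β maximizing the margin between the
known site's score and the best non-overlapping window on either strand;
ties go to the smallest β. This operationalizes "optimize the weights by
maximizing detection of the source site in its own region" as a one-
dimensional sharpness search.

P-values are exact under the i.i.d. background: weights are discretized to
0.01-bit bins and the full window-score pmf is built by convolution over
positions. Window scores are binned identically before lookup, so DP
p-values equal brute-force 4^L enumeration exactly on the binned score
(verified in tests for L ≤ 8). Scanning keeps windows on both strands at
p < 10⁻⁵ by default; a minus-strand hit reports the forward-strand window
start. Hotspot enrichment counts hits in each hotspot (< 10 kb) and in two
flanking controls of the hotspot's own length, truncated with a warning at
sequence bounds; the summary ratio halves the control total because
controls cover twice the hotspot length.

## ZF arrays

Footprint: 3 bp per finger core, +1 bp shared base (3n, 3n+1). Fingers are
compared by their −1/+2/+3/+6 contact residues (or full sequence);
identical-finger groups are audited for whether they bind identical
trinucleotides across sites. The N-terminal finger maps to the 5'-most
triplet by default; the reverse convention and both site anchors (finger 1
or the last finger unengaged) are available because the terminal-finger
engagement is ambiguous at 30–33 bp site lengths. The bundled 11- and
12-finger arrays are synthetic stand-ins (see their filenames) reproducing
the stated structural facts — identical ASNQ contacts at fingers 2/5/7/9
of the 11-finger allele, serine at −2 throughout, two identical pairs in
the 12-finger allele — not the true residues, which are published only as
figures.

## Tiling and truncation simulation

`localize` tiles the region with 300-bp amplicons overlapping 50 bp,
calls a tile positive at shifted fraction ≥ 0.1, and re-tiles the union of
each positive run with halved tile lengths (floored at 90 bp). In the
final round the reported interval is the **intersection** of a run's
positive tiles: every positive tile covers the site, so the intersection
does too and is below 100 bp. `minimal_site` then trims the fragment
(default 1 bp alternately per end; single-end mode available, since the
original end order is unstated) keeping a trim only while the shortened
unlabeled competitor still cuts the labeled probe's signal by ≥ 50%. The
0.1 call threshold and 50% efficacy threshold are package choices; the
original assay scored bands qualitatively.

## Synthetic worlds

The generator emulates the assay design, not ZF biophysics:

* hyperbolic occupancy `f = c·a/(1 + c·a)`; protein activity `c = 1` so
  the reference probe shifts 50%;
* log-additive per-position affinities, reference base = 1; site
  positions uncovered by an oligo each contribute a fixed contact penalty
  0.05 — chosen so a competitor missing one essential base falls below
  the 50% efficacy threshold with wide noise margins;
* competitor sequestration `c' = c/(1 + 20·a·c)` (20-fold molar excess,
  1-h pre-incubation design), giving the closed form
  `B = 2(a − 1)/(2 + 20a)` under defaults, inverted exactly when planting
  target indices;
* defaults: 4 hotspots of 2 kb (hotspots are kilobase-scale; scanned ones
  < 10 kb), GC 0.42 (mouse genome-wide), site length 31 with a central
  8-position high-specificity block, 5 moderate positions per side and
  low-specificity ends (the observed organization, weakest toward 3');
  planted per-class B templates {−.05, −.10, −.15}, {−.30, −.45, −.60},
  {−1, −1, −1} sit mid-band in the observed SD ranges;
* noise: multiplicative lognormal on band densities (σ = 0.02 default),
  additive Gaussian on Ct cycles.

What a green synthetic test does **not** establish: realism of binding
energetics (no cooperativity, no strand asymmetry, no flanking-sequence
effects, no kinetics of the 4-h replacement), densitometry artifacts
(saturation, background gradients), or PCR efficiency effects. The tests
establish that the analysis code inverts its own stated generative model
and meets the arithmetic and distributional identities above.

## Numerical choices

* Exact binomial tails are summed from scipy pmf values; enumeration
  cross-checks to 1e-12 for n ≤ 12.
* Score binning at 0.01 bits; a length-31, β=4 matrix yields pmfs of
  ~10⁵ bins, built in milliseconds.
* Degenerate inputs raise typed errors (`zfbind.errors`): both densities
  zero, equal methylation standards, no competition dynamic range,
  incomplete or duplicated scan positions, site absent from its region,
  non-binding truncation fragment.
* All generators take explicit numpy `Generator`s or integer seeds;
  identical seeds give identical worlds.

## Known limitations

* Pairwise similarity p-values depend on the alignment-length convention;
  alternative n choices must be computed by the caller via
  `binomial_upper_tail`.
* The affinity→probability `affinity^β` construction is this package's
  explicit choice for turning mutagenesis indices into a PWM; other
  monotone maps (e.g. Boltzmann weights with a temperature) would be
  equally consistent with the inputs.
* `best_ungapped_alignment` is exact but O(len a × len b); it targets
  30–40 bp minimal sites, not genomic segments.
* The tiling simulation assumes a single compact site per positive run;
  overlapping sites closer than one tile length merge into one interval.
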