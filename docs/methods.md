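# Methods

## The genetic model

Sex is modelled as a single locus with three alleles, male (M),
hermaphrodite (H) and female (F), under the total dominance order
M > H > F. Genotypes are unordered allele pairs; the phenotype is the
phenotype of the dominant allele (FF female, MF/MH/MM male, HF/HH
hermaphrodite). An FF × MF cross therefore segregates 1:1 female:male, and
HF × MF segregates 2:1:1 male:hermaphrodite:female — these expectations are
produced by enumerating the four equiprobable gamete unions
(`segregation.expected_ratio`), so they stay correct for any genotype pair.

All mapping machinery assumes a **pseudo-testcross** configuration: sites
heterozygous in exactly one parent segregate 1:1 in the F1 like a
backcross, and each offspring call records which parental haplotype it
inherited.

## The simulator

`bsamap.sim` generates data with exactly the statistical structure the
scan assumes, nothing more:

- **Meiosis.** Crossover count per chromosome per meiosis is
  Poisson(genetic length in Morgans), genetic length = bp ×
  recomb_rate(cM/Mb)/100, crossover positions uniform, no interference
  (Haldane model). The sex locus is a point on the same haplotype
  framework, so marker–sex linkage arises mechanistically rather than by
  construction; a cross with `sex_locus=None` segregates sex independently
  of every variant (the null condition).
- **Bulks.** Uniform sampling without replacement of `bulk_size`
  individuals of one phenotype (default 30+30, the study design).
- **Sequencing.** Per variant per bulk: depth ~ Poisson(mean depth;
  defaults 32 and 34), alt reads ~ Binomial(depth, p(1−e) + (1−p)e) with p
  the true bulk alt-haplotype frequency and e a symmetric per-read error
  rate (default 10⁻³). Poisson rather than negative-binomial depth is the
  simplest model consistent with an average-depth summary; overdispersion
  can be emulated by widening the error rate or subclassing the count step.
- **Pseudoexchange.** `apply_pseudoexchange` swaps ref/alt labels (and
  counts) at a seeded random subset of variants, modelling a locally
  mislabelled reference. It is an involution, and the scan statistic |Δ|
  is bit-identical under any flip pattern (Δ is computed from an integer
  cross-multiplied numerator precisely so that this holds exactly in
  floating point, not just algebraically).

`simulate_bsa_experiment` defaults: 117 offspring, bulks of 30, evenly
spaced variants (500 per 10 Mb chromosome), recombination 4 cM/Mb — a
genome-wide grapevine-like average. **By default every variant is a
paternal-testcross site.** Maternal-het sites have the identical marginal
null distribution but carry no information about a paternally segregating
locus; mixing them in (`frac_mother_het`) dilutes the locus-window signal
(at a 50% mix the locus-window mean |Δ| drops from ~0.49 to ~0.37) without
changing null calibration. The default emits the sites the method is
designed to measure; the dilution knob exists for robustness studies.

What the simulator does **not** emulate: read-level artefacts (no FASTQ,
alignment or calling errors beyond the symmetric error rate), uneven
variant density, segmental depth biases, linked clusters of genotyping
error, or both-parent-heterozygous sites (whose null differs from the
testcross null). Passing tests therefore demonstrate correctness of the
statistics under the model the method itself assumes, not robustness to
every real-data pathology.

## The scan

- **SNP index** = alt reads / depth; depth 0 is an error, never a silent 0
  (such records are dropped with a logged count before filtering).
- **Δ** = index_F − index_M, computed as
  (altF·depthM − altM·depthF)/(depthF·depthM); |Δ| is the scan statistic.
- **Filter.** A variant is removed when (a) its index is below `min_index`
  (0.3) in *both* bulks — such sites are uninformative or erroneous
  everywhere — or (b) its depth is below `min_depth` (7) in *either* bulk,
  because one unreliable index corrupts Δ. The source convention is
  ambiguous on (b); `depth_rule="both"` provides the other reading. Note
  the low-index rule keys on the ref/alt labelling: a variant with indices
  (0.9, 0.9) becomes (0.1, 0.1) after a label flip and is then removed, so
  end-to-end region calls are flip-invariant only with `min_index=0`; the
  statistic itself is always invariant.
- **Windows.** Half-open [start, start+2 Mb), 1-based, stepped every
  100 kb from position 1; terminal windows truncate at the chromosome end.
  A window's statistic is the arithmetic mean of |Δ| over the variants
  inside; empty windows carry NaN and never contribute to regions.
- **Null thresholds.** For each read depth d, `n_bootstrap` (1000)
  replicates of the two-stage testcross null: per bulk, k ~
  Binomial(bulk_size, ½) heterozygous individuals, alt frequency
  p = k/(2·bulk_size), then reads ~ Binomial(d, p); |Δ| of the two
  independent bulks is recorded and the 95%/99% nearest-rank empirical
  quantiles stored. A `read_only` null (fixed read probability, default ¼)
  is available for comparison and for constructing exact degenerate cases.
  The two-stage null is exact for the sites the simulator emits; at depths
  ≤ 3 it is verified against full enumeration in the test suite.
- **Threshold assignment.** The table is keyed by a single depth applied
  to both bulks. A variant with unequal bulk depths uses
  min(depthF, depthM) — conservative, since the shallower bulk dominates
  the variance of Δ; window thresholds are the means of the per-variant
  thresholds, mirroring the averaging of the statistic. Together with the
  nearest-rank quantile of a discrete distribution this makes the realised
  null exceedance sit slightly *below* the nominal 1%, never above.
- **Regions.** Windows whose mean |Δ| strictly exceeds their 99% (or 95%)
  threshold are marked; overlapping or touching marked windows merge, a
  single marked window is a valid region, and the peak value is the
  maximum window statistic inside. BED output is 0-based half-open; the
  TSV mirror is 1-based inclusive.

## Segregation testing

chi2 = Σ(|O−E| − c)²/E with c = 0.5 (Yates) by default for two-category
(df = 1) tests and c = 0 otherwise; the p-value is the chi-square survival
function evaluated through the regularized upper incomplete gamma
function. Yates-by-default reproduces the canonical 0.14 for 56:61 against
1:1; the correction is a flag because published values for comparable
populations are not always mutually consistent under a single convention.

## Linkage

Recombination fractions are counted pairwise-complete over individuals
non-missing at both markers; with unknown coupling phase the recombinant
class is min(mismatches, matches), so r̂ ≤ ½ by construction (a perfectly
complementary pair is complete coupling relabelled). The two-point LOD at
the MLE is k·log₁₀(2r̂) + (n−k)·log₁₀(2(1−r̂)); groups are connected
components of the LOD ≥ 4 graph; distances use Kosambi
d = 25·ln((1+2r)/(1−2r)) cM. Ordering minimises the sum of adjacent
recombination fractions exhaustively for ≤ 10 markers (the scale this
package targets; ties and orientation resolve to the lexicographically
smallest sequence) and falls back to nearest-neighbour with a warning
beyond that. Sex itself is scored as a paternal testcross marker
(female → a, male/hermaphrodite → b), which is how a dominant one-locus
trait joins the map.

## Marker tools

In-silico PCR is exact string matching of the forward primer and the
reverse complement of the reverse primer; every forward site paired with
every downstream reverse site within `max_len` is a product. No mismatch
tolerance: the marker is scored as clean presence/absence bands.
Band classification: the 252-bp band alone → FF; 252 plus 273 → carrier
(the M- and H-linked bands are identical, so MF and HF are
indistinguishable here); anything else → unknown. Band lengths match with
±1 bp tolerance, absorbing the 1-bp inconsistency between the reported
band sizes and the reported 22-bp insertion (252 + 22 = 274). ORF length
nt/3 − 1 amino acids with start/stop/internal-stop validation (549 nt →
182 aa). Synthetic marker templates (`make_marker_templates`) are random
sequences built around the real primer pair and are labelled synthetic —
they reproduce the band-length logic, not the real locus sequence.

## Problem sizes and numerical choices

The test and acceptance suites run the full pipeline at reduced but
structurally faithful sizes, chosen as the package's own defaults for
desk-scale verification: null calibration pools 50 independent no-locus
scans of 100 variants each with window = step = 100 kb (so each window is
effectively one variant and window exceedance equals the calibrated
per-variant rate); locus recovery runs 100 seeds of 2 × 400 variants on
two 10-Mb chromosomes; linkage recovery runs 100 seeds of 117 offspring at
nine loci across a ~50-cM segment. Empirical quantiles are nearest-rank;
region merging uses half-open interval arithmetic (touching intervals
merge); all randomness flows through `numpy.random.default_rng` seeds, and
every stochastic CLI command exposes `--seed`.

## Known limitations

- The bootstrap null describes testcross sites; sites heterozygous in both
  parents would need a wider null and are not emitted by the default
  generator.
- Thresholds keyed by min depth are mildly conservative for very
  asymmetric bulk depths.
- Ordering is exhaustive only to 10 markers; larger groups get a heuristic
  order.
- The marker classifier is deliberately coarse (FF vs carrier vs unknown);
  it cannot separate MF from HF, matching the biology of the assay.
- With a strong locus on a short simulated chromosome the candidate region
  legitimately spans most of that chromosome (everything is partially
  linked); localisation sharpens as chromosomes grow or recombination
  increases.
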