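# Methods

This note records the statistical models behind `balsel`, the defaults
and why they were chosen, and what the synthetic-data generators do and
do not emulate.

## Data model

Haplotype alignments are phased chromosomes over a 0-based half-open
region. The variant matrix stores integer allele codes (lexicographic
order of observed bases; 0/1 biallelic, 0/1/2 triallelic, −1 missing);
monomorphic columns are not stored but the surveyed length L always
denominates per-site statistics. Indel-containing columns are excluded
from all statistics (SNP-only analysis). Missing calls are tolerated:
per-site statistics use the non-missing allele count n_i at that site.
With an attached single outgroup sequence every site is classified as
polymorphic, fixed difference, monomorphic-shared or unalignable, and
polymorphic sites are polarized when the outgroup base matches one
segregating allele.

## Diversity estimators and SFS tests

* θ_W = S/(a_{n−1}L) with a_n = Σ_{i≤n} 1/i; π is the mean per-site
  pairwise mismatch (computed as unbiased heterozygosity
  (n_i/(n_i−1))(1−Σp²) summed over sites, which equals the explicit
  pair-average on complete data and counts any allele mismatch at
  triallelic sites). Reports multiply by 1e4, the conventional
  presentation for resequencing surveys.
* η counts mutations (a triallelic site contributes 2 under infinite
  sites), η_s counts alleles observed exactly once, capped at the
  site's mutation count so a 1/1 doubleton contributes one singleton.
  Singletons are defined without polarization, as the starred Fu & Li
  tests require.
* Tajima's D = (Π − S/a₁)/√(e₁S + e₂S(S−1)) with the standard b₁, b₂,
  c₁, c₂, e₁, e₂ coefficients; Π is the region-total pair average.
* Fu & Li's starred statistics use the corrected variance constants
  (the ones adopted by the widely used sequence-analysis libraries, not
  the misprinted originals):

      c_n = 2(n·a₁ − 2(n−1)) / ((n−1)(n−2))
      d_n = c_n + (n−2)/(n−1)² + (2/(n−1))·(3/2 − (2a_{n+1}−3)/(n−2) − 1/n)
      v_D* = [ (n/(n−1))² a₂ + a₁² d_n − 2n·a₁(a₁+1)/(n−1)² ] / (a₁²+a₂)
      u_D* = (n/(n−1))(a₁ − n/(n−1)) − v_D*
      D*   = ( (n/(n−1))η − a₁η_s ) / √(u_D* η + v_D* η²)
      v_F* = [ d_n + 2(n²+n+3)/(9n(n−1)) − (2/(n−1))(4a₂ − 6 + 8/n) ] / (a₁²+a₂)
      u_F* = [ n/(n−1) + (n+1)/(3(n−1)) − 4/(n(n−1))
               + 2(n+1)/(n−1)²·(a_{n+1} − 2n/(n+1)) ] / a₁ − v_F*
      F*   = ( Π − ((n−1)/n)η_s ) / √(u_F* η + v_F* η²)

  All three statistics error (rather than return 0) on monomorphic data
  and require n ≥ 4. An independent transcription of these formulas
  serves as the test oracle (agreement to 1e-10 on random alignments).

## Empirical ranks

Observed statistics are ranked against a reference panel of per-window
statistics with the midrank convention, rank = (#below + ties/2)/#defined;
windows where a statistic is undefined (e.g. monomorphic) leave that
statistic's denominator. Ranks above 0.99 are printed ">0.99" (the exact
value is kept in machine-readable output). Comparing a 2–9 kb region
against 5 kb windows is a deliberate asymmetry of the workflow and is
surfaced as a warning when sample sizes differ.

## Coalescent null and p-values

The neutral null is a backwards-in-time coalescent with recombination,
piecewise-constant population sizes, splits and migration, simulated by
msprime behind the module interface, with infinite-sites mutations on a
continuous interval mapped to discrete bp. Population sizes are diploid
N_e; simulations run with haploid samples, so sizes are doubled
internally to preserve the 1/(2N) pairwise coalescence rate. θ may be
given directly (4N·μ·L) or derived from a μ calibrated on outgroup
divergence, μ = d/(2 t_split/generation) — divergence accrues on both
lineages. p-values use (r+1)/(m+1) over replicates with a defined
statistic (upper tail = balancing-selection direction), never exactly 0.

Three single-population presets are packaged as deliberately coarse
approximations of continental histories (sizes diploid, times in
generations):

| preset    | epochs (start gen → size)                  |
|-----------|--------------------------------------------|
| constant  | 0 → 10,000                                 |
| YRI-like  | 0 → 12,500; 8,000 → 7,000                  |
| CEU-like  | 0 → 10,000; 2,000 → 1,500; 2,120 → 7,000   |
| EAS-like  | 0 → 10,000; 2,000 → 1,000; 2,120 → 7,000   |

They reproduce the qualitative effect that matters for calibration
(out-of-Africa bottlenecks shift the SFS-test null upward) and are fully
overridable via `DemographicModel`; no downstream check depends on their
exact values.

## HKA and MLHKA

Classic multilocus HKA fits per-locus θ_i and a common divergence time T
(2N units) by moment equations and measures departure with
X² = Σ[(S−ES)²/VarS + (D−ED)²/VarD], where ES = θLa_{n−1},
ED = θL(T+1) (the +1 absorbs ancestral polymorphism for a single
outgroup sequence), VarS = ES + (θL)²a₂ and VarD = ED + (θL)². The χ²
approximation uses #loci − 1 degrees of freedom and is known to be
approximate; on data carrying the full genealogical variance it is close
to uniform under the null.

MLHKA models S_i ~ Poisson(k_i θ_i L a) and D_i ~ Poisson(θ_i L(T+1)),
k_i ≡ 1 at unselected loci. k multiplies only the polymorphism
expectation: selection altering diversity, not substitution rate, which
is what makes k > 1 interpretable as diversity excess. θ_i is profiled
in closed form, leaving a smooth low-dimensional surface over
(log(T+1), log k) that is maximized by seeded multi-start Nelder–Mead
(tolerance 1e-8 on logL; restarts stop once two starts agree). This is
a deterministic replacement for the MCMC search of the original
implementation, chosen for reproducibility; the likelihood is identical.
Significance is a likelihood-ratio χ² with df = #selected loci. A
percentile-band filter on Tajima's D (keep loci strictly inside the
5th–95th band) is provided for assembling neutral reference-locus sets.

## Genealogy and TMRCA

* Four-gamete screen: pairs showing all four gametes are incompatible
  with infinite sites without recombination. Removal order: triallelic
  sites first; then a haplotype is removed only when it is the sole
  carrier of the rare gamete in ≥ 3 incompatible pairs (the
  single-recombinant signature); remaining conflicts are resolved by
  greedily dropping the site in the most pairs (ties to the lower
  position).
* LD subregion: the longest contiguous run of common (MAC ≥ 2)
  biallelic sites with all pairwise r² above the threshold, leftmost on
  ties — a simple deterministic stand-in for haplotype-block software
  when recombination forces analysis of a subregion.
* Median-joining network: Bandelt's algorithm with ε = 0 default and
  uniform character weights — iterate minimum-spanning-network
  construction and majority-consensus median addition (triples adjacent
  in the MSN) to closure, then prune medians of degree ≤ 1 and
  geodesic-redundant degree-2 medians. On tree-compatible data the
  result is acyclic with total weight η.
* Gene tree: the unique perfect phylogeny of polarized compatible data,
  built by nesting derived-carrier sets; mutations with identical
  carrier sets share a branch; leaves are haplotype classes with
  multiplicities. Exported as Newick with mutation counts as branch
  lengths.
* TMRCA, moment method (default): average-linkage clustering of the
  pairwise difference matrix defines the basal bipartition; the mean
  per-site difference across that split d estimates the root age as
  t_scaled = d/θ in 2N_e units (a cross-root pair's expected per-site
  divergence is θ·t). The cross-split mean is used instead of the
  single deepest pair because the maximum of many small Poisson counts
  is upward-biased. N_e = θ/(4μ) with θ the per-site Watterson value by
  default, and t_years = t_scaled·2N_e·generation_years.
* TMRCA, coalescent likelihood method: a Griffiths–Tavaré importance
  sampler on the infinite-sites configuration (lineages as mutation
  paths; coalescence of identical types and removal of private newest
  mutations, with the (n_j+1) merge factor of the recursion). θ is
  maximized over a 7-point grid around the Watterson value and the
  reported TMRCA is the likelihood-weighted mean at θ̂, with a
  Monte-Carlo SE from the effective sample size (warning when SE
  exceeds 10% of the estimate). Default 1e5 proposals; the sampler's
  unbiasedness is verified in the tests against exact dynamic
  programming on a small configuration. Migration is ignored in TMRCA
  estimation (single-panmictic approximation) — a documented
  limitation for strongly structured samples.

## Synthetic-data generators

All generators are pure functions of their parameters and a seed, and
write the formats the readers consume. Defaults are sized to the
targeted-resequencing setting the toolkit addresses: n = 40 chromosomes
per population, regions of 2,000–9,100 bp (4,000 default), 5,000 bp
reference windows, diploid N_e = 10,000, generation time 25 years, and
μ = 2.5e-8 per site per generation (the value a 6 MY human–chimpanzee
split with ~1.2% divergence calibrates to — note this classic
phylogenetic rate is roughly twice the pedigree-based rate; it is the
consistent choice here because the TMRCA clock is calibrated the same
way). Reference panels draw per-window θ from a log-normal around
8e-4/site (σ = 0.5) to mimic inter-locus diversity variation; panel
sizes of 238 and 2,000 windows emulate the two common panel scales.

Balanced regions are built structurally: one neutral coalescent sample
per clade, clade MRCAs joined at the specified split times (5 MY
default, two 50/50 clades), Poisson(μ·L·branch) mutations on the joining
branches, haplotypes assigned to populations at the specified clade
frequencies. This gives exact ground-truth TMRCA and clade labels
without forward simulation of overdominance — justified because every
inference the toolkit makes depends only on genealogy shape. The
three-clade variant with a rare private clade reproduces the known
dissociation between extreme diversity and unremarkable SFS tests.
Low-coverage genotyping is emulated only as singleton undercalling
(each singleton site dropped with probability p); no other error modes
(genotype miscalls, mapping bias) are modelled. Consequently, passing
tests demonstrate correctness of the statistical machinery under the
stated genealogical models, not robustness to real-data artefacts
beyond singleton loss.

The HKA generator draws Poisson counts at the MLHKA rates by default
(model-matched, used for LRT calibration); a `genealogical_variance`
mode additionally samples the coalescent branch-length and ancestral
coalescence-time variability, reproducing the classic HKA variances
exactly (used when checking the X² approximation).

## Numerical choices and edge cases

* S = 0 makes θ_W = π = 0 but SFS tests and TMRCA raise explicit
  errors — an undefined statistic is never reported as 0.
* Jukes–Cantor correction is optional and errors at d ≥ 0.75; raw
  divergence is the default used for HKA and μ calibration.
* Window scans tile left-aligned, count = ⌊(L−window)/step⌋+1; a window
  larger than the region is an error (empty result with a warning at
  the pipeline level); a step larger than the region leaves a single
  window.
* All simulation seeds derive from a single user seed via a PRNG
  stream; identical configuration + seed gives byte-identical outputs.
* LD D′ uses the standard D_max bounds; monomorphic-in-subset pairs
  are excluded rather than reported as 0/undefined.

## Scales used by the shipped checks

The test suite and the acceptance script run entirely on synthetic
data at the survey's own scales: 1,000–2,000 coalescent replicates for
moment and TMRCA checks, 100 balanced replicates for the signature
chain, 200 datasets per MLHKA calibration arm, 238-window panels. These
sizes give Monte-Carlo standard errors a few times smaller than the
tolerance bands they are checked against.
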