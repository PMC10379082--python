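# Methods

This note documents the models, estimators, numerical choices and
limitations behind `radsweep`, in the order data flows through the
package.

## Data model and conventions

Genotypes live in a dense samples × sites dosage matrix with codes
0/1/2 (copies of the alternate allele) and −1 for missing; half-called
genotypes (`./1`) are treated as missing, conservatively. Coordinates
are 1-based inclusive as in VCF and GFF3. All sliding windows are
half-open `[start, start + window)` on starts 1, 1+step, … per
chromosome — the VCFtools convention — so window tables from this
package line up with VCFtools output. SNP-density windows are
non-overlapping (step = window, 100 kb default); the sweep scan uses
100 kb windows with a 10 kb step. Contig order follows the VCF header
when present, else first appearance.

## Filter cascade

Order is fixed: site annotations → SNP clusters → depth mask →
missingness/MAF → Hardy–Weinberg. The order matters and is a choice:
the depth mask runs *before* the missingness screen so that
depth-masked genotypes count as missing there, which is how a
bcftools-then-vcftools pipeline behaves.

* **Annotations**: remove iff QD < 2 or FS > 30 (strict inequalities;
  boundary values survive). Sites lacking both annotations are
  retained and counted — variant callers emit these fields only for
  called variants, and dropping unannotated sites would silently
  discard whole files produced without annotation.
* **Clusters**: a site is removed iff any 35 bp window on its
  chromosome containing it holds more than 3 SNPs; all members of a
  violating window go (GATK SnpCluster semantics).
* **Depth**: genotype kept only if 10 < DP < 60 (open interval).
* **Missingness/MAF**: remove iff missing fraction > 0.1 (the
  VCFtools `--max-missing 0.9` reading: at least 90% called) or MAF
  among called alleles < 0.05 (MAF = 0.05 exactly is kept, VCFtools
  semantics). Sites with zero called genotypes are removed and counted
  separately.
* **HWE**: exact two-sided test in the Wigginton style — enumerate
  every heterozygote count compatible with the observed allele counts,
  compute the conditional probabilities with log-gamma arithmetic, and
  sum those no larger than the observed configuration's (with a 1e−12
  relative guard against ties lost to floating point). Genotypes are
  pooled across samples by default; a per-population mode removes a
  site deviating in any one population. The pooled default matches
  running a single-filter pass on the whole VCF, but pooling across
  truly diverged populations deflates heterozygosity (Wahlund effect)
  and can over-remove — the per-population flag exists for that.

Each stage emits a report (n_input, n_removed, n_retained, parameters)
and reports chain: stage k's input equals stage k−1's retained count.

## Diversity

Per-site π uses allele counts: π_s = 2·c_ref·c_alt/(n(n−1)) with n the
number of called alleles — identical to the mean pairwise difference
among the n haplotypes at that site, which is what the brute-force
oracle in the tests verifies to 1e−12. Window π divides the per-site
sum by the *full* window length (VCFtools convention), not by callable
length; a callable-length variant is available via `per_base=False`
plus external normalization. The summary table reports mean per-site
π, which is the scale on which per-SNP diversity tables are usually
printed for reduced-representation data.

F_IS defaults to the PLINK `--het` per-individual method of moments:
F = (O_hom − E_hom)/(L − E_hom), E_hom = Σ_site (1 − 2p(1−p)·n/(n−1)),
restricted to sites polymorphic in the population, averaged over
individuals. The population-level alternative 1 − HO/HE is exposed as
`fis_from_het`; the two disagree in general (the individual-based form
weights loci and individuals differently), which is why both exist.

## Weir–Cockerham F_ST and the sweep scan

Per site, the two-population W&C (1984) variance components are
computed from sample sizes, allele frequencies and observed
heterozygote frequencies; windows aggregate as Σa/Σ(a+b+c) ("ratio of
averages", the weighted F_ST VCFtools reports). Sites monomorphic
across both populations, or with fewer than one called diploid in
either, contribute (0,0) and don't enter the ratio. Window F_ST can be
negative; it is capped above by 1 by construction.

The Z-transform uses the sample standard deviation (ddof = 1).
Windows where either population's π is 0 have an undefined log2
π-ratio: they are excluded from the ratio's quantile and can never be
outliers (the joint rule is AND), though they still carry F_ST. The
5% cut is applied marginally to each statistic (quantile computed by
linear interpolation, type 7) and a window must reach both thresholds
— the conventional reading of a "top 5% of both" rule; the joint-rank
alternative would flag a different, generally larger set. The ratio is
oriented reference/focal so positive outliers mean diversity *loss* in
the focal (e.g. farmed) population. Merged regions are maximal runs of
overlapping-or-adjacent outlier windows; genes attach on ≥1 bp overlap.
Minimum informative SNPs per window defaults to 1 and is configurable —
with very sparse data a larger value trades coverage for variance.

## LD and effective population size

r² is composite genotypic LD: the squared Pearson correlation of
dosages over individuals called at both sites, no phasing — what
PopLDdecay computes on genotype data. It is symmetric and invariant to
allele-coding swaps, and undefined (pair skipped) when a site is
monomorphic among the shared calls. Pair enumeration is intra-
chromosomal within 100 kb after MAF ≥ 0.05 / missingness ≤ 0.1
screens, with seeded uniform thinning to at most 10,000 SNPs per
chromosome. Distance bins default to 0–1 kb then logarithmic to
100 kb.

Ne uses the Sved-type relation per bin: c = midpoint/bp_per_cM/100
Morgans under a fixed map (1 cM/Mb default, configurable — no genetic
map exists for a synthetic genome, and this is also what SNeP assumes
absent a map); adj_r² = mean r² − 1/(2n) removes finite-sample
inflation; Ne = (1/4c)(1/adj_r² − α) with α = 1 (α = 2.2 available as
the mutation-adjusted variant); t = 1/(2c) generations ago. Bins with
adj_r² ≤ 0 or nonpositive Ne yield no estimate.

Two caveats the validation quantifies: (i) the Sved expectation
1/(1+4Nc) overestimates equilibrium σ_d² at small C = 4Nc (the
Ohta–Kimura form (10+C)/(22+13C+C²) tends to 10/22, not 1, as C→0), so
r²-vs-expectation agreement is only checked where C ≥ 2, with the
sharper Ohta–Kimura form checked everywhere; (ii) time points come
from t = 1/(2c), so with pairs confined to ≤100 kb the probed times
depend entirely on the recombination density — the validation
simulation uses 1e−6/bp (1 cM per 10 kb) precisely so that bins reach
t ≤ 50 generations, where the LD clock reflects recent Ne.

## PCA and admixture

PCA mean-imputes missing dosages per site, centers by 2p̂ and scales by
√(2p̂(1−p̂)) (Patterson normalization), then takes the SVD; monomorphic
and all-missing sites are dropped. Signs of PCs are unconstrained.

The admixture model is the standard unsupervised binomial likelihood;
fitting is frappe-style EM with block updates of Q and P from seeded
Dirichlet/uniform starts. EM guarantees a non-decreasing
log-likelihood, and P is kept in [1e−6, 1−1e−6] — the clamp is the
constrained M-step maximizer, so monotonicity survives it. The
stopping rule is an absolute log-likelihood gain < 1e−2 (negligible
relative to typical |ℓ| ~ 1e4–1e5) or 500 iterations; a non-converged
fit returns the best iterate, flagged. EM was chosen over quasi-Newton
acceleration deliberately: the likelihood target is identical and the
per-iteration monotonicity is what the validation asserts; slower
convergence is acceptable at the package's scale. K = 1 has the closed
form (pooled frequencies) and skips EM.

Cross-validation masks random fractions (10% by default) of called
genotype cells, refits on the rest, and scores held-out dosages by
mean binomial deviance; `choose_k` repeats this over independent
holdouts (5 by default), fits each K with best-of-N seeded restarts
(20 restarts for full fits, N/4 for CV refits to bound cost), and
reports the K minimizing CV error.

## Synthetic data: what it emulates, what it does not

**Balding–Nichols generator** (site-independent): ancestral frequency
p ~ U(0.05, 0.95) per site; population frequency ~ Beta(p(1−F)/F,
(1−p)(1−F)/F), degenerating to p at F = 0; genotypes Binomial(2, f);
missingness i.i.d. Bernoulli; depths negative binomial with mean 30
(inside the 10–60 retention band, shape 8, so the depth mask is
exercised without destroying most genotypes); QD ~ U(15, 35) and
FS ~ U(0, 10), benign by construction so that filter tests control
violations explicitly. Planted sweeps push the focal population's
frequency in a region to `freq_shift` (0.98) toward its locally major
allele, with a fraction 1 − 1/pi_reduction of the region's sites made
fully monomorphic — jointly producing the ~10× diversity loss and the
differentiation spike the scan is designed to detect. Truth tables
(drift F per population, sweep coordinates, per-site ancestral and
per-population frequencies) are serialized beside every VCF, and a
fixed seed yields byte-identical output.

**Forward Wright–Fisher simulator**: 2N haplotypes per generation,
random union of gametes (selfing allowed), Poisson(rL) crossovers at
uniform points, infinite-sites mutation at continuous positions
(floored to integer bp at export, with the rare collisions dropped);
burn-in 10N generations to quasi-equilibrium; fixed mutations pruned
every 25 generations. Default validation conditions: N = 100, 1 Mb,
μ = 1e−6/bp chosen to yield ~2,000 segregating sites in a 50-diploid
sample (Watterson's 4NμL·a_n), r = 1e−6/bp as motivated above.

Neither generator emulates: site-frequency-spectrum distortions from
demography, linked selection outside planted regions, sequencing error
in genotypes (missingness and depth are modeled, miscalls are not),
allele dropout at restriction sites (a known RADseq artifact), or
correlated missingness. Passing tests therefore demonstrate estimator
correctness and recovery under the stated models — not robustness to
those real-data artifacts.

## Problem sizes used in validation

The validation suite runs: F_ST recovery at 2×50 diploids × 20,000
SNPs over 10 Mb; sweep recovery with 5 planted 100 kb sweeps among
~1,000 scan windows; the WF equilibrium population above for LD/Ne;
structure recovery at 2×30 × 2,000 SNPs with K ∈ {1..4}, 2–3 restarts
and 3 CV folds. These sizes give comfortable signal-to-noise for every
tested tolerance while keeping the whole suite in the minutes range;
the library itself has no such limits.

## Known limitations

* Two-population F_ST only; the multi-population W&C generalization is
  out of scope.
* The HWE filter's pooled default over-removes under strong structure
  (see above).
* LD-based Ne inherits every assumption of the Sved relation: neutral
  equilibrium, a correct physical→genetic map, and unphased-genotype
  r² standing in for haplotype r²; estimates at deep t (tightly linked
  bins) are upward-noisy.
* The admixture CV masks cells independently; linked sites make the
  held-out cells not strictly independent of training data, which can
  flatten the CV curve at high marker densities.
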