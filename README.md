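# radsweep

Post-variant-calling population genomics for reduced-representation
(e.g. RADseq) SNP data: the full path from a multi-sample VCF to
population-genetic inference — variant filtering, per-population
diversity, windowed F_ST, selective-sweep detection, linkage
disequilibrium, LD-based effective population size, PCA and admixture —
with first-class synthetic-data generators so every stage can be
validated against known truth.

It is written for population / conservation geneticists comparing
diverged populations (say, farmed vs wild stocks of a fish) who would
otherwise chain VCFtools, PLINK, ADMIXTURE, PopLDdecay and SNeP, and
want one importable, tested library instead.

## What it computes

**Filtering.** Sites are removed by GATK-style hard thresholds
(QD < 2 or FS > 30), SNP clusters (>3 SNPs in 35 bp), genotypes are
masked at depth ≤ 10 or ≥ 60, then sites by missingness (>10%), minor
allele frequency (<0.05) and a Hardy–Weinberg exact test (p < 0.001),
the exact p coming from full enumeration of heterozygote counts
conditional on the allele counts.

**Diversity.** Per site, HO = fraction of called genotypes that are
heterozygous; HE = 2p(1−p) (optionally with the n/(n−1) small-sample
factor); π_s = 2·c_ref·c_alt / (n(n−1)) over called alleles, summed in
sliding windows and divided by window length; F_IS per individual by
the method of moments, F = (O_hom − E_hom)/(L − E_hom).

**Differentiation and sweeps.** Per-site Weir & Cockerham (1984)
variance components a (among-population) and a+b+c (total), aggregated
per 100 kb window (10 kb step) as F_ST = Σa / Σ(a+b+c). The window
F_ST distribution is Z-transformed; each window also carries
log2(π_ref/π_focal). Windows in the top 5% of *both* statistics are
outliers; overlapping outlier windows merge into sweep regions and pick
up overlapping genes from a GFF3.

**LD and Ne.** r² is the squared Pearson correlation of dosages over
shared called individuals; pairs within 100 kb are binned by distance,
and each bin's recombination fraction c (under a fixed physical→genetic
map) yields Ne = (1/4c)(1/adj_r² − α) at time t = 1/(2c) generations
ago, with adj_r² = mean r² − 1/(2n).

**Structure.** PCA with Patterson normalization; admixture by EM on the
binomial likelihood g_ij ~ Bin(2, Σ_k q_ik p_kj), with best-of-N seeded
restarts and cross-validated choice of K via masked-genotype deviance.

**Synthetic data.** A Balding–Nichols generator (per-population allele
frequencies Beta-distributed around an ancestral frequency with drift
F, so E[F_ST] ≈ F) with plantable sweep regions, missingness, depths
and filter violations; and a forward Wright–Fisher simulator (random
union of gametes, crossovers, infinite-sites mutation) for genuinely
linked variants.

## Worked example

`examples/03_sweep_scan.py` plants two sweeps in the "farmed"
population (frequencies pushed to 0.98 toward fixation, 10× diversity
loss) on a 3-chromosome, 9,000-SNP genome and scans for them:

```
thresholds: Z(FST) >= 2.63, log2(pi_wild/pi_farmed) >= 1.27
15 outlier windows -> 2 regions
  chr1:270001-430000  windows=7 peakZ=4.7  genes=chr1_g6,chr1_g7,chr1_g8,chr1_g9...
  chr2:560001-730000  windows=8 peakZ=4.8  genes=chr2_g12,chr2_g13,chr2_g14,chr2_g15...
```

The two reported thresholds are the empirical 95th percentiles of
Z(F_ST) and the log2 π-ratio; the two merged regions bracket the
planted sweeps at chr1:300–400 kb and chr2:600–700 kb (window overlap
widens them by up to one window on each side), and the attached gene
IDs are everything overlapping each region in the toy annotation.

The other scripts in `examples/` demonstrate filtering, the diversity
table, LD decay + Ne, PCA + admixture, and the YAML-driven pipeline
with its content-hashed run manifest. The same stages are scriptable
from the shell: `radsweep simulate|filter|stats|scan|ld|ne|pca|admixture|pipeline`.

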