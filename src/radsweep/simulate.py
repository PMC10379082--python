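"""Synthetic call sets with known truth for every analysis stage.

Two generators:

* :func:`simulate_balding_nichols` — site-independent genotypes for
  diversity, F_ST, sweep-scan and structure tests.  Per-population
  allele frequencies are Beta-distributed around a shared ancestral
  frequency with drift parameter F (so E[F_ST] ~ F), genotypes are
  binomial draws, and missingness, read depths and GATK-style QD/FS
  annotations are layered on top.

* :func:`simulate_wright_fisher` — a discrete-generation forward
  simulator (random union of gametes, per-bp crossovers, infinite-sites
  mutation) that produces genuinely linked variants for the LD and Ne
  stages.

All randomness flows from a single seeded generator; the seed is
recorded in the VCF header, and a fixed seed reproduces byte-identical
output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import MISSING, GeneInterval, GenotypeMatrix, PopulationMap, VariantTable
from .vcf_io import write_gff_genes, write_population_map, write_vcf

log = logging.getLogger(__name__)


@dataclass
class SweepSpec:
    """A planted sweep: focal population pushed toward fixation inside a span."""

    chrom: str
    start: int
    end: int
    focal_pop: str
    freq_shift: float = 0.98
    pi_reduction: float = 10.0


@dataclass
class SimulationConfig:
    """Parameters of the site-independent (Balding-Nichols) generator."""

    seed: int
    n_pops: int = 2
    samples_per_pop: int = 50
    n_chrom: int = 10
    chrom_length_bp: int = 1_000_000
    n_snps: int = 20_000
    drift_f: tuple | float = 0.1
    sweep_regions: list = field(default_factory=list)
    missing_rate: float = 0.02
    depth_mean: float = 30.0
    depth_dispersion: float = 8.0  # NB shape; larger = tighter around the mean
    pop_labels: list | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if np.isscalar(self.drift_f):
            self.drift_f = tuple([float(self.drift_f)] * self.n_pops)
        else:
            self.drift_f = tuple(float(f) for f in self.drift_f)
        if len(self.drift_f) != self.n_pops:
            raise ValueError("drift_f length must equal n_pops")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0,1)")
        if self.pop_labels is None:
            self.pop_labels = [f"pop{i + 1}" for i in range(self.n_pops)]
        for s in self.sweep_regions:
            if s.focal_pop not in self.pop_labels:
                raise ValueError(f"sweep focal_pop {s.focal_pop!r} not a population")


@dataclass
class SimulationTruth:
    """Planted parameters serialized beside every generated call set."""

    seed: int
    model: str
    drift_f: dict = field(default_factory=dict)
    sweep_regions: list = field(default_factory=list)
    census_n: int | None = None
    ancestral_freqs: list | None = None
    pop_freqs: dict | None = None

    def to_json(self, path):
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)
        return path


def _positions(rng, cfg):
    """Sorted unique integer positions per chromosome."""
    per = np.full(cfg.n_chrom, cfg.n_snps // cfg.n_chrom)
    per[: cfg.n_snps % cfg.n_chrom] += 1
    chroms, pos = [], []
    for i in range(cfg.n_chrom):
        name = f"chr{i + 1}"
        p = np.sort(rng.choice(cfg.chrom_length_bp, size=per[i], replace=False)) + 1
        chroms.append(np.full(per[i], name, dtype=object))
        pos.append(p)
    return np.concatenate(chroms), np.concatenate(pos)


_BASE_PAIRS = np.array([("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")], dtype=object)


def _alleles(rng, n):
    which = rng.integers(0, len(_BASE_PAIRS), size=n)
    return _BASE_PAIRS[which, 0], _BASE_PAIRS[which, 1]


def simulate_balding_nichols(cfg: SimulationConfig):
    """Generate (VariantTable, GenotypeMatrix, PopulationMap, SimulationTruth).

    Ancestral frequencies are Uniform(0.05, 0.95); each population's
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) (equal to p when F = 0);
    genotypes are Binomial(2, freq); sweeps listed in the config are
    planted before the genotype draw.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom, pos = _positions(rng, cfg)
    n_sites = len(pos)
    p_anc = rng.uniform(0.05, 0.95, size=n_sites)

    freqs = {}
    for label, F in zip(cfg.pop_labels, cfg.drift_f):
        if F <= 0:
            freqs[label] = p_anc.copy()
        else:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            freqs[label] = rng.beta(a, b)

    freqs = plant_sweeps(cfg, chrom, pos, freqs, rng)

    dosages = np.empty((cfg.n_pops * cfg.samples_per_pop, n_sites), dtype=np.int8)
    samples, assignments = [], {}
    for k, label in enumerate(cfg.pop_labels):
        rows = slice(k * cfg.samples_per_pop, (k + 1) * cfg.samples_per_pop)
        dosages[rows] = rng.binomial(2, freqs[label], size=(cfg.samples_per_pop, n_sites))
        for i in range(cfg.samples_per_pop):
            s = f"{label}_{i + 1:03d}"
            samples.append(s)
            assignments[s] = label

    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = MISSING

    k_nb = cfg.depth_dispersion
    depths = rng.negative_binomial(
        k_nb, k_nb / (k_nb + cfg.depth_mean), size=dosages.shape
    ).astype(np.int32)

    ref, alt = _alleles(rng, n_sites)
    qd = rng.uniform(15, 35, size=n_sites).round(2)
    fs = rng.uniform(0, 10, size=n_sites).round(3)

    vt = VariantTable(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qd=qd,
        fs=fs,
        site_id=np.arange(n_sites),
        contigs=[f"chr{i + 1}" for i in range(cfg.n_chrom)],
        contig_lengths={f"chr{i + 1}": cfg.chrom_length_bp for i in range(cfg.n_chrom)},
    )
    gm = GenotypeMatrix(samples=samples, dosages=dosages, depths=depths)
    pmap = PopulationMap(assignments)
    truth = SimulationTruth(
        seed=cfg.seed,
        model="balding_nichols",
        drift_f=dict(zip(cfg.pop_labels, cfg.drift_f)),
        sweep_regions=[asdict(s) for s in cfg.sweep_regions],
        ancestral_freqs=np.round(p_anc, 6).tolist(),
        pop_freqs={k: np.round(v, 6).tolist() for k, v in freqs.items()},
    )
    return vt, gm, pmap, truth


def plant_sweeps(cfg: SimulationConfig, chrom, pos, freqs: dict, rng):
    """Push focal-population frequencies toward fixation inside each region.

    Within a region, a fraction 1 - 1/pi_reduction of sites becomes
    fully monomorphic in the focal population; the rest sit at
    ``freq_shift`` for the locally major allele.  Other populations are
    untouched.  Overlapping regions or regions on unknown chromosomes
    are fatal.
    """
    regions = cfg.sweep_regions
    if not regions:
        return freqs
    known = set(np.unique(chrom))
    by_chrom: dict = {}
    for s in regions:
        if s.chrom not in known:
            raise ValueError(f"sweep region on unknown chromosome {s.chrom!r}")
        for t in by_chrom.get(s.chrom, []):
            if s.start <= t.end and s.end >= t.start:
                raise ValueError("overlapping sweep regions")
        by_chrom.setdefault(s.chrom, []).append(s)

    freqs = {k: v.copy() for k, v in freqs.items()}
    for s in regions:
        sel = (chrom == s.chrom) & (pos >= s.start) & (pos <= s.end)
        f = freqs[s.focal_pop][sel]
        major_is_alt = f >= 0.5
        fix_hard = rng.random(f.shape) < (1.0 - 1.0 / s.pi_reduction)
        shifted = np.where(major_is_alt, s.freq_shift, 1.0 - s.freq_shift)
        hard = np.where(major_is_alt, 1.0, 0.0)
        freqs[s.focal_pop][sel] = np.where(fix_hard, hard, shifted)
    return freqs


def simulate_filter_testcase(seed: int, n_background: int = 200):
    """A small call set with planted violations of each filter rule.

    Returns (vt, gm, truth) where ``truth`` maps each filter stage to
    the set of planted site_ids it must remove (and nothing else).
    Background sites are benign: QD/FS well inside thresholds, spaced
    >= 200 bp apart, depth safely inside (10, 60), no missingness, MAF
    0.3-0.5, genotype counts drawn at HWE.
    """
    rng = np.random.default_rng(seed)
    n_samples = 40
    spacing = 200
    pos = (1 + np.arange(n_background) * spacing).astype(np.int64)
    chrom = np.full(n_background, "chr1", dtype=object)

    p = rng.uniform(0.3, 0.5, size=n_background)
    dosages = rng.binomial(2, p, size=(n_samples, n_background)).astype(np.int8)
    # re-draw rare monomorphic columns so the background passes the MAF screen
    for j in range(n_background):
        while len(np.unique(dosages[:, j])) == 1:
            dosages[:, j] = rng.binomial(2, 0.4, size=n_samples)
    depths = rng.integers(20, 50, size=dosages.shape).astype(np.int32)
    qd = rng.uniform(10, 30, size=n_background)
    fs = rng.uniform(0, 20, size=n_background)

    truth = {"site_annotations": set(), "snp_clusters": set(), "missing_maf": set(), "hwe": set()}

    # QD / FS violations on isolated background sites
    bad = rng.choice(n_background, size=8, replace=False)
    qd[bad[:4]] = rng.uniform(0.1, 1.9, size=4)
    fs[bad[4:]] = rng.uniform(30.5, 60.0, size=4)
    truth["site_annotations"].update(bad.tolist())

    site_id = np.arange(n_background)

    # a cluster of 4 SNPs inside 35 bp, appended past the background span
    base = int(pos[-1]) + 1000
    cl_pos = base + np.array([0, 10, 20, 30])
    cl_dos = rng.binomial(2, 0.4, size=(n_samples, 4)).astype(np.int8)
    cl_ids = np.arange(n_background, n_background + 4)
    truth["snp_clusters"].update(cl_ids.tolist())

    # high-missingness site and a low-MAF site
    mm_pos = base + np.array([2000, 3000])
    mm_dos = np.zeros((n_samples, 2), dtype=np.int8)
    mm_dos[:, 0] = rng.binomial(2, 0.4, size=n_samples)
    mm_dos[: n_samples // 2, 0] = MISSING  # 50% missing
    mm_dos[:, 1] = 0
    mm_dos[0, 1] = 1  # single het: MAF 1/80 < 0.05
    mm_ids = np.arange(n_background + 4, n_background + 6)
    truth["missing_maf"].update(mm_ids.tolist())

    # all-heterozygous site: gross HWE violation
    hwe_pos = base + np.array([4000])
    hwe_dos = np.ones((n_samples, 1), dtype=np.int8)
    hwe_ids = np.array([n_background + 6])
    truth["hwe"].update(hwe_ids.tolist())

    pos = np.concatenate([pos, cl_pos, mm_pos, hwe_pos])
    chrom = np.concatenate([chrom, np.full(7, "chr1", dtype=object)])
    dosages = np.concatenate([dosages, cl_dos, mm_dos, hwe_dos], axis=1)
    depths = np.concatenate(
        [depths, rng.integers(20, 50, size=(n_samples, 7)).astype(np.int32)], axis=1
    )
    qd = np.concatenate([qd, rng.uniform(10, 30, size=7)])
    fs = np.concatenate([fs, rng.uniform(0, 20, size=7)])
    site_id = np.arange(len(pos))

    ref, alt = _alleles(rng, len(pos))
    vt = VariantTable(
        chrom=chrom, pos=pos, ref=ref, alt=alt, qd=qd, fs=fs, site_id=site_id,
        contigs=["chr1"], contig_lengths={"chr1": int(pos[-1]) + 1000},
    )
    samples = [f"s{i + 1:03d}" for i in range(n_samples)]
    gm = GenotypeMatrix(samples=samples, dosages=dosages, depths=depths)
    truth = {k: set(map(int, v)) for k, v in truth.items()}
    return vt, gm, truth


# --------------------------------------------------------------------------
# forward Wright-Fisher simulator (linked variants)


@dataclass
class WrightFisherConfig:
    seed: int
    census_n: int = 100
    chrom_length_bp: int = 1_000_000
    mu_per_bp: float = 1e-6
    recomb_per_bp: float = 1e-8
    burnin_generations: int | None = None  # default 10 * census_n
    n_samples: int = 50
    max_sites: int = 200_000

    def __post_init__(self):
        if self.census_n > 500:
            raise ValueError("census_n > 500 exceeds desk-scale limits")
        if self.burnin_generations is None:
            self.burnin_generations = 10 * self.census_n


def _gamete(h1, h2, n_cross, L, rng):
    if n_cross == 0:
        return h1.copy() if rng.random() < 0.5 else h2.copy()
    xs = np.sort(rng.uniform(0, L, size=n_cross))
    start = int(rng.random() < 0.5)
    s1 = (np.searchsorted(xs, h1) + start) % 2 == 0
    s2 = (np.searchsorted(xs, h2) + start) % 2 == 1
    return np.sort(np.concatenate([h1[s1], h2[s2]]))


def _prune_fixed(haps):
    allm = np.concatenate(haps) if haps else np.empty(0)
    if allm.size == 0:
        return haps
    vals, counts = np.unique(allm, return_counts=True)
    fixed = vals[counts == len(haps)]
    if fixed.size == 0:
        return haps
    return [h[~np.isin(h, fixed)] for h in haps]


def simulate_wright_fisher(cfg: WrightFisherConfig):
    """Equilibrium forward simulation with recombination and mutation.

    Evolves 2N haplotypes (random union of gametes, Poisson crossovers,
    infinite-sites mutation at continuous positions) for the burn-in,
    then samples ``n_samples`` diploids without replacement and returns
    (VariantTable, GenotypeMatrix, PopulationMap, SimulationTruth).
    """
    rng = np.random.default_rng(cfg.seed)
    N, L = cfg.census_n, float(cfg.chrom_length_bp)
    mu_per_gamete = cfg.mu_per_bp * L
    r_per_gamete = cfg.recomb_per_bp * L
    haps = [np.empty(0) for _ in range(2 * N)]

    for gen in range(cfg.burnin_generations):
        new = []
        parents = rng.integers(0, N, size=(N, 2))
        n_cross = rng.poisson(r_per_gamete, size=(N, 2))
        n_mut = rng.poisson(mu_per_gamete, size=(N, 2))
        for i in range(N):
            for side in range(2):
                pa = parents[i, side]
                g = _gamete(haps[2 * pa], haps[2 * pa + 1], n_cross[i, side], L, rng)
                if n_mut[i, side]:
                    g = np.sort(np.concatenate([g, rng.uniform(0, L, size=n_mut[i, side])]))
                new.append(g)
        haps = new
        if gen % 25 == 24:
            haps = _prune_fixed(haps)
            total = sum(len(h) for h in haps)
            if total > cfg.max_sites * 2 * N:
                raise RuntimeError(
                    "site count exploding; lower mu_per_bp or chrom_length_bp"
                )
    haps = _prune_fixed(haps)

    # sample diploids without replacement
    order = rng.permutation(N)[: cfg.n_samples]
    sampled = []
    for i in order:
        sampled.extend([haps[2 * i], haps[2 * i + 1]])

    # segregating sites among the sample
    allm = np.concatenate(sampled)
    vals, counts = np.unique(allm, return_counts=True)
    seg = vals[(counts > 0) & (counts < len(sampled))]
    pos_f = np.sort(seg)
    dosages = np.zeros((cfg.n_samples, len(pos_f)), dtype=np.int8)
    for i in range(cfg.n_samples):
        for h in (sampled[2 * i], sampled[2 * i + 1]):
            j = np.searchsorted(pos_f, h)
            hitting = j[(j < len(pos_f)) & (pos_f[np.minimum(j, len(pos_f) - 1)] == h)]
            dosages[i, hitting] += 1

    # integer positions; drop the rare floor collisions
    pos_i = np.floor(pos_f).astype(np.int64) + 1
    keep = np.concatenate([[True], np.diff(pos_i) > 0])
    pos_i = pos_i[keep]
    dosages = dosages[:, keep]

    n_sites = len(pos_i)
    ref, alt = _alleles(rng, n_sites)
    vt = VariantTable(
        chrom=np.full(n_sites, "chr1", dtype=object),
        pos=pos_i,
        ref=ref,
        alt=alt,
        qd=rng.uniform(15, 35, size=n_sites).round(2),
        fs=rng.uniform(0, 10, size=n_sites).round(3),
        site_id=np.arange(n_sites),
        contigs=["chr1"],
        contig_lengths={"chr1": cfg.chrom_length_bp},
    )
    samples = [f"wf_{i + 1:03d}" for i in range(cfg.n_samples)]
    gm = GenotypeMatrix(samples=samples, dosages=dosages)
    pmap = PopulationMap({s: "wf" for s in samples})
    truth = SimulationTruth(
        seed=cfg.seed, model="wright_fisher", census_n=N,
    )
    log.info("simulate_wright_fisher: %d segregating sites in sample", n_sites)
    return vt, gm, pmap, truth


def toy_gff_genes(n_chrom: int, chrom_length_bp: int, every_bp: int = 50_000, span_bp: int = 20_000):
    """Genes tiled along each chromosome for annotation tests."""
    genes = []
    for i in range(n_chrom):
        c = f"chr{i + 1}"
        start = 10_000
        g = 0
        while start + span_bp <= chrom_length_bp:
            g += 1
            genes.append(GeneInterval(chrom=c, start=start, end=start + span_bp - 1, gene_id=f"{c}_g{g}"))
            start += every_bp
    return genes


def write_simulation(outdir, vt, gm, pmap, truth, genes=None):
    """Serialize a simulated call set (VCF, pops.tsv, truth.json, genes.gff3)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": write_vcf(
            outdir / "sim.vcf", vt, gm,
            extra_header_lines=[f"##radsweep_seed={truth.seed}", f"##radsweep_model={truth.model}"],
        ),
        "pops": write_population_map(outdir / "pops.tsv", pmap),
        "truth": truth.to_json(outdir / "truth.json"),
    }
    if genes:
        paths["gff"] = write_gff_genes(outdir / "genes.gff3", genes)
    return paths
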