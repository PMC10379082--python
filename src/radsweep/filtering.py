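"""The SNP filter cascade applied between raw genotypes and analysis.

Pipeline order is fixed: site annotations (QD/FS) -> SNP clusters ->
per-genotype depth mask -> missingness/MAF -> Hardy-Weinberg exact test.
Each stage returns a boolean keep-mask plus a :class:`FilterReport`, and
reports chain (stage k input = stage k-1 retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .datatypes import MISSING, GenotypeMatrix, VariantTable

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    stage: str
    n_input: int
    n_removed: int
    n_retained: int
    params: dict = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self):
        if self.n_input != self.n_removed + self.n_retained:
            raise ValueError("FilterReport counts do not add up")


def _report(stage, keep, params, notes=""):
    keep = np.asarray(keep, dtype=bool)
    return keep, FilterReport(
        stage=stage,
        n_input=keep.size,
        n_removed=int((~keep).sum()),
        n_retained=int(keep.sum()),
        params=dict(params),
        notes=notes,
    )


def filter_site_annotations(vt: VariantTable, qd_min: float = 2.0, fs_max: float = 30.0):
    """GATK-style hard filter: remove sites with QD < qd_min or FS > fs_max.

    Boundary values are retained (the thresholds are strict inequalities).
    Sites missing both annotations are retained and counted in the notes.
    """
    if not (np.isfinite(qd_min) and np.isfinite(fs_max)):
        raise ValueError("thresholds must be finite")
    bad_qd = np.where(np.isfinite(vt.qd), vt.qd < qd_min, False)
    bad_fs = np.where(np.isfinite(vt.fs), vt.fs > fs_max, False)
    keep = ~(bad_qd | bad_fs)
    n_unannotated = int((~np.isfinite(vt.qd) & ~np.isfinite(vt.fs)).sum())
    notes = f"{n_unannotated} sites lacked both QD and FS (retained)" if n_unannotated else ""
    return _report("site_annotations", keep, {"qd_min": qd_min, "fs_max": fs_max}, notes)


def filter_snp_clusters(vt: VariantTable, window_bp: int = 35, max_snps: int = 3):
    """Remove every SNP lying in any length-``window_bp`` window (same
    chromosome) that contains more than ``max_snps`` SNPs.

    Mirrors GATK's SnpCluster semantics: all members of a violating
    window are removed, so exactly ``max_snps`` SNPs per window survive
    only when no window around them is overfull.
    """
    keep = np.ones(vt.n_sites, dtype=bool)
    for c in vt.contigs:
        idx = np.flatnonzero(vt.chrom == c)
        if len(idx) <= max_snps:
            continue
        pos = vt.pos[idx]
        # window starting at each site: sites within [pos_i, pos_i + window_bp)
        hi = np.searchsorted(pos, pos + window_bp, side="left")
        lo = np.arange(len(pos))
        over = (hi - lo) > max_snps
        for i in np.flatnonzero(over):
            keep[idx[i : hi[i]]] = False
    return _report("snp_clusters", keep, {"window_bp": window_bp, "max_snps": max_snps})


def mask_genotypes_by_depth(
    gm: GenotypeMatrix, min_dp: int = 10, max_dp: int = 60
) -> GenotypeMatrix:
    """Set genotypes with depth <= min_dp or >= max_dp to MISSING.

    A genotype survives only with min_dp < depth < max_dp (open interval).
    """
    if gm.depths is None:
        raise ValueError("depth mask requested but the matrix carries no depths")
    bad = (gm.depths <= min_dp) | (gm.depths >= max_dp)
    dosages = gm.dosages.copy()
    dosages[bad] = MISSING
    return GenotypeMatrix(samples=gm.samples, dosages=dosages, depths=gm.depths)


def filter_missing_maf(
    gm: GenotypeMatrix,
    vt: VariantTable | None = None,
    max_missing_frac: float = 0.1,
    maf_min: float = 0.05,
):
    """Remove sites with too much missingness or too rare a minor allele.

    A site is removed iff its fraction of MISSING genotypes exceeds
    ``max_missing_frac`` (VCFtools ``--max-missing 0.9`` == at most 10%
    missing) or the minor-allele frequency among called alleles falls
    below ``maf_min`` (``--maf 0.05`` retains MAF >= 0.05).  Sites with
    zero called genotypes are removed and counted separately.
    """
    dos = gm.dosages
    called = dos != MISSING
    n_called = called.sum(axis=0)
    miss_frac = 1.0 - n_called / gm.n_samples
    alt = np.where(called, dos, 0).sum(axis=0)
    tot = 2 * n_called
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    no_calls = n_called == 0
    keep = (~no_calls) & (miss_frac <= max_missing_frac) & (maf >= maf_min)
    notes = f"{int(no_calls.sum())} sites had zero called genotypes" if no_calls.any() else ""
    return _report(
        "missing_maf",
        keep,
        {"max_missing_frac": max_missing_frac, "maf_min": maf_min},
        notes,
    )


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test (Wigginton et al. style).

    Enumerates every heterozygote count consistent with the observed
    allele counts and sums the probabilities of configurations no more
    likely than the observed one.  Returns a p-value in (0, 1].
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_alt = n_het + 2 * n_hom_alt
    n_rare = min(n_alt, 2 * n - n_alt)
    # attainable het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    # P(het = h | allele counts): multinomial over genotypes with 2^h phase factor
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_het)]
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_filter(
    gm: GenotypeMatrix,
    vt: VariantTable | None = None,
    pmap=None,
    alpha: float = 0.001,
    per_population: bool = False,
):
    """Remove sites whose HWE exact p-value falls below ``alpha``.

    By default genotypes are pooled across all samples; with
    ``per_population`` a site is removed if it deviates (p < alpha) in
    any one population of the map.
    """
    dos = gm.dosages

    def _site_fails(sub: np.ndarray) -> np.ndarray:
        called = sub != MISSING
        n_rr = ((sub == 0) & called).sum(axis=0)
        n_ra = ((sub == 1) & called).sum(axis=0)
        n_aa = ((sub == 2) & called).sum(axis=0)
        fails = np.zeros(sub.shape[1], dtype=bool)
        cache: dict = {}
        for j in range(sub.shape[1]):
            key = (int(n_rr[j]), int(n_ra[j]), int(n_aa[j]))
            if key[0] + key[1] + key[2] == 0:
                continue
            if key not in cache:
                cache[key] = hwe_exact_test(*key)
            fails[j] = cache[key] < alpha
        return fails

    if per_population:
        if pmap is None:
            raise ValueError("per_population HWE filter needs a population map")
        fails = np.zeros(gm.n_sites, dtype=bool)
        for pop in pmap.populations:
            idx = pmap.indices_for(pop, gm.samples)
            fails |= _site_fails(dos[idx])
    else:
        fails = _site_fails(dos)
    return _report(
        "hwe", ~fails, {"alpha": alpha, "per_population": per_population}
    )


@dataclass
class FilterParams:
    """Thresholds for the full cascade; ``None`` disables a stage."""

    qd_min: float = 2.0
    fs_max: float = 30.0
    cluster_window_bp: int = 35
    cluster_max_snps: int = 3
    min_dp: int | None = 10
    max_dp: int | None = 60
    max_missing_frac: float = 0.1
    maf_min: float = 0.05
    hwe_alpha: float | None = 0.001
    hwe_per_population: bool = False


def apply_filter_pipeline(
    vt: VariantTable, gm: GenotypeMatrix, params: FilterParams | None = None, pmap=None
):
    """Run the fixed filter cascade and return (vt, gm, [FilterReport]).

    The depth mask is applied before missingness/MAF so depth-masked
    cells count as missing downstream.
    """
    params = params or FilterParams()
    reports = []

    keep, rep = filter_site_annotations(vt, params.qd_min, params.fs_max)
    reports.append(rep)
    vt, gm = vt.subset(keep), gm.subset_sites(keep)

    keep, rep = filter_snp_clusters(vt, params.cluster_window_bp, params.cluster_max_snps)
    reports.append(rep)
    vt, gm = vt.subset(keep), gm.subset_sites(keep)

    if params.min_dp is not None and params.max_dp is not None and gm.depths is not None:
        gm = mask_genotypes_by_depth(gm, params.min_dp, params.max_dp)
        reports.append(
            FilterReport(
                stage="depth_mask",
                n_input=vt.n_sites,
                n_removed=0,
                n_retained=vt.n_sites,
                params={"min_dp": params.min_dp, "max_dp": params.max_dp},
                notes="genotype-level mask; no sites removed at this stage",
            )
        )

    keep, rep = filter_missing_maf(gm, vt, params.max_missing_frac, params.maf_min)
    reports.append(rep)
    vt, gm = vt.subset(keep), gm.subset_sites(keep)

    if params.hwe_alpha is not None:
        keep, rep = hwe_filter(
            gm, vt, pmap, alpha=params.hwe_alpha, per_population=params.hwe_per_population
        )
        reports.append(rep)
        vt, gm = vt.subset(keep), gm.subset_sites(keep)

    return vt, gm, reports


def reports_to_tsv(reports, path):
    import pandas as pd

    rows = [
        {
            "stage": r.stage,
            "n_input": r.n_input,
            "n_removed": r.n_removed,
            "n_retained": r.n_retained,
            "params": ";".join(f"{k}={v}" for k, v in r.params.items()),
            "notes": r.notes,
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
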