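"""Pairwise linkage disequilibrium, distance-binned decay and LD-based Ne.

r^2 is the squared Pearson correlation of allele dosages over individuals
called at both sites (composite genotypic LD; no phasing or EM
haplotyping, matching what PopLDdecay computes on genotype data).  Ne
follows the Sved-type relation used by SNeP: for a distance bin with
recombination fraction c (from a fixed physical->genetic map),

    Ne = 1/(4c) * (1/adj_r2 - alpha),    t = 1/(2c) generations ago,

with adj_r2 the bin mean r^2 minus the 1/(2n) sample-size inflation and
alpha the mutation adjustment (1 by default, 2.2 when mutation matters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, VariantTable
from .windows import per_chrom

log = logging.getLogger(__name__)


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared dosage correlation over individuals called at both sites.

    Returns NaN when fewer than 2 shared calls remain or either site has
    zero dosage variance among them.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x, y = g1[ok], g2[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _ld_site_mask(gm: GenotypeMatrix, maf_min: float, max_missing: float) -> np.ndarray:
    dos = gm.dosages
    called = dos != MISSING
    n_called = called.sum(axis=0)
    miss = 1 - n_called / gm.n_samples
    alt = np.where(called, dos, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    return (miss <= max_missing) & (maf >= maf_min)


def ld_pairs(
    gm: GenotypeMatrix,
    vt: VariantTable,
    max_dist: int = 100_000,
    maf_min: float = 0.05,
    max_missing: float = 0.1,
    max_snps_per_chrom: int | None = 10_000,
    rng=None,
):
    """All intra-chromosomal (distance, r^2) pairs within ``max_dist``.

    Sites failing the MAF / missingness screens are excluded first; when
    a chromosome still holds more than ``max_snps_per_chrom`` sites it is
    thinned by seeded uniform subsampling.  Returns (distances, r2)
    arrays; pairs with undefined r^2 are dropped.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    keep = _ld_site_mask(gm, maf_min, max_missing)
    dists, r2s = [], []
    dos = gm.dosages.astype(float)
    dos[gm.dosages == MISSING] = np.nan
    for c, idx in per_chrom(vt):
        idx = idx[keep[idx]]
        if max_snps_per_chrom is not None and len(idx) > max_snps_per_chrom:
            sel = np.sort(rng.choice(len(idx), size=max_snps_per_chrom, replace=False))
            idx = idx[sel]
        if len(idx) < 2:
            continue
        pos = vt.pos[idx]
        X = dos[:, idx]
        ok = ~np.isnan(X)
        Xz = np.where(ok, X, 0.0)
        hi = np.searchsorted(pos, pos + max_dist, side="right")
        for j in range(len(idx) - 1):
            k0, k1 = j + 1, hi[j]
            if k1 <= k0:
                continue
            xj = Xz[:, j][:, None]
            okj = ok[:, j][:, None]
            both = okj & ok[:, k0:k1]
            n = both.sum(axis=0)
            Y = Xz[:, k0:k1]
            sx = (xj * both).sum(axis=0)
            sy = (Y * both).sum(axis=0)
            sxx = (xj * xj * both).sum(axis=0)
            syy = (Y * Y * both).sum(axis=0)
            sxy = (xj * Y * both).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                cov = sxy / n - (sx / n) * (sy / n)
                vx = sxx / n - (sx / n) ** 2
                vy = syy / n - (sy / n) ** 2
                r2 = cov * cov / (vx * vy)
            valid = (n >= 2) & (vx > 0) & (vy > 0) & np.isfinite(r2)
            if valid.any():
                dists.append((pos[k0:k1] - pos[j])[valid])
                r2s.append(r2[valid])
    if not dists:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return np.concatenate(dists), np.concatenate(r2s)


@dataclass
class LDBin:
    dist_lo: float
    dist_hi: float
    mid: float
    mean_r2: float
    n_pairs: int


def default_bin_edges(max_dist: int = 100_000, first_bp: int = 1_000, n_log: int = 12):
    """0-1 kb, then logarithmically spaced bins out to ``max_dist``."""
    edges = np.unique(
        np.concatenate(
            [[0.0, float(first_bp)], np.geomspace(first_bp, max_dist, n_log + 1)[1:]]
        )
    )
    return edges


def ld_decay_bins(dists, r2s, bin_edges=None) -> list:
    """Mean r^2 per physical-distance bin; empty bins are dropped."""
    dists = np.asarray(dists, dtype=float)
    r2s = np.asarray(r2s, dtype=float)
    if len(dists) == 0:
        raise ValueError("no LD pairs to bin")
    if bin_edges is None:
        bin_edges = default_bin_edges(int(dists.max()) + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(dists, bin_edges) - 1
    bins = []
    for b in range(len(bin_edges) - 1):
        sel = which == b
        if not sel.any():
            continue
        bins.append(
            LDBin(
                dist_lo=float(bin_edges[b]),
                dist_hi=float(bin_edges[b + 1]),
                mid=float(dists[sel].mean()),
                mean_r2=float(r2s[sel].mean()),
                n_pairs=int(sel.sum()),
            )
        )
    return bins


@dataclass
class NeEstimate:
    t: float
    ne: float
    c: float
    bin: LDBin


def ne_from_ld(
    bins,
    n: int,
    bp_per_cM: float = 1e6,
    alpha: float = 1.0,
) -> list:
    """LD-based effective population size per distance bin.

    Each bin's mean pair distance maps to a recombination fraction
    ``c = mid / bp_per_cM / 100`` Morgans under the fixed map assumption
    (1 cM/Mb by default).  ``n`` is the number of diploid individuals;
    the 1/(2n) term removes the finite-sample inflation of r^2.  Bins
    whose adjusted r^2 is nonpositive, or whose Ne comes out nonpositive,
    produce no estimate.
    """
    if n < 2:
        raise ValueError("need n >= 2 individuals")
    out = []
    for b in bins:
        c = b.mid / bp_per_cM / 100.0
        if c <= 0:
            log.warning("skipping bin with nonpositive recombination fraction")
            continue
        adj = b.mean_r2 - 1.0 / (2 * n)
        if adj <= 0:
            continue
        ne = (1.0 / (4 * c)) * (1.0 / adj - alpha)
        if ne <= 0:
            continue
        out.append(NeEstimate(t=1.0 / (2 * c), ne=ne, c=c, bin=b))
    return out


def bins_to_tsv(bins, path):
    pd.DataFrame(
        [
            {
                "dist_lo": b.dist_lo,
                "dist_hi": b.dist_hi,
                "mid": b.mid,
                "mean_r2": b.mean_r2,
                "n_pairs": b.n_pairs,
            }
            for b in bins
        ]
    ).to_csv(path, sep="\t", index=False)
    return path


def ne_to_tsv(estimates, path):
    pd.DataFrame(
        [{"t": e.t, "ne": e.ne, "c": e.c, "mean_r2": e.bin.mean_r2} for e in estimates]
    ).to_csv(path, sep="\t", index=False)
    return path
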