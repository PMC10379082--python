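"""Selective-sweep scan: windowed Weir-Cockerham F_ST joined with the
log2 nucleotide-diversity ratio.

The scan follows the classic two-population outlier design: compute
per-site Weir & Cockerham (1984) variance components, aggregate them in
sliding windows as a ratio of sums ("weighted" F_ST, the VCFtools
convention), Z-transform the window F_ST distribution, compute
log2(pi_ref / pi_focal) per window, and flag windows in the top 5% of
BOTH statistics.  Runs of overlapping outlier windows merge into sweep
regions, which pick up overlapping gene annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GeneInterval, GenotypeMatrix, PopulationMap, VariantTable
from .diversity import site_pi
from .windows import per_chrom, window_site_slices, window_spans

log = logging.getLogger(__name__)


def _pop_freq_het(dos: np.ndarray):
    """Per-site (n individuals called, alt freq, observed het freq)."""
    called = dos != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, dos, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, ((dos == 1) & called).sum(axis=0) / np.maximum(n, 1), np.nan)
    return n, p, h


def site_fst_components(dos_a: np.ndarray, dos_b: np.ndarray):
    """Weir & Cockerham (1984) two-population variance components per site.

    Parameters are dosage submatrices (samples x sites) for the two
    populations.  Returns ``(a, abc)`` where ``a`` is the among-population
    component and ``abc = a + b + c`` the total; per-site F_ST is
    ``a / abc`` (may be negative).  Sites monomorphic across both
    populations, or with fewer than 2 called alleles in either, yield
    (0, 0) and are excluded from ratios downstream.
    """
    n1, p1, h1 = _pop_freq_het(dos_a)
    n2, p2, h2 = _pop_freq_het(dos_b)
    r = 2.0
    valid = (n1 >= 1) & (n2 >= 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - s2 * (r - 1) / r
            - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2.0

    abc = a + b + c
    monomorphic = valid & ((p_bar <= 0) | (p_bar >= 1))
    bad = ~valid | monomorphic | ~np.isfinite(abc) | (n_bar <= 1) | (n_c <= 0)
    a = np.where(bad, 0.0, a)
    abc = np.where(bad, 0.0, abc)
    return a, abc


def windowed_fst(
    vt: VariantTable,
    a: np.ndarray,
    abc: np.ndarray,
    window_bp: int = 100_000,
    step_bp: int = 10_000,
    min_snps: int = 1,
) -> pd.DataFrame:
    """Window F_ST as sum(a)/sum(a+b+c) over informative sites per window.

    Windows with fewer than ``min_snps`` informative sites carry NaN and
    are excluded downstream.
    """
    informative = abc != 0
    rows = []
    for ch, idx in per_chrom(vt):
        pos = vt.pos[idx]
        starts = window_spans(int(pos.max()), window_bp, step_bp)
        lo, hi = window_site_slices(pos, starts, window_bp)
        ca = np.concatenate([[0.0], np.cumsum(a[idx])])
        cabc = np.concatenate([[0.0], np.cumsum(abc[idx])])
        cn = np.concatenate([[0], np.cumsum(informative[idx].astype(int))])
        for s, i0, i1 in zip(starts, lo, hi):
            n_inf = int(cn[i1] - cn[i0])
            denom = cabc[i1] - cabc[i0]
            fst = (ca[i1] - ca[i0]) / denom if (n_inf >= min_snps and denom != 0) else np.nan
            rows.append((ch, int(s), int(s) + window_bp - 1, int(i1 - i0), n_inf, fst))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "n_informative", "fst"]
    )


def z_transform(values: np.ndarray) -> np.ndarray:
    """Standardize to zero mean and unit sample standard deviation (ddof=1).

    NaNs pass through; at least two finite values with nonzero spread are
    required.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise ValueError("z_transform needs >=2 finite values")
    sd = np.std(values[finite], ddof=1)
    if sd == 0:
        raise ValueError("z_transform undefined for zero spread")
    out = np.full_like(values, np.nan)
    out[finite] = (values[finite] - values[finite].mean()) / sd
    return out


def log2_pi_ratio(pi_a: np.ndarray, pi_b: np.ndarray) -> np.ndarray:
    """log2(pi_a / pi_b) per window; NaN where either pi is 0 or undefined."""
    pi_a = np.asarray(pi_a, dtype=float)
    pi_b = np.asarray(pi_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((pi_a > 0) & (pi_b > 0), np.log2(pi_a / pi_b), np.nan)
    return out


def joint_outliers(z_fst: np.ndarray, ratio: np.ndarray, quantile: float = 0.95):
    """Joint top-quantile outlier call on Z(F_ST) AND log2 pi-ratio.

    Thresholds are the empirical ``quantile`` (linear-interpolation /
    type-7) of each statistic over windows where it is defined; a window
    is an outlier iff both statistics are defined and both reach their
    threshold.  Returns (flags, t_z, t_ratio).
    """
    z_fst = np.asarray(z_fst, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    both = np.isfinite(z_fst) & np.isfinite(ratio)
    if both.sum() < 20:
        raise ValueError("too few windows with both statistics defined (<20)")
    t_z = float(np.quantile(z_fst[np.isfinite(z_fst)], quantile))
    t_r = float(np.quantile(ratio[np.isfinite(ratio)], quantile))
    flags = both & (z_fst >= t_z) & (ratio >= t_r)
    return flags, t_z, t_r


@dataclass
class SweepRegion:
    """A maximal run of overlapping outlier windows."""

    chrom: str
    start: int
    end: int
    n_windows: int
    peak_z_fst: float
    peak_log2_pi_ratio: float
    genes: list = field(default_factory=list)


def merge_and_annotate(windows: pd.DataFrame, genes=None) -> list:
    """Merge overlapping/adjacent outlier windows into SweepRegions and
    attach genes with >=1 bp overlap (deduplicated)."""
    out = []
    flagged = windows[windows["outlier"]].sort_values(["chrom", "start"])
    for chrom, grp in flagged.groupby("chrom", sort=False):
        cur = None
        for _, w in grp.iterrows():
            if cur is not None and w["start"] <= cur["end"] + 1:
                cur["end"] = max(cur["end"], int(w["end"]))
                cur["n"] += 1
                cur["pz"] = max(cur["pz"], float(w["z_fst"]))
                cur["pr"] = max(cur["pr"], float(w["log2_pi_ratio"]))
            else:
                if cur is not None:
                    out.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(w["start"]),
                    "end": int(w["end"]),
                    "n": 1,
                    "pz": float(w["z_fst"]),
                    "pr": float(w["log2_pi_ratio"]),
                }
        if cur is not None:
            out.append(cur)
    regions = []
    for r in out:
        g_ids = []
        if genes:
            for g in genes:
                if g.chrom == r["chrom"] and g.start <= r["end"] and g.end >= r["start"]:
                    if g.gene_id not in g_ids:
                        g_ids.append(g.gene_id)
        regions.append(
            SweepRegion(
                chrom=r["chrom"],
                start=r["start"],
                end=r["end"],
                n_windows=r["n"],
                peak_z_fst=r["pz"],
                peak_log2_pi_ratio=r["pr"],
                genes=g_ids,
            )
        )
    return regions


def sweep_scan(
    vt: VariantTable,
    gm: GenotypeMatrix,
    pmap: PopulationMap,
    pop_ref: str,
    pop_focal: str,
    window_bp: int = 100_000,
    step_bp: int = 10_000,
    quantile: float = 0.95,
    min_snps: int = 1,
    genes=None,
):
    """Run the full two-population scan.

    The pi-ratio is oriented pi_ref / pi_focal, so large positive values
    mean diversity loss in the focal population.  Returns
    ``(window_table, regions, thresholds)``.
    """
    idx_a = pmap.indices_for(pop_ref, gm.samples)
    idx_b = pmap.indices_for(pop_focal, gm.samples)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both populations must have samples in the matrix")
    a, abc = site_fst_components(gm.dosages[idx_a], gm.dosages[idx_b])
    wf = windowed_fst(vt, a, abc, window_bp, step_bp, min_snps)

    from .diversity import windowed_pi

    pa = windowed_pi(gm, vt, [gm.samples[i] for i in idx_a], window_bp, step_bp)
    pb = windowed_pi(gm, vt, [gm.samples[i] for i in idx_b], window_bp, step_bp)
    wf["pi_a"] = pa["pi"].to_numpy()
    wf["pi_b"] = pb["pi"].to_numpy()

    wf["z_fst"] = z_transform(wf["fst"].to_numpy())
    wf["log2_pi_ratio"] = log2_pi_ratio(wf["pi_a"].to_numpy(), wf["pi_b"].to_numpy())
    flags, t_z, t_r = joint_outliers(
        wf["z_fst"].to_numpy(), wf["log2_pi_ratio"].to_numpy(), quantile
    )
    wf["outlier"] = flags
    regions = merge_and_annotate(wf, genes)
    log.info(
        "sweep_scan: %d/%d outlier windows (t_z=%.3f, t_ratio=%.3f), %d regions",
        int(flags.sum()), len(wf), t_z, t_r, len(regions),
    )
    return wf, regions, (t_z, t_r)


def regions_to_tsv(regions, path):
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "n_windows": r.n_windows,
            "peak_z_fst": r.peak_z_fst,
            "peak_log2_pi_ratio": r.peak_log2_pi_ratio,
            "genes": ";".join(r.genes),
        }
        for r in regions
    ]
    pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "n_windows", "peak_z_fst", "peak_log2_pi_ratio", "genes"
    ]).to_csv(path, sep="\t", index=False)
    return path
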