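"""Per-population diversity: HO, HE, F_IS and windowed nucleotide diversity.

Per-site definitions, with missing genotypes dropped from denominators:

* HO = fraction of called genotypes that are heterozygous.
* HE = 2p(1-p) from called allele counts; the unbiased variant applies
  the n/(n-1) small-sample factor (n = called allele count).
* pi_site = 2 * c_ref * c_alt / (n (n-1)): the mean pairwise difference
  among the n called alleles at the site.
* F_IS follows the PLINK ``--het`` method-of-moments form per individual,
  F = (O_hom - E_hom) / (L - E_hom), averaged over individuals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, PopulationMap, VariantTable
from .windows import per_chrom, window_site_slices, window_spans


def _pop_rows(gm: GenotypeMatrix, pop_samples) -> np.ndarray:
    if pop_samples is None:
        return np.arange(gm.n_samples)
    pop = set(pop_samples)
    idx = np.array([i for i, s in enumerate(gm.samples) if s in pop], dtype=int)
    if len(idx) == 0:
        raise ValueError("no matrix samples in the requested population")
    return idx


def _allele_counts(dos: np.ndarray):
    """Per-site (alt count, called allele count) for a dosage submatrix."""
    called = dos != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, dos, 0).sum(axis=0)
    return alt, 2 * n_called


def observed_heterozygosity(gm: GenotypeMatrix, pop_samples=None):
    """Per-site observed heterozygosity and its mean over callable sites."""
    dos = gm.dosages[_pop_rows(gm, pop_samples)]
    called = dos != MISSING
    n_called = called.sum(axis=0)
    het = (dos == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        ho = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
    callable_ = n_called > 0
    if not callable_.any():
        warnings.warn("no callable sites for HO", stacklevel=2)
        return ho, np.nan
    return ho, float(np.nanmean(ho[callable_]))


def expected_heterozygosity(gm: GenotypeMatrix, pop_samples=None, unbiased: bool = False):
    """Per-site expected heterozygosity 2p(1-p) and its mean.

    With ``unbiased`` the per-site value is scaled by n/(n-1) where n is
    the called allele count (Nei's small-sample correction).
    """
    dos = gm.dosages[_pop_rows(gm, pop_samples)]
    alt, n = _allele_counts(dos)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        he = 2 * p * (1 - p)
        if unbiased:
            he = np.where(n > 1, he * n / np.maximum(n - 1, 1), np.nan)
    valid = np.isfinite(he)
    if not valid.any():
        warnings.warn("no callable sites for HE", stacklevel=2)
        return he, np.nan
    return he, float(np.nanmean(he[valid]))


def site_pi(gm: GenotypeMatrix, pop_samples=None) -> np.ndarray:
    """Per-site nucleotide diversity from called allele counts."""
    dos = gm.dosages[_pop_rows(gm, pop_samples)]
    alt, n = _allele_counts(dos)
    ref = n - alt
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n > 1, 2.0 * ref * alt / (np.maximum(n, 2) * np.maximum(n - 1, 1)), np.nan)
    return pi


def inbreeding_fis(gm: GenotypeMatrix, pop_samples=None):
    """Per-individual method-of-moments inbreeding coefficient and its mean.

    For each individual, over its called sites: F = (O_hom - E_hom) /
    (L - E_hom) with E_hom = sum_site (1 - 2p(1-p) n/(n-1)), allele
    frequencies taken from the population's called genotypes.
    Individuals with L - E_hom ~ 0 are excluded with a warning.
    """
    rows = _pop_rows(gm, pop_samples)
    dos = gm.dosages[rows]
    alt, n = _allele_counts(dos)
    polymorphic = (alt > 0) & (alt < n) & (n > 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / np.maximum(n, 1)
        e_het_site = 2 * p * (1 - p) * n / np.maximum(n - 1, 1)
    fs = []
    for i in range(dos.shape[0]):
        called = (dos[i] != MISSING) & polymorphic
        L = int(called.sum())
        if L == 0:
            fs.append(np.nan)
            continue
        o_hom = int(((dos[i] == 0) | (dos[i] == 2))[called].sum())
        e_hom = float((1.0 - e_het_site[called]).sum())
        denom = L - e_hom
        if abs(denom) < 1e-9:
            warnings.warn(
                f"individual {gm.samples[rows[i]]}: E_hom ~ L, excluded from F_IS",
                stacklevel=2,
            )
            fs.append(np.nan)
            continue
        fs.append((o_hom - e_hom) / denom)
    fs = np.array(fs)
    mean = float(np.nanmean(fs)) if np.isfinite(fs).any() else np.nan
    return fs, mean


def fis_from_het(gm: GenotypeMatrix, pop_samples=None) -> float:
    """Alternative estimator 1 - HO/HE (population-level)."""
    _, ho = observed_heterozygosity(gm, pop_samples)
    _, he = expected_heterozygosity(gm, pop_samples, unbiased=True)
    return float(1.0 - ho / he) if he and np.isfinite(he) and he > 0 else np.nan


def windowed_pi(
    gm: GenotypeMatrix,
    vt: VariantTable,
    pop_samples=None,
    window_bp: int = 100_000,
    step_bp: int = 10_000,
    per_base: bool = True,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity (VCFtools windowed-pi convention).

    Window pi = sum of per-site pi over SNPs in the window, divided by the
    full window length when ``per_base`` (the default); windows with no
    SNPs report pi = 0 with n_snps = 0.
    """
    pi = site_pi(gm, pop_samples)
    pi_filled = np.where(np.isfinite(pi), pi, 0.0)
    rows = []
    for c, idx in per_chrom(vt):
        pos = vt.pos[idx]
        starts = window_spans(int(pos.max()), window_bp, step_bp)
        lo, hi = window_site_slices(pos, starts, window_bp)
        csum = np.concatenate([[0.0], np.cumsum(pi_filled[idx])])
        for s, a, b in zip(starts, lo, hi):
            total = csum[b] - csum[a]
            rows.append(
                (
                    c,
                    int(s),
                    int(s) + window_bp - 1,
                    int(b - a),
                    total / window_bp if per_base else total,
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "pi"])


def diversity_table(gm: GenotypeMatrix, pmap: PopulationMap) -> pd.DataFrame:
    """Per-population summary analogous to a classic diversity table:
    HO, HE, mean per-site pi and F_IS."""
    rows = []
    for pop in pmap.populations:
        samples = pmap.samples_for(pop)
        _, ho = observed_heterozygosity(gm, samples)
        _, he = expected_heterozygosity(gm, samples, unbiased=True)
        pi = site_pi(gm, samples)
        _, fis = inbreeding_fis(gm, samples)
        rows.append(
            {
                "population": pop,
                "n_samples": len(samples),
                "ho": ho,
                "he": he,
                "pi": float(np.nanmean(pi)),
                "fis": fis,
            }
        )
    return pd.DataFrame(rows)
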