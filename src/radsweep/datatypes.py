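"""Core in-memory containers shared by every analysis stage.

The package keeps genotypes as a dense samples x sites dosage matrix
(``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing) with per-site
metadata in a parallel :class:`VariantTable`.  All statistics operate on
these two objects plus a :class:`PopulationMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Dosage code for a missing (uncalled or half-called) genotype.
MISSING: int = -1


@dataclass
class VariantTable:
    """Per-site metadata aligned to the columns of a :class:`GenotypeMatrix`.

    Attributes
    ----------
    chrom : np.ndarray of str
        Chromosome / contig name per site.
    pos : np.ndarray of int
        1-based position, strictly increasing within each chromosome.
    ref, alt : np.ndarray of str
        Single-nucleotide reference and alternate alleles.
    qd : np.ndarray of float
        GATK quality-by-depth annotation; NaN when absent.
    fs : np.ndarray of float
        GATK Fisher-strand phred score; NaN when absent.
    site_id : np.ndarray of int
        Stable integer index assigned at load time; survives filtering.
    contigs : list of str
        Contig order (VCF header order, else first appearance).
    contig_lengths : dict
        Optional contig -> length map from the VCF header.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qd: np.ndarray
    fs: np.ndarray
    site_id: np.ndarray
    contigs: list = field(default_factory=list)
    contig_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.qd = np.asarray(self.qd, dtype=float)
        self.fs = np.asarray(self.fs, dtype=float)
        self.site_id = np.asarray(self.site_id, dtype=np.int64)
        if not self.contigs:
            seen = {}
            for c in self.chrom:
                seen.setdefault(c, None)
            self.contigs = list(seen)
        self._validate()

    def _validate(self):
        n = len(self.pos)
        for name in ("chrom", "ref", "alt", "qd", "fs", "site_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"VariantTable field {name!r} length mismatch")
        if len(np.unique(self.site_id)) != n:
            raise ValueError("site_id values must be unique")
        # positions strictly increasing within chromosome
        for c in self.contigs:
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        """Return a new table keeping sites where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            qd=self.qd[mask],
            fs=self.fs[mask],
            site_id=self.site_id[mask],
            contigs=list(self.contigs),
            contig_lengths=dict(self.contig_lengths),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "qd": self.qd,
                "fs": self.fs,
                "site_id": self.site_id,
            }
        )


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x sites) with optional per-genotype depths."""

    samples: list
    dosages: np.ndarray
    depths: np.ndarray | None = None

    def __post_init__(self):
        self.samples = list(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("dosage rows must match sample count")
        ok = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosage codes must be in {0,1,2,-1}")
        if self.depths is not None:
            self.depths = np.asarray(self.depths)
            if self.depths.shape != self.dosages.shape:
                raise ValueError("depths shape must match dosages")
            if (self.depths < 0).any():
                raise ValueError("depths must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Keep sites selected by a boolean mask or an integer index array."""
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_sites, dtype=bool)
            idx[mask] = True
            mask = idx
        return GenotypeMatrix(
            samples=self.samples,
            dosages=self.dosages[:, mask],
            depths=None if self.depths is None else self.depths[:, mask],
        )

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            dosages=self.dosages[idx],
            depths=None if self.depths is None else self.depths[idx],
        )

    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes."""
        return self.dosages != MISSING


@dataclass
class PopulationMap:
    """Sample -> population label assignment."""

    assignments: dict

    def __post_init__(self):
        if not self.assignments:
            raise ValueError("population map is empty")

    @property
    def populations(self) -> list:
        out = []
        for p in self.assignments.values():
            if p not in out:
                out.append(p)
        return out

    def samples_for(self, population: str) -> list:
        return [s for s, p in self.assignments.items() if p == population]

    def indices_for(self, population: str, samples: list) -> np.ndarray:
        """Row indices of ``samples`` belonging to ``population``."""
        members = set(self.samples_for(population))
        return np.array([i for i, s in enumerate(samples) if s in members], dtype=int)

    def restrict_to(self, samples: list) -> "PopulationMap":
        keep = {s: p for s, p in self.assignments.items() if s in set(samples)}
        return PopulationMap(keep)


@dataclass(frozen=True)
class GeneInterval:
    """A gene feature span, 1-based inclusive as in GFF3."""

    chrom: str
    start: int
    end: int
    gene_id: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
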