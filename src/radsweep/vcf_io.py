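"""Read/write VCF, population maps and GFF3 gene annotations.

VCF parsing goes through :mod:`cyvcf2` (htslib); writing emits plain
VCF 4.2 text so synthetic call sets remain diff-able.  Only biallelic
SNPs enter the data model; anything else is dropped and counted.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import MISSING, GeneInterval, GenotypeMatrix, PopulationMap, VariantTable
from .windows import per_chrom, window_site_slices, window_spans

log = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


def read_vcf(path, require_biallelic: bool = True):
    """Load a VCF into a :class:`VariantTable` and :class:`GenotypeMatrix`.

    Parameters
    ----------
    path : str or Path
        VCF 4.x file (plain or bgzipped) with GT in FORMAT; DP optional.
    require_biallelic : bool
        Drop multiallelic and non-SNP records (counted in the log).

    Returns
    -------
    (VariantTable, GenotypeMatrix)

    Notes
    -----
    ``./.`` and half-missing calls both become the MISSING code; phased
    and unphased genotypes are treated identically.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise OSError(f"cannot read VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path!r} has no sample columns")

    contigs = list(vcf.seqnames)
    contig_lengths = {}
    for c in contigs:
        try:
            contig_lengths[c] = vcf.seqlens[contigs.index(c)]
        except Exception:
            pass

    chrom, pos, ref, alt, qd, fs = [], [], [], [], [], []
    dosages, depths = [], []
    n_dropped = 0
    any_depth = False
    for rec in vcf:
        alts = rec.ALT
        is_snp = (
            len(alts) == 1
            and rec.REF in _BASES
            and all(a in _BASES for a in alts)
        )
        if require_biallelic and not is_snp:
            n_dropped += 1
            continue
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(alts[0] if alts else ".")
        v = rec.INFO.get("QD")
        qd.append(float(v) if v is not None else np.nan)
        v = rec.INFO.get("FS")
        fs.append(float(v) if v is not None else np.nan)

        gts = rec.genotypes  # [[a0, a1, phased], ...]
        row = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a = g[:-1]
            if len(a) < 2 or any(x is None or x < 0 for x in a):
                row[i] = MISSING
            else:
                row[i] = int(a[0] > 0) + int(a[1] > 0)
        dosages.append(row)

        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            any_depth = True
            d = np.asarray(dp).reshape(-1).astype(np.int32)
            d[d < 0] = 0
            depths.append(d)
        else:
            depths.append(np.zeros(len(samples), dtype=np.int32))

    if not chrom:
        raise ValueError(
            f"VCF {path!r}: zero records retained ({n_dropped} dropped as "
            "multiallelic/non-SNP)"
        )
    if n_dropped:
        log.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)

    seen = set(chrom)
    vt = VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        qd=np.array(qd),
        fs=np.array(fs),
        site_id=np.arange(len(chrom)),
        contigs=[c for c in contigs if c in seen] or list(dict.fromkeys(chrom)),
        contig_lengths=contig_lengths,
    )
    gm = GenotypeMatrix(
        samples=samples,
        dosages=np.column_stack(dosages) if dosages else np.empty((len(samples), 0)),
        depths=np.column_stack(depths) if any_depth else None,
    )
    gm.n_dropped_records = n_dropped
    return vt, gm


def write_vcf(path, vt: VariantTable, gm: GenotypeMatrix, extra_header_lines=()):
    """Write the data model back out as plain VCF 4.2 text."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in vt.contigs:
            if c in vt.contig_lengths:
                fh.write(f"##contig=<ID={c},length={vt.contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand phred score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        has_dp = gm.depths is not None
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for line in extra_header_lines:
            fh.write(line.rstrip("\n") + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        # iterate in contig order so output positions stay sorted
        for c in vt.contigs:
            for j in np.flatnonzero(vt.chrom == c):
                info = []
                if np.isfinite(vt.qd[j]):
                    info.append(f"QD={vt.qd[j]:.2f}")
                if np.isfinite(vt.fs[j]):
                    info.append(f"FS={vt.fs[j]:.3f}")
                info_s = ";".join(info) if info else "."
                cells = []
                for i in range(gm.n_samples):
                    g = gt_str[int(gm.dosages[i, j])]
                    if has_dp:
                        g += f":{int(gm.depths[i, j])}"
                    cells.append(g)
                fmt = "GT:DP" if has_dp else "GT"
                fh.write(
                    f"{vt.chrom[j]}\t{vt.pos[j]}\t.\t{vt.ref[j]}\t{vt.alt[j]}\t.\t.\t"
                    f"{info_s}\t{fmt}\t" + "\t".join(cells) + "\n"
                )
    return path


def read_population_map(path, vcf_samples=None) -> PopulationMap:
    """Read a two-column (sample, population) TSV.

    Samples missing from ``vcf_samples`` (when given) are excluded with a
    warning; duplicate sample rows are fatal.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2 or df.empty:
        raise ValueError(f"population map {path!r} must have 2 columns and >=1 row")
    # tolerate an optional header line
    if df.iloc[0, 0].lower() in ("sample", "sample_id", "id"):
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"population map {path!r} is empty")
    samples = df.iloc[:, 0].tolist()
    pops = df.iloc[:, 1].tolist()
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample rows in population map: {dups}")
    assignments = dict(zip(samples, pops))
    if vcf_samples is not None:
        vcf_set = set(vcf_samples)
        extra = [s for s in assignments if s not in vcf_set]
        if extra:
            warnings.warn(
                f"{len(extra)} mapped samples absent from VCF, excluded: {extra[:5]}",
                stacklevel=2,
            )
            assignments = {s: p for s, p in assignments.items() if s in vcf_set}
        unmapped = [s for s in vcf_samples if s not in assignments]
        if unmapped:
            warnings.warn(
                f"{len(unmapped)} VCF samples have no population label: {unmapped[:5]}",
                stacklevel=2,
            )
    if not assignments:
        raise ValueError("population map covers no VCF sample")
    return PopulationMap(assignments)


def write_population_map(path, pmap: PopulationMap):
    with open(path, "w") as fh:
        for s, p in pmap.assignments.items():
            fh.write(f"{s}\t{p}\n")
    return path


def read_gff_genes(path) -> list:
    """Extract gene features from a GFF3 file as 1-based inclusive intervals.

    Only features of type ``gene`` are returned; malformed lines and
    intervals with start > end are skipped with a warning.
    """
    from gffutils.feature import feature_from_line

    genes = []
    n_bad = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception:
                n_bad += 1
                continue
            if feat.featuretype != "gene":
                continue
            gene_id = (
                feat.attributes.get("ID") or feat.attributes.get("gene_id") or [f"gene_line{ln}"]
            )[0]
            if feat.start is None or feat.end is None or feat.start > feat.end:
                warnings.warn(f"gene {gene_id} line {ln}: bad span, skipped", stacklevel=2)
                continue
            genes.append(
                GeneInterval(chrom=feat.seqid, start=int(feat.start), end=int(feat.end), gene_id=gene_id)
            )
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed GFF3 line(s)", stacklevel=2)
    return genes


def write_gff_genes(path, genes):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tradsweep\tgene\t{g.start}\t{g.end}\t.\t+\t.\tID={g.gene_id}\n"
            )
    return path


def snp_density(vt: VariantTable, window_bp: int = 100_000) -> pd.DataFrame:
    """Per-window SNP counts in non-overlapping windows of ``window_bp``.

    Returns a BED-like frame (chrom, start0, end, count); counts sum to
    the number of sites per chromosome.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for c, idx in per_chrom(vt):
        pos = vt.pos[idx]
        starts = window_spans(int(pos.max()), window_bp, window_bp)
        lo, hi = window_site_slices(pos, starts, window_bp)
        for s, a, b in zip(starts, lo, hi):
            rows.append((c, int(s) - 1, int(s) + window_bp - 1, int(b - a)))
    return pd.DataFrame(rows, columns=["chrom", "start0", "end", "count"])
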