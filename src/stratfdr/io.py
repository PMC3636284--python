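"""Readers and writers for the plain-text formats the package consumes.

Summary statistics and annotation tables are TSV; reference panels are
either VCF (via cyvcf2, optional dependency) or a TSV dosage matrix;
gene models are BED12 or GTF/GFF3; masks are BED3.  All genomic intervals
are converted to 0-based half-open coordinates on read.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotation import GeneModel, ReferencePanel
from .inflation import normalize_sumstats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_sumstats(path, clip: bool = False) -> pd.DataFrame:
    """Read a summary-statistics TSV and normalize z/p columns."""
    df = pd.read_csv(path, sep="\t")
    return normalize_sumstats(df, clip=clip)


def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def read_panel_tsv(path) -> ReferencePanel:
    """TSV dosage matrix: snp, chrom, pos, then one column per individual.

    Dosage cells are 0/1/2 or NA for missing.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = df[["snp", "chrom", "pos"]].copy()
    individuals = [c for c in df.columns if c not in ("snp", "chrom", "pos")]
    dosages = df[individuals].to_numpy(dtype=float)
    return ReferencePanel(meta, dosages, individuals)


def write_panel_tsv(panel: ReferencePanel, path) -> None:
    dosage_frame = pd.DataFrame(panel.dosages, columns=panel.individuals)
    df = pd.concat([panel.snps.reset_index(drop=True), dosage_frame], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_panel_vcf(path) -> ReferencePanel:
    """Read bi-allelic SNPs from a (plain or bgzipped) VCF via cyvcf2.

    Multi-allelic and non-SNP records are skipped with a logged count;
    missing genotypes become NaN dosages.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    ids, chroms, positions, rows = [], [], [], []
    skipped = 0
    for i, variant in enumerate(vcf):
        if len(variant.ALT) != 1 or len(variant.REF) != 1 \
                or len(variant.ALT[0]) != 1:
            skipped += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=missing
        gts = variant.gt_types.astype(float)
        gts[gts == 3] = np.nan
        rows.append(gts)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        positions.append(variant.POS)  # 1-based; point coords kept as-is
    if skipped:
        logger.info("skipped %d non-bi-allelic-SNP record(s)", skipped)
    meta = pd.DataFrame({"snp": ids, "chrom": chroms, "pos": positions})
    return ReferencePanel(meta, np.array(rows), individuals)


def read_panel(path) -> ReferencePanel:
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return read_panel_vcf(path)
    return read_panel_tsv(path)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_genes_bed12(path) -> list:
    """Parse BED12 into gene models (0-based half-open, as in BED).

    Blocks are exons; gaps between blocks are introns; the thickStart /
    thickEnd interval delimits the CDS, so exon portions outside it become
    5'/3' UTR by strand.  Name field is taken as ``gene_id:transcript_id``
    or reused for both when there is no colon.
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s)
                     for o, s in zip(offsets, sizes)]
            gene_id, _, tx_id = name.partition(":")
            tx_id = tx_id or name
            elements = []
            for es, ee in exons:
                for seg_s, seg_e, kind in _split_exon(
                        es, ee, thick_s, thick_e, strand):
                    elements.append((kind, seg_s, seg_e))
            for (_, e0), (s1, _) in zip(exons, exons[1:]):
                if s1 > e0:
                    elements.append(("intron", e0, s1))
            genes.append(GeneModel(
                gene_id=gene_id, transcript_id=tx_id, chrom=chrom,
                strand=strand, tx_start=start, tx_end=end,
                elements=tuple(sorted(elements, key=lambda t: t[1])),
            ))
    return genes


def _split_exon(es, ee, thick_s, thick_e, strand):
    """Split one exon interval into utr5/exon/utr3 segments by the CDS."""
    left = "utr5" if strand == "+" else "utr3"
    right = "utr3" if strand == "+" else "utr5"
    if thick_e <= thick_s:  # non-coding: call it all exon
        yield es, ee, "exon"
        return
    if es < min(ee, thick_s):
        yield es, min(ee, thick_s), left
    cs, ce = max(es, thick_s), min(ee, thick_e)
    if cs < ce:
        yield cs, ce, "exon"
    if max(es, thick_e) < ee:
        yield max(es, thick_e), ee, right


def read_genes_gtf(path, transcript_choice: str = "first") -> list:
    """Parse GTF/GFF3 exon+CDS features into gene models.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    UTRs are derived as exon minus CDS (strand-aware); introns as the gaps
    between exons.  One transcript is kept per gene: the first in file
    order (default) or the longest (``transcript_choice='longest'``).
    """
    if transcript_choice not in ("first", "longest"):
        raise ValueError("transcript_choice must be 'first' or 'longest'")
    records = {}
    order = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            feature = f[2].lower()
            if feature not in ("exon", "cds"):
                continue
            attrs = _parse_attributes(f[8])
            gene = attrs.get("gene_id", attrs.get("Parent", "?"))
            tx = attrs.get("transcript_id", attrs.get("Parent", gene))
            key = (gene, tx)
            if key not in records:
                records[key] = {
                    "chrom": f[0], "strand": f[6], "exons": [], "cds": [],
                }
                order.append(key)
            start, end = int(f[3]) - 1, int(f[4])  # to half-open
            records[key]["exons" if feature == "exon" else "cds"].append(
                (start, end)
            )
    chosen = {}
    for gene, tx in order:
        rec = records[(gene, tx)]
        if not rec["exons"]:
            continue
        span = max(e for _, e in rec["exons"]) - \
            min(s for s, _ in rec["exons"])
        if gene not in chosen:
            chosen[gene] = (tx, span)
        elif transcript_choice == "longest" and span > chosen[gene][1]:
            chosen[gene] = (tx, span)
    genes = []
    for gene, (tx, _) in chosen.items():
        rec = records[(gene, tx)]
        exons = sorted(rec["exons"])
        cds = sorted(rec["cds"])
        tx_start = exons[0][0]
        tx_end = exons[-1][1]
        elements = []
        if cds:
            cds_s, cds_e = cds[0][0], cds[-1][1]
        else:
            cds_s = cds_e = None
        for es, ee in exons:
            if cds_s is None:
                elements.append(("exon", es, ee))
            else:
                for seg in _split_exon(es, ee, cds_s, cds_e, rec["strand"]):
                    elements.append((seg[2], seg[0], seg[1]))
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 > e0:
                elements.append(("intron", e0, s1))
        genes.append(GeneModel(
            gene_id=gene, transcript_id=tx, chrom=rec["chrom"],
            strand=rec["strand"], tx_start=tx_start, tx_end=tx_end,
            elements=tuple(sorted(elements, key=lambda t: t[1])),
        ))
    return genes


def _parse_attributes(text: str) -> dict:
    attrs = {}
    for chunk in text.replace(";", "\n").splitlines():
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:  # GFF3 style
            key, _, val = chunk.partition("=")
        else:  # GTF style: key "value"
            key, _, val = chunk.partition(" ")
        attrs[key.strip()] = val.strip().strip('"')
    return attrs


def read_genes(path, coords: str = "bed",
               transcript_choice: str = "first") -> list:
    if coords == "bed":
        return read_genes_bed12(path)
    if coords == "gtf":
        return read_genes_gtf(path, transcript_choice)
    raise ValueError("coords must be 'bed' or 'gtf'")


def read_bed3(path) -> list:
    """BED3 mask intervals as (chrom, start, end) triples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


# ---------------------------------------------------------------------------
# annotation tables and gene-track export
# ---------------------------------------------------------------------------

def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_annotations(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_genes_bed12(genes, path) -> None:
    """Export gene models as BED12 (inverse of :func:`read_genes_bed12`)."""
    with open(path, "w") as fh:
        for g in genes:
            exonic = sorted(
                (s, e) for cat, s, e in g.elements
                if cat in ("utr5", "exon", "utr3")
            )
            merged = []
            for s, e in exonic:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            if not merged:
                merged = [[g.tx_start, g.tx_end]]
            cds = sorted(
                (s, e) for cat, s, e in g.elements if cat == "exon"
            )
            thick_s = cds[0][0] if cds else g.tx_start
            thick_e = cds[-1][1] if cds else g.tx_start
            sizes = ",".join(str(e - s) for s, e in merged)
            offsets = ",".join(str(s - g.tx_start) for s, _ in merged)
            fh.write("\t".join(map(str, [
                g.chrom, g.tx_start, g.tx_end,
                f"{g.gene_id}:{g.transcript_id}", 0, g.strand,
                thick_s, thick_e, 0, len(merged), sizes, offsets,
            ])) + "\n")
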