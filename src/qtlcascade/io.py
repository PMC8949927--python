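"""Readers and writers for the pipeline's on-disk formats.

SNP catalogs travel as minimal two-sample VCF 4.2, gene annotations as
BED (0-based half-open on disk) and GFF3, genotype/phenotype/map tables
as TSV, and single-cell counts as MatrixMarket MTX with barcode/feature
sidecars.  All writers are deterministic for identical inputs.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam
from scipy import io as spio
from scipy import sparse

from .exprfilter import ExpressionMatrix
from .linkage import (
    GENOTYPE_CODES,
    GENOTYPE_LABELS,
    GeneticMap,
    GenotypeMatrix,
    LodCurve,
    PhenotypeTable,
)
from .scprofile import CellMatrix
from .synthdata import BIOTYPES, GeneAnnotation, SnpCatalog

STRAIN_A = "B6"
STRAIN_B = "NZO"


# ---------------------------------------------------------------------------
# VCF


def write_vcf(catalog: SnpCatalog, path) -> None:
    """Minimal VCF 4.2 with one GT column per strain."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={catalog.chromosome}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{STRAIN_A}\t{STRAIN_B}\n"
        )
        for i in range(catalog.n_snps):
            ref, alt = catalog.ref[i], catalog.alt[i]
            gt_a = "0/0" if catalog.allele_a[i] == ref else "1/1"
            gt_b = "0/0" if catalog.allele_b[i] == ref else "1/1"
            fh.write(
                f"{catalog.chromosome}\t{catalog.positions[i]}\tsnp{i + 1}\t"
                f"{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt_a}\t{gt_b}\n"
            )


def read_vcf(path) -> SnpCatalog:
    """Read a two-sample VCF back into a :class:`SnpCatalog`.

    Heterozygous or missing strain calls are treated as the reference
    allele (inbred strains assumed homozygous)."""
    positions, refs, alts, a_alleles, b_alleles = [], [], [], [], []
    chrom = None
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 2:
            raise ValueError(f"expected 2 strain samples, found {len(samples)}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue  # indels out of scope
            chrom = rec.chrom
            positions.append(rec.pos)
            refs.append(ref)
            alts.append(alt)
            calls = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                hom_alt = gt is not None and all(x == 1 for x in gt if x is not None) \
                    and any(x is not None for x in gt)
                calls.append(alt if hom_alt else ref)
            a_alleles.append(calls[0])
            b_alleles.append(calls[1])
    if chrom is None:
        raise ValueError(f"no usable SNP records in {path}")
    return SnpCatalog(
        chrom,
        np.array(positions, dtype=np.int64),
        np.array(refs),
        np.array(alts),
        np.array(a_alleles),
        np.array(b_alleles),
    )


# ---------------------------------------------------------------------------
# gene annotation (BED / GFF3)


def write_bed(annotation: GeneAnnotation, path) -> None:
    """BED with 0-based half-open coordinates (converted on write)."""
    with open(path, "w") as fh:
        for gid, s, e, bt in zip(
            annotation.gene_ids, annotation.start, annotation.end, annotation.biotype
        ):
            fh.write(f"{annotation.chromosome}\t{s - 1}\t{e}\t{gid}\t0\t+\t{bt}\n")


def read_bed(path) -> GeneAnnotation:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene", "score", "strand", "biotype"],
    )
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("annotation must cover a single chromosome")
    return GeneAnnotation(
        chromosome=str(chroms[0]),
        gene_ids=list(df["gene"]),
        start=df["start"].to_numpy() + 1,  # back to 1-based inclusive
        end=df["end"].to_numpy(),
        biotype=df["biotype"].to_numpy(dtype=object),
    )


def write_gff3(annotation: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, s, e, bt in zip(
            annotation.gene_ids, annotation.start, annotation.end, annotation.biotype
        ):
            fh.write(
                f"{annotation.chromosome}\tqtlcascade\tgene\t{s}\t{e}\t.\t+\t.\t"
                f"ID={gid};biotype={bt}\n"
            )


def read_gff3(path) -> GeneAnnotation:
    import gffutils

    db = gffutils.create_db(
        os.fspath(path), ":memory:", merge_strategy="error", keep_order=True
    )
    ids, starts, ends, biotypes = [], [], [], []
    chrom = None
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        chrom = feat.seqid
        ids.append(feat.id)
        starts.append(feat.start)
        ends.append(feat.end)
        bt = feat.attributes.get("biotype", ["coding"])[0]
        biotypes.append(bt if bt in BIOTYPES else "coding")
    if chrom is None:
        raise ValueError(f"no gene features in {path}")
    return GeneAnnotation(
        chromosome=chrom,
        gene_ids=ids,
        start=np.array(starts),
        end=np.array(ends),
        biotype=np.array(biotypes, dtype=object),
    )


# ---------------------------------------------------------------------------
# genotype / phenotype / map TSV


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("map must cover a single chromosome")
    return GeneticMap(
        chromosome=str(chroms[0]),
        markers=tuple(df["marker"]),
        position_bp=df["position_bp"].to_numpy(),
        position_cm=df["position_cm"].to_numpy(),
    )


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    geno.to_frame().to_csv(path, sep="\t")


def read_genotypes(path, gmap: GeneticMap) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if list(df.columns) != list(gmap.markers):
        raise ValueError("genotype columns do not match the map's markers")
    try:
        codes = df.apply(lambda col: col.map(GENOTYPE_CODES)).to_numpy(dtype=float)
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"unparseable genotype codes in {path}") from exc
    if np.isnan(codes).any():
        raise ValueError("genotype codes must be NN, NB or NA")
    return GenotypeMatrix(list(df.index), gmap, codes.astype(np.int8))


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, sep="\t")


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", index_col=0))


def write_lod_curve(curve: LodCurve, path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices


def write_expression(expr: ExpressionMatrix, values_path, groups_path) -> None:
    expr.values.rename_axis("gene").to_csv(values_path, sep="\t")
    expr.groups.rename("group").rename_axis("sample").to_csv(groups_path, sep="\t")


def read_expression(values_path, groups_path, contrast: str = "") -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
    return ExpressionMatrix(values, groups, contrast=contrast)


# ---------------------------------------------------------------------------
# single-cell MTX bundle


def write_single_cell(cells: CellMatrix, directory) -> None:
    """MTX (genes x cells, CellRanger orientation) + sidecar TSVs."""
    os.makedirs(directory, exist_ok=True)
    mat = sparse.csr_matrix(cells.counts.to_numpy().T)
    spio.mmwrite(os.path.join(directory, "matrix.mtx"), mat, field="integer")
    with open(os.path.join(directory, "features.tsv"), "w") as fh:
        for g in cells.counts.columns:
            fh.write(f"{g}\n")
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        for b in cells.counts.index:
            fh.write(f"{b}\n")
    cells.clusters.rename("cluster").rename_axis("barcode").to_csv(
        os.path.join(directory, "clusters.tsv"), sep="\t"
    )


def read_single_cell(directory) -> CellMatrix:
    mat = spio.mmread(os.path.join(directory, "matrix.mtx")).toarray().T
    genes = [line.strip() for line in open(os.path.join(directory, "features.tsv"))]
    barcodes = [line.strip() for line in open(os.path.join(directory, "barcodes.tsv"))]
    clusters = pd.read_csv(
        os.path.join(directory, "clusters.tsv"), sep="\t", index_col=0
    )["cluster"]
    counts = pd.DataFrame(mat.astype(np.int64), index=barcodes, columns=genes)
    return CellMatrix(counts, clusters)


# ---------------------------------------------------------------------------
# flat key-value config


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        for key in sorted(config):
            fh.write(f"{key} = {config[key]}\n")


def read_config(path) -> dict:
    out = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw.rstrip()!r}")
            key, _, val = line.partition("=")
            out[key.strip()] = val.strip()
    return out
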