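"""Reading and writing the standard file formats.

VCF parsing is delegated to cyvcf2; only biallelic SNP records with a GT
field are kept (multiallelic records are skipped and counted).  Writing
produces minimal, valid VCF 4.2 text with GT and AD FORMAT fields.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    AlleleDepthMatrix,
    DataError,
    GenotypeMatrix,
)

logger = logging.getLogger(__name__)


def read_vcf(path) -> tuple[GenotypeMatrix, AlleleDepthMatrix]:
    """Read a VCF into genotype and allele-depth matrices.

    Multiallelic records are skipped (count logged); half-calls are treated
    as missing.  A VCF without AD yields an all-zero depth matrix with a
    warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)

    rows_gt, rows_ref, rows_alt, loci = [], [], [], []
    n_multiallelic = 0
    has_ad = True
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING            # UNKNOWN -> missing
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            has_ad = False
            ref_d = np.zeros(len(samples), dtype=np.int32)
            alt_d = np.zeros(len(samples), dtype=np.int32)
        else:
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0               # cyvcf2 encodes '.' as negative
            ref_d = ad[:, 0].astype(np.int32)
            alt_d = ad[:, 1].astype(np.int32) if ad.shape[1] > 1 else np.zeros(len(samples), np.int32)
        rows_gt.append(gt)
        rows_ref.append(ref_d)
        rows_alt.append(alt_d)
        rid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append((var.CHROM, var.POS, rid, var.REF, var.ALT[0]))

    if n_multiallelic:
        logger.info("skipped %d multiallelic records", n_multiallelic)
    if not has_ad:
        logger.warning("VCF lacks AD FORMAT field; depths set to zero")

    loci_df = pd.DataFrame(loci, columns=["chrom", "pos", "radlocus_id", "ref", "alt"])
    if len(rows_gt):
        calls = np.stack(rows_gt, axis=1)
        ref_depth = np.stack(rows_ref, axis=1)
        alt_depth = np.stack(rows_alt, axis=1)
    else:
        calls = np.zeros((len(samples), 0), dtype=np.int8)
        ref_depth = np.zeros((len(samples), 0), dtype=np.int32)
        alt_depth = np.zeros((len(samples), 0), dtype=np.int32)
    g = GenotypeMatrix(samples=samples, loci=loci_df, calls=calls)
    d = AlleleDepthMatrix(ref_depth=ref_depth, alt_depth=alt_depth)
    g.n_multiallelic_skipped = n_multiallelic
    return g, d


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(path, genotypes: GenotypeMatrix, depths: AlleleDepthMatrix | None = None) -> None:
    """Write a minimal VCF 4.2 with GT (and AD when depths are given)."""
    if depths is not None and depths.shape != genotypes.calls.shape:
        raise DataError("depth matrix not aligned to genotypes")
    loci = genotypes.loci
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in loci["chrom"].drop_duplicates():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depths is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths for the ref and alt alleles">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        fmt = "GT:AD" if depths is not None else "GT"
        for j in range(genotypes.n_loci):
            row = loci.iloc[j]
            fields = [
                str(row["chrom"]), str(row["pos"]), str(row["radlocus_id"]),
                str(row["ref"]), str(row["alt"]), ".", "PASS", ".", fmt,
            ]
            for i in range(genotypes.n_samples):
                cell = _GT_STRINGS[int(genotypes.calls[i, j])]
                if depths is not None:
                    cell += f":{depths.ref_depth[i, j]},{depths.alt_depth[i, j]}"
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


def read_sample_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_env_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_distance_matrix(path) -> pd.DataFrame:
    """Square TSV with site labels as both index and header."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    if list(m.index) != list(m.columns):
        raise DataError("distance matrix rows and columns differ")
    return m
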