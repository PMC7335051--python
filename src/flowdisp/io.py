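"""Plain-text readers and writers for the pipeline's external formats.

Event tables travel as one CSV per sample plus a tab-separated manifest of
sample metadata; genotypes as VCF v4.2 (GT field) or PED/MAP text; CDR3 read
annotations as TSV. Binary FCS input is not supported in this build: no FCS
parser is available in the runtime environment, so acquisitions must be
exported to CSV with the channel columns FSC-A, SSC-A, FSC-W, DAPI, FL.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import EventTable
from .linkage import MISSING, GenotypeMatrix, VariantRecord

__all__ = [
    "read_events_csv",
    "write_vcf",
    "read_vcf",
    "write_ped_map",
    "read_ped_map",
]


def read_events_csv(manifest_path) -> list[EventTable]:
    """Load event tables listed in a ``manifest.tsv`` written by the simulator."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    tables = []
    for _, row in manifest.iterrows():
        data = pd.read_csv(manifest_path.parent / row["path"])
        tables.append(
            EventTable(
                data=data,
                sample_id=str(row["sample_id"]),
                line_id=str(row.get("line_id", "")),
                protein=str(row.get("protein", "")),
                replicate_index=int(row.get("replicate_index", 0)),
                batch_id=str(row.get("batch_id", "batch0")),
            )
        )
    return tables


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with unphased GT calls."""
    path = Path(path)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = dict.fromkeys(v.chrom for v in G.variants)
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.individuals)
            + "\n"
        )
        for j, v in enumerate(G.variants):
            calls = "\t".join(gt_map[int(c)] for c in G.codes[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF (phase is ignored)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        variants.append(
            VariantRecord(
                chrom=str(variant.CHROM),
                pos=int(variant.POS),
                id=variant.ID or f"{variant.CHROM}:{variant.POS}",
                ref=variant.REF,
                alt=variant.ALT[0],
            )
        )
        codes = variant.gt_types.astype(np.int8)  # 0,1,2; 3 = unknown
        codes[codes == 3] = MISSING
        rows.append(codes)
    codes = (
        np.column_stack(rows)
        if rows
        else np.empty((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individuals=individuals, variants=variants, codes=codes)


def write_ped_map(G: GenotypeMatrix, prefix) -> None:
    """Write PLINK-style PED/MAP text files (family id = individual id)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for v in G.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, ind in enumerate(G.individuals):
            fields = [ind, ind, "0", "0", "0", "-9"]
            for j, v in enumerate(G.variants):
                c = int(G.codes[i, j])
                if c == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [v.alt if k < c else v.ref for k in range(2)]
            fh.write("\t".join(fields) + "\n")


def read_ped_map(prefix) -> GenotypeMatrix:
    """Read PED/MAP text back into a genotype matrix (alt = non-ref allele).

    Allele roles are inferred per variant: with no allele metadata in the
    format, the first allele observed is taken as reference unless the MAP
    file was paired with a VCF; codes count the second (alternate) allele.
    """
    prefix = Path(prefix)
    variants_raw = []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            chrom, vid, _, pos = line.split()
            variants_raw.append((chrom, vid, int(pos)))
    individuals = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            fields = line.split()
            individuals.append(fields[1])
            alleles = fields[6:]
            allele_pairs.append(
                [(alleles[2 * j], alleles[2 * j + 1]) for j in range(len(variants_raw))]
            )
    n, m = len(individuals), len(variants_raw)
    codes = np.full((n, m), MISSING, dtype=np.int8)
    variants = []
    for j, (chrom, vid, pos) in enumerate(variants_raw):
        observed = [a for pair in allele_pairs for a in (pair[j]) if a != "0"]
        uniq = sorted(set(observed), key=observed.index)
        ref = uniq[0] if uniq else "N"
        alt = uniq[1] if len(uniq) > 1 else "N"
        variants.append(VariantRecord(chrom=chrom, pos=pos, id=vid, ref=ref, alt=alt))
        for i in range(n):
            a, b = allele_pairs[i][j]
            if a == "0" or b == "0":
                continue
            codes[i, j] = (a == alt) + (b == alt)
    return GenotypeMatrix(individuals=individuals, variants=variants, codes=codes)
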