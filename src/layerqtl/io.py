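"""Readers and writers for the standard interchange formats.

Genotypes travel as PLINK PED/MAP (whitespace dialect, alleles ``A``
(major) / ``B`` (minor), ``0 0`` for a missing call) or as minimal VCF
v4.2 (GT field only). On reading, the minor allele of every marker is
determined from the observed allele frequencies in the file, so dosages
always count the minor allele regardless of how the file was coded;
frequency ties break towards the alphabetically later allele for
determinism. Pedigrees, phenotypes, sire means and reports are
tab-separated tables with a header line. Every writer round-trips
through its reader.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .data import GenotypeMatrix, Pedigree, UNKNOWN_PARENT, validate_phenotypes

__all__ = [
    "write_ped_map", "read_ped_map", "write_vcf", "read_vcf",
    "write_pedigree", "read_pedigree", "write_phenotypes", "read_phenotypes",
    "write_table", "read_table",
]


# ---------------- PLINK PED/MAP ----------------

def write_ped_map(g: GenotypeMatrix, prefix: str) -> tuple[str, str]:
    """Write ``prefix.ped`` and ``prefix.map``; returns the two paths."""
    map_path, ped_path = f"{prefix}.map", f"{prefix}.ped"
    with open(map_path, "w") as fh:
        for row in g.markers.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.marker}\t0\t{row.pos}\n")
    code = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.sire_ids):
            alleles = " ".join(
                "0 0" if np.isnan(d) else code[d] for d in g.dosages[i])
            fh.write(f"FAM {sid} 0 0 1 -9 {alleles}\n")
    return ped_path, map_path


def _orient_to_minor(dosages: np.ndarray) -> np.ndarray:
    """Flip columns whose coded allele is the major one."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    flip = freq > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    return dosages


def read_ped_map(prefix: str) -> GenotypeMatrix:
    """Read a PED/MAP pair into a minor-allele dosage matrix.

    Alleles are arbitrary single tokens; per marker the minor allele is
    whichever observed allele is rarer (ties break to the alphabetically
    later allele).
    """
    markers = pd.read_csv(
        f"{prefix}.map", sep=r"\s+", header=None,
        names=["chrom", "marker", "cm", "pos"], dtype={"chrom": str})
    markers = markers[["marker", "chrom", "pos"]]
    m = len(markers)
    sire_ids: list[str] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(f"{prefix}.ped") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}")
            sire_ids.append(parts[1])
            allele_pairs.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)])
    n = len(sire_ids)
    # choose per-marker reference (minor) allele by observed counts
    dosages = np.full((n, m), np.nan)
    for j in range(m):
        counts: dict[str, int] = {}
        for i in range(n):
            for a in allele_pairs[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if not counts:
            continue
        if len(counts) > 2:
            raise ValueError(f"marker {markers['marker'][j]}: more than two alleles")
        # minor = rarer allele; tie -> alphabetically later
        if len(counts) == 2:
            low = min(counts.values())
            minor = sorted(a for a, c in counts.items() if c == low)[-1]
        else:
            minor = "\x00"  # monomorphic: observed allele is major
        for i in range(n):
            a1, a2 = allele_pairs[i][j]
            if a1 == "0" or a2 == "0":
                continue
            dosages[i, j] = (a1 == minor) + (a2 == minor)
    return GenotypeMatrix(sire_ids=sire_ids,
                          dosages=_orient_to_minor(dosages), markers=markers)


# ---------------- VCF ----------------

def write_vcf(g: GenotypeMatrix, path: str) -> str:
    """Write a minimal VCF v4.2 with GT-only genotype fields.

    REF is the major allele ``A``, ALT the minor allele ``B``; dosages
    map to ``0/0``, ``0/1``, ``1/1`` and missing to ``./.``.
    """
    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(g.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sire_ids) + "\n")
        for j, row in enumerate(g.markers.itertuples(index=False)):
            calls = "\t".join(
                "./." if np.isnan(d) else gt[d] for d in g.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.marker}\tA\tB\t.\t.\t.\tGT\t"
                     + calls + "\n")
    return path


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a minor-allele dosage matrix (GT field only).

    ALT-allele counts are flipped per marker wherever the ALT allele is
    the major one, so dosages count the observed minor allele.
    """
    vcf = VCF(path)
    sire_ids = list(vcf.samples)
    rows = []
    dosage_rows = []
    for variant in vcf:
        if len(variant.ALT) > 1:
            raise ValueError(f"{variant.ID}: multi-allelic records not supported")
        rows.append({"marker": variant.ID or f"{variant.CHROM}:{variant.POS}",
                     "chrom": str(variant.CHROM), "pos": int(variant.POS)})
        dos = np.full(len(sire_ids), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                continue
            if len(alleles) != 2:
                raise ValueError(f"{variant.ID}: mixed ploidy in sample {sire_ids[i]}")
            dos[i] = float(sum(alleles))
        dosage_rows.append(dos)
    vcf.close()
    dosages = (np.vstack(dosage_rows).T if dosage_rows
               else np.empty((len(sire_ids), 0)))
    return GenotypeMatrix(sire_ids=sire_ids,
                          dosages=_orient_to_minor(dosages),
                          markers=pd.DataFrame(rows, columns=["marker", "chrom", "pos"]))


# ---------------- TSV tables ----------------

def write_pedigree(p: Pedigree, path: str) -> str:
    p.table.to_csv(path, sep="\t", index=False)
    return path


def read_pedigree(path: str) -> Pedigree:
    table = pd.read_csv(path, sep="\t", dtype=str).fillna(UNKNOWN_PARENT)
    return Pedigree(table)


def write_phenotypes(records: pd.DataFrame, path: str) -> str:
    records.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_phenotypes(path: str) -> pd.DataFrame:
    rec = pd.read_csv(path, sep="\t", dtype={"sire": str, "record_id": str})
    return validate_phenotypes(rec)


def write_table(df: pd.DataFrame, path: str) -> str:
    """Write any result table (sire means, scan results, reports) as TSV."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
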