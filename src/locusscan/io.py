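"""Standard-format I/O: VCF genotypes, BED annotation tracks, TSV sample
sheets, TSV capture-count tables and TSV pedigrees.

VCF reading goes through :mod:`cyvcf2`; writing emits minimal VCF v4.2
text (GT format, site quality in QUAL, reference-panel membership as an
INFO flag) sufficient for a lossless round trip of the fields this
package uses.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    MISSING,
    AnnotationTrack,
    CohortSheet,
    GenotypeMatrix,
    VariantRecord,
    compute_maf,
)
from .pedigree import Pedigree, PedigreeMember
from .pool import CaptureCount

__all__ = [
    "NonSNPError",
    "read_vcf",
    "write_vcf",
    "read_bed_track",
    "read_sample_sheet",
    "read_capture_counts",
    "read_pedigree",
    "write_pedigree",
]

PANEL_FLAG = "PANEL"


class NonSNPError(ValueError):
    """A non-biallelic-SNP record was encountered in strict mode."""


def read_vcf(path, strict: bool = False) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` of ALT dosages.

    Multi-allelic and indel records are skipped with a warning by
    default (``strict=True`` raises :class:`NonSNPError` instead).
    Missing genotypes (``./.``) become missing calls.  MAFs are
    recomputed from the parsed calls.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        snp = len(rec.ALT) == 1 and len(rec.REF) == 1 and len(rec.ALT[0]) == 1
        if not snp:
            msg = f"{rec.CHROM}:{rec.POS}: not a biallelic SNP (REF={rec.REF}, ALT={rec.ALT})"
            if strict:
                raise NonSNPError(msg)
            warnings.warn(f"skipping {msg}", stacklevel=2)
            continue
        # with gts012: 0/1/2 = ALT dosage, 3 = unknown
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        columns.append(gt)
        variants.append(
            VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                site_quality=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                in_reference_panel=bool(rec.INFO.get(PANEL_FLAG)),
            )
        )
    calls = (
        np.column_stack(columns)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(samples, variants, calls)
    for j, v in enumerate(matrix.variants):
        col = matrix.calls[:, j]
        if (col != MISSING).any():
            v.maf, v.minor_is_alt = compute_maf(col)
    return matrix


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as minimal VCF v4.2 text."""
    path = Path(path)
    contigs = sorted({v.chrom for v in matrix.variants})
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=locusscan\n")
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            f'##INFO=<ID={PANEL_FLAG},Number=0,Type=Flag,'
            'Description="Site present in the external reference panel">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        order = sorted(
            range(len(matrix.variants)),
            key=lambda j: (matrix.variants[j].chrom, matrix.variants[j].pos),
        )
        for j in order:
            v = matrix.variants[int(j)]
            info = PANEL_FLAG if v.in_reference_panel else "."
            gts = "\t".join(_GT_STRINGS[int(c)] for c in matrix.calls[:, int(j)])
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t"
                f"{v.site_quality:g}\t.\t{info}\tGT\t{gts}\n"
            )


def read_bed_track(path, class_label: str) -> AnnotationTrack:
    """Read a BED3 file (0-based half-open) as one functional class."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        comment="#",
        dtype={"chrom": str},
    )
    intervals = [
        (row.chrom, int(row.start), int(row.end)) for row in frame.itertuples()
    ]
    return AnnotationTrack(class_label=class_label, intervals=intervals)


def read_sample_sheet(path) -> CohortSheet:
    """TSV with header ``sample_id, group, age, sex`` then trait columns."""
    return CohortSheet.from_tsv(path)


def read_capture_counts(path) -> list:
    """TSV with header ``stratum, n1, n2, m`` — one row per MAF stratum."""
    frame = pd.read_csv(path, sep="\t")
    required = {"stratum", "n1", "n2", "m"}
    if not required.issubset(frame.columns):
        raise ValueError(f"capture-count table needs columns {sorted(required)}")
    return [
        CaptureCount(str(r.stratum), int(r.n1), int(r.n2), int(r.m))
        for r in frame.itertuples()
    ]


_PED_COLS = ["member_id", "father", "mother", "sex", "diagnosis", "carrier"]


def read_pedigree(path) -> Pedigree:
    """TSV pedigree: columns ``member_id, father, mother, sex, diagnosis,
    carrier``; '.' or empty mean unknown parent/diagnosis."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    missing = [c for c in _PED_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"pedigree file missing columns {missing}")
    members = [
        PedigreeMember(
            member_id=r.member_id,
            father=None if r.father == "." else r.father,
            mother=None if r.mother == "." else r.mother,
            sex=r.sex,
            diagnosis=None if r.diagnosis == "." else r.diagnosis,
            carrier=r.carrier,
        )
        for r in frame.itertuples()
    ]
    return Pedigree(members)


def write_pedigree(pedigree: Pedigree, path) -> None:
    rows = [
        {
            "member_id": m.member_id,
            "father": m.father or ".",
            "mother": m.mother or ".",
            "sex": m.sex,
            "diagnosis": m.diagnosis or ".",
            "carrier": m.carrier,
        }
        for m in pedigree
    ]
    pd.DataFrame(rows, columns=_PED_COLS).to_csv(path, sep="\t", index=False)
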