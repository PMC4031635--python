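"""Core domain types for targeted locus-resequencing analysis.

The objects here model the data a deep-resequencing study of a single
genomic region produces once alignment and variant calling are done:

* :class:`VariantRecord` — one biallelic SNP with its minor-allele
  frequency, site quality and membership in seven functional classes
  (exonic incl. UTR, protein-coding, non-synonymous, conserved,
  regulatory potential, conserved TFBS, CpG island).
* :class:`GenotypeMatrix` — samples x variants minor/ALT allele dosages
  with explicit missing calls.
* :class:`CohortSheet` — per-sample diagnosis group, age, sex and any
  number of quantitative traits.
* :class:`AnnotationTrack` — BED-style interval sets used to assign the
  functional classes by positional overlap.

Coordinate conventions follow the field standards: variant positions are
1-based (VCF), annotation intervals are 0-based half-open (BED).  A
variant at 1-based position ``p`` overlaps interval ``(start, end)`` iff
``start < p <= end``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "CASE_GROUPS",
    "CLASS_LABELS",
    "MISSING",
    "AllMissingError",
    "EmptyInputError",
    "VariantRecord",
    "GenotypeMatrix",
    "CohortSheet",
    "AnnotationTrack",
    "DiscoverySummary",
    "compute_maf",
    "classify_functional",
    "exclude_by_track",
    "summarize_discovery",
    "recovery_percentage",
]

#: Diagnosis vocabulary: schizophrenia, bipolar disorder, recurrent major
#: depressive disorder, and population controls.
GROUPS = ("SZ", "BD", "rMDD", "control")
CASE_GROUPS = ("SZ", "BD", "rMDD")

#: The seven functional classes used for burden subsets, ordered.
CLASS_LABELS = (
    "exon_incl_utr",
    "coding",
    "nonsyn",
    "conserved",
    "regpot",
    "tfbs",
    "cpg",
)

#: Sentinel for a missing genotype call in integer dosage storage.
MISSING = -1

VALIDATION_STATES = ("unvalidated", "confirmed", "refuted")


class AllMissingError(ValueError):
    """Raised when a MAF is requested for a site with no called genotypes."""


class EmptyInputError(ValueError):
    """Raised when an operation receives an empty table."""


def _default_flags() -> dict:
    return {label: False for label in CLASS_LABELS}


@dataclass
class VariantRecord:
    """A single biallelic SNP at a locus.

    ``maf`` is the minor-allele frequency in the analysed sample
    (``0 <= maf <= 0.5``); ``minor_is_alt`` records which VCF allele the
    minor allele is, so that dosage matrices (stored ALT-oriented) can be
    re-oriented to minor-allele counts.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    site_quality: float = 0.0
    maf: float = float("nan")
    minor_is_alt: bool = True
    class_flags: dict = field(default_factory=_default_flags)
    in_reference_panel: bool = False
    validation_status: str = "unvalidated"

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.chrom}:{self.pos}: only single-base SNPs supported")
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt")
        if self.site_quality < 0:
            raise ValueError("site_quality must be non-negative")
        if not np.isnan(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf {self.maf} outside [0, 0.5]")
        if self.validation_status not in VALIDATION_STATES:
            raise ValueError(f"unknown validation_status {self.validation_status!r}")
        unknown = set(self.class_flags) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class flags {sorted(unknown)}")
        for label in CLASS_LABELS:
            self.class_flags.setdefault(label, False)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def enforce_class_hierarchy(self) -> None:
        """Non-synonymous implies coding implies exonic."""
        if self.class_flags["nonsyn"]:
            self.class_flags["coding"] = True
        if self.class_flags["coding"]:
            self.class_flags["exon_incl_utr"] = True


def compute_maf(dosages: Sequence) -> tuple[float, bool]:
    """Minor-allele frequency from ALT-oriented diploid dosages.

    Missing calls may be encoded as ``None``, ``nan`` or any negative
    value and are excluded.  The ALT frequency is
    ``f = sum(dosage) / (2 * n_nonmissing)``; the MAF is ``min(f, 1-f)``
    and at an exact tie (f = 0.5) the minor allele is taken to be ALT so
    the orientation is deterministic.

    Raises
    ------
    AllMissingError
        If every call is missing.
    """
    arr = np.asarray(
        [np.nan if d is None else float(d) for d in np.ravel(np.asarray(dosages, dtype=object))],
        dtype=float,
    )
    missing = np.isnan(arr) | (arr < 0)
    called = arr[~missing]
    if called.size == 0:
        raise AllMissingError("MAF undefined: all genotype calls missing")
    if np.any((called != 0) & (called != 1) & (called != 2)):
        raise ValueError("dosages must be 0, 1, 2 or missing")
    f_alt = called.sum() / (2.0 * called.size)
    minor_is_alt = bool(f_alt <= 0.5)
    return float(min(f_alt, 1.0 - f_alt)), minor_is_alt


class GenotypeMatrix:
    """Samples x variants matrix of ALT-allele dosages.

    ``calls`` is an ``int8`` array of shape ``(n_samples, n_variants)``
    holding values in {0, 1, 2} with :data:`MISSING` (-1) for no-calls.
    Dosages are stored oriented to the VCF ALT allele; use
    :meth:`minor_dosages` for minor-allele counts (the quantity all
    association and burden machinery operates on).
    """

    def __init__(self, samples: Sequence[str], variants: Sequence[VariantRecord], calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2 or calls.shape != (len(samples), len(variants)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        bad = (calls < MISSING) | (calls > 2)
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2} or -1 (missing)")
        if len(set(samples)) != len(samples):
            raise ValueError("sample IDs must be unique")
        self.samples = list(samples)
        self.variants = list(variants)
        self.calls = calls

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def alt_dosages(self) -> np.ndarray:
        """Float matrix of ALT dosages with ``nan`` for missing calls."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        return out

    def minor_dosages(self) -> np.ndarray:
        """Float matrix of minor-allele dosages with ``nan`` for missing."""
        out = self.alt_dosages()
        flip = np.array([not v.minor_is_alt for v in self.variants])
        if flip.any():
            out[:, flip] = 2.0 - out[:, flip]
        return out

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def recompute_maf(self) -> "GenotypeMatrix":
        """Set each variant's ``maf``/``minor_is_alt`` from the calls."""
        for j, v in enumerate(self.variants):
            v.maf, v.minor_is_alt = compute_maf(self.calls[:, j])
        return self

    def mafs(self) -> np.ndarray:
        return np.array([v.maf for v in self.variants])

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        samples = [s for s, keep in zip(self.samples, mask) if keep]
        return GenotypeMatrix(samples, self.variants, self.calls[mask, :])

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        variants = [v for v, keep in zip(self.variants, mask) if keep]
        return GenotypeMatrix(self.samples, variants, self.calls[:, mask])

    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]


class CohortSheet:
    """Per-sample metadata: diagnosis group, age, sex and trait columns.

    Backed by a :class:`pandas.DataFrame` whose first four columns are
    ``sample_id, group, age, sex``; any further columns are quantitative
    traits (missing values allowed).
    """

    REQUIRED = ("sample_id", "group", "age", "sex")

    def __init__(self, frame: pd.DataFrame):
        missing_cols = [c for c in self.REQUIRED if c not in frame.columns]
        if missing_cols:
            raise ValueError(f"sample sheet missing columns {missing_cols}")
        frame = frame.reset_index(drop=True).copy()
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample ID {dup!r}")
        bad_groups = set(frame["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown groups {sorted(bad_groups)}; expected {GROUPS}")
        bad_sex = set(frame["sex"]) - {"M", "F"}
        if bad_sex:
            raise ValueError(f"sex must be 'M' or 'F', got {sorted(bad_sex)}")
        self.frame = frame

    @classmethod
    def from_tsv(cls, path) -> "CohortSheet":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def group(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    @property
    def age(self) -> np.ndarray:
        return self.frame["age"].to_numpy(dtype=float)

    @property
    def sex01(self) -> np.ndarray:
        """Sex coded numerically: M = 0, F = 1."""
        return (self.frame["sex"].to_numpy() == "F").astype(float)

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.REQUIRED]

    def trait(self, name: str) -> np.ndarray:
        if name not in self.trait_names:
            raise KeyError(f"no trait column {name!r}")
        return self.frame[name].to_numpy(dtype=float)

    def case_mask(self, case_group: str) -> np.ndarray:
        """Boolean case indicator for one diagnosis or ``all_cases``."""
        if case_group == "all_cases":
            return np.isin(self.group, CASE_GROUPS)
        if case_group not in CASE_GROUPS:
            raise ValueError(f"case_group must be one of {CASE_GROUPS} or 'all_cases'")
        return self.group == case_group

    def analysis_mask(self, case_group: str) -> np.ndarray:
        """Samples entering a case-control contrast: chosen cases + controls."""
        return self.case_mask(case_group) | (self.group == "control")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class AnnotationTrack:
    """A functional class as a union of BED intervals (0-based half-open)."""

    class_label: str
    intervals: list  # of (chrom, start, end)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"{self.class_label}: empty interval ({chrom}, {start}, {end})")

    def merged_by_chrom(self) -> dict:
        """Per-chromosome merged (starts, ends) arrays for fast lookup."""
        by_chrom: dict = {}
        for chrom, start, end in self.intervals:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        merged = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            out: list[list[int]] = []
            for s, e in ivals:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = (
                np.array([s for s, _ in out]),
                np.array([e for _, e in out]),
            )
        return merged

    def contains(self, chrom: str, pos: int, _merged: dict | None = None) -> bool:
        """Whether 1-based position ``pos`` falls in the interval union."""
        merged = _merged if _merged is not None else self.merged_by_chrom()
        if chrom not in merged:
            return False
        starts, ends = merged[chrom]
        p0 = pos - 1  # to 0-based
        i = int(np.searchsorted(starts, p0, side="right")) - 1
        return i >= 0 and p0 < ends[i]


def classify_functional(
    variants: Sequence[VariantRecord],
    tracks: Iterable[AnnotationTrack],
) -> list[VariantRecord]:
    """Set functional class flags on variants by interval overlap.

    Each track flags the variants whose 1-based position ``p`` satisfies
    ``start < p <= end`` for some interval of the track's class.  Flags
    from distinct tracks are independent; afterwards the consequence
    hierarchy (nonsyn => coding => exonic) is enforced, so pre-set
    consequence labels propagate upward.  A track whose chromosomes are
    disjoint from the variants' raises a warning and flags nothing.
    """
    variants = list(variants)
    var_chroms = {v.chrom for v in variants}
    for track in tracks:
        if track.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {track.class_label!r}")
        merged = track.merged_by_chrom()
        if merged and var_chroms.isdisjoint(merged):
            warnings.warn(
                f"track {track.class_label!r}: no chromosome in common with variants",
                stacklevel=2,
            )
        for v in variants:
            if track.contains(v.chrom, v.pos, merged):
                v.class_flags[track.class_label] = True
    for v in variants:
        v.enforce_class_hierarchy()
    return variants


def exclude_by_track(matrix: GenotypeMatrix, track: AnnotationTrack) -> GenotypeMatrix:
    """Drop variants overlapping an exclusion track (e.g. repeat-masked
    regions), using the same ``start < pos <= end`` overlap rule."""
    merged = track.merged_by_chrom()
    keep = np.array([not track.contains(v.chrom, v.pos, merged) for v in matrix.variants])
    return matrix.subset_variants(keep)


@dataclass
class DiscoverySummary:
    """Site counts by frequency class, reference-panel overlap and the
    per-functional-class tallies of a discovery experiment."""

    n_total: int
    n_common: int  # maf >= 1%
    n_rare: int  # maf < 1%
    n_in_panel: int
    overlap_pct: int  # rounded to nearest integer percent
    class_counts: Mapping[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total", self.n_total),
            ("common_maf_ge_1pct", self.n_common),
            ("rare_maf_lt_1pct", self.n_rare),
            ("in_reference_panel", self.n_in_panel),
            ("panel_overlap_pct", self.overlap_pct),
        ] + [(f"class_{k}", v) for k, v in self.class_counts.items()]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def summarize_discovery(variants: Sequence[VariantRecord]) -> DiscoverySummary:
    """Summarise a variant table: common/rare split at MAF 1% (common
    means ``maf >= 0.01`` exactly), reference-panel overlap percentage
    (rounded to the nearest integer) and per-class counts."""
    variants = list(variants)
    if not variants:
        raise EmptyInputError("empty variant table")
    mafs = np.array([v.maf for v in variants])
    if np.isnan(mafs).any():
        raise ValueError("all variants need a populated maf")
    n_total = len(variants)
    n_common = int((mafs >= 0.01).sum())
    n_panel = sum(v.in_reference_panel for v in variants)
    class_counts = {
        label: sum(v.class_flags[label] for v in variants) for label in CLASS_LABELS
    }
    return DiscoverySummary(
        n_total=n_total,
        n_common=n_common,
        n_rare=n_total - n_common,
        n_in_panel=n_panel,
        overlap_pct=int(round(100.0 * n_panel / n_total)),
        class_counts=class_counts,
    )


def recovery_percentage(n_recovered: int, n_known: int) -> float:
    """Percentage of previously reported variants re-identified,
    rounded to one decimal (e.g. 12 of 17 -> 70.6)."""
    if n_known <= 0:
        raise ValueError("n_known must be positive")
    if not 0 <= n_recovered <= n_known:
        raise ValueError("n_recovered must be between 0 and n_known")
    return round(100.0 * n_recovered / n_known, 1)
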