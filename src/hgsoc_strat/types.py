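"""Shared domain types for the HGSOC stratification pipeline.

Conventions
-----------
Genomic coordinates are 1-based, closed intervals (SEG convention), so a
segment's length in bp is ``end_bp - start_bp + 1``.  Chromosome labels are
opaque strings; no "chr"-prefix normalisation is applied.  Expression
matrices are plain :class:`pandas.DataFrame` objects with gene ids as the
index and sample ids as the columns (log-scale values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = "NA"  # explicit marker for missing categorical clinical values

MB = 1_000_000  # bp per megabase


@dataclass(frozen=True)
class Segment:
    """One absolute copy-number segment (1-based, closed coordinates)."""

    chrom: str
    start_bp: int
    end_bp: int
    total_cn: int
    major_cn: int | None = None

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError(
                f"segment {self.chrom}:{self.start_bp}-{self.end_bp}: end < start"
            )
        if self.total_cn < 0:
            raise ValueError(f"negative total_cn {self.total_cn}")
        if self.major_cn is not None:
            if self.major_cn < 0 or self.major_cn > self.total_cn:
                raise ValueError(
                    f"major_cn {self.major_cn} outside [0, total_cn={self.total_cn}]"
                )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def state(self) -> tuple[int, int | None]:
        """Copy-number state used for breakpoint/merge decisions."""
        return (self.total_cn, self.major_cn)


@dataclass
class SegmentProfile:
    """Per-sample ordered absolute copy-number segments.

    Segments are stored sorted by (chromosome, start) and must not overlap
    within a chromosome; the constructor sorts and validates.
    """

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start_bp))
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and seg.chrom == prev.chrom:
                if seg.start_bp <= prev.end_bp:
                    raise ValueError(
                        f"sample {self.sample_id}: overlapping segments on "
                        f"{seg.chrom}: {prev.start_bp}-{prev.end_bp} and "
                        f"{seg.start_bp}-{seg.end_bp}"
                    )
            prev = seg

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.chrom, None)
        return list(seen)

    def by_chromosome(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    @property
    def total_length_bp(self) -> int:
        return sum(s.length_bp for s in self.segments)


@dataclass(frozen=True)
class PloidyCall:
    """Near-diploid / near-tetraploid call from the DNA index.

    ``dna_index`` ~ 1.0 for a diploid genome; the class boundary sits at
    1.3, with the boundary value itself assigned near-tetraploid.
    """

    dna_index: float
    ploidy_class: str  # "near_diploid" | "near_tetraploid"

    def __post_init__(self) -> None:
        expected = "near_diploid" if self.dna_index < 1.3 else "near_tetraploid"
        if self.ploidy_class != expected:
            raise ValueError(
                f"ploidy_class {self.ploidy_class!r} inconsistent with "
                f"dna_index {self.dna_index}"
            )


@dataclass(frozen=True)
class LstCall:
    """Large-scale state transition count and the HRD classification."""

    lst_count: int
    cutoff_used: int  # 15 (near-diploid) or 20 (near-tetraploid)
    lst_class: str  # "LST_high" | "LST_low"

    def __post_init__(self) -> None:
        expected = "LST_high" if self.lst_count >= self.cutoff_used else "LST_low"
        if self.lst_class != expected:
            raise ValueError(
                f"lst_class {self.lst_class!r} inconsistent with count "
                f"{self.lst_count} and cutoff {self.cutoff_used}"
            )


@dataclass
class GeneSignature:
    """A named classification scheme: disjoint, non-empty up-gene sets."""

    scheme_name: str
    gene_sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, genes in self.gene_sets.items():
            if not genes:
                raise ValueError(f"signature set {name!r} is empty")
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(
                    f"scheme {self.scheme_name!r}: genes shared between sets: "
                    f"{sorted(overlap)[:5]}"
                )
            seen |= set(genes)

    def all_genes(self) -> list[str]:
        out: list[str] = []
        for genes in self.gene_sets.values():
            out.extend(genes)
        return out

    @property
    def labels(self) -> list[str]:
        return list(self.gene_sets)


@dataclass
class SurvivalRecord:
    """One patient's follow-up: time (months), event flag, covariates."""

    sample_id: str
    time: float
    event: int
    covariates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"sample {self.sample_id}: time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"sample {self.sample_id}: event must be 0/1, got {self.event}")


@dataclass
class ContingencyTable:
    """r x c non-negative counts with row/column category names."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)

    def row_percentages(self) -> pd.DataFrame:
        """Percentages within each group column (rows are variable levels,
        columns are groups; each column sums to 100)."""
        totals = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals
        return pd.DataFrame(pct, index=self.row_labels, columns=self.col_labels)


@dataclass
class SubgroupAssignment:
    """sample id -> subtype label under a named classification scheme."""

    scheme_name: str
    labels: dict[str, str]

    def label_set(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, name=self.scheme_name)


@dataclass(frozen=True)
class TestResult:
    """Generic hypothesis-test summary."""

    statistic: float
    p_value: float
    method: str
    df: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class CoxLevelResult:
    """Hazard ratio for one non-reference level of a factor."""

    factor: str
    level: str
    reference_level: str
    hazard_ratio: float
    ci95_low: float
    ci95_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci95_low <= self.hazard_ratio <= self.ci95_high):
            raise ValueError("confidence interval does not cover the hazard ratio")


@dataclass
class KmCurve:
    """Kaplan-Meier product-limit estimate on the event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def survival_at(self, t: float) -> float:
        """Step-function evaluation, S(t) = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])
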