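"""Readers and writers for the pipeline's file formats.

Formats
-------
* Segments: tab-delimited with header ``sample chrom start end total_cn
  [major_cn]`` — a SEG-like dialect with 1-based closed coordinates.
* Gene signatures: standard GMT (set name, description, gene ids); set names
  are grouped into schemes by a ``scheme.set`` dot convention.
* Expression: TSV, first column gene id, remaining columns samples,
  log-scale values.
* Clinical: CSV with a declared column mapping for time/event; all other
  mapped columns become categorical covariates, missing values kept as
  explicit ``NA`` markers.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import pandas as pd

from .types import (
    MISSING,
    ContingencyTable,
    GeneSignature,
    Segment,
    SegmentProfile,
    SurvivalRecord,
)

logger = logging.getLogger(__name__)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn"]


def read_seg(path: str | Path, casefold_chrom: bool = False) -> list[SegmentProfile]:
    """Parse a SEG-like file into one :class:`SegmentProfile` per sample.

    Parsing is strict: non-integer copy numbers are rejected with the line
    number, and overlapping segments within a chromosome are rejected naming
    the sample, chromosome and positions (via SegmentProfile validation).
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(SEG_COLUMNS)] != SEG_COLUMNS:
            raise ValueError(
                f"{path}: expected header starting with {SEG_COLUMNS}, got {header}"
            )
        has_major = len(header) > 5 and header[5] == "major_cn"
        by_sample: dict[str, list[Segment]] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 fields")
            sample, chrom = fields[0], fields[1]
            if casefold_chrom:
                chrom = chrom.lower()
            try:
                start, end, total_cn = int(fields[2]), int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field: {exc}") from None
            major_cn: int | None = None
            if has_major and len(fields) > 5 and fields[5] not in ("", MISSING):
                try:
                    major_cn = int(fields[5])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer major_cn {fields[5]!r}"
                    ) from None
            by_sample.setdefault(sample, []).append(
                Segment(chrom, start, end, total_cn, major_cn)
            )
    return [SegmentProfile(sample, segs) for sample, segs in by_sample.items()]


def write_seg(profiles: list[SegmentProfile], path: str | Path) -> None:
    path = Path(path)
    any_major = any(
        seg.major_cn is not None for p in profiles for seg in p.segments
    )
    cols = SEG_COLUMNS + (["major_cn"] if any_major else [])
    with path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for profile in profiles:
            for seg in profile.segments:
                row = [
                    profile.sample_id,
                    seg.chrom,
                    str(seg.start_bp),
                    str(seg.end_bp),
                    str(seg.total_cn),
                ]
                if any_major:
                    row.append(MISSING if seg.major_cn is None else str(seg.major_cn))
                fh.write("\t".join(row) + "\n")


def read_gmt(path: str | Path, scheme_sep: str = ".") -> list[GeneSignature]:
    """Parse a GMT file, grouping set names into schemes.

    A set named ``mateescu.fibrosis_up`` belongs to scheme ``mateescu`` with
    set key ``fibrosis_up``; names without the separator form a single-set
    scheme of their own name.
    """
    path = Path(path)
    schemes: dict[str, dict[str, list[str]]] = {}
    seen_names: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name = fields[0]
            if name in seen_names:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen_names.add(name)
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            if scheme_sep in name:
                scheme, set_name = name.split(scheme_sep, 1)
            else:
                scheme, set_name = name, name
            schemes.setdefault(scheme, {})[set_name] = genes
    return [GeneSignature(scheme, sets) for scheme, sets in schemes.items()]


def write_gmt(signatures: list[GeneSignature], path: str | Path,
              scheme_sep: str = ".") -> None:
    with Path(path).open("w") as fh:
        for sig in signatures:
            for set_name, genes in sig.gene_sets.items():
                full = (
                    sig.scheme_name if set_name == sig.scheme_name
                    else f"{sig.scheme_name}{scheme_sep}{set_name}"
                )
                fh.write("\t".join([full, "na"] + list(genes)) + "\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log-expression TSV into a DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids: {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    values = df.to_numpy(dtype=float)
    if not pd.notna(values).all():
        raise ValueError(f"{path}: non-finite or missing expression values")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "gene"
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_clinical(
    path: str | Path,
    time_col: str = "time",
    event_col: str = "event",
    id_col: str = "sample",
    covariate_cols: list[str] | None = None,
) -> list[SurvivalRecord]:
    """Read a clinical CSV into survival records.

    ``covariate_cols`` selects the categorical covariates to carry along
    (all remaining columns by default).  Unknown categorical levels are
    preserved verbatim; empty cells become the explicit ``NA`` marker and are
    dropped pairwise by downstream tests, never imputed.
    """
    path = Path(path)
    records: list[SurvivalRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        fieldnames = reader.fieldnames or []
        for col in (id_col, time_col, event_col):
            if col not in fieldnames:
                raise ValueError(f"{path}: missing required column {col!r}")
        if covariate_cols is None:
            covariate_cols = [
                c for c in fieldnames if c not in (id_col, time_col, event_col)
            ]
        for lineno, row in enumerate(reader, start=2):
            try:
                time = float(row[time_col])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric time {row[time_col]!r}"
                ) from None
            if not time > 0:
                raise ValueError(f"{path}:{lineno}: non-positive time {time}")
            if row[event_col] not in ("0", "1"):
                raise ValueError(
                    f"{path}:{lineno}: event must be 0 or 1, got {row[event_col]!r}"
                )
            covariates = {
                c: (row[c] if row.get(c) not in (None, "") else MISSING)
                for c in covariate_cols
            }
            records.append(
                SurvivalRecord(row[id_col], time, int(row[event_col]), covariates)
            )
    return records


def write_clinical(records: list[SurvivalRecord], path: str | Path) -> None:
    cov_cols: list[str] = []
    for rec in records:
        for c in rec.covariates:
            if c not in cov_cols:
                cov_cols.append(c)
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample", "time", "event"] + cov_cols)
        for rec in records:
            writer.writerow(
                [rec.sample_id, repr(rec.time), rec.event]
                + [rec.covariates.get(c, MISSING) for c in cov_cols]
            )


def read_assignment(path: str | Path, scheme_name: str | None = None):
    """Read a two-column (sample, label) TSV written by the CLI."""
    from .types import SubgroupAssignment

    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample, label")
    sample_col, label_col = df.columns[:2]
    return SubgroupAssignment(
        scheme_name or label_col, dict(zip(df[sample_col], df[label_col]))
    )


def write_assignment(assignment, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"sample\t{assignment.scheme_name}\n")
        for sample, label in sorted(assignment.labels.items()):
            fh.write(f"{sample}\t{label}\n")


def read_centromeres(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read centromere intervals from BED (0-based half-open), returning
    1-based closed intervals per chromosome."""
    out: dict[str, tuple[int, int]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out[chrom] = (int(start) + 1, int(end))
    return out


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Survival records as a DataFrame (index sample, time/event + covariates)."""
    rows = []
    for rec in records:
        row = {"time": rec.time, "event": rec.event}
        row.update(rec.covariates)
        rows.append(row)
    return pd.DataFrame(rows, index=[r.sample_id for r in records])


def crosstab(a: pd.Series, b: pd.Series) -> ContingencyTable:
    """Cross-tabulate two aligned label series into a ContingencyTable."""
    tab = pd.crosstab(a, b)
    return ContingencyTable(
        [str(x) for x in tab.index], [str(x) for x in tab.columns], tab.to_numpy()
    )
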