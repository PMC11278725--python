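"""Import and export of sequencing-depth tables.

Depth tables record the mean per-base read depth of each feature (a MAG or
an assembled contig) in each sample.  They are produced upstream by tools
such as MetaBAT's ``jgi_summarize_bam_contig_depths`` or CoverM and arrive
as tab-separated text.  MAG-level workflows typically emit a single table
(MAGs x samples); contig-level workflows emit one table per sample, each
measuring that sample's contigs across *all* samples, which this module
concatenates into one matrix after the caller's header rule has removed
the sample-specific part of the column names.
"""

from __future__ import annotations

import re
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthTable",
    "HeaderRule",
    "DepthFormatError",
    "read_mag_depths",
    "read_contig_depths",
    "write_depth_table",
]

#: Metadata columns emitted by jgi_summarize_bam_contig_depths that carry
#: no per-sample depth and are always dropped on import.
_DIALECT_COLUMNS = {"contigLen", "totalAvgDepth"}


class DepthFormatError(ValueError):
    """Raised when a depth file violates the expected tabular contract."""


@dataclass(frozen=True)
class HeaderRule:
    """Regular-expression rewrite applied to sample column headers.

    Contig depth files name their sample columns with a file-specific
    prefix or suffix (e.g. ``S1_contigs.S1.bam``); the rule removes it so
    that all files share one sample axis.  Applied only to sample columns,
    never to the feature-name column.
    """

    pattern: str
    replacement: str = ""

    def __post_init__(self) -> None:
        re.compile(self.pattern)  # raises re.error on a bad pattern

    def apply(self, header: str) -> str:
        out = re.sub(self.pattern, self.replacement, header)
        if not out:
            raise DepthFormatError(
                f"header rule {self.pattern!r} -> {self.replacement!r} "
                f"maps column {header!r} to an empty string"
            )
        return out


#: Rule that leaves headers untouched.
IDENTITY_RULE = HeaderRule(pattern=r"$^", replacement="")


@dataclass
class DepthTable:
    """Features x samples matrix of mean sequencing depths.

    ``df`` is indexed by feature id (MAG or contig name) with one column
    per sample; all entries are finite and non-negative.  ``mode`` records
    whether rows are MAGs or contigs, which downstream code uses to pick
    the right gene-to-feature linker.
    """

    df: pd.DataFrame
    mode: str = "mag"

    def __post_init__(self) -> None:
        if self.mode not in ("mag", "contig"):
            raise ValueError(f"mode must be 'mag' or 'contig', got {self.mode!r}")
        if self.df.index.has_duplicates:
            dups = sorted(set(self.df.index[self.df.index.duplicated()]))
            raise DepthFormatError(f"duplicate feature ids: {dups}")
        if self.df.columns.has_duplicates:
            dups = sorted(set(self.df.columns[self.df.columns.duplicated()]))
            raise DepthFormatError(f"duplicate sample ids: {dups}")
        values = self.df.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise DepthFormatError("depth matrix contains non-finite values")
        if values.size and (values < 0).any():
            raise DepthFormatError("depth matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthTable):
            return NotImplemented
        return self.mode == other.mode and self.df.equals(other.df)


def _strip_bam(name: str) -> str:
    return name[: -len(".bam")] if name.endswith(".bam") else name


def _parse_depth_frame(path: Path, header_rule: HeaderRule) -> pd.DataFrame:
    """Read one depth TSV into a validated float frame indexed by feature."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise DepthFormatError(f"{path}: need a feature column plus >=1 sample column")
    feature_col = raw.columns[0]
    keep = [
        c
        for c in raw.columns[1:]
        if c not in _DIALECT_COLUMNS and not c.endswith("-var")
    ]
    features = raw[feature_col]
    if features.duplicated().any():
        dups = sorted(set(features[features.duplicated()]))
        raise DepthFormatError(f"{path}: duplicate feature names: {dups}")

    out = {}
    for col in keep:
        new_name = _strip_bam(header_rule.apply(col))
        cells = raw[col]

        # float() round-trips repr-formatted values bit-exactly, which
        # pandas' fast numeric parser does not guarantee; non-finite
        # literals ("nan", "inf") are rejected like any other bad cell
        def _to_float(x: str) -> float:
            try:
                v = float(x)
            except ValueError:
                return float("nan")
            return v if np.isfinite(v) else float("nan")

        numeric = cells.map(_to_float).astype(float)
        bad = numeric.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            cell = cells.iloc[i]
            what = "empty cell" if cell.strip() == "" else f"non-numeric value {cell!r}"
            raise DepthFormatError(
                f"{path}: {what} at feature {features.iloc[i]!r}, column {col!r}"
            )
        if (numeric < 0).any():
            i = int(np.flatnonzero((numeric < 0).to_numpy())[0])
            raise DepthFormatError(
                f"{path}: negative depth {numeric.iloc[i]} at feature "
                f"{features.iloc[i]!r}, column {col!r}"
            )
        if new_name in out:
            raise DepthFormatError(f"{path}: header rule collapses two columns onto {new_name!r}")
        out[new_name] = numeric.astype(float)

    frame = pd.DataFrame(out)
    frame.index = pd.Index(features.astype(str), name="feature")
    return frame


def read_mag_depths(path: str | Path) -> DepthTable:
    """Read a single MAG depth table (MAGs in rows, samples in columns).

    MetaBAT dialect columns (``contigLen``, ``totalAvgDepth``, ``*-var``)
    are dropped; a trailing ``.bam`` on sample names is stripped.
    """
    frame = _parse_depth_frame(Path(path), IDENTITY_RULE)
    return DepthTable(df=frame, mode="mag")


def read_contig_depths(
    paths: Sequence[str | Path],
    header_rule: HeaderRule = IDENTITY_RULE,
    n_workers: int = 1,
) -> DepthTable:
    """Concatenate per-sample contig depth files into one table.

    Every file must, after ``header_rule`` is applied to its sample
    columns, expose the same column set; rows are stacked in the order the
    paths are given.  The result is independent of ``n_workers``.
    """
    if not paths:
        raise DepthFormatError("no contig depth files given")
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    paths = [Path(p) for p in paths]

    if n_workers == 1:
        frames = [_parse_depth_frame(p, header_rule) for p in paths]
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            frames = list(pool.map(lambda p: _parse_depth_frame(p, header_rule), paths))

    reference = frames[0].columns
    for path, frame in zip(paths[1:], frames[1:]):
        if set(frame.columns) != set(reference):
            diff = sorted(set(frame.columns) ^ set(reference))
            raise DepthFormatError(
                f"post-rule sample columns of {path} differ from {paths[0]}; "
                f"symmetric difference: {diff}"
            )
    frames = [f[reference] for f in frames]
    combined = pd.concat(frames, axis=0)
    if combined.index.has_duplicates:
        dups = sorted(set(combined.index[combined.index.duplicated()]))
        raise DepthFormatError(f"duplicate contig ids across files: {dups}")
    return DepthTable(df=combined, mode="contig")


def write_depth_table(table: DepthTable, path: str | Path) -> None:
    """Write a depth table as TSV; re-reading reproduces the table exactly.

    Floats are written with full round-trip precision so that
    ``read_mag_depths(write(t)) == t`` holds bit-for-bit.
    """
    path = Path(path)
    out = table.df.copy()
    out.insert(0, "name", out.index)
    with open(path, "w") as fh:
        fh.write("\t".join(out.columns) + "\n")
        for _, row in out.iterrows():
            cells = [row.iloc[0]] + [repr(float(v)) for v in row.iloc[1:]]
            fh.write("\t".join(cells) + "\n")
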