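"""Linkers: map a called gene back to the MAG or contig it came from.

A linker is any callable ``(fasta_path, gene_id) -> feature_id``.  Two
built-ins cover the common layouts: one FASTA per MAG, where the filename
is the feature; and one FASTA per sample with Prodigal-style gene ids
``<contig>_<ordinal>``, where stripping the ordinal recovers the contig.
User-supplied linkers are accepted anywhere a built-in is.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Callable

from .hmmer import HitTable

__all__ = ["Linker", "LinkerError", "mag_linker", "contig_linker", "link_hits"]

Linker = Callable[[str, str], str]

_FASTA_EXTENSIONS = (".fa", ".faa", ".fasta", ".fna")
_PRODIGAL_ID = re.compile(r"^(.+)_\d+$")


class LinkerError(ValueError):
    """Raised when a gene id or file name cannot be mapped to a feature."""


def mag_linker(fasta_path: str, gene_id: str) -> str:
    """Feature = FASTA base filename, final extension (and .gz) stripped."""
    name = Path(fasta_path).name
    if name.endswith(".gz"):
        name = name[:-3]
    for ext in _FASTA_EXTENSIONS:
        if name.endswith(ext):
            name = name[: -len(ext)]
            break
    if not name:
        raise LinkerError(f"cannot derive a MAG name from {fasta_path!r}")
    return name


def contig_linker(fasta_path: str, gene_id: str) -> str:
    """Feature = gene id minus its final Prodigal ``_<ordinal>`` suffix.

    Only the last ``_<digits>`` group is removed, so contig names that
    themselves contain underscores (``k141_550``) survive intact.
    """
    m = _PRODIGAL_ID.match(gene_id)
    if m is None:
        raise LinkerError(
            f"gene id {gene_id!r} does not end in '_<ordinal>'; cannot infer its contig"
        )
    return m.group(1)


def link_hits(hits: HitTable, linker: Linker) -> HitTable:
    """Attach a ``feature_id`` column to every hit via the linker.

    The record count and all original fields are preserved; a linker
    failure is re-raised with the offending record attached.
    """
    df = hits.df.copy()
    features = []
    for row in df.itertuples(index=False):
        try:
            feature = linker(row.source_file, row.gene_id)
        except Exception as exc:
            raise LinkerError(
                f"linker failed on gene {row.gene_id!r} from {row.source_file!r}: {exc}"
            ) from exc
        if not feature:
            raise LinkerError(
                f"linker returned an empty feature for gene {row.gene_id!r} "
                f"from {row.source_file!r}"
            )
        features.append(feature)
    df["feature_id"] = features
    return HitTable(df)
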