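"""End-to-end convenience drivers gluing the pipeline stages together.

These are thin: depth import -> search-table parse -> gene/feature
linking -> scoring, using either the MAG-mode layout (one FASTA and one
search table per MAG) or the contig-mode layout (one per sample).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .depth_io import read_contig_depths, read_mag_depths
from .fixtures import CommunityManifest
from .hmmer import HitTable, SearchConfig, parse_tblout
from .linking import contig_linker, mag_linker
from .scoring import ScoreTable, TaxonomyTable, compute_scores

__all__ = ["parse_tblout_files", "score_community"]


def parse_tblout_files(
    pairs: Sequence[tuple[str | Path, str | Path]],
    config: SearchConfig = SearchConfig(),
) -> HitTable:
    """Parse (tblout path, source FASTA path) pairs into one hit table."""
    tables = []
    for tbl, fasta in pairs:
        with open(tbl) as fh:
            tables.append(parse_tblout(fh, config, source_file=fasta))
    return HitTable.concat(tables)


def score_community(
    manifest: CommunityManifest,
    mode: str = "mag",
    counting: str = "per_feature",
    stratify: bool = False,
    rank: str = "phylum",
    denominator: str = "global",
    config: SearchConfig = SearchConfig(),
) -> ScoreTable:
    """Run the full scoring pipeline on a generated community's files."""
    if mode == "mag":
        depths = read_mag_depths(manifest.mag_depths)
        linker = mag_linker
        pairs = manifest.mag_tblouts
    elif mode == "contig":
        depths = read_contig_depths(
            manifest.contig_depth_files, manifest.header_rule
        )
        linker = contig_linker
        pairs = manifest.contig_tblouts
    else:
        raise ValueError(f"mode must be 'mag' or 'contig', got {mode!r}")

    all_hits = parse_tblout_files(pairs, config)
    is_control = all_hits.df["query_id"] == manifest.control_id
    control_hits = HitTable(all_hits.df[is_control])
    gene_hits = HitTable(all_hits.df[~is_control])
    taxonomy = TaxonomyTable.from_tsv(manifest.taxonomy) if stratify else None
    return compute_scores(
        manifest.queries,
        gene_hits,
        control_hits,
        depths,
        linker,
        taxonomy=taxonomy,
        rank=rank,
        counting=counting,
        denominator=denominator,
    )
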