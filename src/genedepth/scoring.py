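"""Depth aggregation and copy-number normalization.

For each sample, the depths of all features (MAGs or contigs) that carry
the gene of interest are summed and divided by the summed depth of the
features carrying a universal single-copy control gene.  Because the
control gene occurs once per genome, its total depth estimates the total
number of genome copies sequenced in the sample, so the ratio

    score(q, s) = sum of depths of features with gene q in sample s
                  / sum of depths of features with the control gene

is a unitless quantity interpretable as the average per-genome copy
number of gene q — comparable across samples and across sequencing
projects.

When taxonomy assignments are known the numerator can be computed within
each taxon.  With the default *global* denominator the per-taxon scores
sum exactly to the unstratified score (the decomposition used by stacked
"contribution" bar plots); with the *per_taxon* denominator each taxon is
normalized by its own control depth, giving a within-taxon copy number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hmmer import HitTable
from .linking import Linker, link_hits

__all__ = [
    "ScoreTable",
    "TaxonomyTable",
    "ScoringError",
    "aggregate_depth",
    "normalize",
    "compute_scores",
    "scores_to_long",
]

UNCLASSIFIED = "Unclassified"

#: Recognized lineage ranks, most to least inclusive.
RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]


class ScoringError(ValueError):
    """Raised on inconsistencies between hits, depths, and taxonomy."""


@dataclass
class TaxonomyTable:
    """Feature id -> ranked lineage labels.

    ``df`` is indexed by feature id with one column per rank (any subset
    of domain...species).  Features absent from the table are reported as
    ``Unclassified`` rather than dropped, so stratified scores stay
    additive.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dups = sorted(set(self.df.index[self.df.index.duplicated()]))
            raise ScoringError(f"duplicate feature ids in taxonomy: {dups}")

    @staticmethod
    def from_tsv(path: str | Path) -> "TaxonomyTable":
        df = pd.read_csv(path, sep="\t", dtype=str).set_index("feature")
        return TaxonomyTable(df)

    def label(self, feature_id: str, rank: str) -> str:
        if rank not in self.df.columns:
            raise ScoringError(
                f"rank {rank!r} not in taxonomy table (have {list(self.df.columns)})"
            )
        if feature_id not in self.df.index:
            return UNCLASSIFIED
        value = self.df.at[feature_id, rank]
        if pd.isna(value) or str(value).strip() == "":
            return UNCLASSIFIED
        return str(value)


@dataclass
class ScoreTable:
    """Queries (x optional taxa) x samples matrix of copy-number scores.

    ``df`` rows are query ids, or (query, taxon) pairs when stratified;
    columns are samples.  NaN marks an undefined score (the control gene
    had zero depth in that cell's denominator).
    """

    df: pd.DataFrame
    stratified: bool = False

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    def query_row(self, query: str) -> pd.Series:
        """Per-sample scores of one query (summed over taxa if stratified)."""
        if self.stratified:
            return self.df.xs(query, level="query").sum(axis=0, min_count=1)
        return self.df.loc[query]

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t")


def _distinct_hit_features(linked: pd.DataFrame, counting: str) -> pd.Series:
    """Feature multiset induced by one query's hits under a counting rule.

    per_feature: each feature with >=1 hit counts once.  per_gene: each
    distinct hit gene contributes its parent feature once, so a feature
    carrying k hit genes counts k times.
    """
    if counting == "per_feature":
        return linked["feature_id"].drop_duplicates()
    if counting == "per_gene":
        genes = linked.drop_duplicates(subset=["gene_id", "source_file"])
        return genes["feature_id"]
    raise ValueError(f"counting must be 'per_feature' or 'per_gene', got {counting!r}")


def aggregate_depth(
    linked_hits: HitTable | pd.DataFrame,
    depths,
    counting: str = "per_feature",
) -> pd.Series:
    """Sum, per sample, the depths of the features carrying one query's hits.

    ``linked_hits`` must carry a ``feature_id`` column (see
    :func:`genedepth.linking.link_hits`) and hold the hits of a single
    query.  Features not present in the depth table signal a mismatched
    linker or the wrong depth file and raise an error naming them.
    """
    df = linked_hits.df if isinstance(linked_hits, HitTable) else linked_hits
    if "feature_id" not in df.columns:
        raise ScoringError("hits are not linked: no feature_id column")
    if df.empty:
        return pd.Series(0.0, index=depths.df.columns)
    missing = sorted(set(df["feature_id"]) - set(depths.df.index))
    if missing:
        raise ScoringError(
            f"hit features absent from the depth table: {missing} "
            "(mismatched linker or wrong depth file?)"
        )
    features = _distinct_hit_features(df, counting)
    return depths.df.loc[features].sum(axis=0)


def normalize(target_vector: pd.Series, control_vector: pd.Series) -> pd.Series:
    """Elementwise target/control depth; undefined (NaN) where control is 0.

    A zero control depth means the sample carries no detectable universal
    marker, making it unusable for normalization — the score is marked
    undefined with a warning, never coerced to 0 or infinity.
    """
    if list(target_vector.index) != list(control_vector.index):
        raise ScoringError(
            "sample axes differ between target and control depth vectors"
        )
    zero = control_vector == 0
    if zero.any():
        warnings.warn(
            "control depth is zero in sample(s) "
            f"{list(control_vector.index[zero])}; scores there are undefined",
            stacklevel=2,
        )
    out = target_vector / control_vector.where(~zero)
    return out


def compute_scores(
    queries: Sequence[str],
    hits: HitTable,
    control_hits: HitTable,
    depths,
    linker: Linker,
    taxonomy: TaxonomyTable | None = None,
    rank: str = "phylum",
    counting: str = "per_feature",
    denominator: str = "global",
) -> ScoreTable:
    """End-to-end scoring: link hits, aggregate depths, normalize by control.

    Returns one score per query per sample, or per (query, taxon, sample)
    when a taxonomy is given.  Queries with no hits at all yield an
    all-zero row with a warning.  ``denominator='global'`` (default)
    divides every taxon's numerator by the whole-sample control depth so
    taxa sum to the unstratified score; ``'per_taxon'`` divides by the
    control depth within the same taxon.
    """
    if denominator not in ("global", "per_taxon"):
        raise ValueError(f"denominator must be 'global' or 'per_taxon', got {denominator!r}")
    if len(control_hits) == 0:
        raise ScoringError("control hit table is empty; cannot normalize")

    linked = link_hits(hits, linker).df
    linked_control = link_hits(control_hits, linker).df
    samples = depths.df.columns

    control_total = aggregate_depth(linked_control, depths, counting)

    unknown = [q for q in queries if q not in set(linked["query_id"])]
    if unknown:
        warnings.warn(f"queries with no hits (scored 0): {unknown}", stacklevel=2)

    if taxonomy is None:
        rows = {}
        for q in queries:
            num = aggregate_depth(linked[linked["query_id"] == q], depths, counting)
            rows[q] = num / control_total.where(control_total != 0)
        zero_samples = list(samples[control_total == 0])
        if zero_samples:
            warnings.warn(
                f"control depth is zero in sample(s) {zero_samples}; "
                "scores there are undefined",
                stacklevel=2,
            )
        df = pd.DataFrame(rows).T
        df.index.name = "query"
        df.columns = samples
        return ScoreTable(df=df, stratified=False)

    # stratified: numerator within each taxon's features
    taxon_of = {
        f: taxonomy.label(f, rank)
        for f in set(linked["feature_id"]) | set(linked_control["feature_id"])
    }
    taxa = sorted(set(taxon_of.values()))
    if denominator == "per_taxon":
        control_by_taxon = {
            t: aggregate_depth(
                linked_control[
                    linked_control["feature_id"].map(taxon_of).eq(t)
                ],
                depths,
                counting,
            )
            for t in taxa
        }

    index = pd.MultiIndex.from_tuples([], names=["query", "taxon"])
    out = pd.DataFrame(index=index, columns=samples, dtype=float)
    for q in queries:
        q_hits = linked[linked["query_id"] == q]
        for t in taxa:
            t_hits = q_hits[q_hits["feature_id"].map(taxon_of).eq(t)]
            num = aggregate_depth(t_hits, depths, counting)
            denom = control_total if denominator == "global" else control_by_taxon[t]
            out.loc[(q, t), :] = (num / denom.where(denom != 0)).to_numpy()
    zero = control_total == 0
    if zero.any() and denominator == "global":
        warnings.warn(
            f"control depth is zero in sample(s) {list(samples[zero])}; "
            "scores there are undefined",
            stacklevel=2,
        )
    return ScoreTable(df=out, stratified=True)


def scores_to_long(table: ScoreTable) -> pd.DataFrame:
    """Tidy reshape: one record per defined (query[, taxon], sample) cell.

    Undefined (NaN) cells are omitted; their count is reported in a
    warning so the drop is never silent.
    """
    df = table.df.copy()
    df.columns.name = "sample"
    long = df.stack(future_stack=True).rename("score").reset_index()
    n_undefined = int(long["score"].isna().sum())
    if n_undefined:
        warnings.warn(f"omitting {n_undefined} undefined score cell(s)", stacklevel=2)
        long = long.dropna(subset=["score"])
    return long.reset_index(drop=True)
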