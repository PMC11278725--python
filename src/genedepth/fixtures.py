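"""Synthetic metagenomic communities with known ground truth.

The generator plants a community of genomes with log-normal per-sample
abundances, splits each genome into contigs, places copies of the query
genes (at most one copy per contig) and exactly one copy of a universal
single-copy control gene per genome, and writes every file the pipeline
consumes: a MAG-level depth table, per-sample contig depth tables in the
MetaBAT dialect (with prefix-bearing sample columns, ``contigLen`` /
``totalAvgDepth`` / ``*-var`` metadata columns), called-gene protein
FASTAs with Prodigal-style ids, per-target search tables for the planted
hits, and a taxonomy table.

Because gene placement is known exactly, the true copy-number score is
the abundance-weighted mean copy count

    truth(q, s) = sum_g a[g,s] * k[g,q] / sum_g a[g,s]

where ``a`` is genome abundance and ``k`` the planted copy count; the
per-taxon decomposition of this quantity sums to the total.  Everything
is driven by one seed: regeneration is byte-identical.

What this emulates — and what it does not: depths are genome abundances
plus optional truncated Gaussian noise, not read simulation; there is no
assembly fragmentation bias, no chimeric contigs, no binning error, and
search tables are written directly rather than produced by a real
homology search (a separate helper builds a real profile/target pair for
exercising the search engine itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .depth_io import HeaderRule

__all__ = [
    "CommunitySpec",
    "CommunityManifest",
    "GroundTruth",
    "generate_community",
    "generate_tblout_lines",
    "generate_hmm_fixture",
    "build_control_profile",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Phyla cycled over genomes when the spec names none.
DEFAULT_PHYLA = ("Proteobacteria", "Bacteroidota", "Cyanobacteria", "Actinobacteriota")

#: Header rule stripping the file tag the generator prepends to contig
#: depth sample columns (``F0.S1.bam`` -> ``S1.bam``).
FIXTURE_HEADER_RULE = HeaderRule(pattern=r"^F\d+\.", replacement="")


@dataclass
class CommunitySpec:
    """Ground-truth description of a synthetic community.

    gene_plan maps each query id to its per-genome copy counts (length
    n_genomes, each count <= contigs_per_genome so copies land on
    distinct contigs); the control gene is placed exactly once per
    genome.  noise_sd is the per-contig depth noise as a fraction of the
    genome's abundance; abundances may be given explicitly (genomes x
    samples) or drawn log-normally.
    """

    gene_plan: Mapping[str, Sequence[int]]
    n_samples: int = 6
    n_genomes: int = 50
    contigs_per_genome: int = 5
    abundance_log_mean: float = 1.0
    abundance_log_sd: float = 0.7
    noise_sd: float = 0.0
    control_id: str = "GRPE_CTRL"
    taxonomy: Sequence[str] | None = None
    abundances: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for q, counts in self.gene_plan.items():
            counts = list(counts)
            if len(counts) != self.n_genomes:
                raise ValueError(
                    f"gene plan for {q!r} has {len(counts)} entries, expected {self.n_genomes}"
                )
            if any(c < 0 for c in counts):
                raise ValueError(f"negative copy count for {q!r}")
            if any(c > self.contigs_per_genome for c in counts):
                raise ValueError(
                    f"gene plan for {q!r} exceeds contigs_per_genome="
                    f"{self.contigs_per_genome}; copies must sit on distinct contigs"
                )
        if self.control_id in self.gene_plan:
            raise ValueError("control gene id collides with a query id")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.taxonomy is not None and len(self.taxonomy) != self.n_genomes:
            raise ValueError("taxonomy must name one label per genome")
        if self.abundances is not None:
            arr = np.asarray(self.abundances, dtype=float)
            if arr.shape != (self.n_genomes, self.n_samples):
                raise ValueError(
                    f"abundances must be {self.n_genomes}x{self.n_samples}, got {arr.shape}"
                )
            if (arr < 0).any():
                raise ValueError("abundances must be non-negative")


@dataclass
class CommunityManifest:
    """Paths of everything one generated community wrote to disk."""

    out_dir: Path
    mag_depths: Path
    mag_fastas: dict[str, Path]
    mag_tblouts: list[tuple[Path, Path]]  # (tblout, source fasta) pairs
    contig_depth_files: list[Path]
    contig_fastas: list[Path]
    contig_tblouts: list[tuple[Path, Path]]
    taxonomy: Path
    header_rule: HeaderRule
    control_id: str
    queries: list[str]
    samples: list[str]


@dataclass
class GroundTruth:
    """Planted copy-number scores: total and per-taxon decomposition."""

    scores: pd.DataFrame  # query x sample
    by_taxon: pd.DataFrame  # (query, taxon) MultiIndex x sample


def generate_tblout_lines(
    hits: Sequence[tuple[str, str, float, float]],
    description: str = "synthetic planted hit",
) -> str:
    """Render (gene, query, bit score, E-value) records as a per-target table.

    Emits comment headers plus one 18-field data line per record (with a
    free-text description after field 18); numbers use round-trip float
    formatting so parsing recovers them exactly.
    """
    lines = [
        "#                                                               --- full sequence ---- --- best 1 domain ---- --- domain number estimation ----",
        "# target name        accession  query name           accession    E-value  score  bias   E-value  score  bias   exp reg clu  ov env dom rep inc description of target",
        "#------------------- ---------- -------------------- ---------- --------- ------ ----- --------- ------ -----   --- --- --- --- --- --- --- --- ---------------------",
    ]
    for gene, query, score, e_value in hits:
        if any(ch.isspace() for ch in gene + query):
            raise ValueError(f"whitespace in identifier: {gene!r}/{query!r}")
        if e_value < 0:
            raise ValueError(f"negative E-value for {gene!r}")
        lines.append(
            f"{gene} - {query} - {e_value!r} {score!r} 0.0 "
            f"{e_value!r} {score!r} 0.0 1.0 1 0 0 1 1 1 1 0 {description}"
        )
    lines.append("#")
    return "\n".join(lines) + "\n"


def _random_protein(rng: np.random.Generator, length: int = 60) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _write_fasta(path: Path, records: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def _write_depth_tsv(
    path: Path,
    feature_col: str,
    features: Sequence[str],
    columns: Sequence[str],
    matrix: np.ndarray,
    metabat_dialect: bool,
) -> None:
    """Write a depth TSV; the MetaBAT dialect adds the metadata columns."""
    with open(path, "w") as fh:
        header = [feature_col]
        if metabat_dialect:
            header += ["contigLen", "totalAvgDepth"]
        for c in columns:
            header.append(c)
            if metabat_dialect:
                header.append(f"{c}-var")
        fh.write("\t".join(header) + "\n")
        for i, feat in enumerate(features):
            row = [feat]
            if metabat_dialect:
                row += ["100000", repr(float(matrix[i].mean()))]
            for j in range(len(columns)):
                row.append(repr(float(matrix[i, j])))
                if metabat_dialect:
                    row.append("0.1")
            fh.write("\t".join(row) + "\n")


def generate_community(
    spec: CommunitySpec, out_dir: str | Path
) -> tuple[CommunityManifest, GroundTruth]:
    """Write a full synthetic community under ``out_dir``; return its truth.

    Both layouts are emitted: a MAG-mode tree (single depth table, one
    FASTA and one search table per genome) and a contig-mode tree (one
    MetaBAT-dialect depth file, FASTA, and search table per sample, with
    contigs partitioned round-robin over the per-sample files).
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{j + 1}" for j in range(spec.n_samples)]
    mags = [f"bin{g + 1:03d}" for g in range(spec.n_genomes)]
    queries = sorted(spec.gene_plan)

    if spec.abundances is not None:
        abundance = np.asarray(spec.abundances, dtype=float)
    else:
        abundance = rng.lognormal(
            spec.abundance_log_mean,
            spec.abundance_log_sd,
            size=(spec.n_genomes, spec.n_samples),
        )

    # per-contig depths: abundance plus truncated Gaussian noise
    n_contigs = spec.contigs_per_genome
    contig_depth = np.repeat(abundance[:, None, :], n_contigs, axis=1)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, 1.0, size=contig_depth.shape)
        contig_depth = np.maximum(0.0, contig_depth * (1.0 + spec.noise_sd * noise))
    mag_depth = contig_depth.mean(axis=1)

    # gene placement: control on contig 0; query copies on contigs 0..k-1,
    # at most one copy of a given query per contig
    contig_ids = [[f"{mag}c{c + 1}" for c in range(n_contigs)] for mag in mags]
    genes: list[tuple[str, str, str, int, int]] = []  # (gene_id, query, mag, g, c)
    for g, mag in enumerate(mags):
        ordinals = [0] * n_contigs
        placements: list[tuple[int, str]] = [(0, spec.control_id)]
        for q in queries:
            k = int(spec.gene_plan[q][g])
            placements += [(c, q) for c in range(k)]
        for c, q in placements:
            ordinals[c] += 1
            genes.append((f"{contig_ids[g][c]}_{ordinals[c]}", q, mag, g, c))

    taxa = (
        list(spec.taxonomy)
        if spec.taxonomy is not None
        else [DEFAULT_PHYLA[g % len(DEFAULT_PHYLA)] for g in range(spec.n_genomes)]
    )

    # ---- MAG layout ----
    mag_dir = out_dir / "mag"
    (mag_dir / "fastas").mkdir(parents=True, exist_ok=True)
    (mag_dir / "tblout").mkdir(parents=True, exist_ok=True)
    mag_depths_path = mag_dir / "mag_depths.tsv"
    _write_depth_tsv(
        mag_depths_path,
        "name",
        mags,
        [f"{s}.bam" for s in samples],
        mag_depth,
        metabat_dialect=False,
    )
    mag_fastas: dict[str, Path] = {}
    mag_tblouts: list[tuple[Path, Path]] = []
    for g, mag in enumerate(mags):
        fasta = mag_dir / "fastas" / f"{mag}.faa"
        records = [
            (gene, _random_protein(rng))
            for gene, q, m, gg, c in genes
            if gg == g
        ]
        _write_fasta(fasta, records)
        mag_fastas[mag] = fasta
        tbl = mag_dir / "tblout" / f"{mag}.tbl"
        tbl.write_text(
            generate_tblout_lines(
                [(gene, q, 100.0, 1e-30) for gene, q, m, gg, c in genes if gg == g]
            )
        )
        mag_tblouts.append((tbl, fasta))

    # ---- contig layout: genomes partitioned round-robin over sample files ----
    contig_dir = out_dir / "contig"
    (contig_dir / "depths").mkdir(parents=True, exist_ok=True)
    (contig_dir / "fastas").mkdir(parents=True, exist_ok=True)
    (contig_dir / "tblout").mkdir(parents=True, exist_ok=True)
    contig_depth_files: list[Path] = []
    contig_fastas: list[Path] = []
    contig_tblouts: list[tuple[Path, Path]] = []
    n_files = min(spec.n_samples, spec.n_genomes)
    for i in range(n_files):
        members = [g for g in range(spec.n_genomes) if g % n_files == i]
        feats = [contig_ids[g][c] for g in members for c in range(n_contigs)]
        matrix = np.vstack(
            [contig_depth[g, c] for g in members for c in range(n_contigs)]
        )
        dpath = contig_dir / "depths" / f"F{i}.tsv"
        _write_depth_tsv(
            dpath,
            "contigName",
            feats,
            [f"F{i}.{s}.bam" for s in samples],
            matrix,
            metabat_dialect=True,
        )
        contig_depth_files.append(dpath)
        fasta = contig_dir / "fastas" / f"F{i}.faa"
        file_genes = [entry for entry in genes if entry[3] in members]
        _write_fasta(fasta, [(gene, _random_protein(rng)) for gene, *_ in file_genes])
        contig_fastas.append(fasta)
        tbl = contig_dir / "tblout" / f"F{i}.tbl"
        tbl.write_text(
            generate_tblout_lines(
                [(gene, q, 100.0, 1e-30) for gene, q, m, gg, c in file_genes]
            )
        )
        contig_tblouts.append((tbl, fasta))

    # ---- taxonomy (MAGs and their contigs share the genome's lineage) ----
    tax_path = out_dir / "taxonomy.tsv"
    with open(tax_path, "w") as fh:
        fh.write("feature\tdomain\tphylum\n")
        for g, mag in enumerate(mags):
            fh.write(f"{mag}\tBacteria\t{taxa[g]}\n")
        for g in range(spec.n_genomes):
            for c in range(n_contigs):
                fh.write(f"{contig_ids[g][c]}\tBacteria\t{taxa[g]}\n")

    # ---- ground truth ----
    denom = abundance.sum(axis=0)
    truth = {
        q: (abundance * np.asarray(spec.gene_plan[q], dtype=float)[:, None]).sum(axis=0)
        / denom
        for q in queries
    }
    scores = pd.DataFrame(truth, index=samples).T
    scores.index.name = "query"
    rows = {}
    for q in queries:
        k = np.asarray(spec.gene_plan[q], dtype=float)
        for t in sorted(set(taxa)):
            mask = np.array([tx == t for tx in taxa])
            rows[(q, t)] = (abundance[mask] * k[mask, None]).sum(axis=0) / denom
    by_taxon = pd.DataFrame(rows, index=samples).T
    by_taxon.index = pd.MultiIndex.from_tuples(by_taxon.index, names=["query", "taxon"])

    manifest = CommunityManifest(
        out_dir=out_dir,
        mag_depths=mag_depths_path,
        mag_fastas=mag_fastas,
        mag_tblouts=mag_tblouts,
        contig_depth_files=contig_depth_files,
        contig_fastas=contig_fastas,
        contig_tblouts=contig_tblouts,
        taxonomy=tax_path,
        header_rule=FIXTURE_HEADER_RULE,
        control_id=spec.control_id,
        queries=queries,
        samples=samples,
    )
    return manifest, GroundTruth(scores=scores, by_taxon=by_taxon)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice(AMINO_ACIDS))
    return "".join(out)


def _family_to_hmm(name: str, members: Sequence[tuple[str, str]]):
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    msa = pyhmmer.easel.TextMSA(
        name=name,
        sequences=[
            pyhmmer.easel.TextSequence(name=n, sequence=s) for n, s in members
        ],
    )
    builder = pyhmmer.plan7.Builder(alphabet)
    hmm, _, _ = builder.build_msa(
        msa.digitize(alphabet), pyhmmer.plan7.Background(alphabet)
    )
    return hmm


def generate_hmm_fixture(
    out_dir: str | Path,
    seed: int = 0,
    family_size: int = 5,
    length: int = 80,
    n_planted: int = 2,
    n_decoys: int = 4,
    mutation_rate: float = 0.1,
) -> dict:
    """Build a real searchable profile/target pair with known answers.

    A random seed protein is diverged into a family; a profile is built
    from the (ungapped, equal-length) family alignment.  The target FASTA
    plants near-copies of the seed alongside shuffled decoys with the
    same residue composition, so a correct search recovers exactly the
    planted ids at the default bit-score floor.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seed_seq = _random_protein(rng, length)
    family = [
        (f"fam_{i + 1}", _mutate(rng, seed_seq, mutation_rate))
        for i in range(family_size)
    ]
    hmm = _family_to_hmm("FIXFAM", family)
    hmm_path = out_dir / "fixture_family.hmm"
    with open(hmm_path, "wb") as fh:
        hmm.write(fh)
    family_path = out_dir / "fixture_family.faa"
    _write_fasta(family_path, family)

    planted = [
        (f"planted_contig_{i + 1}", _mutate(rng, seed_seq, mutation_rate / 2))
        for i in range(n_planted)
    ]
    decoys = [
        (f"decoy_contig_{i + 1}", "".join(rng.permutation(list(seed_seq))))
        for i in range(n_decoys)
    ]
    target_path = out_dir / "fixture_targets.faa"
    _write_fasta(target_path, planted + decoys)
    return {
        "hmm": hmm_path,
        "family_fasta": family_path,
        "target_fasta": target_path,
        "planted_ids": [n for n, _ in planted],
        "decoy_ids": [n for n, _ in decoys],
    }


def build_control_profile(out_path: str | Path, seed: int = 424242) -> Path:
    """Build the packaged synthetic single-copy-marker control profile.

    A GrpE-like stand-in: a deterministic 60-residue family diverged from
    one seed protein.  It exercises the control-gene plumbing offline; a
    real marker profile (e.g. GrpE from GTDB marker alignments) should
    replace it for biological use.
    """
    rng = np.random.default_rng(seed)
    seed_seq = _random_protein(rng, 60)
    family = [(f"marker_{i + 1}", _mutate(rng, seed_seq, 0.08)) for i in range(8)]
    hmm = _family_to_hmm("GrpE_synthetic", family)
    out_path = Path(out_path)
    with open(out_path, "wb") as fh:
        hmm.write(fh)
    return out_path
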