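"""Profile-HMM construction, similarity search, and hit parsing.

The search direction here is reversed with respect to bulk annotators:
the gene of interest (as a profile HMM) is the query and the called genes
of the sample are the target database.  Searches run through pyhmmer's
reimplementation of the HMMER3 pipeline, so results match ``hmmsearch``
while staying a pure function of the inputs regardless of how many
processes or threads are used.

Hits are filtered on the full-sequence bit score (default floor 25.0
bits, a conventional weak-homology cutoff) and optionally on the
full-sequence E-value; one best-scoring record is kept per
(gene, query, file) triple.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence, TextIO

import pandas as pd
import pyhmmer

__all__ = [
    "HitTable",
    "SearchConfig",
    "TbloutParseError",
    "parse_tblout",
    "search_hmm",
    "build_profile_from_ko",
    "control_hmm",
    "kegg_fetcher",
    "mafft_aligner",
]

HIT_COLUMNS = ["gene_id", "query_id", "bit_score", "e_value", "source_file"]


def _as_str(name) -> str:
    return name.decode() if isinstance(name, bytes) else str(name)


class TbloutParseError(ValueError):
    """Raised when a per-target tabular search output line is malformed."""


@dataclass(frozen=True)
class SearchConfig:
    """Filtering thresholds and parallelism for HMM searches.

    min_bit_score filters on the full-sequence bit score; max_e_value, when
    set, additionally filters on the full-sequence E-value.  n_processes
    bounds the number of concurrent searches over target files and
    threads_per_process the worker threads inside each search; neither
    affects the result.
    """

    min_bit_score: float = 25.0
    max_e_value: float | None = None
    n_processes: int = 1
    threads_per_process: int = 1

    def __post_init__(self) -> None:
        if self.n_processes < 1:
            raise ValueError("n_processes must be >= 1")
        if self.threads_per_process < 1:
            raise ValueError("threads_per_process must be >= 1")
        if self.max_e_value is not None and self.max_e_value < 0:
            raise ValueError("max_e_value must be non-negative")


@dataclass
class HitTable:
    """Best-per-gene HMM hits with their scores.

    One record per (gene_id, query_id, source_file): the id of a called
    gene, the profile (KO) that matched it, the full-sequence bit score
    and E-value, and the FASTA file the gene came from.
    """

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=HIT_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in HIT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"hit table missing columns: {missing}")
        extra = [c for c in self.df.columns if c not in HIT_COLUMNS]
        self.df = self.df[HIT_COLUMNS + extra].reset_index(drop=True)
        key = self.df[["gene_id", "query_id", "source_file"]]
        if key.duplicated().any():
            raise ValueError("duplicate (gene, query, source_file) records")

    def __len__(self) -> int:
        return len(self.df)

    def filter(self, min_bit_score: float) -> "HitTable":
        return HitTable(self.df[self.df["bit_score"] >= min_bit_score])

    @staticmethod
    def concat(tables: Iterable["HitTable"]) -> "HitTable":
        frames = [t.df for t in tables]
        if not frames:
            return HitTable()
        return HitTable(pd.concat(frames, ignore_index=True))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path: str | Path) -> "HitTable":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "query_id": str, "source_file": str})
        if df.empty:
            return HitTable()
        return HitTable(df)


def _dedup_best(records: list[dict]) -> pd.DataFrame:
    """Collapse duplicate (gene, query, file) records, keeping the top score."""
    df = pd.DataFrame(records, columns=HIT_COLUMNS)
    if df.empty:
        return df
    df = df.sort_values("bit_score", ascending=False, kind="stable")
    df = df.drop_duplicates(subset=["gene_id", "query_id", "source_file"], keep="first")
    return df.sort_values(["source_file", "gene_id", "query_id"], kind="stable").reset_index(
        drop=True
    )


def parse_tblout(
    stream: TextIO | Iterable[str],
    config: SearchConfig = SearchConfig(),
    source_file: str | Path = "",
) -> HitTable:
    """Parse HMMER per-target tabular output (``--tblout``) into a HitTable.

    Data lines carry >=18 whitespace-separated fields; the full-sequence
    E-value (field 5) and bit score (field 6) are used.  Lines below the
    bit-score floor (or above the E-value ceiling, if set) are dropped,
    and duplicate (gene, query) lines collapse onto the highest score.
    """
    records: list[dict] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 18:
            raise TbloutParseError(
                f"line {lineno}: expected >=18 fields, found {len(fields)}"
            )
        target, query = fields[0], fields[2]
        try:
            e_value = float(fields[4])
            score = float(fields[5])
        except ValueError as exc:
            raise TbloutParseError(f"line {lineno}: unparsable numeric field: {exc}") from exc
        if e_value < 0:
            raise TbloutParseError(f"line {lineno}: negative E-value {e_value}")
        if score < config.min_bit_score:
            continue
        if config.max_e_value is not None and e_value > config.max_e_value:
            continue
        records.append(
            {
                "gene_id": target,
                "query_id": query,
                "bit_score": score,
                "e_value": e_value,
                "source_file": str(source_file),
            }
        )
    return HitTable(_dedup_best(records))


def _search_one_file(
    hmms: list, fasta: Path, config: SearchConfig
) -> list[dict]:
    alphabet = pyhmmer.easel.Alphabet.amino()
    with pyhmmer.easel.SequenceFile(fasta, digital=True, alphabet=alphabet) as sf:
        targets = sf.read_block()
    records: list[dict] = []
    for tophits in pyhmmer.hmmer.hmmsearch(
        hmms, targets, cpus=config.threads_per_process
    ):
        query_name = _as_str(tophits.query.name)
        for hit in tophits:
            if hit.score < config.min_bit_score:
                continue
            if config.max_e_value is not None and hit.evalue > config.max_e_value:
                continue
            records.append(
                {
                    "gene_id": _as_str(hit.name),
                    "query_id": query_name,
                    "bit_score": float(hit.score),
                    "e_value": float(hit.evalue),
                    "source_file": str(fasta),
                }
            )
    return records


def search_hmm(
    hmm_file: str | Path,
    target_fasta_files: Sequence[str | Path],
    config: SearchConfig = SearchConfig(),
) -> HitTable:
    """Search the profiles in ``hmm_file`` against called-gene FASTA files.

    One FASTA per MAG (MAG mode) or per sample (contig mode).  Up to
    ``config.n_processes`` files are searched concurrently; the returned
    table is identical for any parallelism setting.
    """
    if not target_fasta_files:
        raise ValueError("no target FASTA files given")
    hmm_file = Path(hmm_file)
    if not hmm_file.exists():
        raise FileNotFoundError(f"HMM file not found: {hmm_file}")
    fastas = [Path(f) for f in target_fasta_files]
    for f in fastas:
        if not f.exists():
            raise FileNotFoundError(f"target FASTA not found: {f}")

    with pyhmmer.plan7.HMMFile(hmm_file) as hf:
        hmms = list(hf)

    if config.n_processes == 1:
        per_file = [_search_one_file(hmms, f, config) for f in fastas]
    else:
        with ThreadPoolExecutor(max_workers=config.n_processes) as pool:
            per_file = list(
                pool.map(lambda f: _search_one_file(hmms, f, config), fastas)
            )
    records = [r for chunk in per_file for r in chunk]
    return HitTable(_dedup_best(records))


def mafft_aligner(sequences: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Align protein sequences with the external ``mafft`` binary.

    The default aligner for profile construction; any callable with the
    same (name, sequence) -> (name, aligned sequence) contract may
    substitute, e.g. one wrapping Muscle.
    """
    if shutil.which("mafft") is None:
        raise RuntimeError(
            "the 'mafft' binary is required for the default aligner; install "
            "MAFFT or pass a custom aligner callable"
        )
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.faa"
        with open(infile, "w") as fh:
            for name, seq in sequences:
                fh.write(f">{name}\n{seq}\n")
        proc = subprocess.run(
            ["mafft", "--quiet", "--auto", str(infile)],
            capture_output=True,
            text=True,
            check=True,
        )
    aligned: list[tuple[str, str]] = []
    name, chunks = None, []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if name is not None:
                aligned.append((name, "".join(chunks)))
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if name is not None:
        aligned.append((name, "".join(chunks)))
    return aligned


def kegg_fetcher(ko_id: str, timeout: float = 30.0) -> list[tuple[str, str]]:
    """Fetch the protein sequences of a KEGG ortholog family over REST.

    Production sequence source for :func:`build_profile_from_ko`; tests
    inject local fixture fetchers instead, so no network is touched there.
    """
    from urllib.request import urlopen

    with urlopen(f"https://rest.kegg.jp/link/genes/ko:{ko_id}", timeout=timeout) as r:
        genes = [line.split("\t")[1] for line in r.read().decode().splitlines() if "\t" in line]
    sequences: list[tuple[str, str]] = []
    for start in range(0, len(genes), 10):
        chunk = "+".join(genes[start : start + 10])
        with urlopen(f"https://rest.kegg.jp/get/{chunk}/aaseq", timeout=timeout) as r:
            text = r.read().decode()
        name, parts = None, []
        for line in text.splitlines():
            if line.startswith(">"):
                if name is not None:
                    sequences.append((name, "".join(parts)))
                name, parts = line[1:].split()[0], []
            else:
                parts.append(line.strip())
        if name is not None:
            sequences.append((name, "".join(parts)))
    return sequences


def build_profile_from_ko(
    ko_id: str,
    sequence_source: Callable[[str], Sequence[tuple[str, str]]] = kegg_fetcher,
    aligner: Callable[[Sequence[tuple[str, str]]], Sequence[tuple[str, str]]] = mafft_aligner,
    out_path: str | Path | None = None,
) -> Path:
    """Build a profile HMM for a KEGG ortholog: fetch, align, construct.

    ``sequence_source`` maps the KO id to >=2 (name, protein sequence)
    pairs; ``aligner`` produces a multiple alignment; the profile is then
    built from the alignment and written as an HMMER3 text file.
    """
    sequences = list(sequence_source(ko_id))
    if len(sequences) < 2:
        raise ValueError(
            f"need >=2 sequences to build a profile for {ko_id}, got {len(sequences)}"
        )
    aligned = list(aligner(sequences))
    widths = {len(s) for _, s in aligned}
    if len(widths) != 1:
        raise ValueError("aligner returned sequences of unequal length")

    alphabet = pyhmmer.easel.Alphabet.amino()
    msa = pyhmmer.easel.TextMSA(
        name=ko_id,
        sequences=[
            pyhmmer.easel.TextSequence(name=n, sequence=s) for n, s in aligned
        ],
    )
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    hmm, _, _ = builder.build_msa(msa.digitize(alphabet), background)

    out_path = Path(out_path) if out_path is not None else Path(f"{ko_id}.hmm")
    with open(out_path, "wb") as fh:
        hmm.write(fh)
    return out_path


def control_hmm(path: str | Path | None = None) -> Path:
    """Return the control (single-copy marker) profile HMM.

    The packaged default is a synthetic GrpE-like profile built from the
    fixtures module's marker family; it exists so the whole pipeline is
    runnable offline.  For real analyses pass ``path`` pointing at a
    proper marker profile (e.g. a GrpE profile derived from GTDB marker
    alignments) — it is honored verbatim.
    """
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"control HMM not found: {path}")
        return path
    packaged = Path(__file__).parent / "data" / "control_synthetic.hmm"
    if not packaged.exists():
        raise FileNotFoundError(
            f"packaged control profile missing: {packaged}; reinstall the package"
        )
    return packaged
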