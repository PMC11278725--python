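"""Hit parsing, search determinism, and profile construction."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genedepth.fixtures import generate_tblout_lines
from genedepth.hmmer import (
    HitTable,
    SearchConfig,
    TbloutParseError,
    build_profile_from_ko,
    control_hmm,
    parse_tblout,
    search_hmm,
)

ONE_LINE = (
    "c1_1 - K00927 - 1.2e-30 105.3 0.1 1.5e-30 105.0 0.1 1.0 1 0 0 1 1 1 1 0 "
    "phosphoglycerate kinase\n"
)


class TestParseTblout:
    def test_comments_only_is_empty(self):
        stream = io.StringIO("# comment\n#\n\n")
        assert len(parse_tblout(stream)) == 0

    def test_fields_read_off_one_line(self):
        hits = parse_tblout(io.StringIO(ONE_LINE), source_file="s.faa")
        assert len(hits) == 1
        rec = hits.df.iloc[0]
        assert rec.gene_id == "c1_1"
        assert rec.query_id == "K00927"
        assert rec.bit_score == 105.3  # full-sequence, not best-domain
        assert rec.e_value == 1.2e-30
        assert rec.source_file == "s.faa"

    def test_threshold_excludes(self):
        hits = parse_tblout(io.StringIO(ONE_LINE), SearchConfig(min_bit_score=200))
        assert len(hits) == 0

    def test_evalue_ceiling(self):
        hits = parse_tblout(io.StringIO(ONE_LINE), SearchConfig(max_e_value=1e-40))
        assert len(hits) == 0

    def test_short_line_reports_line_number(self):
        with pytest.raises(TbloutParseError, match="line 2"):
            parse_tblout(io.StringIO("# ok\na b c\n"))

    def test_bad_number_reports_line_number(self):
        bad = ONE_LINE.replace("105.3", "ten")
        with pytest.raises(TbloutParseError, match="line 1"):
            parse_tblout(io.StringIO(bad))

    def test_duplicates_keep_best_score(self):
        text = ONE_LINE + ONE_LINE.replace("105.3", "50.0")
        hits = parse_tblout(io.StringIO(text))
        assert len(hits) == 1
        assert hits.df.iloc[0].bit_score == 105.3

    def test_agrees_with_naive_splitter_on_generated_lines(self):
        """Parser oracle: naive field-splitting reference on 1,000 lines."""
        rng = np.random.default_rng(42)
        records = [
            (
                f"g{i}_1",
                f"K{rng.integers(10000, 99999)}",
                float(np.round(rng.uniform(-50, 500), 3)),
                float(10.0 ** rng.uniform(-60, 2)),
            )
            for i in range(1000)
        ]
        text = generate_tblout_lines(records)
        config = SearchConfig(min_bit_score=-1e9)
        parsed = parse_tblout(io.StringIO(text), config)

        # independent naive reference: split every non-comment line
        ref = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            key = (f[0], f[2])
            if key not in ref or float(f[5]) > ref[key][0]:
                ref[key] = (float(f[5]), float(f[4]))
        got = {
            (r.gene_id, r.query_id): (r.bit_score, r.e_value)
            for r in parsed.df.itertuples()
        }
        assert got == ref

    def test_generate_parse_round_trip_exact(self):
        rng = np.random.default_rng(0)
        records = sorted(
            (f"gene_{i}", "K00001", float(rng.normal(100, 30)), float(abs(rng.normal(0, 1e-20))))
            for i in range(100)
        )
        parsed = parse_tblout(
            io.StringIO(generate_tblout_lines(records)), SearchConfig(min_bit_score=-1e9)
        )
        got = sorted(
            (r.gene_id, r.query_id, r.bit_score, r.e_value) for r in parsed.df.itertuples()
        )
        assert got == records

    def test_description_whitespace_tolerated(self):
        text = generate_tblout_lines(
            [("g_1", "K1", 99.0, 1e-10)], description="a description with   spaces"
        )
        hits = parse_tblout(io.StringIO(text))
        assert list(hits.df.gene_id) == ["g_1"]


@settings(max_examples=50, deadline=None)
@given(
    scores=st.lists(st.floats(min_value=0, max_value=500), min_size=1, max_size=30),
    t1=st.floats(min_value=0, max_value=500),
    t2=st.floats(min_value=0, max_value=500),
)
def test_threshold_monotonicity(scores, t1, t2):
    """Raising the bit-score floor never adds hits; higher floor ⊆ lower."""
    lo, hi = sorted([t1, t2])
    records = [(f"g_{i}", "K1", s, 1e-5) for i, s in enumerate(scores)]
    text = generate_tblout_lines(records)
    at_lo = parse_tblout(io.StringIO(text), SearchConfig(min_bit_score=lo))
    at_hi = parse_tblout(io.StringIO(text), SearchConfig(min_bit_score=hi))
    lo_set = set(at_lo.df.gene_id)
    hi_set = set(at_hi.df.gene_id)
    assert hi_set <= lo_set
    assert all(s >= hi for s in at_hi.df.bit_score)


class TestSearchHmm:
    def test_planted_sequences_recovered_exactly(self, hmm_fixture):
        """Profile search finds the planted family members, not the
        composition-matched shuffled decoys."""
        hits = search_hmm(hmm_fixture["hmm"], [hmm_fixture["target_fasta"]])
        assert sorted(hits.df.gene_id) == sorted(hmm_fixture["planted_ids"])
        assert (hits.df.bit_score >= 25.0).all()

    def test_parallelism_does_not_change_result(self, hmm_fixture):
        files = [hmm_fixture["target_fasta"], hmm_fixture["family_fasta"]]
        serial = search_hmm(hmm_fixture["hmm"], files, SearchConfig(n_processes=1))
        parallel = search_hmm(
            hmm_fixture["hmm"], files, SearchConfig(n_processes=4, threads_per_process=2)
        )
        assert serial.df.equals(parallel.df)

    def test_empty_target_list_errors(self, hmm_fixture):
        with pytest.raises(ValueError):
            search_hmm(hmm_fixture["hmm"], [])

    def test_missing_fasta_named(self, hmm_fixture, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.faa"):
            search_hmm(hmm_fixture["hmm"], [tmp_path / "nope.faa"])


def identity_aligner(seqs):
    return list(seqs)


class TestBuildProfile:
    def test_identical_sequences_give_full_length_profile(self, tmp_path):
        seqs = [(f"s{i}", "ACDEFGHIKL" * 5) for i in range(3)]
        assert len(seqs[0][1]) == 50
        out = build_profile_from_ko(
            "K99999", lambda ko: seqs, aligner=identity_aligner, out_path=tmp_path / "k.hmm"
        )
        import pyhmmer

        with pyhmmer.plan7.HMMFile(out) as hf:
            hmm = next(iter(hf))
        assert hmm.M == 50
        assert str(hmm.name) == "K99999"

    def test_single_sequence_errors(self, tmp_path):
        with pytest.raises(ValueError, match=">=2"):
            build_profile_from_ko(
                "K1", lambda ko: [("a", "MKV")], aligner=identity_aligner,
                out_path=tmp_path / "k.hmm",
            )

    def test_diverged_family_recovers_its_own_members(self, hmm_fixture, tmp_path):
        """Self-recovery: a profile built from a family hits all members."""
        members = []
        name, seq = None, []
        for line in open(hmm_fixture["family_fasta"]):
            if line.startswith(">"):
                if name:
                    members.append((name, "".join(seq)))
                name, seq = line[1:].strip(), []
            else:
                seq.append(line.strip())
        members.append((name, "".join(seq)))
        out = build_profile_from_ko(
            "KFAM", lambda ko: members, out_path=tmp_path / "fam.hmm"
        )  # default (mafft) aligner exercises the external contract
        hits = search_hmm(out, [hmm_fixture["family_fasta"]])
        assert sorted(hits.df.gene_id) == sorted(n for n, _ in members)


class TestControlHmm:
    def test_packaged_profile_parses_with_name(self):
        import pyhmmer

        path = control_hmm()
        assert path.exists()
        with pyhmmer.plan7.HMMFile(path) as hf:
            hmm = next(iter(hf))
        assert hmm.name  # non-empty NAME field

    def test_override_honored_verbatim(self, hmm_fixture):
        assert control_hmm(hmm_fixture["hmm"]) == hmm_fixture["hmm"]

    def test_missing_override_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            control_hmm(tmp_path / "absent.hmm")


def test_hit_table_rejects_duplicate_keys():
    import pandas as pd

    df = pd.DataFrame(
        [["g", "K1", 50.0, 1e-9, "f.faa"]] * 2,
        columns=["gene_id", "query_id", "bit_score", "e_value", "source_file"],
    )
    with pytest.raises(ValueError, match="duplicate"):
        HitTable(df)
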