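"""Read merging, demultiplexing and barcode counting."""

import numpy as np
import pandas as pd
import pytest

from dirscreen import simdata
from dirscreen._utils import revcomp, seq_to_u8
from dirscreen.amplicon import BARCODE_OFFSET, index_seq, primer_seq
from dirscreen.readproc import (
    UNASSIGNED,
    _best_unique_match,
    _merge_mask_batch,
    count_barcodes,
    count_reads,
    demultiplex,
    merge_pair,
    read_barcode_map_tsv,
)
from dirscreen.snp_library import barcode_map, build_sample_sheet


def _brute_force_merge(r1, r2, min_overlap, max_rate):
    """Independent oracle: exhaustive scan kept deliberately naive."""
    rc2 = revcomp(r2)
    best = None
    for L in range(min_overlap, min(len(r1), len(r2)) + 1):
        mm = sum(a != b for a, b in zip(r1[len(r1) - L :], rc2[:L]))
        if mm <= max_rate * L:
            if best is None or (L - mm, L) > best[:2]:
                best = (L - mm, L, mm)
    return best


class TestMergePair:
    def test_worked_example(self):
        r1 = "ACGTACGT"
        r2 = revcomp("GTACGTTT")
        m = merge_pair(r1, r2, min_overlap=4)
        assert m.sequence == "ACGTACGTTT"
        assert m.overlap_length == 6
        assert m.mismatches_in_overlap == 0
        assert len(m.sequence) == len(r1) + len(r2) - m.overlap_length

    def test_identical_full_overlap(self):
        r1 = "ACGTACGTACGTACGTACGTACGT"
        m = merge_pair(r1, revcomp(r1), min_overlap=4)
        assert m.sequence == r1 and m.overlap_length == len(r1)

    def test_no_admissible_overlap_is_rejected(self):
        m = merge_pair("A" * 30, revcomp("C" * 30), min_overlap=20)
        assert m is None

    def test_consensus_prefers_higher_quality_base(self):
        frag = "ACGTTGCAATCGGATCTAGCAAGGTCATCG"  # 30 nt, overlap 10
        r1, rc2 = frag[:20], frag[10:]
        rc2 = ("G" if rc2[0] != "G" else "C") + rc2[1:]  # disagree at merged pos 10
        r2 = revcomp(rc2)
        m = merge_pair(r1, r2, q1="I" * 20, q2="#" * 20, min_overlap=10)
        assert m.sequence[10] == r1[10]  # r1's base wins on quality
        m2 = merge_pair(r1, r2, q1="#" * 20, q2="I" * 20, min_overlap=10)
        assert m2.sequence[10] == rc2[0]

    @pytest.mark.parametrize("error_rate", [0.0, 0.05])
    def test_matches_brute_force_oracle(self, error_rate):
        rng = np.random.default_rng(17)
        for _ in range(40):
            L = 60
            ov = int(rng.integers(20, 50))
            frag = "".join("ACGT"[b] for b in rng.integers(0, 4, 2 * L - ov))
            r1, rc2 = frag[:L], frag[-L:]
            if error_rate:
                pos = rng.integers(0, L, size=max(1, int(error_rate * L)))
                r1 = "".join(
                    "ACGT"[(("ACGT".index(c)) + 1) % 4] if i in pos else c
                    for i, c in enumerate(r1)
                )
            r2 = revcomp(rc2)
            got = merge_pair(r1, r2)
            want = _brute_force_merge(r1, r2, 20, 0.1)
            if want is None:
                assert got is None
            else:
                assert (got.overlap_length, got.mismatches_in_overlap) == (want[1], want[2])

    def test_batched_mask_agrees_with_reference(self):
        rng = np.random.default_rng(23)
        n, L = 200, 80
        frags = rng.integers(0, 4, size=(n, 110))
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        r1s, r2s = [], []
        for row in frags:
            s = bytes(bases[row]).decode()
            r1s.append(s[:L])
            r2s.append(revcomp(s[-L:]))
        # corrupt a third of pairs beyond recognition
        for i in range(0, n, 3):
            r2s[i] = "".join("ACGT"[b] for b in rng.integers(0, 4, L))
        m1 = np.array([seq_to_u8(s) for s in r1s])
        m2 = np.array([seq_to_u8(s) for s in r2s])
        ok, best_len = _merge_mask_batch(m1, m2, 20, 0.1)
        for i in range(n):
            ref = merge_pair(r1s[i], r2s[i])
            assert ok[i] == (ref is not None)
            if ref is not None:
                assert best_len[i] == ref.overlap_length


class TestDemultiplex:
    @pytest.fixture()
    def sheet(self):
        return build_sample_sheet([("MCF7", "DNA", 1), ("MCF7", "RNA", 1)])

    def test_exact_primer_index_assigns(self, sheet):
        read = primer_seq(1) + index_seq(2) + "ACGT" * 10
        assert demultiplex(read, sheet) == "MCF7_RNA_r1"

    def test_one_primer_substitution_still_assigned(self, sheet):
        p = primer_seq(1)
        p = ("C" if p[0] != "C" else "G") + p[1:]
        read = p + index_seq(1) + "ACGT" * 10
        assert demultiplex(read, sheet) == "MCF7_DNA_r1"

    def test_index_mismatch_unassigned_by_default(self, sheet):
        i = index_seq(1)
        i = ("C" if i[0] != "C" else "G") + i[1:]
        read = primer_seq(1) + i + "ACGT" * 10
        assert demultiplex(read, sheet) == UNASSIGNED

    def test_equidistant_tie_is_ambiguous(self, sheet):
        # two custom primers at Hamming distance 2; read at distance 1 from both
        primers = ["AAAAAAAAAA", "AAAAAAAACC"]
        read = "AAAAAAAAAC" + "TTTTT" + "ACGT" * 10
        got = demultiplex(
            read, sheet, primer_seqs=primers, index_seqs=["TTTTT"], max_primer_mm=1
        )
        assert got == UNASSIGNED

    def test_best_unique_match_distance_table(self):
        """Exhaustive check of the matcher against a hand distance table."""
        refs = np.array([seq_to_u8(s) for s in ["AAAA", "TTTT", "AATT"]])
        cases = {
            "AAAA": 0,
            "AAAT": 0,  # distance 1/4/1 -> tie between refs 0 and 2 ... ambiguous
            "TTTT": 1,
            "AATT": 2,
        }
        fields = np.array([seq_to_u8(s) for s in cases])
        got = _best_unique_match(fields, refs, max_mm=1)
        assert got[0] == 0 and got[2] == 1 and got[3] == 2
        assert got[1] == -1  # equidistant tie


class TestCountBarcodes:
    def test_simple_counts(self):
        bmap = {"AAAA": "c1", "TTTT": "c2"}
        reads = ["X" * BARCODE_OFFSET + "AAAA"] * 10 + ["X" * BARCODE_OFFSET + "TTTT"] * 5
        counts, unassigned = count_barcodes(reads, bmap)
        assert counts == {"c1": 10, "c2": 5} and unassigned == 0

    def test_single_substitution_unassigned_at_mm0(self):
        bmap = {"AAAA": "c1"}
        counts, unassigned = count_barcodes(["X" * BARCODE_OFFSET + "AAAT"], bmap)
        assert counts["c1"] == 0 and unassigned == 1

    def test_mm1_ambiguity_rejected(self):
        bmap = {"AAAA": "c1", "AAAT": "c2"}  # distance 1 apart
        counts, unassigned = count_barcodes(
            ["X" * BARCODE_OFFSET + "AAAC"], bmap, max_barcode_mm=1
        )
        assert unassigned == 1 and sum(counts.values()) == 0

    def test_duplicate_barcode_map_rejected(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("barcode\tconstruct_id\nAAAA\tc1\nAAAA\tc2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_barcode_map_tsv(p)


@pytest.fixture(scope="module")
def run(tmp_path_factory):
    cfg = simdata.SimConfig(n_snps=15, read_depth=5000, seed=21)
    st = simdata.simulate_study(cfg)
    tmp = tmp_path_factory.mktemp("fastq")
    rng = np.random.default_rng(2)
    row = st.sheet.rows.iloc[0]
    col = st.counts[row.sample_id]
    simdata.simulate_fastq(
        col, st.constructs, int(row.primer_set), int(row["index"]), cfg, rng,
        tmp / "r1.fq", tmp / "r2.fq",
    )
    return st, tmp, row, col


class TestPipeline:

    def test_roundtrip_exact_at_error_zero(self, run):
        st, tmp, row, col = run
        table = count_reads(tmp / "r1.fq", tmp / "r2.fq", st.sheet, barcode_map(st.constructs))
        got = table.df[row.sample_id].reindex(col.index)
        assert (got == col).all()

    def test_conservation_per_sample(self, run):
        st, tmp, row, col = run
        table = count_reads(tmp / "r1.fq", tmp / "r2.fq", st.sheet, barcode_map(st.constructs))
        qc = table.qc
        stats = qc.attrs
        assigned = int(qc["assigned"].sum())
        lost = stats["filtered"] + stats["merge_rejected"] + stats["demux_unassigned"]
        barcode_lost = int(qc["barcode_unassigned"].sum())
        assert assigned + lost + barcode_lost == stats["reads"]

    def test_order_independence(self, run, tmp_path):
        st, tmp, row, col = run
        lines1 = (tmp / "r1.fq").read_text().splitlines()
        lines2 = (tmp / "r2.fq").read_text().splitlines()
        rec1 = [lines1[i : i + 4] for i in range(0, len(lines1), 4)]
        rec2 = [lines2[i : i + 4] for i in range(0, len(lines2), 4)]
        order = np.random.default_rng(5).permutation(len(rec1))
        (tmp_path / "s1.fq").write_text(
            "\n".join("\n".join(rec1[i]) for i in order) + "\n"
        )
        (tmp_path / "s2.fq").write_text(
            "\n".join("\n".join(rec2[i]) for i in order) + "\n"
        )
        bmap = barcode_map(st.constructs)
        a = count_reads(tmp / "r1.fq", tmp / "r2.fq", st.sheet, bmap)
        b = count_reads(tmp_path / "s1.fq", tmp_path / "s2.fq", st.sheet, bmap)
        assert a.df.equals(b.df)

    def test_gzip_input_supported(self, run, tmp_path):
        import gzip

        st, tmp, row, col = run
        for name in ("r1.fq", "r2.fq"):
            with open(tmp / name, "rb") as src, gzip.open(tmp_path / f"{name}.gz", "wb") as dst:
                dst.write(src.read())
        table = count_reads(
            tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz", st.sheet, barcode_map(st.constructs)
        )
        assert (table.df[row.sample_id].reindex(col.index) == col).all()
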