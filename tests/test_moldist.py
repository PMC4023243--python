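import io
import math

import numpy as np
import pytest

from mratax import (
    barcoding_gap_summary,
    code_indels,
    distance_matrix,
    gtr_distance,
    p_distance,
    read_alignment,
    write_alignment,
)
from mratax.moldist import AlignedSeqSet, AlignmentError, read_otu_map

from conftest import make_alignment


# ----------------------------------------------------------------------
# reading / writing

def test_read_identical_records():
    aln = read_alignment(io.StringIO(">a\nACGTACGTAC\n>b\nACGTACGTAC\n"))
    assert aln.n == 2 and aln.length == 10


def test_read_normalizes_case_and_u():
    aln = read_alignment(io.StringIO(">a\nacgu\n>b\nACGT\n"))
    assert aln.seqs[0] == aln.seqs[1] == "ACGT"


def test_read_ragged_rejected():
    with pytest.raises(AlignmentError, match="ragged"):
        read_alignment(io.StringIO(">a\nACGT\n>b\nACG\n"))


def test_read_duplicate_ids_rejected():
    with pytest.raises(AlignmentError, match="duplicate"):
        read_alignment(io.StringIO(">a\nACGT\n>a\nACGT\n"))


def test_read_empty_rejected():
    with pytest.raises(AlignmentError, match="empty"):
        read_alignment(io.StringIO(""))


def test_all_ambiguous_sequence_rejected():
    with pytest.raises(AlignmentError, match="unambiguous"):
        make_alignment(["ACGT", "NNNN"])


def test_otu_map_attachment(tmp_path):
    fasta = tmp_path / "a.fasta"
    fasta.write_text(">s1\nACGT\n>s2\nACGT\n")
    mapping = tmp_path / "m.tsv"
    mapping.write_text("s1\totuA\ns2\totuB\n")
    aln = read_alignment(fasta, otu_map=read_otu_map(mapping))
    assert aln.otus == ("otuA", "otuB")
    mapping.write_text("s1\totuA\n")
    with pytest.raises(AlignmentError, match="missing from OTU map"):
        read_alignment(fasta, otu_map=read_otu_map(mapping))


def test_write_read_roundtrip(tmp_path):
    from mratax.simulate import SeqGenSpec, gen_alignment

    aln = gen_alignment(SeqGenSpec(otus={"x": 3, "y": 2}, between_d=0.05,
                                   within_d=0.01, length=200, seed=3))
    path = tmp_path / "out.fasta"
    write_alignment(aln, path)
    back = read_alignment(path)
    assert back.seqs == aln.seqs and back.ids == aln.ids
    assert back.otus == aln.otus
    # byte-identical on re-write
    path2 = tmp_path / "out2.fasta"
    write_alignment(back, path2)
    assert path.read_bytes() == path2.read_bytes()


# ----------------------------------------------------------------------
# distances

def test_gtr_zero_for_identical():
    s = "ACGTACGTACGTACGTACGT" * 5
    assert gtr_distance(s, s) == 0.0


def test_gtr_symmetry():
    from mratax.simulate import gen_pair

    a, b = gen_pair(0.3, length=2000, seed=1).seqs
    assert gtr_distance(a, b) == pytest.approx(gtr_distance(b, a), rel=1e-12)


def _jc_pair(p_diff: float, length: int = 1200):
    """Uniform-composition pair differing at exactly p_diff of sites with a
    perfectly uniform substitution pattern (12 ordered types equally)."""
    assert (length * p_diff) % 12 == 0 and length % 4 == 0
    per_type = int(length * p_diff / 12)
    bases = "ACGT"
    a, b = [], []
    # identical block keeps composition uniform
    same = (length - 12 * per_type) // 4
    for x in bases:
        a += [x] * same
        b += [x] * same
    for x in bases:
        for y in bases:
            if x != y:
                a += [x] * per_type
                b += [y] * per_type
    return "".join(a), "".join(b)


@pytest.mark.parametrize("p_diff", [0.01, 0.12, 0.3])
def test_gtr_matches_jc_closed_form(p_diff):
    a, b = _jc_pair(p_diff)
    expected = -0.75 * math.log(1.0 - 4.0 * p_diff / 3.0)
    assert gtr_distance(a, b) == pytest.approx(expected, abs=1e-9)


def test_gtr_at_least_p_distance(rng):
    from mratax.simulate import gen_pair

    for seed in range(5):
        aln = gen_pair(0.15, length=2000, seed=seed)
        g = gtr_distance(aln.seqs[0], aln.seqs[1])
        p = p_distance(aln.seqs[0], aln.seqs[1])
        assert g >= p - 1e-12


def test_gtr_converges_to_p_distance_at_low_divergence():
    a, b = _jc_pair(0.01, length=2400)
    g = gtr_distance(a, b)
    p = p_distance(a, b)
    assert abs(g - p) / p < 0.05


def test_gtr_column_permutation_invariance(rng):
    from mratax.simulate import gen_pair

    aln = gen_pair(0.08, length=1000, seed=9)
    a = np.array(list(aln.seqs[0]))
    b = np.array(list(aln.seqs[1]))
    perm = rng.permutation(1000)
    d1 = gtr_distance(aln.seqs[0], aln.seqs[1])
    d2 = gtr_distance("".join(a[perm]), "".join(b[perm]))
    assert d1 == pytest.approx(d2, rel=1e-12)


def test_gtr_simulation_recovery():
    """Pair simulated at true d = 0.05 (10 kb): estimate within 3 SE."""
    from mratax.simulate import gen_pair

    d_true = 0.05
    ests = [
        gtr_distance(*gen_pair(d_true, length=10_000, seed=s).seqs)
        for s in range(8)
    ]
    se = np.std(ests, ddof=1) / np.sqrt(len(ests))
    assert abs(np.mean(ests) - d_true) < 3 * se + 1e-4


def test_gtr_pairwise_deletion_and_ambiguity():
    # gap and N columns excluded for the pair
    a = "ACGTAC-TN" + "ACGT" * 10
    b = "ACGTACGTA" + "ACGT" * 10
    assert gtr_distance(a, b) == 0.0
    assert p_distance(a, b) == 0.0


def test_gtr_no_usable_columns_rejected():
    with pytest.raises(AlignmentError, match="no usable"):
        p_distance("AC--", "--GT")


def test_distance_matrix_identical_sequences():
    aln = make_alignment(["ACGT" * 20] * 4)
    dm = distance_matrix(aln, model="gtr")
    np.testing.assert_array_equal(dm.d, 0.0)


def test_distance_matrix_hand_counted_p_distances():
    # 10 columns; a-b differ at 2 sites, a-c at 4, b-c at 4
    aln = make_alignment(
        ["ACGTACGTAC", "ACGTACGTGT", "TCGAACGAAC"],
        otus=["x", "x", "y"],
    )
    dm = distance_matrix(aln, model="p")
    assert dm.d[0, 1] == pytest.approx(2 / 10)
    assert dm.d[0, 2] == pytest.approx(3 / 10)
    assert dm.d[1, 2] == pytest.approx(5 / 10)
    assert dm.d[1, 0] == dm.d[0, 1]
    assert (np.diag(dm.d) == 0).all()
    assert dm.sites_used[0, 1] == 10


def test_distance_matrix_needs_two():
    with pytest.raises(AlignmentError, match="at least 2"):
        distance_matrix(make_alignment(["ACGT"]))


# ----------------------------------------------------------------------
# barcoding gap

def test_gap_summary_trivial_two_otus():
    seq1 = "ACGT" * 25
    seq2 = "ACGT" * 24 + "ACGA"  # one difference in 100
    aln = make_alignment([seq1, seq1, seq2, seq2],
                         otus=["x", "x", "y", "y"],
                         ids=["x1", "x2", "y1", "y2"])
    df = barcoding_gap_summary(distance_matrix(aln, model="p"))
    row_x = df[df["otu"] == "x"].iloc[0]
    assert row_x["within_max_pct"] == pytest.approx(0.0)
    assert row_x["between_min_pct"] == pytest.approx(1.0)
    assert row_x["gap_flag"] == 1
    assert row_x["nearest_otu"] == "y"


def test_gap_summary_singleton_flagged():
    aln = make_alignment(["ACGT" * 25, "ACGT" * 24 + "TTTT"],
                         otus=["x", "y"], ids=["x1", "y1"])
    df = barcoding_gap_summary(distance_matrix(aln, model="p"))
    assert np.isnan(df[df["otu"] == "x"]["within_max_pct"].iloc[0])


def test_gap_summary_constructed_recovery():
    """Star scenario with within-noise << between-distance: summary
    recovers both scales and sets the gap flag."""
    from mratax.simulate import SeqGenSpec, gen_alignment

    spec = SeqGenSpec(otus={"a": 4, "b": 4}, between_d=0.10, within_d=0.002,
                      length=5000, seed=42)
    dm = distance_matrix(gen_alignment(spec), model="gtr")
    df = barcoding_gap_summary(dm)
    for _, row in df.iterrows():
        assert row["within_max_pct"] < 1.0
        assert row["between_min_pct"] == pytest.approx(10.0, rel=0.3)
        assert row["gap_flag"] == 1


def test_gap_summary_needs_two_otus():
    aln = make_alignment(["ACGT", "ACGT"], otus=["x", "x"], ids=["a", "b"])
    with pytest.raises(AlignmentError, match="2 OTUs"):
        barcoding_gap_summary(distance_matrix(aln, model="p"))


# ----------------------------------------------------------------------
# indel coding

def test_code_indels_enumerated_toy():
    # taxa 1-2 share an internal gap (cols 2-4, 0-based), taxon 3 has a
    # distinct single-column gap; taxon 4 gapless
    aln = make_alignment(
        [
            "AC---GTACG",
            "AC---GTACG",
            "ACGTAGT-CG",
            "ACGTAGTACG",
        ]
    )
    chars = code_indels(aln)
    assert len(chars.characters) == 2
    by_span = {(c.start, c.end): c for c in chars.characters}
    shared = by_span[(2, 5)]
    assert shared.states == (1, 1, 0, 0)
    assert shared.classification == "parsimony-informative"
    single = by_span[(7, 8)]
    assert single.states == (0, 0, 1, 0)
    assert single.classification == "autapomorphic"
    counts = chars.counts()
    assert counts["total"] == 2
    assert counts["parsimony-informative"] == 1
    assert counts["autapomorphic"] == 1


def test_code_indels_single_gap_autapomorphic():
    aln = make_alignment(["A" + "C" * 10 + "G" * 9,
                          "A" + "-" * 10 + "G" * 9])
    chars = code_indels(aln)
    assert len(chars.characters) == 1
    assert chars.characters[0].classification == "autapomorphic"


def test_code_indels_different_boundaries_distinct_characters():
    aln = make_alignment(["AC--GTAC", "AC---TAC", "ACGTGTAC"])
    chars = code_indels(aln)
    spans = {(c.start, c.end) for c in chars.characters}
    assert spans == {(2, 4), (2, 5)}


def test_code_indels_terminal_overhangs_excluded():
    aln = make_alignment(["--GTACGT", "ACGTAC--", "ACGTACGT"])
    assert code_indels(aln).characters == ()


def test_code_indels_gapless_empty():
    aln = make_alignment(["ACGT", "ACGT"])
    assert code_indels(aln).characters == ()


def test_code_indels_covering_gap_scored_missing():
    # taxon 2's larger gap fully covers taxon 1's span: missing, not absent
    aln = make_alignment(["ACG--TACGT", "AC----ACGT", "ACGTATACGT"])
    chars = code_indels(aln)
    by_span = {(c.start, c.end): c for c in chars.characters}
    assert by_span[(3, 5)].states == (1, -1, 0)
    assert by_span[(2, 6)].states == (0, 1, 0)
    # classification ignores missing entries
    assert by_span[(3, 5)].classification == "autapomorphic"


def test_code_indels_classes_sum_to_total(rng):
    from mratax.simulate import IndelEvent, SeqGenSpec, gen_alignment

    spec = SeqGenSpec(
        otus={"a": 3, "b": 3}, between_d=0.05, within_d=0.01, length=300,
        indels=(IndelEvent(50, 5, ("a",)), IndelEvent(100, 3, ("b_1",)),
                IndelEvent(200, 8, ("a", "b"))),
        seed=7,
    )
    chars = code_indels(gen_alignment(spec))
    counts = chars.counts()
    assert counts["total"] == (
        counts["parsimony-informative"] + counts["autapomorphic"]
        + counts["constant"]
    )
    assert counts["total"] == 3


def test_code_indels_taxon_duplication_monotone():
    aln = make_alignment(["AC--GTAC", "ACGTGTAC", "AC--GTAC"])
    base = code_indels(aln).counts()
    dup = make_alignment(["AC--GTAC", "ACGTGTAC", "AC--GTAC", "ACGTGTAC"])
    more = code_indels(dup).counts()
    assert more["parsimony-informative"] >= base["parsimony-informative"]


def test_phylip_output_shapes():
    aln = make_alignment(["AC--GTAC", "ACGTGTAC", "AC--GTAC"])
    chars = code_indels(aln)
    text = chars.to_phylip()
    header = text.splitlines()[0].split()
    assert header == ["3", "1"]
    df = chars.to_frame()
    assert list(df.columns) == ["char", "start", "end", "class"]
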