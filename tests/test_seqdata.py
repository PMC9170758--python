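"""Site loading, window construction, negative sampling, encoding, folds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulse import seqdata
from pulse.seqdata import (
    GenomicSite,
    LabeledSample,
    build_negative_samples,
    build_positive_samples,
    extract_window,
    load_sites,
    make_folds,
    one_hot_decode,
    one_hot_encode,
    reverse_complement,
)


def _random_ref(rng, length=400, name="tx1"):
    return {name: "".join(rng.choice(list("ACGT"), size=length))}


class TestLoadSites:
    REF = {"chr1": "ACGTACGTAC"}

    def test_plus_strand_thymine_retained(self):
        sites, discarded = load_sites([("chr1", 3, "+")], self.REF)
        assert [s.position for s in sites] == [3]
        assert discarded == 0

    def test_non_thymine_discarded_and_counted(self):
        sites, discarded = load_sites([("chr1", 2, "+"), ("chr1", 3, "+")], self.REF)
        assert len(sites) == 1
        assert discarded == 1

    def test_minus_strand_over_reference_a_is_thymine(self):
        # base 'A' at position 0; its reverse complement is T
        sites, discarded = load_sites([("chr1", 0, "-")], self.REF)
        assert len(sites) == 1 and discarded == 0
        # brute-force check on the 10-nt toy: every '-' site kept iff ref base is A
        for pos in range(10):
            kept, _ = load_sites([("chr1", pos, "-")], self.REF)
            assert bool(kept) == (self.REF["chr1"][pos] == "A")

    def test_missing_sequence_id_raises(self):
        with pytest.raises(KeyError, match="chrX"):
            load_sites([("chrX", 0, "+")], self.REF)

    def test_position_out_of_range_raises(self):
        with pytest.raises(ValueError, match="outside"):
            load_sites([("chr1", 99, "+")], self.REF)

    def test_malformed_bed_reports_line_number(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t3\t4\nchr1\tnotanumber\t5\n")
        with pytest.raises(ValueError, match=":2"):
            seqdata.read_bed(bed)


class TestPositiveSamples:
    def test_interior_window_no_padding(self):
        rng = np.random.default_rng(0)
        ref = _random_ref(rng, 200)
        seq = ref["tx1"]
        pos = next(i for i in range(60, 100) if seq[i] == "T")
        samples = build_positive_samples([GenomicSite("tx1", pos, "+")], ref)
        assert samples[0].sequence == seq[pos - 50:pos + 51]
        assert "N" not in samples[0].sequence

    def test_edge_window_left_padded(self):
        ref = {"tx1": "ACGTACGTAC" * 20}
        pos = 3  # a T
        samples = build_positive_samples([GenomicSite("tx1", pos, "+")], ref)
        s = samples[0].sequence
        assert s.startswith("N" * 47)
        assert s[47] != "N"
        assert s[50] == "T"
        assert len(s) == 101

    def test_minus_strand_is_reverse_complement_of_plus_slice(self):
        # hand-checkable 12-nt toy; '-' site over reference 'A'
        ref = {"tx1": "GGGAAACCCTTT"}
        pos = 4
        samples = build_positive_samples([GenomicSite("tx1", pos, "-")], ref)
        plus_window = extract_window(ref["tx1"], pos, strand="+")
        assert samples[0].sequence == reverse_complement(plus_window)
        assert samples[0].sequence[50] == "T"


def _brute_force_negatives(seq, pos_centers, ratio_n, flank=50):
    """Exhaustive nearest-non-overlapping-thymine search, one positive at
    a time, ties downstream; '+' strand only."""
    windows = [(max(0, c - flank), min(len(seq), c + flank + 1)) for c in pos_centers]
    out = set()
    for c in pos_centers:
        eligible = []
        for t, ch in enumerate(seq):
            if ch != "T":
                continue
            w0, w1 = max(0, t - flank), min(len(seq), t + flank + 1)
            if any(w0 < e and s < w1 for s, e in windows):
                continue
            eligible.append(t)
        eligible.sort(key=lambda t: (abs(t - c), 0 if t > c else 1))
        out.update(eligible[:ratio_n])
    return out


class TestNegativeSamples:
    @pytest.mark.parametrize("ratio_n", [1, 3])
    def test_matches_brute_force_on_random_toys(self, ratio_n):
        rng = np.random.default_rng(42)
        for trial in range(20):
            ref = _random_ref(rng, 400)
            seq = ref["tx1"]
            t_pos = [i for i, ch in enumerate(seq) if ch == "T"]
            centers = list(rng.choice(t_pos, size=2, replace=False))
            sites = [GenomicSite("tx1", int(c), "+") for c in centers]
            positives = build_positive_samples(sites, ref)
            negatives = build_negative_samples(positives, ref, ratio_n=ratio_n)
            got = {n.origin.position for n in negatives}
            assert got == _brute_force_negatives(seq, centers, ratio_n)
            for n in negatives:
                assert len(n.sequence) == 101
                assert n.sequence[50] == "T"

    def test_equidistant_tie_goes_downstream(self):
        # positive T at 150; free thymines equidistant at 150±101 (windows
        # just clear of the positive window)
        seq = ["C"] * 400
        seq[150] = "T"
        seq[49] = "T"
        seq[251] = "T"
        ref = {"tx1": "".join(seq)}
        positives = build_positive_samples([GenomicSite("tx1", 150, "+")], ref)
        negatives = build_negative_samples(positives, ref, ratio_n=1)
        assert [n.origin.position for n in negatives] == [251]

    def test_no_eligible_thymine_warns_and_skips(self):
        seq = ["C"] * 200
        seq[100] = "T"  # the positive itself is the only T
        ref = {"tx1": "".join(seq)}
        positives = build_positive_samples([GenomicSite("tx1", 100, "+")], ref)
        with pytest.warns(UserWarning, match="0/1 eligible"):
            negatives = build_negative_samples(positives, ref)
        assert negatives == []

    def test_duplicate_negatives_deduplicated(self):
        # two close positives share the same nearest eligible thymine
        seq = ["C"] * 500
        for p in (200, 204):
            seq[p] = "T"
        seq[310] = "T"
        ref = {"tx1": "".join(seq)}
        sites = [GenomicSite("tx1", 200, "+"), GenomicSite("tx1", 204, "+")]
        positives = build_positive_samples(sites, ref)
        negatives = build_negative_samples(positives, ref, ratio_n=1)
        assert [n.origin.position for n in negatives] == [310]


class TestOneHot:
    def test_definition_alphabetical_channels(self):
        mat = one_hot_encode("ACGT")
        assert mat.tolist() == [
            [1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1],
        ]

    def test_n_is_zero_row_and_u_maps_to_t(self):
        assert one_hot_encode("N").tolist() == [[0, 0, 0, 0]]
        assert one_hot_encode("u").tolist() == [[0, 0, 0, 1]]

    def test_illegal_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            one_hot_encode("ACXT")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=101))
    def test_round_trip(self, s):
        assert one_hot_decode(one_hot_encode(s)) == s


class TestFolds:
    def test_even_partition(self):
        f = make_folds(list(range(100)), k=10, seed=0)
        counts = np.bincount(f.fold_index, minlength=10)
        assert counts.tolist() == [10] * 10

    def test_uneven_partition_differs_by_at_most_one(self):
        f = make_folds(list(range(101)), k=10, seed=0)
        counts = sorted(np.bincount(f.fold_index, minlength=10).tolist())
        assert counts == [10] * 9 + [11]

    def test_deterministic_for_fixed_seed(self):
        a = make_folds(list(range(57)), k=5, seed=3)
        b = make_folds(list(range(57)), k=5, seed=3)
        assert np.array_equal(a.fold_index, b.fold_index)

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            make_folds(list(range(5)), k=10, seed=0)


class TestSampleInvariants:
    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            LabeledSample("ACGT", 1)

    def test_wrong_center_rejected(self):
        seq = "A" * 101
        with pytest.raises(ValueError, match="center"):
            LabeledSample(seq, 1)

    def test_tsv_round_trip(self, tmp_path):
        seq = "A" * 50 + "T" + "G" * 50
        s = LabeledSample(seq, 1, origin=GenomicSite("tx1", 60, "+"), window_start=10)
        path = tmp_path / "samples.tsv"
        seqdata.write_samples_tsv([s], path)
        back = seqdata.read_samples_tsv(path)
        assert back[0].sequence == seq
        assert back[0].label == 1
        assert back[0].origin.sequence_id == "tx1"
        assert back[0].window_start == 10
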