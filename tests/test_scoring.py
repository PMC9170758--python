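"""Transcript scanning, tPPS, Ψ calls, and AFCP variant scoring."""

import numpy as np
import pytest

from pulse import (
    ModelConfig,
    ReferenceMismatchError,
    VariantRecord,
    afcp,
    afcp_batch,
    build_model,
    call_sites,
    scan_transcript,
    tpps,
)
from pulse.model import TrainedModel
from pulse.scoring import SiteScore, read_vcf
from pulse.seqdata import extract_window, one_hot_encode


def _constant_model():
    """All first-layer weights zero: the model ignores the sequence and
    emits one constant score."""
    cfg = ModelConfig(conv1_filters=4, conv2_filters=4, fc_units=(8,), seed=0)
    net = build_model(cfg)
    net.conv1.W[...] = 0.0
    net.conv1.b[...] = 0.0
    return TrainedModel(config=cfg, net=net)


class TestScanTranscript:
    def test_no_thymines_gives_empty_list(self, trained_small_model):
        assert scan_transcript(trained_small_model, "tx", "A" * 30) == []

    def test_edge_window_padding_arithmetic(self, trained_small_model):
        seq = "GG" + "T" + "A" * 27  # thymine at offset 2 of a 30-nt transcript
        scores = scan_transcript(trained_small_model, "tx", seq)
        window = extract_window(seq, 2)
        assert window.startswith("N" * 48)
        assert window.endswith("N" * (101 - 48 - 30))
        assert scores[0].position == 2

    def test_one_score_per_thymine(self, trained_small_model):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(20, 200))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            scores = scan_transcript(trained_small_model, "tx", seq)
            assert len(scores) == seq.count("T")
            assert [s.position for s in scores] == [
                i for i, ch in enumerate(seq) if ch == "T"
            ]

    def test_position_consistency_with_manual_windows(self, trained_small_model):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=150))
        scores = scan_transcript(trained_small_model, "tx", seq)
        for s in scores[:5]:
            manual = trained_small_model.predict(
                one_hot_encode(extract_window(seq, s.position))[None]
            )[0]
            # single-window vs batched prediction: float32 rounding only
            assert manual == pytest.approx(s.lpps, abs=1e-5)


class TestCallSites:
    def test_exact_threshold_goes_to_non_psi(self):
        scores = [SiteScore("tx", 0, 0.5)]
        psi, non_psi = call_sites(scores)
        assert psi == [] and len(non_psi) == 1

    def test_threshold_monotonicity_and_partition(self):
        rng = np.random.default_rng(2)
        scores = [SiteScore("tx", i, float(v)) for i, v in enumerate(rng.random(100))]
        psi_40, _ = call_sites(scores, 0.4)
        psi_60, _ = call_sites(scores, 0.6)
        assert {s.position for s in psi_60} <= {s.position for s in psi_40}
        psi, non_psi = call_sites(scores)
        assert len(psi) + len(non_psi) == len(scores)


def brute_force_tpps(lpps_values, L):
    num_psi = sum(1 for v in lpps_values if v > 0.5)
    num_u = sum(1 for v in lpps_values if v <= 0.5)
    K = len(lpps_values)
    if K == 0 or num_u == 0:
        return None
    return (num_psi / num_u) / (K / L)


class TestTpps:
    def test_hand_worked_example(self):
        scores = [SiteScore("tx", i, v) for i, v in enumerate([0.9, 0.8, 0.3, 0.2])]
        ts = tpps(scores, L=10)
        assert (ts.num_psi, ts.num_u, ts.K, ts.L) == (2, 2, 4, 10)
        assert ts.tpps == pytest.approx(2.5)

    def test_zero_numerator(self):
        scores = [SiteScore("tx", i, 0.2) for i in range(4)]
        assert tpps(scores, L=10).tpps == 0.0

    def test_all_psi_is_undefined(self):
        scores = [SiteScore("tx", i, 0.9) for i in range(4)]
        ts = tpps(scores, L=10)
        assert ts.tpps is None and not ts.defined

    def test_position_beyond_length_raises(self):
        with pytest.raises(ValueError):
            tpps([SiteScore("tx", 12, 0.9)], L=10)

    def test_matches_direct_formula_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            K = int(rng.integers(0, 40))
            vals = rng.random(K)
            L = int(rng.integers(max(K, 1), 500))
            scores = [SiteScore("tx", i, float(v)) for i, v in enumerate(vals)]
            ts = tpps(scores, L=L)
            expected = brute_force_tpps(vals, L)
            if expected is None:
                assert ts.tpps is None
            else:
                assert ts.tpps == pytest.approx(expected)


class TestAfcp:
    @staticmethod
    def _toy_reference(rng, length=400):
        return {"tx1": "".join(rng.choice(list("ACGT"), size=length))}

    def test_constant_model_gives_exactly_zero(self):
        model = _constant_model()
        rng = np.random.default_rng(4)
        ref = self._toy_reference(rng)
        pos = 200
        major = ref["tx1"][pos]
        minor = next(b for b in "ACGT" if b != major)
        rec = afcp(model, VariantRecord("v1", "tx1", pos, major, minor), ref)
        assert rec is not None
        assert rec.afcp == 0.0

    def test_antisymmetry_under_allele_swap_is_exact(self, trained_small_model):
        rng = np.random.default_rng(5)
        ref = self._toy_reference(rng)
        seq = ref["tx1"]
        for _ in range(20):
            pos = int(rng.integers(60, 340))
            major = seq[pos]
            minor = str(rng.choice([b for b in "ACGT" if b != major]))
            fwd = afcp(trained_small_model,
                       VariantRecord("v", "tx1", pos, major, minor), ref)
            swapped_ref = {"tx1": seq[:pos] + minor + seq[pos + 1:]}
            rev = afcp(trained_small_model,
                       VariantRecord("v", "tx1", pos, minor, major), swapped_ref)
            assert fwd is not None and rev is not None
            assert rev.afcp == -fwd.afcp
            assert rev.target_position == fwd.target_position

    def test_reference_mismatch_raises(self, trained_small_model):
        ref = {"tx1": "ACGT" * 100}
        base = ref["tx1"][100]  # 'A'
        assert base == "A"
        with pytest.raises(ReferenceMismatchError, match="v1"):
            afcp(trained_small_model, VariantRecord("v1", "tx1", 100, "G", "C"), ref)

    def test_no_eligible_thymine_is_skipped_with_reason(self, trained_small_model):
        ref = {"tx1": "C" * 300}
        variants = [VariantRecord("v1", "tx1", 150, "C", "G")]
        records, skipped = afcp_batch(trained_small_model, variants, ref)
        assert records == []
        assert skipped == [("v1", "no eligible thymine within 50 nt")]

    def test_motif_destroying_variant_positive_afcp(self, trained_small_model):
        # plant GTTCAA (Ψ at its index 2) and destroy the G beside the target T
        rng = np.random.default_rng(6)
        seq = list("".join(rng.choice(list("ACG"), size=301)))
        seq[148:154] = "GTTCAA"
        ref = {"tx1": "".join(seq)}
        rec = afcp(trained_small_model, VariantRecord("v", "tx1", 148, "G", "C"), ref)
        assert rec is not None
        # the motif's first T (offset 149) is the thymine nearest the variant
        assert rec.target_position == 149
        assert rec.afcp > 0

    def test_vcf_reader(self, tmp_path, trained_small_model):
        vcf = tmp_path / "test.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=tx1,length=400>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "tx1\t151\tv1\tA\tG\t.\t.\t.\n"
            "tx1\t201\tv2\tAT\tA\t.\t.\t.\n"  # indel: ignored
        )
        variants = read_vcf(vcf)
        assert len(variants) == 1
        v = variants[0]
        assert (v.variant_id, v.sequence_id, v.position) == ("v1", "tx1", 150)
        assert (v.major_allele, v.minor_allele) == ("A", "G")


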