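import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgmark import (
    CodecParams,
    PredictionModel,
    choose_adaptive_param,
    empirical_params,
    lcb_embed,
    lcb_extract,
    lcbp_embed,
    lcbp_extract,
    saved_space,
)
from ecgmark.errors import CorruptStreamError, InsufficientCapacityError, \
    TamperError
from ecgmark.lcb import (
    compress,
    compressed_size,
    decompress,
    huffman_decode,
    huffman_encode,
    rle_decode,
    rle_encode,
)
from ecgmark.signal_model import ECGRecord, LeadSignal, get_bit_plane


class TestRle:
    def test_two_runs(self):
        enc = rle_encode("00001111", 3)
        assert enc.tolist() == [0, 1, 0, 0, 1, 0, 0]  # 0|100|100

    def test_long_run_split_with_zero_switch(self):
        enc = rle_encode("00000000", 3)
        assert enc.tolist() == [0, 1, 1, 1, 0, 0, 0, 0, 0, 1]  # 0|111|000|001

    def test_empty_input(self):
        enc = rle_encode([], 3)
        assert enc.size == 1
        assert rle_decode(enc, 3, 0).size == 0

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(2, 10), st.integers(0, 2 ** 31 - 1),
           st.integers(1, 400))
    def test_roundtrip_random(self, B, seed, n):
        bits = np.random.default_rng(seed).integers(0, 2, n).astype(np.uint8)
        assert np.array_equal(rle_decode(rle_encode(bits, B), B, n), bits)

    def test_truncated_stream_is_corrupt(self):
        enc = rle_encode("00001111", 3)
        with pytest.raises(CorruptStreamError):
            rle_decode(enc[:-2], 3, 8)


class TestHuffman:
    def test_optimal_code_length_three_symbols(self):
        # frequencies {0b00: 2, 0b01: 1, 0b10: 1} -> total 2*1+1*2+1*2 = 6
        bits = "00" + "00" + "01" + "10"
        codebook, enc = huffman_encode(bits, 2)
        assert enc.size == 6
        assert codebook.size == 4 * 5

    def test_degenerate_single_symbol(self):
        bits = np.zeros(40, dtype=np.uint8)
        codebook, enc = huffman_encode(bits, 4)
        assert enc.size == 10  # one bit per symbol
        assert np.array_equal(huffman_decode(codebook, enc, 4, 40), bits)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(2, 8), st.integers(0, 2 ** 31 - 1),
           st.integers(1, 600))
    def test_roundtrip_random(self, L, seed, n):
        bits = np.random.default_rng(seed).integers(0, 2, n).astype(np.uint8)
        codebook, enc = huffman_encode(bits, L)
        assert np.array_equal(huffman_decode(codebook, enc, L, n), bits)

    def test_roundtrip_on_ecg_planes(self, record):
        for p in (5, 8, 11):
            bits = get_bit_plane(record.lead("II"), p)
            for L in (2, 6, 8):
                codebook, enc = huffman_encode(bits, L)
                assert np.array_equal(
                    huffman_decode(codebook, enc, L, bits.size), bits)

    def test_truncated_stream_is_corrupt(self):
        bits = np.random.default_rng(1).integers(0, 2, 64).astype(np.uint8)
        codebook, enc = huffman_encode(bits, 3)
        with pytest.raises(CorruptStreamError):
            huffman_decode(codebook, enc[: enc.size // 2], 3, 64)


class TestParams:
    @pytest.mark.parametrize("p,b,l", [(8, 5, 6), (5, 2, 3), (11, 8, 8)])
    def test_empirical_rule_with_clamping(self, p, b, l):
        assert empirical_params(p) == (b, l)

    def test_adaptive_never_worse_than_formula(self, record):
        for codec in ("rle", "huffman"):
            for p in (5, 8, 11):
                bits = get_bit_plane(record.lead("V3"), p)
                b_emp, l_emp = empirical_params(p)
                emp = b_emp if codec == "rle" else l_emp
                best = choose_adaptive_param(bits, codec)
                assert compressed_size(bits, codec, best) <= \
                    compressed_size(bits, codec, emp)

    def test_adaptive_prefers_large_b_for_long_runs(self):
        bits = np.repeat([0, 1], 600).astype(np.uint8)
        assert choose_adaptive_param(bits, "rle") == 10

    def test_compressed_size_matches_stream(self, record):
        bits = get_bit_plane(record.lead("I"), 7)
        for codec, v in (("rle", 4), ("huffman", 5)):
            assert compressed_size(bits, codec, v) == \
                compress(bits, codec, v).size


class TestLcb:
    @pytest.mark.parametrize("codec", ["rle", "huffman"])
    def test_roundtrip_both_codecs(self, record, payload64, codec):
        res = lcb_embed(record, payload64, planes=(7, 8),
                        params=CodecParams(codec=codec, adaptive=True))
        payload, restored = lcb_extract(res.record, res.side_info)
        assert np.array_equal(payload, payload64)
        for a, b in zip(record.leads, restored.leads):
            assert np.array_equal(a.samples, b.samples)

    def test_empirical_params_roundtrip(self, record, payload64):
        res = lcb_embed(record, payload64, planes=(8, 9),
                        params=CodecParams(codec="huffman"))
        payload, restored = lcb_extract(res.record, res.side_info)
        assert np.array_equal(payload, payload64)
        assert np.array_equal(restored.lead("V5").samples,
                              record.lead("V5").samples)

    def test_incompressible_planes_rejected(self, rng):
        x = rng.integers(-32768, 32768, 4000)
        rec = ECGRecord(leads=(LeadSignal(name="I", samples=x),))
        with pytest.raises(InsufficientCapacityError):
            lcb_embed(rec, [1], planes=(7, 8),
                      params=CodecParams(codec="huffman", adaptive=True))

    def test_lower_planes_give_higher_psnr(self, record):
        lo = lcb_embed(record, [], planes=(8, 9),
                       params=CodecParams(codec="huffman", adaptive=True))
        hi = lcb_embed(record, [], planes=(10, 11),
                       params=CodecParams(codec="huffman", adaptive=True))
        assert lo.psnr_mean > hi.psnr_mean

    def test_distortion_bounded_by_highest_plane(self, record):
        res = lcb_embed(record, [], planes=(7, 8),
                        params=CodecParams(codec="huffman", adaptive=True))
        for lead in record.leads:
            diff = np.abs(res.record.lead(lead.name).samples - lead.samples)
            assert diff.max() < 2 ** 8

    def test_bit_flip_in_plane_is_tamper(self, record, payload64):
        res = lcb_embed(record, payload64, planes=(7, 8),
                        params=CodecParams(codec="huffman", adaptive=True))
        lead = res.record.lead("I")
        bits = get_bit_plane(lead, 7).copy()
        bits[10] ^= 1  # lands inside header or compressed region
        from ecgmark.signal_model import set_bit_plane
        bad = res.record.with_lead("I", set_bit_plane(lead, 7, bits).samples)
        with pytest.raises(TamperError):
            lcb_extract(bad, res.side_info)

    def test_wrong_plane_selection_is_tamper(self, record, payload64):
        res = lcb_embed(record, payload64, planes=(7, 8),
                        params=CodecParams(codec="huffman", adaptive=True))
        with pytest.raises(TamperError):
            lcb_extract(res.record, res.side_info, planes=(8, 9))


class TestLcbp:
    @pytest.mark.parametrize("kind,ps", [
        ("physical", 2), ("physical", 4),
        ("interlead_regression", 2), ("interlead_regression", 4),
    ])
    def test_roundtrip(self, record, payload64, kind, ps):
        res = lcbp_embed(record, payload64, "III",
                         PredictionModel(kind=kind), ps=ps)
        payload, restored = lcbp_extract(res.record, res.side_info)
        assert np.array_equal(payload, payload64)
        assert np.array_equal(restored.lead("III").samples,
                              record.lead("III").samples)

    def test_exact_prediction_small_distortion(self, record):
        res = lcbp_embed(record, [], "III",
                         PredictionModel(kind="physical"), ps=2)
        diff = np.abs(res.record.lead("III").samples -
                      record.lead("III").samples)
        assert diff.max() < 4      # only planes 1-2 change
        assert res.psnr_per_lead["III"] > 60

    def test_ps4_capacity_exceeds_ps2(self, record):
        r2 = lcbp_embed(record, [], "III",
                        PredictionModel(kind="physical"), ps=2)
        r4 = lcbp_embed(record, [], "III",
                        PredictionModel(kind="physical"), ps=4)
        assert r4.bps > r2.bps

    def test_unpredictable_lead_rejected(self, rng):
        # white-noise target cannot be predicted: errors incompressible
        leads = tuple(
            LeadSignal(name=nm, samples=rng.integers(-2000, 2000, 3000))
            for nm in ("I", "II", "III", "V1"))
        rec = ECGRecord(leads=leads)
        with pytest.raises(InsufficientCapacityError):
            lcbp_embed(rec, [1], "V1",
                       PredictionModel(kind="interlead_regression"), ps=2)

    def test_modified_predictor_lead_is_tamper(self, record, payload64):
        res = lcbp_embed(record, payload64, "III",
                         PredictionModel(kind="physical"), ps=2)
        bad = res.record.with_lead("I", res.record.lead("I").samples + 3)
        with pytest.raises(TamperError):
            lcbp_extract(bad, res.side_info)

    def test_zero_payload_pure_compress_restore(self, record):
        res = lcbp_embed(record, [], "III",
                         PredictionModel(kind="physical"), ps=2)
        payload, restored = lcbp_extract(res.record, res.side_info)
        assert payload.size == 0
        assert np.array_equal(restored.lead("III").samples,
                              record.lead("III").samples)


class TestTrends:
    def test_huffman_saves_more_than_rle_on_planes_5_to_9(self, corpus20):
        """Average saved space across corpus planes 5-9: Huffman (adaptive
        L) at or above RLE (adaptive B)."""
        hv, rv = [], []
        for rec in corpus20[:8]:
            for p in range(5, 10):
                bits = get_bit_plane(rec.lead("II"), p)
                u = bits.size
                l_best = choose_adaptive_param(bits, "huffman")
                b_best = choose_adaptive_param(bits, "rle")
                hv.append(saved_space(
                    compressed_size(bits, "huffman", l_best), u))
                rv.append(saved_space(
                    compressed_size(bits, "rle", b_best), u))
        assert np.mean(hv) >= np.mean(rv)
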