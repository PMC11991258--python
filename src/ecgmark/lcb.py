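"""Lossless-compression-based embedding (LCB) and its prediction-error
variant (LCBP).

LCB frees capacity by losslessly compressing selected bit planes of the
signal and writing the watermark into the released space.  Two binary
codecs are provided:

* **RLE** — run lengths stored as B-bit numbers (B ∈ 2..10); a run longer
  than 2^B − 1 is split by emitting the maximum followed by a zero-length
  run of the opposite bit.
* **Huffman** — the bit sequence is cut into L-bit symbols (L ∈ 2..8),
  a canonical Huffman code is built from symbol frequencies and the
  codebook travels as 2^L five-bit code lengths in front of the payload.

The codec parameter can be chosen adaptively (exhaustive search over its
range, ties to the smaller value) or by the empirical rules

    B = P − 3 (RLE),    L = P − 2 (Huffman),

with P the compressed bit-plane index, each clamped to its valid range.

LCBP compresses the prediction error of one target lead instead of raw
planes: errors are zigzag-mapped to unsigned, serialized at the minimal
fixed width m, compressed, and written (with a self-describing header)
into the ps least-significant planes of the target lead.  The higher
planes keep their original bits, so per-sample distortion stays below
2^ps; restoration is original = prediction + stored error.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from heapq import heapify, heappop, heappush

import numpy as np

from .embed_result import EmbedResult
from .errors import (
    CorruptStreamError,
    InsufficientCapacityError,
    TamperError,
    ValidationError,
)
from .payload import as_bits, bits_to_bytes, deframe_payload, frame_payload
from .predictors import (
    PredictionModel,
    fit_interlead_regression,
    model_from_side_info,
    model_to_side_info,
    predict,
)
from .signal_model import (
    ECGRecord,
    MetricsConfig,
    bps as bps_metric,
    get_bit_plane,
    psnr,
    record_psnr,
    set_bit_plane,
)

B_RANGE = range(2, 11)   # RLE run-length field width
L_RANGE = range(2, 9)    # Huffman symbol length
_CODEC_IDS = {"rle": 0, "huffman": 1}
_CODEC_NAMES = {v: k for k, v in _CODEC_IDS.items()}


@dataclass(frozen=True)
class CodecParams:
    """Codec choice and parameter policy.

    With ``adaptive`` set, B or L is found by exhaustive search over its
    range per signal.  Otherwise an explicitly given B/L is used; when
    neither is given the empirical plane rule B = P−3 / L = P−2 applies.
    """

    codec: str = "huffman"
    B: int | None = None
    L: int | None = None
    adaptive: bool = False

    def __post_init__(self):
        if self.codec not in _CODEC_IDS:
            raise ValidationError(f"unknown codec {self.codec!r}")
        if self.B is not None and self.B not in B_RANGE:
            raise ValidationError(f"B must be in [2, 10], got {self.B}")
        if self.L is not None and self.L not in L_RANGE:
            raise ValidationError(f"L must be in [2, 8], got {self.L}")

    @property
    def value(self) -> int | None:
        return self.B if self.codec == "rle" else self.L


def empirical_params(p: int) -> tuple[int, int]:
    """Empirical codec parameters for compressed bit plane P:
    B = P − 3, L = P − 2, clamped into their valid ranges."""
    b = min(max(p - 3, B_RANGE.start), B_RANGE.stop - 1)
    l = min(max(p - 2, L_RANGE.start), L_RANGE.stop - 1)
    return b, l


# ---------------------------------------------------------------------------
# Bit helpers

def _int_to_bits(value: int, width: int) -> np.ndarray:
    if value < 0 or value >= 1 << width:
        raise ValidationError(f"value {value} does not fit in {width} bits")
    return np.array([(value >> (width - 1 - i)) & 1 for i in range(width)],
                    dtype=np.uint8)


def _bits_to_int(bits) -> int:
    out = 0
    for b in bits:
        out = (out << 1) | int(b)
    return out


# ---------------------------------------------------------------------------
# RLE codec

def rle_encode(bits, B: int) -> np.ndarray:
    if B not in B_RANGE:
        raise ValidationError(f"B must be in [2, 10], got {B}")
    bits = as_bits(bits)
    max_run = (1 << B) - 1
    if bits.size == 0:
        return np.array([0], dtype=np.uint8)
    out = [np.array([bits[0]], dtype=np.uint8)]
    edges = np.flatnonzero(np.diff(bits)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [bits.size]])
    for s, e in zip(starts, ends):
        run = int(e - s)
        while run > max_run:
            out.append(_int_to_bits(max_run, B))
            out.append(_int_to_bits(0, B))   # zero-length opposite run
            run -= max_run
        out.append(_int_to_bits(run, B))
    return np.concatenate(out)


def rle_decode(encoded, B: int, n_bits: int) -> np.ndarray:
    if B not in B_RANGE:
        raise ValidationError(f"B must be in [2, 10], got {B}")
    enc = as_bits(encoded)
    if enc.size < 1:
        raise CorruptStreamError("RLE stream empty")
    value = int(enc[0])
    pos = 1
    out = np.empty(n_bits, dtype=np.uint8)
    filled = 0
    while filled < n_bits:
        if pos + B > enc.size:
            raise CorruptStreamError(
                "RLE stream exhausted before expected length recovered")
        run = _bits_to_int(enc[pos:pos + B])
        pos += B
        if filled + run > n_bits:
            raise CorruptStreamError("RLE run overruns expected length")
        out[filled:filled + run] = value
        filled += run
        value ^= 1
    return out


# ---------------------------------------------------------------------------
# Huffman codec (canonical, L-bit symbols, codebook = 2^L code lengths
# of 5 bits each; a single distinct symbol gets a 1-bit code)

_LEN_BITS = 5
_MAX_CODE_LEN = (1 << _LEN_BITS) - 1


def _symbolize(bits: np.ndarray, L: int) -> np.ndarray:
    pad = (-bits.size) % L
    if pad:
        bits = np.concatenate([bits, np.zeros(pad, dtype=np.uint8)])
    groups = bits.reshape(-1, L)
    weights = (1 << np.arange(L - 1, -1, -1)).astype(np.int64)
    return groups @ weights


def _code_lengths(freqs: np.ndarray) -> np.ndarray:
    """Huffman code lengths from symbol frequencies; ties broken by
    insertion order (symbol value)."""
    lengths = np.zeros(freqs.size, dtype=np.int64)
    alive = [(int(f), i, (i,)) for i, f in enumerate(freqs) if f > 0]
    if not alive:
        return lengths
    if len(alive) == 1:
        lengths[alive[0][1]] = 1
        return lengths
    heapify(alive)
    counter = freqs.size
    while len(alive) > 1:
        f1, _, s1 = heappop(alive)
        f2, _, s2 = heappop(alive)
        for s in s1 + s2:
            lengths[s] += 1
        heappush(alive, (f1 + f2, counter, s1 + s2))
        counter += 1
    if lengths.max() > _MAX_CODE_LEN:
        raise ValidationError("Huffman code length exceeds serializable "
                              "maximum")
    return lengths


def _canonical_codes(lengths: np.ndarray) -> dict[int, tuple[int, int]]:
    """symbol -> (code, length), canonical order (length, symbol)."""
    order = sorted((int(l), s) for s, l in enumerate(lengths) if l > 0)
    codes = {}
    code = 0
    prev_len = 0
    for length, sym in order:
        code <<= (length - prev_len)
        codes[sym] = (code, length)
        code += 1
        prev_len = length
    return codes


def huffman_encode(bits, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (codebook_bits, encoded_bits).

    The codebook is 2^L code lengths, 5 bits each; the encoded stream is
    the concatenation of canonical codes of the L-bit symbols of the
    zero-padded input."""
    if L not in L_RANGE:
        raise ValidationError(f"L must be in [2, 8], got {L}")
    bits = as_bits(bits)
    symbols = _symbolize(bits, L)
    freqs = np.bincount(symbols, minlength=1 << L)
    lengths = _code_lengths(freqs)
    codes = _canonical_codes(lengths)
    codebook = np.concatenate([_int_to_bits(int(l), _LEN_BITS)
                               for l in lengths]) if lengths.size else \
        np.array([], dtype=np.uint8)
    if symbols.size == 0:
        return codebook, np.array([], dtype=np.uint8)
    total = int(sum(codes[int(s)][1] for s in symbols))
    out = np.empty(total, dtype=np.uint8)
    pos = 0
    for s in symbols:
        code, length = codes[int(s)]
        for i in range(length - 1, -1, -1):
            out[pos] = (code >> i) & 1
            pos += 1
    return codebook, out


def huffman_decode(codebook, encoded, L: int, n_bits: int) -> np.ndarray:
    """Exact inverse of :func:`huffman_encode` given the expected output
    bit count (which also determines how much zero padding to drop)."""
    if L not in L_RANGE:
        raise ValidationError(f"L must be in [2, 8], got {L}")
    cb = as_bits(codebook)
    if cb.size != (1 << L) * _LEN_BITS:
        raise CorruptStreamError("Huffman codebook has wrong size")
    lengths = np.array([_bits_to_int(cb[i * _LEN_BITS:(i + 1) * _LEN_BITS])
                        for i in range(1 << L)], dtype=np.int64)
    codes = _canonical_codes(lengths)
    decode_map = {(length, code): sym for sym, (code, length) in codes.items()}
    enc = as_bits(encoded)
    n_symbols = -(-n_bits // L)
    out = np.empty(n_symbols * L, dtype=np.uint8)
    pos = 0
    code = 0
    length = 0
    produced = 0
    for b in enc:
        code = (code << 1) | int(b)
        length += 1
        if length > _MAX_CODE_LEN:
            raise CorruptStreamError("invalid Huffman code path")
        sym = decode_map.get((length, code))
        if sym is None:
            continue
        for i in range(L - 1, -1, -1):
            out[pos] = (sym >> i) & 1
            pos += 1
        code = 0
        length = 0
        produced += 1
        if produced == n_symbols:
            break
    if produced < n_symbols:
        raise CorruptStreamError(
            "Huffman stream exhausted before expected length recovered")
    return out[:n_bits]


# ---------------------------------------------------------------------------
# Unified codec front end

def compressed_size(bits, codec: str, value: int) -> int:
    """Size in bits of the compressed representation (codebook included
    for Huffman) without materialising the stream where avoidable."""
    bits = as_bits(bits)
    if codec == "rle":
        return int(rle_encode(bits, value).size)
    symbols = _symbolize(bits, value)
    freqs = np.bincount(symbols, minlength=1 << value)
    lengths = _code_lengths(freqs)
    return int((1 << value) * _LEN_BITS + (freqs * lengths).sum())


def choose_adaptive_param(bits, codec: str) -> int:
    """Parameter in the codec's range minimising compressed size; ties
    break toward the smaller parameter."""
    bits = as_bits(bits)
    if bits.size == 0:
        raise ValidationError("cannot tune a codec on an empty plane")
    rng = B_RANGE if codec == "rle" else L_RANGE
    best, best_c = None, None
    for v in rng:
        c = compressed_size(bits, codec, v)
        if best_c is None or c < best_c:
            best, best_c = v, c
    return best


def compress(bits, codec: str, value: int) -> np.ndarray:
    if codec == "rle":
        return rle_encode(bits, value)
    codebook, enc = huffman_encode(bits, value)
    return np.concatenate([codebook, enc])


def decompress(stream, codec: str, value: int, n_bits: int) -> np.ndarray:
    stream = as_bits(stream)
    if codec == "rle":
        return rle_decode(stream, value, n_bits)
    cb_size = (1 << value) * _LEN_BITS
    if stream.size < cb_size:
        raise CorruptStreamError("stream shorter than Huffman codebook")
    return huffman_decode(stream[:cb_size], stream[cb_size:], value, n_bits)


def _resolve_param(bits, params: CodecParams,
                   plane_for_formula: int | None) -> int:
    if params.adaptive:
        return choose_adaptive_param(bits, params.codec)
    if params.value is not None:
        return params.value
    if plane_for_formula is None:
        raise ValidationError("need an explicit B/L or adaptive search "
                              "when no bit plane drives the empirical rule")
    b, l = empirical_params(plane_for_formula)
    return b if params.codec == "rle" else l


# ---------------------------------------------------------------------------
# In-band headers.  LCB:  codec(3) | param(4) | comp_len(24) | pay_len(24)
# | crc32(32) = 87 bits.  LCBP adds a 5-bit error width m after param.

_LCB_HEADER_BITS = 3 + 4 + 24 + 24 + 32
_LCBP_HEADER_BITS = _LCB_HEADER_BITS + 5


def _crc_bits(bits: np.ndarray) -> int:
    return zlib.crc32(bits_to_bytes(bits)) & 0xFFFFFFFF


def _build_header(codec: str, value: int, comp_len: int, pay_len: int,
                  crc: int, m: int | None = None) -> np.ndarray:
    parts = [_int_to_bits(_CODEC_IDS[codec], 3), _int_to_bits(value, 4)]
    if m is not None:
        parts.append(_int_to_bits(m, 5))
    parts += [_int_to_bits(comp_len, 24), _int_to_bits(pay_len, 24),
              _int_to_bits(crc, 32)]
    return np.concatenate(parts)


def _parse_header(stream: np.ndarray, with_m: bool):
    need = _LCBP_HEADER_BITS if with_m else _LCB_HEADER_BITS
    if stream.size < need:
        raise CorruptStreamError("plane budget shorter than header")
    pos = 0
    codec_id = _bits_to_int(stream[pos:pos + 3]); pos += 3
    value = _bits_to_int(stream[pos:pos + 4]); pos += 4
    m = None
    if with_m:
        m = _bits_to_int(stream[pos:pos + 5]); pos += 5
    comp_len = _bits_to_int(stream[pos:pos + 24]); pos += 24
    pay_len = _bits_to_int(stream[pos:pos + 24]); pos += 24
    crc = _bits_to_int(stream[pos:pos + 32]); pos += 32
    if codec_id not in _CODEC_NAMES:
        raise CorruptStreamError("unknown codec id in header")
    return _CODEC_NAMES[codec_id], value, m, comp_len, pay_len, crc, pos


# ---------------------------------------------------------------------------
# Plain LCB over signal bit planes

def _read_planes(lead, planes) -> np.ndarray:
    return np.concatenate([get_bit_plane(lead, p) for p in planes])


def _write_planes(lead, planes, bits: np.ndarray):
    n = len(lead)
    out = lead
    for i, p in enumerate(planes):
        out = set_bit_plane(out, p, bits[i * n:(i + 1) * n])
    return out


def lcb_embed(record: ECGRecord, payload, planes,
              params: CodecParams = CodecParams(adaptive=True),
              leads: list[str] | None = None,
              metrics: MetricsConfig = MetricsConfig()) -> EmbedResult:
    """Compress the selected planes of each lead and embed the framed
    payload in the freed space.

    ``planes`` is an ascending list of 1-based plane indices (a "bpX"
    preset uses planes (X, X+1)).  The payload is split across leads in
    record order; what does not fit raises insufficient capacity."""
    planes = sorted(int(p) for p in planes)
    if not planes:
        raise ValidationError("plane selection must be non-empty")
    lead_names = list(leads) if leads is not None else record.lead_names
    framed = frame_payload(as_bits(payload))
    out = record
    remaining = framed
    capacity_total = 0
    info = {"method": "lcb", "planes": ",".join(map(str, planes)),
            "codec": params.codec, "adaptive": str(int(params.adaptive)),
            "leads": ",".join(lead_names)}
    for name in lead_names:
        ld = record.lead(name)
        n = len(ld)
        budget = len(planes) * n
        plane_bits = _read_planes(ld, planes)
        value = _resolve_param(plane_bits, params, planes[0])
        stream = compress(plane_bits, params.codec, value)
        spare = budget - _LCB_HEADER_BITS - int(stream.size)
        if spare < 0:
            raise InsufficientCapacityError(
                f"lead {name}: compressed planes ({stream.size} bits) plus "
                f"header exceed the {budget}-bit plane budget",
                required=_LCB_HEADER_BITS + int(stream.size),
                available=budget)
        chunk = remaining[:spare]
        remaining = remaining[spare:]
        capacity_total += spare
        header = _build_header(params.codec, value, int(stream.size),
                               int(chunk.size), _crc_bits(stream))
        body = np.concatenate([header, stream, chunk])
        padded = np.zeros(budget, dtype=np.uint8)
        padded[:body.size] = body
        out = out.with_lead(name, _write_planes(ld, planes, padded).samples)
    if remaining.size:
        raise InsufficientCapacityError(
            f"payload needs {framed.size} bits but only {capacity_total} "
            f"fit in the selected planes",
            required=framed.size, available=capacity_total)
    return EmbedResult(
        record=out, side_info=info,
        bps=bps_metric(capacity_total, record.n_samples * len(lead_names)),
        payload_bits=int(as_bits(payload).size),
        psnr_mean=record_psnr(record.subset(lead_names),
                              out.subset(lead_names), metrics),
        psnr_per_lead={nm: psnr(record.lead(nm), out.lead(nm), metrics)
                       for nm in lead_names})


def lcb_extract(record: ECGRecord, side_info: dict[str, str] | None = None,
                planes=None, leads: list[str] | None = None):
    """Decompress the plane payload of each lead, restore the planes and
    return ``(payload_bits, restored_record)``."""
    side_info = side_info or {}
    if planes is None:
        planes = [int(p) for p in side_info["planes"].split(",")]
    planes = sorted(int(p) for p in planes)
    if leads is not None:
        lead_names = list(leads)
    elif side_info.get("leads"):
        lead_names = side_info["leads"].split(",")
    else:
        lead_names = record.lead_names
    restored = record
    chunks = []
    for name in lead_names:
        ld = record.lead(name)
        n = len(ld)
        stream = _read_planes(ld, planes)
        codec, value, _, comp_len, pay_len, crc, pos = \
            _parse_header(stream, with_m=False)
        if pos + comp_len + pay_len > stream.size:
            raise CorruptStreamError("header lengths exceed plane budget")
        comp = stream[pos:pos + comp_len]
        if _crc_bits(comp) != crc:
            raise CorruptStreamError("compressed stream checksum mismatch")
        plane_bits = decompress(comp, codec, value, len(planes) * n)
        if np.any(stream[pos + comp_len + pay_len:]):
            raise TamperError("watermark test failed: nonzero padding in "
                              f"the planes of lead {name}")
        chunks.append(stream[pos + comp_len:pos + comp_len + pay_len])
        restored = restored.with_lead(
            name, _write_planes(ld, planes, plane_bits).samples)
    payload = deframe_payload(np.concatenate(chunks))
    return payload, restored


# ---------------------------------------------------------------------------
# LCBP: compressed prediction errors in the low planes of one lead

def _zigzag(e: np.ndarray) -> np.ndarray:
    return np.where(e >= 0, 2 * e, -2 * e - 1).astype(np.int64)


def _unzigzag(z: np.ndarray) -> np.ndarray:
    return np.where(z % 2 == 0, z // 2, -(z + 1) // 2).astype(np.int64)


def _serialize_errors(e: np.ndarray) -> tuple[np.ndarray, int]:
    z = _zigzag(e)
    m = max(1, int(z.max()).bit_length()) if z.size else 1
    shifts = np.arange(m - 1, -1, -1)
    bits = ((z[:, None] >> shifts) & 1).astype(np.uint8)
    return bits.ravel(), m


def _deserialize_errors(bits: np.ndarray, m: int, n: int) -> np.ndarray:
    if bits.size != n * m:
        raise CorruptStreamError("error stream has wrong length")
    groups = bits.reshape(n, m).astype(np.int64)
    weights = (1 << np.arange(m - 1, -1, -1)).astype(np.int64)
    return _unzigzag(groups @ weights)


def lcbp_embed(record: ECGRecord, payload, target_lead: str,
               predictor: PredictionModel, ps: int = 2,
               params: CodecParams = CodecParams(adaptive=True),
               metrics: MetricsConfig = MetricsConfig()) -> EmbedResult:
    """Compress the target lead's prediction errors into its ``ps`` least
    significant planes together with the framed payload.

    The predictor must not read the target lead; an unfitted regression
    model is fit on the record first and its coefficients stored in side
    information."""
    if ps < 1 or ps > 16:
        raise ValidationError("ps must be in 1..16")
    ld = record.lead(target_lead)
    n = len(ld)
    if predictor.kind == "interlead_regression" and not predictor.coefficients:
        p_leads = predictor.predictor_leads or tuple(
            nm for nm in record.lead_names if nm != target_lead)
        predictor = fit_interlead_regression(record, target_lead, p_leads)
    if predictor.kind != "neighbor" and predictor.target_lead != target_lead:
        predictor = PredictionModel(kind=predictor.kind,
                                    target_lead=target_lead,
                                    predictor_leads=predictor.predictor_leads,
                                    coefficients=predictor.coefficients,
                                    variant=predictor.variant)
    x_hat = predict(predictor, record)
    e = ld.samples - x_hat
    err_bits, m = _serialize_errors(e)
    value = _resolve_param(err_bits, params, None)
    stream = compress(err_bits, params.codec, value)
    budget = ps * n
    framed = frame_payload(as_bits(payload))
    spare = budget - _LCBP_HEADER_BITS - int(stream.size)
    if spare < framed.size:
        raise InsufficientCapacityError(
            f"lead {target_lead}: need {framed.size} payload bits but only "
            f"{max(spare, 0)} remain after compressed errors "
            f"({stream.size} bits) in a {budget}-bit budget",
            required=framed.size, available=max(spare, 0))
    header = _build_header(params.codec, value, int(stream.size),
                           int(framed.size), _crc_bits(stream), m=m)
    body = np.concatenate([header, stream, framed])
    padded = np.zeros(budget, dtype=np.uint8)
    padded[:body.size] = body
    planes = list(range(1, ps + 1))
    out = record.with_lead(target_lead,
                           _write_planes(ld, planes, padded).samples)
    info = {"method": "lcbp", "target": target_lead, "ps": str(ps),
            "codec": params.codec, "adaptive": str(int(params.adaptive)),
            "orig.crc32": str(zlib.crc32(
                ld.samples.astype("<i8").tobytes()) & 0xFFFFFFFF)}
    info.update(model_to_side_info(predictor, prefix="model"))
    return EmbedResult(
        record=out, side_info=info,
        bps=bps_metric(spare, n),
        payload_bits=int(as_bits(payload).size),
        psnr_mean=psnr(ld, out.lead(target_lead), metrics),
        psnr_per_lead={target_lead: psnr(ld, out.lead(target_lead), metrics)})


def lcbp_extract(record: ECGRecord, side_info: dict[str, str],
                 target_lead: str | None = None, ps: int | None = None):
    """Recompute the prediction, decode the stored errors and payload,
    and restore the target lead exactly.

    Requires the predictor leads to be unmodified; any tampering surfaces
    as a checksum or stream error."""
    target_lead = target_lead or side_info["target"]
    ps = int(ps or side_info["ps"])
    model = model_from_side_info(side_info, prefix="model")
    ld = record.lead(target_lead)
    n = len(ld)
    stream = _read_planes(ld, list(range(1, ps + 1)))
    codec, value, m, comp_len, pay_len, crc, pos = \
        _parse_header(stream, with_m=True)
    if pos + comp_len + pay_len > stream.size:
        raise CorruptStreamError("header lengths exceed plane budget")
    comp = stream[pos:pos + comp_len]
    if _crc_bits(comp) != crc:
        raise CorruptStreamError("compressed stream checksum mismatch")
    err_bits = decompress(comp, codec, value, n * m)
    e = _deserialize_errors(err_bits, m, n)
    x_hat = predict(model, record)
    original = x_hat + e
    lo, hi = ld.valid_range
    if original.min() < lo or original.max() > hi:
        raise CorruptStreamError("restored samples leave the valid range; "
                                 "record or predictor leads were modified")
    # the watermarked target keeps the original's planes above ps; any
    # inconsistency there means the record or a predictor lead changed
    recv_high = (ld.samples & 0xFFFF) >> ps
    orig_high = (original & 0xFFFF) >> ps
    if not np.array_equal(recv_high, orig_high):
        raise TamperError("watermark test failed: restored signal "
                          "disagrees with the untouched bit planes")
    if "orig.crc32" in side_info:
        crc_orig = zlib.crc32(original.astype("<i8").tobytes()) & 0xFFFFFFFF
        if crc_orig != int(side_info["orig.crc32"]):
            raise TamperError("watermark test failed: restored-signal "
                              "checksum mismatch")
    if np.any(stream[pos + comp_len + pay_len:]):
        raise TamperError("watermark test failed: nonzero padding in the "
                          "embedded planes")
    restored = record.with_lead(target_lead, original)
    payload = deframe_payload(stream[pos + comp_len:pos + comp_len + pay_len])
    return payload, restored
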