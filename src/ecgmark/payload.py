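"""Watermark payload framing.

Every embedding method carries the user payload inside a common frame:

    [32-bit big-endian length] [payload bits] [32-bit CRC-32]

The CRC is computed over the payload bits packed MSB-first into bytes
(zero-padded to a whole byte).  Extraction that cannot produce a frame
whose length field fits the recovered bit budget, or whose CRC does not
match, is a watermark-test failure (tamper signal), never silent output.
"""

from __future__ import annotations

import zlib

import numpy as np

from .errors import TamperError, ValidationError

FRAME_OVERHEAD_BITS = 64  # 32-bit length + 32-bit CRC


def as_bits(bits) -> np.ndarray:
    """Normalise a bit-sequence argument (list/str/bytes/array) to uint8."""
    if isinstance(bits, (bytes, bytearray)):
        return np.unpackbits(np.frombuffer(bytes(bits), dtype=np.uint8))
    if isinstance(bits, str):
        bits = [int(c) for c in bits]
    arr = np.asarray(bits, dtype=np.uint8).ravel()
    if arr.size and arr.max() > 1:
        raise ValidationError("bit sequence may only contain 0 and 1")
    return arr


def bits_to_bytes(bits: np.ndarray) -> bytes:
    return np.packbits(as_bits(bits)).tobytes()


def _int_to_bits(value: int, width: int) -> np.ndarray:
    return np.array([(value >> (width - 1 - i)) & 1 for i in range(width)],
                    dtype=np.uint8)


def _bits_to_int(bits: np.ndarray) -> int:
    out = 0
    for b in bits:
        out = (out << 1) | int(b)
    return out


def crc32_of_bits(bits: np.ndarray) -> int:
    return zlib.crc32(bits_to_bytes(bits)) & 0xFFFFFFFF


def frame_payload(payload_bits) -> np.ndarray:
    """Wrap payload bits with the 32-bit length header and CRC-32 trailer."""
    payload = as_bits(payload_bits)
    if payload.size >= 1 << 32:
        raise ValidationError("payload too long for 32-bit length field")
    return np.concatenate([
        _int_to_bits(payload.size, 32),
        payload,
        _int_to_bits(crc32_of_bits(payload), 32),
    ])


def deframe_payload(stream_bits, check_padding: bool = True) -> np.ndarray:
    """Parse a frame from the head of ``stream_bits``.

    With ``check_padding`` (the default) any nonzero bit after the frame
    is treated as tampering: embedders fill the unused capacity with
    zero bits, so the whole embedded stream is covered either by the CRC
    or by the all-zero padding invariant.  Raises :class:`TamperError`
    on any inconsistency."""
    stream = as_bits(stream_bits)
    if stream.size < FRAME_OVERHEAD_BITS:
        raise TamperError("watermark test failed: stream shorter than frame "
                          "overhead")
    length = _bits_to_int(stream[:32])
    if 32 + length + 32 > stream.size:
        raise TamperError("watermark test failed: length header exceeds "
                          "extracted bits")
    payload = stream[32:32 + length]
    crc = _bits_to_int(stream[32 + length:32 + length + 32])
    if crc != crc32_of_bits(payload):
        raise TamperError("watermark test failed: checksum mismatch")
    if check_padding and np.any(stream[32 + length + 32:]):
        raise TamperError("watermark test failed: nonzero padding after "
                          "the payload frame")
    return payload
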