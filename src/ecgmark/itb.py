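"""Integer transform-based (ITB) difference expansion.

A block of n samples is mapped to a same-parity sequence

    y_i = 2·x_i − ⌊mean(x)⌋,

inverted exactly by x_i = ⌊(n·y_i + Σ_j y_j) / (2n)⌋.  Watermark bits
modulate the parity of y_2..y_n; y_1 keeps the block's original parity
so extraction can read each bit as (y_i^w − p) mod 2 with p = y_1 mod 2.

The method has no tunable embedding parameter; the block length n
(default 2, the value that minimises |x_i − mean| distortion on smooth
signals) is a container choice recorded in side information.  Blocks
whose transformed or modulated values would leave the 16-bit range are
skipped, left untouched, and recorded in a per-lead skip bitmap.
"""

from __future__ import annotations

import numpy as np

from .embed_result import EmbedResult, bitmap_to_text, text_to_bitmap
from .errors import InsufficientCapacityError, ValidationError
from .payload import as_bits, deframe_payload, frame_payload
from .signal_model import ECGRecord, MetricsConfig, bps as bps_metric, \
    psnr, record_psnr


def itb_transform(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    if x.size < 1:
        raise ValidationError("block must be non-empty")
    m = int(np.floor(np.mean(x)))
    return 2 * x - m


def itb_inverse(y) -> np.ndarray:
    y = np.asarray(y, dtype=np.int64)
    if y.size < 1:
        raise ValidationError("block must be non-empty")
    if np.unique(y % 2).size > 1:
        raise ValidationError("mixed parity: block still carries watermark "
                              "bits or was modified")
    n = y.size
    return (n * y + y.sum()) // (2 * n)


def itb_embed_block(y, bits) -> np.ndarray:
    y = np.asarray(y, dtype=np.int64)
    bits = as_bits(bits)
    if bits.size != y.size - 1:
        raise ValidationError(
            f"block of {y.size} needs {y.size - 1} bits, got {bits.size}")
    out = y.copy()
    out[1:] += bits
    return out


def itb_extract_block(y_w) -> tuple[np.ndarray, np.ndarray]:
    y_w = np.asarray(y_w, dtype=np.int64)
    p = int(y_w[0] % 2)
    bits = ((y_w[1:] - p) % 2).astype(np.uint8)
    y = y_w.copy()
    y[1:] -= bits
    return bits, y


def _block_view(x: np.ndarray, n: int):
    n_blocks = x.size // n
    return x[: n_blocks * n].reshape(n_blocks, n), n_blocks


def itb_embed(record: ECGRecord, payload, n: int = 2,
              leads: list[str] | None = None,
              metrics: MetricsConfig = MetricsConfig()) -> EmbedResult:
    """Embed a framed payload into disjoint consecutive blocks of ``n``
    samples per lead; the trailing remainder of each lead is untouched."""
    if n < 2:
        raise ValidationError("block length must be >= 2")
    lead_names = list(leads) if leads is not None else record.lead_names
    framed = frame_payload(as_bits(payload))

    per_lead = {}
    capacity = 0
    for name in lead_names:
        ld = record.lead(name)
        lo, hi = ld.valid_range
        blocks, n_blocks = _block_view(ld.samples, n)
        means = np.floor(blocks.mean(axis=1)).astype(np.int64)
        y = 2 * blocks - means[:, None]
        # worst case per element: y_i (bit 0) and y_i + 1 (bit 1, i > 1)
        ok = (y.min(axis=1) >= lo) & (y.max(axis=1) + 1 <= hi)
        per_lead[name] = (y, ok, n_blocks)
        capacity += int(ok.sum()) * (n - 1)
    if framed.size > capacity:
        raise InsufficientCapacityError(
            f"payload needs {framed.size} bits but only {capacity} are "
            f"available", required=framed.size, available=capacity)

    stream = np.zeros(capacity, dtype=np.uint8)
    stream[:framed.size] = framed
    out = record
    pos = 0
    info = {"method": "itb", "n": str(n), "leads": ",".join(lead_names)}
    for name in lead_names:
        y, ok, n_blocks = per_lead[name]
        n_ok = int(ok.sum())
        bits = stream[pos:pos + n_ok * (n - 1)].reshape(n_ok, n - 1)
        pos += n_ok * (n - 1)
        y_w = y[ok].copy()
        y_w[:, 1:] += bits
        new = record.lead(name).samples.copy()
        view, _ = _block_view(new, n)
        view[ok] = y_w
        out = out.with_lead(name, new)
        info[f"skip.{name}"] = bitmap_to_text((~ok).astype(np.uint8))

    total = record.n_samples * len(lead_names)
    return EmbedResult(
        record=out, side_info=info,
        bps=bps_metric(capacity, total),
        payload_bits=int(as_bits(payload).size),
        psnr_mean=record_psnr(record.subset(lead_names),
                              out.subset(lead_names), metrics),
        psnr_per_lead={nm: psnr(record.lead(nm), out.lead(nm), metrics)
                       for nm in lead_names})


def itb_extract(record: ECGRecord, side_info: dict[str, str],
                n: int | None = None, leads: list[str] | None = None):
    """Extract payload and restore the record bit-exactly.

    Returns ``(payload_bits, restored_record)``; raises
    :class:`~ecgmark.errors.TamperError` via the frame checksum when the
    watermarked record was modified.
    """
    n = int(side_info.get("n", n or 2))
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
        y_all, n_blocks = _block_view(ld.samples, n)
        skip = text_to_bitmap(side_info[f"skip.{name}"], n_blocks)
        ok = skip == 0
        y_w = y_all[ok]
        p = (y_w[:, :1] % 2)
        bits = ((y_w[:, 1:] - p) % 2).astype(np.uint8)
        y = y_w.copy()
        y[:, 1:] -= bits
        x = (n * y + y.sum(axis=1, keepdims=True)) // (2 * n)
        new = ld.samples.copy()
        view, _ = _block_view(new, n)
        view[ok] = x
        restored = restored.with_lead(name, new)
        chunks.append(bits.ravel())
    stream = np.concatenate(chunks) if chunks else np.array([], dtype=np.uint8)
    payload = deframe_payload(stream)
    return payload, restored
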