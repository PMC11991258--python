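"""Reversible contrast mapping (RCM) difference expansion.

RCM embeds an s-bit symbol into each non-overlapping pair of consecutive
samples.  With k = 2^s − 1, the pair transform

    y1 = (k+1)·x1 − k·x2,      y2 = (k+1)·x2 − k·x1

always leaves y1 − y2 divisible by 2k+1, so the remainder of the
watermarked difference modulo 2k+1 carries the symbol w ∈ [1, 2k]:

    y1w = y1 + w            (w ≤ k)
    y1w = y1 + w − (2k+1)   (w > k)

Remainder 0 is reserved as the skip marker: a pair whose transform or
embedding would leave the 16-bit range is replaced by (y1', x2) where y1'
is the nearest integer to x1 with (y1' − x2) ≡ 0 (mod 2k+1).  Skipped
pairs restore x2 exactly and x1 with absolute error at most 2k — RCM is
the only method here that is not perfectly reversible on such pairs.

The second embedding branch uses the offset −(2k+1) rather than −2k:
with −2k the symbol w = 2k would produce remainder 0 and masquerade as a
skip marker, breaking the remainder partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embed_result import EmbedResult
from .errors import (
    InsufficientCapacityError,
    UnembeddablePairError,
    ValidationError,
)
from .payload import as_bits, deframe_payload, frame_payload
from .signal_model import ECGRecord, MetricsConfig, bps as bps_metric, \
    psnr, record_psnr


@dataclass(frozen=True)
class RcmParams:
    """s = bits per pair; k = 2^s − 1 is derived."""

    s: int = 1

    def __post_init__(self):
        if self.s < 1:
            raise ValidationError("s must be >= 1")

    @property
    def k(self) -> int:
        return 2 ** self.s - 1

    @property
    def modulus(self) -> int:
        return 2 * self.k + 1


def rcm_transform_pair(x1: int, x2: int, params: RcmParams) -> tuple[int, int]:
    k = params.k
    return (k + 1) * x1 - k * x2, (k + 1) * x2 - k * x1


def rcm_embed_pair(y1: int, y2: int, w: int, params: RcmParams) -> int:
    k, m = params.k, params.modulus
    if not 1 <= w <= 2 * k:
        raise ValidationError(f"symbol w must be in [1, {2 * k}], got {w}")
    if (y1 - y2) % m != 0:
        raise ValidationError("pair is not in transformed (divisible) state")
    return y1 + w if w <= k else y1 + w - m


def rcm_skip_adjust(x1: int, x2: int, params: RcmParams,
                    valid_range: tuple[int, int]) -> tuple[int, int]:
    """Replace (x1, x2) by the nearest pair satisfying the skip condition
    (y1 − y2) ≡ 0 (mod 2k+1) with y2 = x2, staying inside ``valid_range``.

    Ties (x1 equidistant from two valid values) break toward the smaller
    value; the adjustment error never exceeds k in the unconstrained case
    and 2k when the range forces the second-nearest choice.
    """
    m = params.modulus
    lo, hi = valid_range
    r = (x1 - x2) % m
    candidates = sorted({x1 - r, x1 - r + m} | ({x1 - r - m} if r == 0 else set()),
                        key=lambda c: (abs(c - x1), c))
    for c in candidates:
        if lo <= c <= hi:
            return c, x2
    raise UnembeddablePairError(
        f"no in-range skip value for pair ({x1}, {x2}) with modulus {m}")


def rcm_extract_pair(y1w: int, y2: int, params: RcmParams):
    """Return (w, x1, x2); w is None for a skipped pair, in which case x1
    is the stored (approximate) value."""
    k, m = params.k, params.modulus
    r = (y1w - y2) % m
    if r == 0:
        return None, y1w, y2
    w = r
    y1 = y1w - w if w <= k else y1w - w + m
    x1 = ((k + 1) * y1 + k * y2) // m
    x2 = (k * y1 + (k + 1) * y2) // m
    return w, x1, x2


def _pair_embeddable(y1: np.ndarray, y2: np.ndarray, k: int,
                     lo: int, hi: int) -> np.ndarray:
    """A pair takes any symbol iff y2 and the whole reachable band
    [y1 − k, y1 + k] stay in range (symbol-independent, so capacity is
    known before the payload is assigned)."""
    return (y2 >= lo) & (y2 <= hi) & (y1 - k >= lo) & (y1 + k <= hi)


def _symbols_from_bits(bits: np.ndarray, s: int, n_symbols: int) -> np.ndarray:
    """Pack framed bits into s-bit symbol values w = value + 1, padding
    with w = 1 (value 0) so every embeddable pair carries a symbol."""
    padded = np.zeros(n_symbols * s, dtype=np.uint8)
    padded[:bits.size] = bits
    groups = padded.reshape(n_symbols, s)
    weights = (1 << np.arange(s - 1, -1, -1)).astype(np.int64)
    return groups @ weights + 1


def rcm_embed(record: ECGRecord, payload, params: RcmParams = RcmParams(),
              leads: list[str] | None = None,
              metrics: MetricsConfig = MetricsConfig()) -> EmbedResult:
    """Embed a framed payload across consecutive sample pairs of ``leads``
    (default: all leads, in record order)."""
    lead_names = list(leads) if leads is not None else record.lead_names
    payload_bits = as_bits(payload)
    framed = frame_payload(payload_bits)
    s, k, m = params.s, params.k, params.modulus

    # capacity: embeddable pairs over all selected leads
    pair_info = {}
    capacity_pairs = 0
    for name in lead_names:
        x = record.lead(name).samples
        lo, hi = record.lead(name).valid_range
        n_pairs = x.size // 2
        x1, x2 = x[0:2 * n_pairs:2], x[1:2 * n_pairs:2]
        y1 = (k + 1) * x1 - k * x2
        y2 = (k + 1) * x2 - k * x1
        ok = _pair_embeddable(y1, y2, k, lo, hi)
        pair_info[name] = (x1, x2, y1, y2, ok, lo, hi)
        capacity_pairs += int(ok.sum())
    capacity_bits = capacity_pairs * s
    if framed.size > capacity_bits:
        raise InsufficientCapacityError(
            f"payload needs {framed.size} bits but only {capacity_bits} "
            f"are available", required=framed.size, available=capacity_bits)

    symbols = _symbols_from_bits(framed, s, capacity_pairs)
    out = record
    sym_pos = 0
    raw_bits = 0
    for name in lead_names:
        x1, x2, y1, y2, ok, lo, hi = pair_info[name]
        n_pairs = x1.size
        new = record.lead(name).samples.copy()
        n_ok = int(ok.sum())
        w = symbols[sym_pos:sym_pos + n_ok]
        sym_pos += n_ok
        raw_bits += n_ok * s
        # embeddable pairs: transformed + symbol offset
        y1w_ok = y1[ok] + np.where(w <= k, w, w - m)
        new[0:2 * n_pairs:2][ok] = y1w_ok
        new[1:2 * n_pairs:2][ok] = y2[ok]
        # skip pairs: nearest congruent y1, y2 = x2
        for idx in np.flatnonzero(~ok):
            sy1, sy2 = rcm_skip_adjust(int(x1[idx]), int(x2[idx]), params,
                                       (lo, hi))
            new[2 * idx] = sy1
            new[2 * idx + 1] = sy2
        out = out.with_lead(name, new)

    per_lead = {nm: psnr(record.lead(nm), out.lead(nm), metrics)
                for nm in lead_names}
    total_samples = record.n_samples * len(lead_names)
    info = {
        "method": "rcm",
        "s": str(s),
        "leads": ",".join(lead_names),
    }
    return EmbedResult(record=out, side_info=info,
                       bps=bps_metric(raw_bits, total_samples),
                       payload_bits=int(payload_bits.size),
                       psnr_mean=record_psnr(record.subset(lead_names),
                                             out.subset(lead_names), metrics),
                       psnr_per_lead=per_lead)


def rcm_extract(record: ECGRecord, params: RcmParams = RcmParams(),
                leads: list[str] | None = None):
    """Extract the payload and restore the record.

    Returns ``(payload_bits, restored_record)``.  Non-skip pairs restore
    exactly; skipped pairs restore x2 exactly and x1 within ±2k.
    """
    lead_names = list(leads) if leads is not None else record.lead_names
    s, k, m = params.s, params.k, params.modulus
    restored = record
    symbols = []
    for name in lead_names:
        y = record.lead(name).samples
        n_pairs = y.size // 2
        y1w, y2 = y[0:2 * n_pairs:2].copy(), y[1:2 * n_pairs:2].copy()
        r = (y1w - y2) % m
        emb = r != 0
        w = r[emb]
        symbols.append(w)
        y1 = np.where(w <= k, y1w[emb] - w, y1w[emb] - w + m)
        x1 = ((k + 1) * y1 + k * y2[emb]) // m
        x2 = (k * y1 + (k + 1) * y2[emb]) // m
        new = y.copy()
        new[0:2 * n_pairs:2][emb] = x1
        new[1:2 * n_pairs:2][emb] = x2
        restored = restored.with_lead(name, new)
    w_all = np.concatenate(symbols) if symbols else np.array([], dtype=np.int64)
    values = w_all - 1
    bits = ((values[:, None] >> np.arange(s - 1, -1, -1)) & 1).astype(np.uint8)
    payload = deframe_payload(bits.ravel())
    return payload, restored
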