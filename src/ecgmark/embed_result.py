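"""Common result container and flat-text side-information serialization.

Side information is everything extraction needs beyond the watermarked
record itself: method parameters, lead subsets, skip/location maps and
predictor coefficients.  It travels as a flat ``key=value`` text file,
one entry per line; values never contain newlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .signal_model import ECGRecord


@dataclass
class EmbedResult:
    """Watermarked record plus the side information and achieved metrics."""

    record: ECGRecord
    side_info: dict[str, str]
    bps: float                      # raw embedded bits / host samples
    payload_bits: int               # user payload length (without framing)
    psnr_mean: float                # mean of per-lead PSNR vs original
    psnr_per_lead: dict[str, float] = field(default_factory=dict)


def dump_side_info(info: dict[str, str], path: str | Path) -> None:
    lines = []
    for key, value in info.items():
        value = str(value)
        if "\n" in value or "=" in key:
            raise ValidationError(f"side-info entry {key!r} not flat-text safe")
        lines.append(f"{key}={value}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_side_info(path: str | Path) -> dict[str, str]:
    info: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if "=" not in ln:
            raise ValidationError(f"malformed side-info line {ln!r}")
        key, value = ln.split("=", 1)
        info[key] = value
    return info


def bitmap_to_text(bits: np.ndarray) -> str:
    """Run-length text encoding of a 0/1 map: 'first;len,len,...'."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size == 0:
        return "0;"
    edges = np.flatnonzero(np.diff(bits)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [bits.size]])
    runs = ",".join(str(e - s) for s, e in zip(starts, ends))
    return f"{int(bits[0])};{runs}"


def text_to_bitmap(text: str, n: int) -> np.ndarray:
    try:
        first, runs = text.split(";", 1)
        value = int(first)
        out = np.empty(n, dtype=np.uint8)
        pos = 0
        if runs:
            for tok in runs.split(","):
                length = int(tok)
                out[pos:pos + length] = value
                pos += length
                value ^= 1
        if pos != n:
            raise ValueError("run lengths do not cover the map")
    except ValueError as exc:
        raise ValidationError(f"malformed bitmap text: {exc}") from exc
    return out
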