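"""Domain types for multi-lead integer ECG plus shared metrics.

Everything downstream (difference expansion, prediction-error expansion,
bit-plane compression) operates on raw digital units: signed integers as
stored in the file, one unit = 1 µV at the default resolution.  Physical
scaling (gain/baseline) is carried in metadata and never applied to the
embedding domain.

Bit planes are defined on the 16-bit two's-complement encoding of each
sample, plane 1 = least significant bit.  This makes plane operations
total and exactly reversible for negative samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import (
    FormatError,
    RangeError,
    UnsupportedFormatError,
    ValidationError,
)

INT16_MIN = -32768
INT16_MAX = 32767

#: Standard 12-lead order used throughout the package.
STANDARD_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
                  "V1", "V2", "V3", "V4", "V5", "V6")
LIMB_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF")
PRECORDIAL_LEADS = ("V1", "V2", "V3", "V4", "V5", "V6")


@dataclass(frozen=True)
class LeadSignal:
    """One ECG lead: a named, finite sequence of signed integer samples."""

    name: str
    samples: np.ndarray
    valid_range: tuple[int, int] = (INT16_MIN, INT16_MAX)

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=np.int64)
        if arr.ndim != 1 or arr.size == 0:
            raise ValidationError(f"lead {self.name!r}: samples must be a "
                                  "non-empty 1-D integer sequence")
        lo, hi = self.valid_range
        if arr.min() < lo or arr.max() > hi:
            raise RangeError(
                f"lead {self.name!r}: sample outside valid range [{lo}, {hi}]")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    def with_samples(self, samples: np.ndarray) -> "LeadSignal":
        return replace(self, samples=np.asarray(samples, dtype=np.int64))


@dataclass(frozen=True)
class ECGRecord:
    """An ordered collection of equally long leads plus sampling metadata."""

    leads: tuple[LeadSignal, ...]
    sampling_rate: float = 500.0
    resolution_mv: float = 0.001  # physical mV per digital unit

    def __post_init__(self):
        leads = tuple(self.leads)
        if not leads:
            raise ValidationError("record must contain at least one lead")
        n = len(leads[0])
        if any(len(ld) != n for ld in leads):
            raise ValidationError("all leads must have the same sample count")
        names = [ld.name for ld in leads]
        if len(set(names)) != len(names):
            raise ValidationError("lead names must be unique")
        object.__setattr__(self, "leads", leads)

    @property
    def n_samples(self) -> int:
        return len(self.leads[0])

    @property
    def lead_names(self) -> list[str]:
        return [ld.name for ld in self.leads]

    def lead(self, name: str) -> LeadSignal:
        for ld in self.leads:
            if ld.name == name:
                return ld
        raise ValidationError(f"no lead named {name!r} in record")

    def with_lead(self, name: str, samples: np.ndarray) -> "ECGRecord":
        """Return a copy with one lead's samples replaced."""
        new = tuple(ld.with_samples(samples) if ld.name == name else ld
                    for ld in self.leads)
        if all(a is b for a, b in zip(new, self.leads)):
            raise ValidationError(f"no lead named {name!r} in record")
        return replace(self, leads=new)

    def subset(self, names) -> "ECGRecord":
        return replace(self, leads=tuple(self.lead(n) for n in names))


@dataclass(frozen=True)
class MetricsConfig:
    """PSNR configuration.

    ``s_max`` is the supremum used as the peak value; the default 5223
    digital units is the peak amplitude range of the reference corpus.
    """

    s_max: int = 5223

    def __post_init__(self):
        if self.s_max <= 0:
            raise ValidationError("s_max must be positive")


# ---------------------------------------------------------------------------
# Bit planes

def _as_uint16(samples: np.ndarray) -> np.ndarray:
    return np.asarray(samples, dtype=np.int64) & 0xFFFF


def _from_uint16(enc: np.ndarray) -> np.ndarray:
    enc = enc.astype(np.int64)
    return np.where(enc >= 32768, enc - 65536, enc)


def _check_plane(p: int) -> int:
    p = int(p)
    if not 1 <= p <= 16:
        raise ValidationError(f"bit plane index must be in 1..16, got {p}")
    return p


def get_bit_plane(lead: LeadSignal, p: int) -> np.ndarray:
    """Bits of plane ``p`` (1-based, plane 1 = LSB) across all samples."""
    p = _check_plane(p)
    return ((_as_uint16(lead.samples) >> (p - 1)) & 1).astype(np.uint8)


def set_bit_plane(lead: LeadSignal, p: int, bits: np.ndarray) -> LeadSignal:
    """Overwrite plane ``p`` with ``bits``; all other planes unchanged."""
    p = _check_plane(p)
    bits = np.asarray(bits, dtype=np.int64)
    if bits.size != len(lead):
        raise ValidationError(
            f"plane bits length {bits.size} != sample count {len(lead)}")
    if bits.size and (bits.min() < 0 or bits.max() > 1):
        raise ValidationError("plane bits must be 0/1")
    enc = _as_uint16(lead.samples)
    mask = 1 << (p - 1)
    enc = (enc & ~mask) | (bits << (p - 1))
    return lead.with_samples(_from_uint16(enc))


# ---------------------------------------------------------------------------
# Metrics

def mse(original: np.ndarray, distorted: np.ndarray) -> float:
    a = np.asarray(original, dtype=np.float64)
    b = np.asarray(distorted, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError("signals must have equal length for MSE")
    return float(np.mean((a - b) ** 2))


def psnr(original, distorted, cfg: MetricsConfig = MetricsConfig()) -> float:
    """Peak signal-to-noise ratio, 10·log10(s_max² / MSE), in dB.

    Accepts a pair of LeadSignals, arrays, or ECGRecords.  For records the
    MSE is pooled over all leads (see :func:`record_psnr` for the
    mean-of-per-lead alternative used in benchmarks).  Identical signals
    return ``inf``.
    """
    if isinstance(original, ECGRecord):
        if not isinstance(distorted, ECGRecord) or \
                original.lead_names != distorted.lead_names:
            raise ValidationError("records must have matching leads")
        a = np.concatenate([ld.samples for ld in original.leads])
        b = np.concatenate([ld.samples for ld in distorted.leads])
    else:
        a = original.samples if isinstance(original, LeadSignal) else original
        b = distorted.samples if isinstance(distorted, LeadSignal) else distorted
    m = mse(a, b)
    if m == 0.0:
        return math.inf
    return 10.0 * math.log10(cfg.s_max ** 2 / m)


def record_psnr(original: ECGRecord, distorted: ECGRecord,
                cfg: MetricsConfig = MetricsConfig(),
                aggregate: str = "mean") -> float:
    """Per-lead PSNR aggregated across a record.

    ``aggregate='mean'`` (default, used in benchmarks) averages the
    per-lead PSNR values; ``'pooled'`` pools the MSE across leads first.
    Leads with zero distortion are excluded from the mean (their PSNR is
    infinite); if every lead is untouched the result is ``inf``.
    """
    if original.lead_names != distorted.lead_names:
        raise ValidationError("records must have matching leads")
    if aggregate == "pooled":
        return psnr(original, distorted, cfg)
    if aggregate != "mean":
        raise ValidationError("aggregate must be 'mean' or 'pooled'")
    vals = [psnr(a, b, cfg) for a, b in zip(original.leads, distorted.leads)]
    finite = [v for v in vals if math.isfinite(v)]
    return float(np.mean(finite)) if finite else math.inf


def bps(payload_bits: int, n_samples: int) -> float:
    """Bits per sample: payload length over host sample count."""
    if n_samples <= 0:
        raise ValidationError("n_samples must be positive")
    return payload_bits / n_samples


def saved_space(c: int, u: int) -> float:
    """Saved storage fraction 1 − C/U; negative when compression expands."""
    if u <= 0:
        raise ValidationError("uncompressed size must be positive")
    return 1.0 - c / u


# ---------------------------------------------------------------------------
# WFDB I/O (format 16: little-endian two's complement, one multi-signal
# record per directory).  Only the fields the embedding domain needs are
# interpreted; gain/baseline are preserved as opaque header text defaults.

def write_wfdb(record: ECGRecord, path: str | Path) -> None:
    """Write ``record`` as a WFDB format-16 record.

    ``path`` is the record path without extension; ``path.hea`` and
    ``path.dat`` are produced.  Samples must fit in 16 bits.
    """
    path = Path(path)
    name = path.name
    n_sig = len(record.leads)
    n_samp = record.n_samples
    mat = np.stack([ld.samples for ld in record.leads], axis=1)
    if mat.min() < INT16_MIN or mat.max() > INT16_MAX:
        raise RangeError("sample outside 16-bit range; cannot store as fmt 16")
    data = mat.astype("<i2")
    gain = 1.0 / record.resolution_mv  # ADC units per mV
    lines = [f"{name} {n_sig} {record.sampling_rate:g} {n_samp}"]
    for j, ld in enumerate(record.leads):
        init = int(data[0, j])
        # 16-bit signed checksum of the signal's samples
        s = int(np.sum(data[:, j], dtype=np.int64)) & 0xFFFF
        csum = s - 65536 if s >= 32768 else s
        lines.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 {init} {csum} 0 {ld.name}")
    path.parent.mkdir(parents=True, exist_ok=True)
    (path.parent / f"{name}.hea").write_text("\n".join(lines) + "\n")
    (path.parent / f"{name}.dat").write_bytes(data.tobytes())


def read_wfdb(path: str | Path) -> ECGRecord:
    """Read a WFDB format-16 record written by :func:`write_wfdb` or
    standard WFDB tooling (single multi-signal .dat file)."""
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing header file {hea}")
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"empty header file {hea}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed record line in {hea}: {lines[0]!r}")
    try:
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0])
        n_samp = int(head[3])
    except ValueError as exc:
        raise FormatError(f"malformed record line in {hea}") from exc
    if n_sig < 1 or len(lines) < 1 + n_sig:
        raise FormatError(f"header {hea} advertises {n_sig} signals but "
                          f"describes {len(lines) - 1}")
    names, dat_files, gains = [], [], []
    for j in range(n_sig):
        toks = lines[1 + j].split()
        if len(toks) < 2:
            raise FormatError(f"malformed signal line in {hea}")
        fmt = toks[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "16":
            raise UnsupportedFormatError(
                f"signal format {toks[1]!r} not supported (need 16)")
        dat_files.append(toks[0])
        gains.append(toks[2] if len(toks) > 2 else "200")
        names.append(" ".join(toks[8:]) if len(toks) > 8 else f"sig{j}")
    if len(set(dat_files)) != 1:
        raise UnsupportedFormatError("multi-.dat records are not supported")
    dat = path.parent / dat_files[0]
    if not dat.exists():
        raise FormatError(f"missing data file {dat}")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if raw.size < n_sig * n_samp:
        raise FormatError(
            f"data file {dat} truncated: expected {n_sig * n_samp} samples, "
            f"found {raw.size}")
    mat = raw[: n_sig * n_samp].reshape(n_samp, n_sig).astype(np.int64)
    try:
        gain_val = float(gains[0].split("(")[0].split("/")[0])
    except ValueError:
        gain_val = 200.0
    resolution = 1.0 / gain_val if gain_val else 0.001
    leads = tuple(LeadSignal(name=names[j], samples=mat[:, j])
                  for j in range(n_sig))
    return ECGRecord(leads=leads, sampling_rate=fs, resolution_mv=resolution)
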