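"""Deterministic synthetic 12-lead ECG generator.

The generator exists to give the watermarking methods inputs with the two
statistical properties they exploit on real ECGs:

* smoothness — adjacent samples differ by little relative to amplitude,
  so difference/prediction-error expansion stays low-distortion;
* inter-lead linear dependence — the derived limb leads are exact integer
  functions of leads I and II (Einthoven/Goldberger relations):

      III = II − I,   aVR = ⌊−(I+II)/2⌋,
      aVL = ⌊(2·I−II)/2⌋,   aVF = ⌊(2·II−I)/2⌋.

Each measured lead (I, II, V1..V6) is a sum of Gaussian bumps (P, Q, R,
S, T waves) repeated on a heart-rate-spaced beat grid, plus sinusoidal
baseline wander and white noise, quantised to integers.  The four derived
limb leads are then computed from the *integer* I and II, so with
``interlead_noise_sd = 0`` the relations above hold exactly at every
sample.  This is a waveform emulator, not a biophysical simulator: it has
no arrhythmias, no pathological morphologies and no electrode artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .signal_model import ECGRecord, LeadSignal, INT16_MIN, INT16_MAX


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings, all amplitudes in digital units (1 unit = 1 µV).

    Defaults emulate the reference corpus conditions: 12 leads, 500 Hz,
    10 s, mean peak-to-peak amplitude 1548 units.
    """

    seed: int = 0
    duration_s: float = 10.0
    fs: float = 500.0
    heart_rate_bpm: float = 72.0
    amplitude_units: float = 1548.0   # target peak-to-peak of lead II
    interlead_noise_sd: float = 0.0   # integer noise on derived limb leads
    baseline_wander_amp: float = 20.0
    white_noise_sd: float = 2.0

    def __post_init__(self):
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValidationError("fs and duration_s must be positive")
        if self.heart_rate_bpm <= 0:
            raise ValidationError("heart_rate_bpm must be positive")
        if min(self.interlead_noise_sd, self.baseline_wander_amp,
               self.white_noise_sd) < 0:
            raise ValidationError("noise parameters must be non-negative")


# (amplitude rel. to R, centre offset s, width s) for P, Q, R, S, T
_BUMPS = (
    (0.15, -0.180, 0.025),
    (-0.10, -0.035, 0.010),
    (1.00, 0.000, 0.014),
    (-0.22, 0.032, 0.011),
    (0.35, 0.250, 0.045),
)

# Per-lead scaling of the beat template relative to lead II.  V1/V2 are
# predominantly negative (rS morphology); the precordial progression
# V1→V6 mimics increasing R-wave amplitude.
_LEAD_SCALE = {
    "I": 0.60, "II": 1.00,
    "V1": -0.45, "V2": -0.25, "V3": 0.35, "V4": 0.80, "V5": 0.95, "V6": 0.75,
}

MEASURED_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")
DERIVED_LEADS = ("III", "aVR", "aVL", "aVF")


def derive_limb_leads(lead_i: np.ndarray, lead_ii: np.ndarray) -> dict:
    """Einthoven/Goldberger relations on integer leads; halves floored."""
    i = np.asarray(lead_i, dtype=np.int64)
    ii = np.asarray(lead_ii, dtype=np.int64)
    return {
        "III": ii - i,
        "aVR": (-(i + ii)) // 2,
        "aVL": (2 * i - ii) // 2,
        "aVF": (2 * ii - i) // 2,
    }


def _beat_train(t: np.ndarray, rr_s: float,
                amp_jitter: np.ndarray) -> np.ndarray:
    """Sum of Gaussian-bump beats centred every ``rr_s`` seconds."""
    out = np.zeros_like(t)
    n_beats = int(np.ceil(t[-1] / rr_s)) + 2
    for b in range(n_beats):
        centre = b * rr_s + 0.35 * rr_s
        for (amp, mu, sig), j in zip(_BUMPS, amp_jitter):
            out += amp * j * np.exp(-0.5 * ((t - centre - mu) / sig) ** 2)
    return out


def generate_record(cfg: SynthConfig = SynthConfig()) -> ECGRecord:
    """Generate one deterministic 12-lead integer ECG record."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    rr = 60.0 / cfg.heart_rate_bpm

    waves: dict[str, np.ndarray] = {}
    for name in MEASURED_LEADS:
        # small per-lead, per-bump amplitude variation; same beat grid
        amp_jitter = rng.uniform(0.85, 1.15, size=len(_BUMPS))
        waves[name] = _beat_train(t, rr, amp_jitter) * _LEAD_SCALE[name]

    # scale so lead II peak-to-peak hits amplitude_units, then add noise
    # in digital units and quantise
    ref = waves["II"]
    ptp = float(ref.max() - ref.min())
    scale = cfg.amplitude_units / ptp if ptp else 1.0
    measured: dict[str, np.ndarray] = {}
    for name in MEASURED_LEADS:
        wave = waves[name] * scale
        phase = rng.uniform(0, 2 * np.pi)
        wave = wave + cfg.baseline_wander_amp * \
            np.sin(2 * np.pi * 0.25 * t + phase)
        if cfg.white_noise_sd > 0:
            wave = wave + rng.normal(0.0, cfg.white_noise_sd, n)
        measured[name] = np.rint(wave).astype(np.int64)

    derived = derive_limb_leads(measured["I"], measured["II"])
    if cfg.interlead_noise_sd > 0:
        for name in DERIVED_LEADS:
            noise = np.rint(rng.normal(0.0, cfg.interlead_noise_sd, n))
            derived[name] = derived[name] + noise.astype(np.int64)

    order = ("I", "II", "III", "aVR", "aVL", "aVF",
             "V1", "V2", "V3", "V4", "V5", "V6")
    all_leads = {**measured, **derived}
    leads = tuple(
        LeadSignal(name=nm,
                   samples=np.clip(all_leads[nm], INT16_MIN, INT16_MAX))
        for nm in order)
    return ECGRecord(leads=leads, sampling_rate=cfg.fs)


def generate_corpus(n: int, base_seed: int = 0,
                    cfg: SynthConfig = SynthConfig()) -> list[ECGRecord]:
    """Generate ``n`` records with per-record jitter of heart rate and
    amplitude, seeds ``base_seed .. base_seed+n−1``.

    Jitter ranges (55–95 bpm, 1100–2100 units peak-to-peak) keep peak
    values within the 5223-unit supremum used for PSNR.
    """
    if n <= 0:
        raise ValidationError("corpus size must be positive")
    records = []
    for i in range(n):
        seed = base_seed + i
        jit = np.random.default_rng(seed)
        rec_cfg = SynthConfig(
            seed=seed,
            duration_s=cfg.duration_s,
            fs=cfg.fs,
            heart_rate_bpm=float(jit.uniform(55.0, 95.0)),
            amplitude_units=float(jit.uniform(1100.0, 2100.0)),
            interlead_noise_sd=cfg.interlead_noise_sd,
            baseline_wander_amp=cfg.baseline_wander_amp,
            white_noise_sd=cfg.white_noise_sd,
        )
        records.append(generate_record(rec_cfg))
    return records
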