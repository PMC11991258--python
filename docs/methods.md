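# Methods

`ecgmark` implements four families of reversible (lossless-restoration)
fragile watermarking for multi-lead integer ECG records, plus the
synthetic signal generator used to exercise them. This note documents the
models, the numerical conventions, and the design decisions taken where
the underlying algorithms leave choices open.

## Signal model

All embedding operates on raw digital units: each lead is a sequence of
signed integers (1 unit = 1 µV at the default resolution), stored as
16-bit two's complement in WFDB format-16 files. Bit planes are defined
on that 16-bit encoding, plane 1 = least significant bit; this makes
plane operations total and exactly reversible for negative samples,
which a sign-magnitude definition would not be. Physical scaling
(gain/baseline) is metadata only and is never touched.

Fidelity is measured as PSNR = 10·log₁₀(S²ₘₐₓ/MSE) with the default
supremum Sₘₐₓ = 5223 digital units (the peak amplitude range of the
reference corpus conditions). Identical signals report +∞ rather than an
error, since untouched leads occur routinely. Record-level PSNR defaults
to the mean of per-lead PSNR values, leads with zero distortion
excluded; a pooled-MSE aggregate is available (`record_psnr(...,
aggregate="pooled")`). Capacity is reported as bits per sample (BPS):
raw embedded bits over host samples of the processed leads.

## Payload framing and the watermark test

Every method carries the user payload in a common frame: a 32-bit
big-endian length, the payload bits, and a CRC-32 of the packed payload.
Capacity beyond the frame is filled with zero bits (RCM: the symbol
w = 1). Extraction fails the watermark test — a `TamperError`, surfaced
by the CLI as a `tampered` verdict — when the length field exceeds the
recovered bit budget, the CRC mismatches, or any padding bit is nonzero.
The zero-padding invariant extends fragility to modifications landing
after the frame. One genuine blind spot remains in RCM: a modification
that turns a padding pair into a skip pair (remainder 0) removes a zero
bit and is indistinguishable from one fewer embeddable pair; this is the
synchronization fragility inherent to the skip protocol.

## RCM difference expansion

Pairs of consecutive samples are transformed with k = 2ˢ − 1 as
y₁ = (k+1)x₁ − kx₂, y₂ = (k+1)x₂ − kx₁, leaving y₁ − y₂ divisible by
2k+1; the symbol w ∈ [1, 2k] is added so that (y₁ʷ − y₂) mod (2k+1) = w.
The second embedding branch subtracts 2k+1 (not 2k): with an offset of
−2k the symbol w = 2k would collide with the remainder-0 skip marker.
`mod` is the nonnegative remainder throughout.

A pair is embeddable only if y₂ and the whole reachable band
[y₁ − k, y₁ + k] stay in range; this makes capacity symbol-independent.
Unembeddable pairs keep x₂ and replace x₁ by the nearest congruent value
(ties toward the smaller value, second-nearest if the range forces it),
so skip-pair restoration error is ≤ k normally and ≤ 2k worst-case —
RCM is the only method here that is not perfectly reversible. An s-bit
group maps to w = value + 1, so 2ˢ ≤ 2k symbols are always available.

## ITB difference expansion

Blocks of n samples map to the same-parity sequence yᵢ = 2xᵢ − ⌊mean⌋,
inverted exactly by xᵢ = ⌊(n·yᵢ + Σyⱼ)/(2n)⌋. Bits modulate the parity
of y₂..yₙ; y₁ preserves the block parity p for extraction. Floors follow
mathematical floor (−4.5 → −5). The block length is not an embedding
parameter of the method itself; the default n = 2 minimises
|xᵢ − mean| distortion on smooth signals and matches
difference-expansion convention. Blocks that would overflow are skipped
untouched and recorded in a run-length-encoded per-lead bitmap in side
information (semi-blind extraction).

## Predictors

* **Neighbor averaging**, variants (l, r) ∈ {(1,0), (0,1), (2,0), (0,2),
  (1,1), (2,2)}: floor of the mean of l left and r right neighbours.
  Left neighbours are read from the already-watermarked signal, right
  neighbours from the original; extraction therefore runs right-to-left
  so each sample sees the identical context. Edge samples without a full
  neighbourhood are never embedded.
* **Inter-lead regression**: OLS of the target lead on N other leads
  plus an intercept (the intercept is implied by the 8·(N+1)-byte side
  information budget). Coefficients are serialized as little-endian
  64-bit floats — exactly 8·(N+1) bytes — hex-encoded in the side-info
  file. Rank-deficient designs (the derived limb leads are exact linear
  combinations of I and II) fall back to the minimum-norm pseudoinverse
  solution. Per-record fitting is the default; a corpus-level shared fit
  is provided for the lower-cost deployment option.
* **Physical limb-lead relations**: III = II − I, aVR = ⌊−(I+II)/2⌋,
  aVL = ⌊(2I−II)/2⌋, aVF = ⌊(2II−I)/2⌋. Only these four targets are
  supported; III is exact, halves are floored.

Predictions must be integers: regression rounds half-up
(⌊v + 0.5⌋), physical floors. Both conventions are fixed and recorded so
embedding and extraction agree.

## PEE

yʷ = x̂ + 2e + w with e = x − x̂; inversion uses the floored half of the
watermarked error (mathematical floor for negative e). Distortion per
sample is ≤ |e| + 1. Overflow handling: a sample is embeddable only if
both x̂ + 2e and x̂ + 2e + 1 are in range (bit-independent); skipped
samples stay unchanged and are recorded in a per-sample location map.

With inter-lead prediction only the target lead is modified. Multiple
target leads are handled as sequential independent passes in record
order; each pass fits its model on the record's current state (earlier
targets already watermarked) and stores its coefficients, and extraction
undoes passes in reverse order, which reproduces each pass's exact
predictor context without assuming anything about shared state.

## LCB and LCBP

LCB concatenates the selected bit planes of each lead (ascending plane,
sample order), compresses them, and writes
`[header | compressed stream | payload chunk | zero padding]` back into
the same planes. The in-band header is fixed-width: 3-bit codec id,
4-bit parameter (B or L), 24-bit compressed length, 24-bit payload
length, 32-bit CRC of the compressed stream; LCBP inserts a 5-bit error
width m after the parameter. The payload frame is split across leads in
record order. Per-sample distortion is bounded by 2^max(plane).

Codecs:

* **RLE** — 1 first-bit header, then alternating B-bit run lengths; runs
  above 2^B − 1 split via a zero-length run of the opposite bit. B ∈
  [2, 10].
* **Huffman** — L-bit symbols (input zero-padded to a multiple of L; the
  pad is derivable from the expected bit count at decode), canonical
  code from symbol frequencies, tree ties broken by symbol value, the
  codebook serialized as 2^L five-bit code lengths. A single distinct
  symbol receives a 1-bit code. L ∈ [2, 8].

Parameters come from the empirical rules B = P − 3, L = P − 2 (P the
compressed plane index, clamped into range), from explicit overrides, or
from exhaustive adaptive search (ties toward the smaller value). The
benchmark presets use Huffman with adaptive L. When several planes are
compressed together the empirical rule uses the lowest selected plane —
the quantity the preset is named by.

LCBP compresses the prediction error of one target lead instead of raw
planes: errors are zigzag-mapped to unsigned, serialized at the minimal
fixed width m (entropy removal is the codec's job; fixed width keeps the
decoder trivial), compressed and written into the ps least significant
planes of the target lead. The higher planes keep their original bits,
bounding distortion below 2^ps; restoration is original = prediction +
error at full precision. An alternative reading — replacing the signal
with the prediction and coded errors entirely — was rejected because it
loses the distortion bound. Extraction additionally verifies that the
received high planes agree with the reconstruction and that a CRC-32 of
the restored samples (carried in side information) matches, so modifying
a predictor lead or the target's untouched planes is flagged as
tampering rather than silently mis-restoring.

If the prediction is poor (e.g. a regression target with no linear
relation to the other leads), the compressed errors exceed the plane
budget and embedding fails with an insufficient-capacity error — the
expected failure mode for precordial targets.

## Synthetic generator

Each measured lead (I, II, V1–V6) is a sum of Gaussian bumps (P, Q, R,
S, T waves) on a heart-rate-spaced beat grid with per-lead amplitude
scaling (V1/V2 predominantly negative), plus sinusoidal baseline wander
(0.25 Hz) and white noise, quantized to integers. Defaults are the study
conditions: 12 leads, 500 Hz, 10 s, lead-II peak-to-peak 1548 digital
units, supremum 5223 for PSNR. The derived limb leads are computed from
the *integer* I and II with floored halves, so with
`interlead_noise_sd = 0` the limb-lead identities hold exactly at every
sample; optional integer noise on the derived leads breaks them
controllably. Defaults chosen where no value was prescribed:
72 bpm heart rate, baseline wander 20 units, white noise sd 2 units —
small realistic perturbations that do not disturb the smoothness or
dependence structure. Corpus generation jitters heart rate (55–95 bpm)
and amplitude (1100–2100 units) per seed, keeping peaks under the
5223-unit supremum.

What the generator does not emulate: arrhythmias and pathological
morphologies, electrode artefacts, muscle noise bursts, and — most
relevantly — independent sensor noise on leads I and II. Real recordings
carry noise in every electrode, which is why per-record regression beats
the hard-coded physical relations there (implicit noise filtration).
Here the physical predictor's error is exactly the target lead's own
noise, so regression converges to the same relation and the two are
near-equal rather than strictly ordered; tests assert near-equality (the
honest property under this noise model). Passing tests demonstrate
algorithmic correctness and the qualitative capacity/fidelity trends,
not performance on clinical data.

## Problem sizes

The reversibility suite runs all fifteen presets over a 100-record
corpus at full default conditions (12 × 5000 samples). Oracle
equivalence is checked exhaustively on the stated grids (RCM
[−64, 64]², s ≤ 3, all symbols; PEE [−50, 50]², both bits; ITB blocks of
2–3 in [−20, 20]). Trend checks use 6–10 records, enough for the mean
orderings they assert to be stable across seeds.

## Known limitations

* RCM skip pairs restore the first sample only to within 2k; all other
  methods are bit-exact.
* The RCM padding/skip ambiguity described above limits fragility for
  modifications that mimic skip pairs.
* LCBP supports one target lead per record-pass; multi-lead LCBP would
  need per-lead budgets and is not implemented.
* Huffman code lengths are capped at 31 (5-bit codebook entries); with
  ≤ 2⁸ symbols and desk-scale plane sizes this bound is never active.
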