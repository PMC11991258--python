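# ecgmark

Reversible, fragile watermarking for multi-lead digital ECG records.

Telemedicine systems move ECGs between machines and people, and a
recipient needs two guarantees: that the record was not modified in
transit, and that the diagnostically exact original samples can be
recovered. `ecgmark` provides both by embedding an arbitrary bit payload
directly into the integer samples of a WFDB record so that

* an unmodified record yields back the payload **and** the bit-exact
  original signal, and
* any modification of the watermarked samples makes the watermark test
  fail (a *tampered* verdict) instead of producing silent wrong output.

Four method families are implemented as a library plus CLI:

| family | idea | capacity | typical fidelity |
|---|---|---|---|
| **RCM** | pair transform y₁=(k+1)x₁−kx₂, y₂=(k+1)x₂−kx₁; the residue of y₁ʷ−y₂ mod 2k+1 carries an s-bit symbol | s/2 BPS, tunable | intermediate |
| **ITB** | block transform yᵢ=2xᵢ−⌊mean⌋ to a same-parity sequence; bits modulate parity | 0.5 BPS (n=2) | intermediate |
| **PEE** | prediction-error expansion yʷ=x̂+2e+w with neighbour, inter-lead-regression, or physical limb-lead predictors | 1 BPS | high (distortion ≤ \|e\|+1) |
| **LCB / LCBP** | losslessly compress bit planes (RLE or canonical Huffman) or prediction errors; embed in the freed space | depends on compressibility | low (LCB) / high (LCBP) |

The inter-lead predictors exploit the physical dependencies among the
limb leads (III = II − I, aVR = −(I+II)/2, aVL = (2I−II)/2,
aVF = (2II−I)/2); capacity and fidelity are evaluated as bits per sample
(BPS) and PSNR = 10·log₁₀(S²ₘₐₓ/MSE) with Sₘₐₓ = 5223 digital units.
Fifteen named presets (`rcm-bl1..4`, `itb`, `lcb-huff-bp6/7/8`,
`pee-neigh`, `pee-neighchan`, `pee-depchan`,
`lcbp-huff-{neighchan,depchan}-ps{2,4}`) cover the benchmark
configurations. See `docs/methods.md` for the full model and the design
decisions.

A deterministic synthetic 12-lead generator (500 Hz, 10 s, 1 µV
resolution, exact limb-lead dependencies, configurable noise) provides
test signals, so nothing needs to be downloaded.

## Worked example

```sh
$ ecgmark synth demo/rec --seed 7
wrote 12 leads x 5000 samples (seed=7) to demo/rec.hea/.dat

$ ecgmark embed demo/rec demo/wm --preset pee-depchan --payload-bits 128
embedded 128 payload bits (BPS 1.000, mean PSNR 92.05 dB)

$ ecgmark extract demo/wm --side-info demo/wm.side --restored-out demo/restored
verdict: intact; payload 128 bits
```

The embed step watermarks the four derived limb leads using the physical
predictor and writes `demo/wm.side` (side information: method
parameters, location maps, predictor coefficients) plus a JSON report:

```json
{
  "preset": "pee-depchan",
  "payload_bits": 128,
  "bps": 1.0,
  "psnr_mean_db": 92.05391130295712,
  "psnr_per_lead_db": {
    "III": 92.05391130295712,
    "aVR": Infinity,
    "aVL": Infinity,
    "aVF": Infinity
  },
  "s_max": 5223
}
```

BPS 1.0 means every embeddable sample carried a bit (payload plus zero
padding). On this record the physical prediction is exact, so the only
distortion is the payload bits themselves — 92 dB on lead III and no
change at all on leads whose bits were all zero padding. `demo/restored`
is bit-identical to `demo/rec`. Flipping any sample of `demo/wm.dat`
turns the verdict into `tampered` (exit code 2), e.g. via
`ecgmark verify demo/wm --side-info demo/wm.side`.

`ecgmark bench out.csv --n-records 10` embeds every preset over a
synthetic corpus and tabulates mean/σ BPS and PSNR separately for limb
and precordial lead groups.

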