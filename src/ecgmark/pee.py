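"""Prediction-error expansion (PEE) embedding and extraction.

One watermark bit per sample: with integer prediction x̂ and error
e = x − x̂,

    y_w = x̂ + 2e + w,

and extraction inverts it from the watermarked error e_w = y_w − x̂:

    w = e_w − 2⌊e_w/2⌋,    x = y_w − ⌊e_w/2⌋ − w.

Distortion per sample is |e + w| ≤ |e| + 1, so the whole method lives or
dies by prediction quality.

Neighbor predictors are sample-sequential: embedding runs left-to-right
(left neighbours already watermarked, right neighbours still original)
and extraction right-to-left so each sample sees the same context.
Inter-lead and physical predictors compute the whole prediction vector
from untouched other leads, so order does not matter and the arithmetic
is vectorised.

Samples whose watermarked value would leave the valid range are skipped
(left unchanged) and recorded in a per-lead location map carried in side
information.  Skip decisions are made from the worst case over both bit
values, so capacity is bit-independent and extraction needs only the map.
"""

from __future__ import annotations

import numpy as np

from .embed_result import EmbedResult, bitmap_to_text, text_to_bitmap
from .errors import InsufficientCapacityError, ValidationError
from .payload import as_bits, deframe_payload, frame_payload
from .predictors import (
    PredictionModel,
    fit_interlead_regression,
    model_from_side_info,
    model_to_side_info,
    predict,
)
from .signal_model import ECGRecord, MetricsConfig, bps as bps_metric, \
    psnr, record_psnr


def pee_embed_sample(x: int, x_hat: int, w: int) -> int:
    if w not in (0, 1):
        raise ValidationError("watermark bit must be 0 or 1")
    return x_hat + 2 * (x - x_hat) + w


def pee_extract_sample(y_w: int, x_hat: int) -> tuple[int, int]:
    e_w = y_w - x_hat
    half = e_w // 2  # mathematical floor for negative errors
    w = e_w - 2 * half
    x = y_w - half - w
    return w, x


def _neighbor_index_range(variant: tuple[int, int], n: int) -> range:
    l_n, r_n = variant
    return range(l_n, n - r_n)


def _neighbor_pass(samples: np.ndarray, variant: tuple[int, int],
                   lo: int, hi: int, bits: np.ndarray | None,
                   skip: np.ndarray | None):
    """One sequential pass.  With ``bits`` given: embed (left-to-right),
    return (watermarked, skip_map, n_embedded).  With ``skip`` given:
    extract (right-to-left), return (restored, bits_in_embed_order)."""
    l_n, r_n = variant
    y = samples.copy()
    idxs = _neighbor_index_range(variant, y.size)
    if bits is not None:
        skip_map = np.zeros(y.size, dtype=np.uint8)
        pos = 0
        for i in idxs:
            ctx = 0
            for off in range(1, l_n + 1):
                ctx += int(y[i - off])
            for off in range(1, r_n + 1):
                ctx += int(y[i + off])
            x_hat = ctx // (l_n + r_n)  # Python // floors negatives
            base = 2 * int(y[i]) - x_hat  # x̂ + 2e
            if base < lo or base + 1 > hi:
                skip_map[i] = 1
                continue
            y[i] = base + int(bits[pos])
            pos += 1
        return y, skip_map, pos
    # extraction
    out_bits = []
    for i in reversed(idxs):
        if skip[i]:
            continue
        ctx = 0
        for off in range(1, l_n + 1):
            ctx += int(y[i - off])        # still watermarked
        for off in range(1, r_n + 1):
            ctx += int(y[i + off])        # already restored = original
        x_hat = ctx // (l_n + r_n)
        e_w = int(y[i]) - x_hat
        half = e_w // 2
        w = e_w - 2 * half
        y[i] = int(y[i]) - half - w
        out_bits.append(w)
    out_bits.reverse()
    return y, np.array(out_bits, dtype=np.uint8)


def _vector_embed(x: np.ndarray, x_hat: np.ndarray, lo: int, hi: int,
                  bits: np.ndarray):
    """Vectorised embed for whole-lead predictors; returns
    (watermarked, skip_map, n_embedded)."""
    base = x_hat + 2 * (x - x_hat)
    ok = (base >= lo) & (base + 1 <= hi)
    n_ok = int(ok.sum())
    y = x.copy()
    y[ok] = base[ok] + bits[:n_ok]
    skip_map = (~ok).astype(np.uint8)
    return y, skip_map, n_ok


def _vector_extract(y: np.ndarray, x_hat: np.ndarray, skip: np.ndarray):
    ok = skip == 0
    e_w = y[ok] - x_hat[ok]
    half = np.floor_divide(e_w, 2)
    w = (e_w - 2 * half).astype(np.uint8)
    x = y.copy()
    x[ok] = y[ok] - half - w
    return x, w


def _resolve_targets(record: ECGRecord, predictor: PredictionModel,
                     leads) -> list[str]:
    if leads is not None:
        return list(leads)
    if predictor.kind == "physical":
        return [nm for nm in ("III", "aVR", "aVL", "aVF")
                if nm in record.lead_names]
    if predictor.kind == "interlead_regression" and predictor.target_lead:
        return [predictor.target_lead]
    return record.lead_names


def pee_embed(record: ECGRecord, payload,
              predictor: PredictionModel,
              leads: list[str] | None = None,
              metrics: MetricsConfig = MetricsConfig()) -> EmbedResult:
    """Embed a framed payload into ``leads`` (the target leads).

    * neighbor predictor: each lead is embedded independently,
      sequentially left-to-right.
    * inter-lead regression: one pass per target lead, in the given
      order; the model for each pass is fit on the record's current state
      and its coefficients stored in side information.
    * physical: targets restricted to III/aVR/aVL/aVF, predictions from
      the untouched leads I and II.
    """
    lead_names = _resolve_targets(record, predictor, leads)
    framed = frame_payload(as_bits(payload))
    stream_pos = 0
    out = record
    info = {"method": "pee", "leads": ",".join(lead_names)}
    total_embedded = 0
    original = record

    for pass_idx, name in enumerate(lead_names):
        ld = out.lead(name)
        lo, hi = ld.valid_range
        # remaining framed bits for this pass, padded with zeros
        remaining = framed[stream_pos:]
        if predictor.kind == "neighbor":
            n_cap = len(_neighbor_index_range(predictor.variant, len(ld)))
            bits = np.zeros(n_cap, dtype=np.uint8)
            bits[:remaining.size] = remaining[:n_cap]
            y, skip_map, n_emb = _neighbor_pass(
                ld.samples, predictor.variant, lo, hi, bits, None)
            model = PredictionModel(kind="neighbor", target_lead=name,
                                    variant=predictor.variant)
        else:
            if predictor.kind == "interlead_regression":
                p_leads = predictor.predictor_leads or tuple(
                    nm for nm in out.lead_names if nm != name)
                p_leads = tuple(nm for nm in p_leads if nm != name)
                model = fit_interlead_regression(out, name, p_leads)
            else:
                model = PredictionModel(kind="physical", target_lead=name)
            x_hat = predict(model, out)
            bits = np.zeros(len(ld), dtype=np.uint8)
            bits[:remaining.size] = remaining[:len(ld)]
            y, skip_map, n_emb = _vector_embed(ld.samples, x_hat, lo, hi, bits)
        out = out.with_lead(name, y)
        stream_pos = min(stream_pos + n_emb, framed.size)
        total_embedded += n_emb
        info[f"map.{name}"] = bitmap_to_text(skip_map)
        info.update(model_to_side_info(model, prefix=f"model.{name}"))
    consumed_all = stream_pos >= framed.size
    if not consumed_all:
        raise InsufficientCapacityError(
            f"payload needs {framed.size} bits but only {stream_pos} could "
            f"be embedded", required=framed.size, available=stream_pos)

    return EmbedResult(
        record=out, side_info=info,
        bps=bps_metric(total_embedded, record.n_samples * len(lead_names)),
        payload_bits=int(as_bits(payload).size),
        psnr_mean=record_psnr(original.subset(lead_names),
                              out.subset(lead_names), metrics),
        psnr_per_lead={nm: psnr(original.lead(nm), out.lead(nm), metrics)
                       for nm in lead_names})


def pee_extract(record: ECGRecord, side_info: dict[str, str],
                leads: list[str] | None = None):
    """Extract payload and restore the record bit-exactly.

    Passes are undone in reverse embedding order so inter-lead predictor
    contexts match; returns ``(payload_bits, restored_record)``.
    """
    if leads is not None:
        lead_names = list(leads)
    else:
        lead_names = side_info["leads"].split(",")
    restored = record
    chunks: list[np.ndarray] = []
    for name in reversed(lead_names):
        model = model_from_side_info(side_info, prefix=f"model.{name}")
        ld = restored.lead(name)
        skip = text_to_bitmap(side_info[f"map.{name}"], len(ld))
        if model.kind == "neighbor":
            x, bits = _neighbor_pass(ld.samples, model.variant,
                                     *ld.valid_range, None, skip)
        else:
            x_hat = predict(model, restored)
            x, bits = _vector_extract(ld.samples, x_hat, skip)
        restored = restored.with_lead(name, x)
        chunks.append(bits)
    chunks.reverse()
    stream = np.concatenate(chunks) if chunks else np.array([], dtype=np.uint8)
    payload = deframe_payload(stream)
    return payload, restored
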