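"""Sample predictors feeding prediction-error expansion and LCBP.

Three classes:

* **neighbor** — causal/anti-causal averaging of up to two neighbours on
  each side of the predicted sample.  Left-side neighbours are read from
  the already-watermarked signal, right-side neighbours from the original
  signal; extraction therefore runs right-to-left.  Variants are written
  (l, r) = neighbours used on the (left, right) side.
* **interlead_regression** — ordinary least squares of the target lead on
  N other leads plus an intercept; the fitted coefficients travel as side
  information (8·(N+1) bytes as 64-bit floats).  Fitting per record is
  more accurate than a single corpus-level model; both are provided.
* **physical** — the Einthoven/Goldberger limb-lead identities
  III = II − I, aVR = ⌊−(I+II)/2⌋, aVL = ⌊(2I−II)/2⌋, aVF = ⌊(2II−I)/2⌋.
  Exact for III; halves are floored.  Only the four derived limb leads
  can be predicted this way.

Predictions must be integers (the expansion arithmetic is integer):
regression predictions use round-half-up, physical predictions floor.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .errors import UnsupportedLeadError, ValidationError
from .signal_model import ECGRecord, MetricsConfig, psnr
from .synth_ecg import derive_limb_leads

NEIGHBOR_VARIANTS = ((1, 0), (0, 1), (2, 0), (0, 2), (1, 1), (2, 2))
PHYSICAL_TARGETS = ("III", "aVR", "aVL", "aVF")


@dataclass(frozen=True)
class PredictionModel:
    """A predictor specification, serializable into side information."""

    kind: str  # neighbor | interlead_regression | physical
    target_lead: str | None = None
    predictor_leads: tuple[str, ...] = ()
    coefficients: tuple[float, ...] = ()  # intercept first (regression only)
    variant: tuple[int, int] = (1, 1)     # neighbor only

    def __post_init__(self):
        if self.kind not in ("neighbor", "interlead_regression", "physical"):
            raise ValidationError(f"unknown predictor kind {self.kind!r}")
        if self.kind == "neighbor" and tuple(self.variant) not in \
                NEIGHBOR_VARIANTS:
            raise ValidationError(f"unknown neighbor variant {self.variant}")
        if self.kind == "interlead_regression" and self.coefficients and \
                len(self.coefficients) != len(self.predictor_leads) + 1:
            raise ValidationError("regression needs N+1 coefficients "
                                  "(intercept first)")
        if self.kind == "physical" and self.target_lead is not None and \
                self.target_lead not in PHYSICAL_TARGETS:
            raise UnsupportedLeadError(
                f"physical prediction only supports {PHYSICAL_TARGETS}, "
                f"got {self.target_lead!r}")


def predict_neighbor(left, right, variant=(2, 2)) -> int:
    """Floor of the mean of the used neighbours.

    ``left`` holds already-watermarked samples ordered towards the
    predicted one (left[-1] is its immediate left neighbour); ``right``
    holds original samples (right[0] immediately to the right).
    """
    l_n, r_n = variant
    if tuple(variant) not in NEIGHBOR_VARIANTS:
        raise ValidationError(f"unknown neighbor variant {variant}")
    if len(left) < l_n or len(right) < r_n:
        raise ValidationError("sequence edge: missing neighbours for variant")
    vals = [int(v) for v in list(left)[len(left) - l_n:]] + \
           [int(v) for v in list(right)[:r_n]]
    return int(np.floor(sum(vals) / len(vals)))


def fit_interlead_regression(record: ECGRecord, target_lead: str,
                             predictor_leads) -> PredictionModel:
    """OLS fit of the target lead on the predictor leads plus intercept.

    Rank-deficient designs are resolved by the minimum-norm
    (pseudoinverse) solution.
    """
    predictor_leads = tuple(predictor_leads)
    if target_lead in predictor_leads:
        raise ValidationError("target lead may not be one of its predictors")
    if not predictor_leads:
        raise ValidationError("need at least one predictor lead")
    y = record.lead(target_lead).samples.astype(np.float64)
    X = np.column_stack(
        [np.ones_like(y)] +
        [record.lead(nm).samples.astype(np.float64) for nm in predictor_leads])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return PredictionModel(kind="interlead_regression",
                           target_lead=target_lead,
                           predictor_leads=predictor_leads,
                           coefficients=tuple(float(c) for c in coef))


def fit_corpus_regression(corpus, target_lead: str,
                          predictor_leads) -> PredictionModel:
    """One shared OLS model fit on the pooled samples of a record corpus."""
    corpus = list(corpus)
    if not corpus:
        raise ValidationError("corpus must be non-empty")
    predictor_leads = tuple(predictor_leads)
    if target_lead in predictor_leads:
        raise ValidationError("target lead may not be one of its predictors")
    y = np.concatenate([r.lead(target_lead).samples for r in corpus]) \
        .astype(np.float64)
    X = np.column_stack(
        [np.ones_like(y)] +
        [np.concatenate([r.lead(nm).samples for r in corpus])
         .astype(np.float64) for nm in predictor_leads])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return PredictionModel(kind="interlead_regression",
                           target_lead=target_lead,
                           predictor_leads=predictor_leads,
                           coefficients=tuple(float(c) for c in coef))


def predict_interlead(model: PredictionModel, record: ECGRecord) -> np.ndarray:
    """Integer prediction of the model's target lead (round-half-up).

    Never reads the target lead itself."""
    if model.kind != "interlead_regression":
        raise ValidationError("model is not an inter-lead regression")
    pred = np.full(record.n_samples, model.coefficients[0], dtype=np.float64)
    for c, nm in zip(model.coefficients[1:], model.predictor_leads):
        pred += c * record.lead(nm).samples
    return np.floor(pred + 0.5).astype(np.int64)


def predict_physical(record: ECGRecord, target_lead: str) -> np.ndarray:
    """Einthoven/Goldberger prediction of a derived limb lead from I, II."""
    if target_lead not in PHYSICAL_TARGETS:
        raise UnsupportedLeadError(
            f"physical prediction only supports {PHYSICAL_TARGETS}, "
            f"got {target_lead!r}")
    derived = derive_limb_leads(record.lead("I").samples,
                                record.lead("II").samples)
    return derived[target_lead]


def predict(model: PredictionModel, record: ECGRecord) -> np.ndarray:
    """Dispatch whole-lead prediction for non-neighbor models."""
    if model.kind == "interlead_regression":
        return predict_interlead(model, record)
    if model.kind == "physical":
        return predict_physical(record, model.target_lead)
    raise ValidationError("neighbor prediction is sample-sequential; "
                          "use the PEE embedding loop")


def prediction_psnr(record: ECGRecord, model: PredictionModel,
                    cfg: MetricsConfig = MetricsConfig()) -> float:
    """PSNR between the predicted and original target lead (a pure
    prediction-quality measure, no embedding involved).

    For neighbor models the prediction of sample i uses the *original*
    neighbours (no embedding has happened)."""
    if model.kind == "neighbor":
        x = record.lead(model.target_lead).samples
        l_n, r_n = model.variant
        lo, hi = l_n, x.size - r_n
        cols = []
        for off in range(-l_n, 0):
            cols.append(x[lo + off: hi + off])
        for off in range(1, r_n + 1):
            cols.append(x[lo + off: hi + off])
        pred = np.floor(np.mean(np.stack(cols, axis=0), axis=0)).astype(np.int64)
        return psnr(x[lo:hi], pred, cfg)
    target = record.lead(model.target_lead).samples
    return psnr(target, predict(model, record), cfg)


# ---------------------------------------------------------------------------
# Side-information serialization

def serialize_coefficients(model: PredictionModel) -> bytes:
    """Pack intercept + N weights as little-endian 64-bit floats:
    exactly 8·(N+1) bytes for N predictor leads."""
    return struct.pack(f"<{len(model.coefficients)}d", *model.coefficients)


def model_to_side_info(model: PredictionModel, prefix: str = "pred") -> dict:
    info = {f"{prefix}.kind": model.kind}
    if model.target_lead:
        info[f"{prefix}.target"] = model.target_lead
    if model.kind == "neighbor":
        info[f"{prefix}.variant"] = f"{model.variant[0]},{model.variant[1]}"
    if model.kind == "interlead_regression":
        info[f"{prefix}.leads"] = ",".join(model.predictor_leads)
        info[f"{prefix}.coef"] = serialize_coefficients(model).hex()
    return info


def model_from_side_info(info: dict, prefix: str = "pred") -> PredictionModel:
    kind = info[f"{prefix}.kind"]
    target = info.get(f"{prefix}.target")
    if kind == "neighbor":
        l_n, r_n = (int(v) for v in info[f"{prefix}.variant"].split(","))
        return PredictionModel(kind=kind, target_lead=target,
                               variant=(l_n, r_n))
    if kind == "physical":
        return PredictionModel(kind=kind, target_lead=target)
    leads = tuple(info[f"{prefix}.leads"].split(","))
    raw = bytes.fromhex(info[f"{prefix}.coef"])
    coefs = struct.unpack(f"<{len(raw) // 8}d", raw)
    return PredictionModel(kind=kind, target_lead=target,
                           predictor_leads=leads, coefficients=coefs)
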