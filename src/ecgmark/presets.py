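"""Named method presets: the 15 best-performing configurations.

Each preset resolves to an ``embed(record, payload)`` /
``extract(record, side_info)`` pair over a concrete method
configuration.  Naming scheme:

* ``lcb-huff-bpX`` — LCB, Huffman with adaptive symbol length, planes
  (X, X+1) of every lead.
* ``itb`` — integer-transform difference expansion, block length 2,
  every lead.
* ``rcm-blS`` — RCM with S bits per sample pair, every lead (BPS = S/2).
* ``pee-neigh`` — PEE with one-neighbour-per-side averaging, every lead.
* ``pee-neighchan`` — PEE with per-record inter-lead regression, one
  sequential pass per lead.
* ``pee-depchan`` — PEE with physical limb-lead prediction, targets
  III/aVR/aVL/aVF.
* ``lcbp-huff-{neighchan|depchan}-ps{2|4}`` — prediction-error
  compression into the 2 or 4 least significant planes of lead III
  (default target, overridable), Huffman with adaptive symbol length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .errors import ValidationError
from .itb import itb_embed, itb_extract
from .lcb import CodecParams, lcb_embed, lcb_extract, lcbp_embed, lcbp_extract
from .pee import pee_embed, pee_extract
from .predictors import PredictionModel
from .rcm import RcmParams, rcm_embed, rcm_extract
from .signal_model import ECGRecord


@dataclass(frozen=True)
class MethodPreset:
    name: str
    embed: Callable
    extract: Callable


def _rcm_preset(s: int) -> MethodPreset:
    params = RcmParams(s=s)

    def embed(record, payload, leads=None, **kw):
        return rcm_embed(record, payload, params, leads=leads, **kw)

    def extract(record, side_info, leads=None):
        p = RcmParams(s=int(side_info.get("s", s)))
        if leads is None and side_info.get("leads"):
            leads = side_info["leads"].split(",")
        return rcm_extract(record, p, leads=leads)

    return MethodPreset(f"rcm-bl{s}", embed, extract)


def _itb_preset() -> MethodPreset:
    def embed(record, payload, leads=None, **kw):
        return itb_embed(record, payload, n=2, leads=leads, **kw)

    def extract(record, side_info, leads=None):
        return itb_extract(record, side_info, leads=leads)

    return MethodPreset("itb", embed, extract)


def _lcb_preset(low_plane: int) -> MethodPreset:
    planes = (low_plane, low_plane + 1)
    params = CodecParams(codec="huffman", adaptive=True)

    def embed(record, payload, leads=None, **kw):
        return lcb_embed(record, payload, planes, params, leads=leads, **kw)

    def extract(record, side_info, leads=None):
        return lcb_extract(record, side_info, leads=leads)

    return MethodPreset(f"lcb-huff-bp{low_plane}", embed, extract)


def _pee_preset(name: str, predictor: PredictionModel,
                default_leads=None) -> MethodPreset:
    def embed(record, payload, leads=None, **kw):
        return pee_embed(record, payload, predictor,
                         leads=leads if leads is not None else default_leads,
                         **kw)

    def extract(record, side_info, leads=None):
        return pee_extract(record, side_info, leads=leads)

    return MethodPreset(name, embed, extract)


def _lcbp_preset(name: str, kind: str, ps: int,
                 default_target: str = "III") -> MethodPreset:
    params = CodecParams(codec="huffman", adaptive=True)

    def embed(record: ECGRecord, payload, leads=None, target=None, **kw):
        tgt = target or (leads[0] if leads else default_target)
        predictor = PredictionModel(kind=kind, target_lead=tgt) \
            if kind == "physical" else PredictionModel(kind=kind)
        return lcbp_embed(record, payload, tgt, predictor, ps=ps,
                          params=params, **kw)

    def extract(record, side_info, leads=None):
        return lcbp_extract(record, side_info)

    return MethodPreset(name, embed, extract)


def _build_registry() -> dict[str, MethodPreset]:
    presets = [
        _lcb_preset(6), _lcb_preset(7), _lcb_preset(8),
        _itb_preset(),
        _rcm_preset(1), _rcm_preset(2), _rcm_preset(3), _rcm_preset(4),
        _pee_preset("pee-neigh",
                    PredictionModel(kind="neighbor", variant=(1, 1))),
        _pee_preset("pee-neighchan",
                    PredictionModel(kind="interlead_regression")),
        _pee_preset("pee-depchan", PredictionModel(kind="physical")),
        _lcbp_preset("lcbp-huff-neighchan-ps2", "interlead_regression", 2),
        _lcbp_preset("lcbp-huff-neighchan-ps4", "interlead_regression", 4),
        _lcbp_preset("lcbp-huff-depchan-ps2", "physical", 2),
        _lcbp_preset("lcbp-huff-depchan-ps4", "physical", 4),
    ]
    return {p.name: p for p in presets}


PRESETS = _build_registry()


def get_preset(name: str) -> MethodPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}") \
            from None
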