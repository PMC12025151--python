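"""Four-way integrated assessment from the three binary mechanism calls.

The angle-closure mechanism categories partition the boolean cube of
(PB, TPI, ALCB) calls:

* pure pupillary block: only PB, no TPI and no ALCB;
* pure non-PB: TPI and/or ALCB without PB;
* multiple mechanisms (MM): PB together with TPI and/or ALCB;
* others: none of the three mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .classify import Mechanism, MechanismCall, TrainedModel, predict_mechanism
from .features import FeatureRow, extract_feature_row
from .geometry import AngleMechError, SegmentationMask

__all__ = ["IntegratedClass", "AssessmentRecord", "integrate", "assess_image"]


class IntegratedClass(str, Enum):
    PURE_PB = "PURE_PB"
    PURE_NON_PB = "PURE_NON_PB"
    MM = "MM"
    OTHERS = "OTHERS"


def integrate(pb: bool, tpi: bool, alcb: bool) -> IntegratedClass:
    """Total mapping of the three mechanism booleans to the final category."""
    if pb:
        return IntegratedClass.MM if (tpi or alcb) else IntegratedClass.PURE_PB
    return IntegratedClass.PURE_NON_PB if (tpi or alcb) else IntegratedClass.OTHERS


@dataclass(frozen=True)
class AssessmentRecord:
    """Per-image final assessment with full provenance."""

    image_id: str
    call: MechanismCall
    integrated: IntegratedClass
    features: FeatureRow
    model_ids: dict

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "p_pb": self.call.p_pb,
            "p_tpi": self.call.p_tpi,
            "p_alcb": self.call.p_alcb,
            "pb": self.call.pb,
            "tpi": self.call.tpi,
            "alcb": self.call.alcb,
            "integrated_class": self.integrated.value,
        }


def _check_bundle(bundle: Mapping[Mechanism, TrainedModel]) -> None:
    targets = set(bundle)
    if targets != {Mechanism.PB, Mechanism.TPI, Mechanism.ALCB}:
        raise AngleMechError(f"model bundle must cover PB/TPI/ALCB exactly, got {targets}")
    for mech, model in bundle.items():
        if model.target is not mech:
            raise AngleMechError(f"model for {mech.value} was trained for {model.target.value}")


def assess_image(
    mask: SegmentationMask,
    bundle: Mapping[Mechanism, TrainedModel],
    image_id: str = "image",
) -> AssessmentRecord:
    """Features -> three mechanism predictions -> integrated category."""
    _check_bundle(bundle)
    row = extract_feature_row(mask, image_id=image_id)
    p_pb, pb = predict_mechanism(bundle[Mechanism.PB], row)
    p_tpi, tpi = predict_mechanism(bundle[Mechanism.TPI], row)
    p_alcb, alcb = predict_mechanism(bundle[Mechanism.ALCB], row)
    call = MechanismCall(pb=pb, tpi=tpi, alcb=alcb, p_pb=p_pb, p_tpi=p_tpi, p_alcb=p_alcb)
    return AssessmentRecord(
        image_id=image_id,
        call=call,
        integrated=integrate(pb, tpi, alcb),
        features=row,
        model_ids={m.value: f"{b.algorithm.value}:{b.seed}" for m, b in bundle.items()},
    )
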