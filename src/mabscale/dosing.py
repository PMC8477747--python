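"""First-in-human dose projection from a single animal species.

Five projections are computed from one animal dose, the animal clearance
and a predicted human clearance:

* Method I (linear): absolute animal dose x (CL_human / CL_animal),
  converted back to mg/kg with the 70 kg human weight.
* Method II (exponential): as Method I but the clearance ratio is raised
  to 0.85.
* Method III (HED by weight): mg/kg dose x (W_animal / W_human)^0.33.
* Method IV (HED by clearance, 0.33): mg/kg dose x (CL_animal / CL_human)^0.33.
* Method V (HED by clearance, 0.25): mg/kg dose x (CL_animal / CL_human)^0.25.

The animal dose feeding all five is chosen by a fixed rule: use 10 mg/kg
if administered, otherwise the largest dose below 10 mg/kg; if every dose
exceeds 10 mg/kg, a single available dose is accepted as-is, and with
several such doses the smallest is taken as the conservative choice.

When the human clearance comes from 0.85-exponent allometry the animal
clearance cancels and each method collapses to
``dose_mgkg x (W_animal/70)^p`` with p = 0.15, 0.2775, 0.33, 0.2805 and
0.2125 for Methods I-V — the closed form used by the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .scaling import MabRecord
from .species import HUMAN_WEIGHT_KG, SpeciesProfile, round_half_away

__all__ = [
    "DoseProjection",
    "select_animal_dose",
    "dose_linear",
    "dose_exponential",
    "hed_weight",
    "hed_cl",
    "project_all",
    "round_dose",
]

#: Target preclinical dose (mg/kg) for the selection rule.
TARGET_DOSE_MGKG = 10.0


@dataclass(frozen=True)
class DoseProjection:
    """Five first-in-human dose estimates (mg/kg) for one mab x species."""

    mab_id: str
    source_species: str
    animal_dose_mgkg: float
    method_I_linear: float
    method_II_exp085: float
    method_III_hed_weight: float
    method_IV_hed_cl033: float
    method_V_hed_cl025: float

    def __post_init__(self) -> None:
        for attr in (
            "animal_dose_mgkg",
            "method_I_linear",
            "method_II_exp085",
            "method_III_hed_weight",
            "method_IV_hed_cl033",
            "method_V_hed_cl025",
        ):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0, got {getattr(self, attr)}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (
            self.method_I_linear,
            self.method_II_exp085,
            self.method_III_hed_weight,
            self.method_IV_hed_cl033,
            self.method_V_hed_cl025,
        )

    def rounded(self) -> tuple[float, float, float, float, float]:
        """The five projections at report precision."""
        return tuple(round_dose(v) for v in self.as_tuple())


def round_dose(value: float) -> float:
    """Report rounding for doses: one decimal, integers from 100 up."""
    if value >= 100:
        return round_half_away(value, 0)
    return round_half_away(value, 1)


def select_animal_dose(doses_mgkg: Sequence[float]) -> float:
    """Pick the animal dose for projection: 10 mg/kg or the nearest lower.

    A lone dose above 10 mg/kg is used as given; with several doses all
    above 10 the smallest is chosen.
    """
    doses = list(doses_mgkg)
    if not doses:
        raise ValueError("dose list must be non-empty")
    if any(d <= 0 for d in doses):
        raise ValueError(f"all doses must be > 0, got {doses}")
    at_or_below = [d for d in doses if d <= TARGET_DOSE_MGKG]
    if at_or_below:
        return max(at_or_below)
    if len(doses) == 1:
        return doses[0]
    return min(doses)


def _check_positive(**kwargs: float) -> None:
    bad = {k: v for k, v in kwargs.items() if v <= 0}
    if bad:
        raise ValueError(f"arguments must be > 0: {bad}")


def dose_linear(
    dose_animal_mgkg: float,
    weight_animal: float,
    cl_animal: float,
    cl_human_pred: float,
    weight_human: float = HUMAN_WEIGHT_KG,
) -> float:
    """Method I: absolute dose scaled by the clearance ratio, per kg human."""
    _check_positive(
        dose=dose_animal_mgkg,
        weight_animal=weight_animal,
        cl_animal=cl_animal,
        cl_human_pred=cl_human_pred,
        weight_human=weight_human,
    )
    dose_abs = dose_animal_mgkg * weight_animal
    return dose_abs * (cl_human_pred / cl_animal) / weight_human


def dose_exponential(
    dose_animal_mgkg: float,
    weight_animal: float,
    cl_animal: float,
    cl_human_pred: float,
    weight_human: float = HUMAN_WEIGHT_KG,
) -> float:
    """Method II: as Method I with the clearance ratio raised to 0.85."""
    _check_positive(
        dose=dose_animal_mgkg,
        weight_animal=weight_animal,
        cl_animal=cl_animal,
        cl_human_pred=cl_human_pred,
        weight_human=weight_human,
    )
    dose_abs = dose_animal_mgkg * weight_animal
    return dose_abs * (cl_human_pred / cl_animal) ** 0.85 / weight_human


def hed_weight(
    dose_animal_mgkg: float,
    weight_animal: float,
    weight_human: float = HUMAN_WEIGHT_KG,
) -> float:
    """Method III: human-equivalent dose from the weight ratio at 0.33."""
    _check_positive(
        dose=dose_animal_mgkg, weight_animal=weight_animal, weight_human=weight_human
    )
    return dose_animal_mgkg * (weight_animal / weight_human) ** 0.33


def hed_cl(
    dose_animal_mgkg: float,
    cl_animal: float,
    cl_human_pred: float,
    exponent: float,
) -> float:
    """Methods IV/V: human-equivalent dose from the clearance ratio.

    ``exponent`` must be 0.33 (Method IV) or 0.25 (Method V).
    """
    if exponent not in (0.33, 0.25):
        raise ValueError(f"exponent must be 0.33 or 0.25, got {exponent}")
    _check_positive(
        dose=dose_animal_mgkg, cl_animal=cl_animal, cl_human_pred=cl_human_pred
    )
    return dose_animal_mgkg * (cl_animal / cl_human_pred) ** exponent


def project_all(
    record: MabRecord,
    cl_human_pred: float,
    profile: SpeciesProfile,
    weight_human: float = HUMAN_WEIGHT_KG,
    animal_dose_mgkg: float | None = None,
) -> DoseProjection:
    """Apply all five dose methods to one animal record.

    The animal dose defaults to :func:`select_animal_dose` over the
    record's administered doses. Values are kept at full precision;
    rounding happens only in report rendering.
    """
    if record.species != profile.name:
        raise ValueError(
            f"record species {record.species!r} does not match profile {profile.name!r}"
        )
    if cl_human_pred <= 0:
        raise ValueError(f"cl_human_pred must be > 0, got {cl_human_pred}")
    if animal_dose_mgkg is None:
        animal_dose_mgkg = select_animal_dose(record.doses_mgkg)
    w = profile.body_weight
    cl = record.clearance
    return DoseProjection(
        mab_id=record.mab_id,
        source_species=record.species,
        animal_dose_mgkg=animal_dose_mgkg,
        method_I_linear=dose_linear(animal_dose_mgkg, w, cl, cl_human_pred, weight_human),
        method_II_exp085=dose_exponential(
            animal_dose_mgkg, w, cl, cl_human_pred, weight_human
        ),
        method_III_hed_weight=hed_weight(animal_dose_mgkg, w, weight_human),
        method_IV_hed_cl033=hed_cl(animal_dose_mgkg, cl, cl_human_pred, 0.33),
        method_V_hed_cl025=hed_cl(animal_dose_mgkg, cl, cl_human_pred, 0.25),
    )
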