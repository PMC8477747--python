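"""Human clearance prediction from a single animal species.

Seven methods are implemented. Four are allometric: predicted human CL =
animal CL x (70 / animal weight)^b with b in {0.75, 0.80, 0.85, 0.90}.
Three multiply the animal clearance by a species-specific physiological
factor: minimal PBPK, lymph flow, and liver blood flow (see
:mod:`mabscale.species` for the factor values).

Clearance is handled in ABSOLUTE terms (mL/day for the whole animal),
never per-kg: the allometric form (70/W)^b only reproduces the published
behaviour with absolute clearances. :mod:`mabscale.io` converts per-kg
inputs at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .species import ANIMAL_SPECIES, HUMAN_WEIGHT_KG, SpeciesProfile

__all__ = [
    "METHODS",
    "ALLOMETRIC_EXPONENTS",
    "MabRecord",
    "ClearancePrediction",
    "predict_cl_allometric",
    "predict_cl_factor",
    "predict_cl",
    "predict_all_methods",
]

#: Allometric exponents evaluated by the workflow.
ALLOMETRIC_EXPONENTS = (0.75, 0.80, 0.85, 0.90)

#: The closed set of seven method labels.
METHODS = (
    "allometric_0.75",
    "allometric_0.80",
    "allometric_0.85",
    "allometric_0.90",
    "mpbpk",
    "lymph_flow",
    "liver_blood_flow",
)


@dataclass(frozen=True)
class MabRecord:
    """One antibody x species observation.

    ``clearance`` is the absolute clearance in mL/day, taken at a dose in
    the linear range (linearity assessment happens upstream of this
    package). ``doses_mgkg`` lists the administered doses in mg/kg.
    """

    mab_id: str
    species: str
    clearance: float
    doses_mgkg: tuple[float, ...] = ()
    reference: str = ""

    def __post_init__(self) -> None:
        if not self.mab_id:
            raise ValueError("mab_id must be non-empty")
        object.__setattr__(self, "clearance", float(self.clearance))
        if self.clearance <= 0:
            raise ValueError(f"clearance must be > 0, got {self.clearance}")
        object.__setattr__(self, "doses_mgkg", tuple(float(d) for d in self.doses_mgkg))
        if any(d <= 0 for d in self.doses_mgkg):
            raise ValueError(f"all doses must be > 0, got {self.doses_mgkg}")


@dataclass(frozen=True)
class ClearancePrediction:
    """A predicted human clearance, tagged with its method and source."""

    mab_id: str
    source_species: str
    method: str
    predicted_cl_human: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.predicted_cl_human <= 0:
            raise ValueError(
                f"predicted_cl_human must be > 0, got {self.predicted_cl_human}"
            )


def predict_cl_allometric(
    cl_animal: float,
    weight_animal: float,
    weight_human: float = HUMAN_WEIGHT_KG,
    exponent: float = 0.85,
) -> float:
    """Allometric scaling: CL_human = CL_animal x (W_human / W_animal)^b."""
    if cl_animal <= 0 or weight_animal <= 0 or weight_human <= 0 or exponent <= 0:
        raise ValueError(
            "cl_animal, weights and exponent must all be > 0; got "
            f"cl={cl_animal}, w_animal={weight_animal}, w_human={weight_human}, b={exponent}"
        )
    return cl_animal * (weight_human / weight_animal) ** exponent


def predict_cl_factor(cl_animal: float, factor: float) -> float:
    """Factor scaling: CL_human = CL_animal x physiological factor."""
    if cl_animal <= 0 or factor <= 0:
        raise ValueError(f"cl_animal and factor must be > 0, got {cl_animal}, {factor}")
    return cl_animal * factor


def predict_cl(
    record: MabRecord,
    profile: SpeciesProfile,
    method: str,
    weight_human: float = HUMAN_WEIGHT_KG,
) -> ClearancePrediction:
    """Predict human clearance for one record by one named method."""
    if record.species != profile.name:
        raise ValueError(
            f"record species {record.species!r} does not match profile {profile.name!r}"
        )
    if record.species not in ANIMAL_SPECIES:
        raise ValueError(
            f"source species must be one of {ANIMAL_SPECIES}, got {record.species!r}"
        )
    if method.startswith("allometric_"):
        exponent = float(method.removeprefix("allometric_"))
        cl = predict_cl_allometric(
            record.clearance, profile.body_weight, weight_human, exponent
        )
    elif method == "mpbpk":
        cl = predict_cl_factor(record.clearance, _require(profile, "factor_mpbpk"))
    elif method == "lymph_flow":
        cl = predict_cl_factor(record.clearance, _require(profile, "factor_lymph"))
    elif method == "liver_blood_flow":
        cl = predict_cl_factor(record.clearance, _require(profile, "factor_lbf"))
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return ClearancePrediction(
        mab_id=record.mab_id,
        source_species=record.species,
        method=method,
        predicted_cl_human=cl,
    )


def _require(profile: SpeciesProfile, attr: str) -> float:
    value = getattr(profile, attr)
    if value is None:
        raise ValueError(f"profile {profile.name!r} has no {attr}")
    return value


def predict_all_methods(
    record: MabRecord,
    profile: SpeciesProfile,
    weight_human: float = HUMAN_WEIGHT_KG,
) -> list[ClearancePrediction]:
    """Fan one animal record out over all seven methods.

    Returns exactly seven predictions, in :data:`METHODS` order.
    """
    if not profile.has_all_factors:
        raise ValueError(f"profile {profile.name!r} is missing physiological factors")
    return [predict_cl(record, profile, m, weight_human) for m in METHODS]
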