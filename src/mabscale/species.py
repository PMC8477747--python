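"""Species physiology: body weights, liver blood flows, scaling factors.

The package ships constants for the four species used in single-species
scaling of therapeutic antibodies (mouse, rat, monkey, human):

* body weight (kg) — 0.02, 0.25, 3.5 and 70;
* hepatic blood flow (mL/min) — 1.8, 13.8, 158 (a 3.5 kg monkey) and 1600;
* three animal-to-human clearance multipliers ("physiological factors"):
  a minimal-PBPK factor built from liver/kidney weights, flows and lymph
  flow (936 / 130 / 10 for mouse / rat / monkey), a lymph-flow-only factor
  (1009 / 94 / 10), and a liver-blood-flow factor, which is simply the
  human:animal hepatic flow ratio rounded to the nearest integer
  (889 / 116 / 10).

The mPBPK and lymph-flow factors are stored as literature constants; the
liver-blood-flow factor is recomputed from the flows by :func:`flow_factor`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "SpeciesProfile",
    "flow_factor",
    "builtin_profiles",
    "load_profiles",
    "round_half_away",
    "ANIMAL_SPECIES",
    "HUMAN_WEIGHT_KG",
]

ANIMAL_SPECIES = ("mouse", "rat", "monkey")
HUMAN_WEIGHT_KG = 70.0


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (2.5 -> 3), unlike built-in round.

    Report tables round this way: the printed flow factors 889/116/10 and the
    one-decimal dose columns all use conventional half-away-from-zero rounding.
    """
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class SpeciesProfile:
    """Constants for one species.

    ``factor_mpbpk``, ``factor_lymph`` and ``factor_lbf`` are the
    animal-to-human clearance multipliers; they are ``None`` for human
    (human is the scaling target, not a source).
    """

    name: str
    body_weight: float
    liver_blood_flow: float
    factor_mpbpk: float | None = None
    factor_lymph: float | None = None
    factor_lbf: float | None = None

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError(f"body_weight must be > 0, got {self.body_weight}")
        if self.liver_blood_flow <= 0:
            raise ValueError(
                f"liver_blood_flow must be > 0, got {self.liver_blood_flow}"
            )
        for attr in ("factor_mpbpk", "factor_lymph", "factor_lbf"):
            value = getattr(self, attr)
            if value is not None and value <= 0:
                raise ValueError(f"{attr} must be > 0, got {value}")

    @property
    def has_all_factors(self) -> bool:
        return None not in (self.factor_mpbpk, self.factor_lymph, self.factor_lbf)


def flow_factor(flow_human: float, flow_animal: float) -> float:
    """Human:animal liver-blood-flow ratio, unrounded.

    Both flows must be positive and in the same units (mL/min internally).
    The reported integer factor is ``round_half_away(flow_factor(...))``.
    """
    if flow_human <= 0 or flow_animal <= 0:
        raise ValueError(
            f"flows must be > 0, got human={flow_human}, animal={flow_animal}"
        )
    return flow_human / flow_animal


def _profiles_from_mapping(raw: Mapping[str, Mapping[str, float]]) -> dict[str, SpeciesProfile]:
    profiles = {}
    for name, fields in raw.items():
        profiles[name] = SpeciesProfile(name=name, **fields)
    return profiles


def builtin_profiles() -> dict[str, SpeciesProfile]:
    """The four packaged species profiles, keyed by species name."""
    text = resources.files("mabscale.data").joinpath("species_profiles.json").read_text()
    return _profiles_from_mapping(json.loads(text))


def load_profiles(path: str | Path) -> dict[str, SpeciesProfile]:
    """Load species profiles from a user JSON or YAML file.

    The schema matches the packaged resource: a mapping from species name to
    ``{body_weight, liver_blood_flow, factor_mpbpk?, factor_lymph?,
    factor_lbf?}``. Species present in the file override the packaged
    defaults; others are kept.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    profiles = builtin_profiles()
    profiles.update(_profiles_from_mapping(raw))
    return profiles
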