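"""Reference-individual physiology and allometric scaling of renal function.

The package parametrises species physiology through four fixed *reference
individuals* — a male and a female adult human, and a "young" (250 g) and
"old" (480 g) adult rat.  Each carries literature values for blood volume,
tissue volumes and densities, organ blood flows, haematocrit and glomerular
filtration rate (GFR).  Rather than scaling every organ to an arbitrary body
weight, callers pick the nearest reference individual; only GFR is scaled
allometrically (body weight for rats, body surface area for humans).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

__all__ = [
    "TISSUES",
    "ReferenceIndividual",
    "ScalingContext",
    "load_reference_individuals",
    "reference_for",
    "scale_gfr_rat",
    "scale_gfr_human",
    "tissue_mass",
]

#: The seven peripheral tissue compartments of the model.
TISSUES = ("liv", "spl", "mus", "bon", "bra", "kid", "rob")


class InvalidInputError(ValueError):
    """Raised when a physiological argument is outside its valid domain."""


@dataclass(frozen=True)
class ReferenceIndividual:
    """Fixed physiology of one reference individual.

    Volumes in L, flows in L/h, densities in kg/L, GFR in L/h, body weight
    in kg, height in m, body surface area in m².  ``BH``/``BSA`` are only
    defined for humans.
    """

    species: str
    label: str
    BW: float
    Hct: float
    V_blo: float
    V_tis: Mapping[str, float]
    D_tis: Mapping[str, float]
    Q_tis: Mapping[str, float]
    GFR: float
    BH: float | None = None
    BSA: float | None = None

    def __post_init__(self) -> None:
        if self.species not in ("rat", "human"):
            raise InvalidInputError(f"unknown species {self.species!r}")
        if not 0.0 < self.Hct < 1.0:
            raise InvalidInputError(f"haematocrit must be in (0,1), got {self.Hct}")
        for name, value in (("BW", self.BW), ("V_blo", self.V_blo), ("GFR", self.GFR)):
            if value <= 0:
                raise InvalidInputError(f"{name} must be positive, got {value}")
        for mapping, kind in ((self.V_tis, "volume"), (self.D_tis, "density"), (self.Q_tis, "flow")):
            missing = set(TISSUES) - set(mapping)
            if missing:
                raise InvalidInputError(f"missing tissue {kind}s: {sorted(missing)}")
            for tis in TISSUES:
                if mapping[tis] <= 0:
                    raise InvalidInputError(f"non-positive {kind} for {tis!r}")

    @property
    def Q_kid(self) -> float:
        """Kidney blood flow, L/h (enters the renal-clearance formula)."""
        return self.Q_tis["kid"]

    @property
    def plasma_volume(self) -> float:
        """Plasma volume V_blo × (1 − Hct), L."""
        return self.V_blo * (1.0 - self.Hct)

    def with_gfr(self, gfr: float) -> "ReferenceIndividual":
        if gfr <= 0:
            raise InvalidInputError(f"GFR must be positive, got {gfr}")
        return replace(self, GFR=gfr)


@dataclass(frozen=True)
class ScalingContext:
    """Constants of the allometric GFR scaling rules.

    ``SF_unit`` converts mL/min to L/h.  Rat GFR scales with (BW/BW_ref)^¾
    from 1.31 mL/min at 0.25 kg; human GFR scales linearly with body surface
    area from 105 mL/min at 1.73 m².
    """

    GFR_ref_rat: float = 1.31     # mL/min
    BW_ref: float = 0.25          # kg
    GFR_ref_human: float = 105.0  # mL/min
    BSA_ref: float = 1.73         # m²
    SF_unit: float = 60.0 / 1000.0  # mL/min → L/h


_SCALING = ScalingContext()


def load_reference_individuals(path: str | None = None) -> dict[str, ReferenceIndividual]:
    """Load the packaged (or a user-supplied) reference-physiology file."""
    if path is None:
        text = resources.files("alumtk.data").joinpath("reference_individuals.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    return {key: ReferenceIndividual(**entry) for key, entry in raw.items()}


_REFERENCES: dict[str, ReferenceIndividual] = load_reference_individuals()


def reference_for(species: str, selector: str | float) -> ReferenceIndividual:
    """Pick the appropriate reference individual.

    For humans ``selector`` is the sex (``"male"``/``"female"``).  For rats
    it is the body weight in kg and the reference with the nearer body
    weight is chosen (ties go to the young, 250 g reference).
    """
    if species == "human":
        if selector not in ("male", "female"):
            raise InvalidInputError(f"unknown human sex {selector!r}")
        return _REFERENCES[f"human_{selector}"]
    if species == "rat":
        try:
            bw = float(selector)
        except (TypeError, ValueError):
            raise InvalidInputError(f"rat selector must be a body weight in kg, got {selector!r}")
        if bw <= 0:
            raise InvalidInputError(f"rat body weight must be positive, got {bw}")
        young, old = _REFERENCES["rat_young"], _REFERENCES["rat_old"]
        if abs(bw - young.BW) <= abs(bw - old.BW):
            return young
        return old
    raise InvalidInputError(f"unknown species {species!r}")


def scale_gfr_rat(BW: float, ctx: ScalingContext = _SCALING) -> float:
    """Allometric rat GFR in L/h: SF × 1.31 mL/min × (BW / 0.25 kg)^¾."""
    if BW <= 0:
        raise InvalidInputError(f"body weight must be positive, got {BW}")
    return ctx.SF_unit * ctx.GFR_ref_rat * (BW / ctx.BW_ref) ** 0.75


def scale_gfr_human(BSA: float, ctx: ScalingContext = _SCALING) -> float:
    """Human GFR in L/h scaled with body surface area: SF × 105 mL/min × BSA/1.73 m²."""
    if BSA <= 0:
        raise InvalidInputError(f"body surface area must be positive, got {BSA}")
    return ctx.SF_unit * ctx.GFR_ref_human * BSA / ctx.BSA_ref


def tissue_mass(ref: ReferenceIndividual, tissue: str) -> float:
    """Whole-organ mass in kg: V_tis × D_tis."""
    if tissue not in TISSUES:
        raise InvalidInputError(f"unknown tissue {tissue!r}")
    return ref.V_tis[tissue] * ref.D_tis[tissue]
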