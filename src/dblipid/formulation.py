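"""LNP formulation arithmetic: weight ratios <-> mole percentages.

An LNP formulation lists its lipid components (ionizable lipidoid,
phospholipid, cholesterol, PEG-lipid) either by weight ratio or by mole
percentage. Conversion needs only the molecular weights: mole percentages
are proportional to weight/MW, normalized to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

#: Average molecular weights (Da) of stock formulation components.
STANDARD_MW = {
    "DOPE": 744.03,
    "DSPC": 790.15,
    "cholesterol": 386.65,
    "DMG-PEG2000": 2509.2,
    "MC3": 642.09,
}

MOLAR_SUM_TOLERANCE = 0.1


def weight_to_molar(
    weights: Sequence[float], molecular_weights: Sequence[float]
) -> np.ndarray:
    """Mole percentages (summing to 100) from a weight ratio."""
    w = np.asarray(weights, dtype=float)
    mw = np.asarray(molecular_weights, dtype=float)
    if w.shape != mw.shape:
        raise ValidationError(
            f"length mismatch: {len(w)} weights vs {len(mw)} molecular weights"
        )
    if np.any(w <= 0) or np.any(mw <= 0):
        raise ValidationError("weights and molecular weights must be positive")
    moles = w / mw
    return 100.0 * moles / moles.sum()


def molar_to_weight(
    molar: Sequence[float], molecular_weights: Sequence[float]
) -> np.ndarray:
    """Relative weights (normalized to sum 100) from mole percentages."""
    p = np.asarray(molar, dtype=float)
    mw = np.asarray(molecular_weights, dtype=float)
    if p.shape != mw.shape:
        raise ValidationError(
            f"length mismatch: {len(p)} percentages vs {len(mw)} molecular weights"
        )
    if np.any(p <= 0) or np.any(mw <= 0):
        raise ValidationError("percentages and molecular weights must be positive")
    w = p * mw
    return 100.0 * w / w.sum()


@dataclass
class FormulationSpec:
    """A named LNP recipe over an ordered component list.

    Either ``weight_ratio`` or ``molar_ratio`` (or both) may be given;
    ``validate`` checks internal consistency. ``lipidoid_to_rna_weight``
    is the ionizable-lipid : RNA weight ratio used at mixing.
    """

    name: str
    components: list[tuple[str, float]]  # (component name, MW in Da)
    weight_ratio: list[float] | None = None
    molar_ratio: list[float] | None = None
    lipidoid_to_rna_weight: float | None = None
    notes: list[str] = field(default_factory=list)

    def validate(self) -> "FormulationSpec":
        n = len(self.components)
        for label, ratio in (("weight_ratio", self.weight_ratio), ("molar_ratio", self.molar_ratio)):
            if ratio is not None and len(ratio) != n:
                raise ValidationError(
                    f"{self.name}: {label} length {len(ratio)} != {n} components"
                )
        if self.molar_ratio is not None:
            total = float(np.sum(self.molar_ratio))
            if abs(total - 100.0) > MOLAR_SUM_TOLERANCE:
                raise ValidationError(
                    f"{self.name}: molar ratio sums to {total:.2f}, not 100"
                )
        if self.weight_ratio is None and self.molar_ratio is None:
            raise ValidationError(f"{self.name}: no ratio given")
        return self

    @property
    def molecular_weights(self) -> list[float]:
        return [mw for _, mw in self.components]

    def as_molar(self) -> np.ndarray:
        """Mole percentages, derived from weights when not given directly."""
        self.validate()
        if self.molar_ratio is not None:
            return np.asarray(self.molar_ratio, dtype=float)
        return weight_to_molar(self.weight_ratio, self.molecular_weights)


def screening_formulation(lipidoid_mw: float) -> FormulationSpec:
    """The fixed initial-screening recipe (weight ratio 16:10:10:3, lipid:RNA 10)."""
    return FormulationSpec(
        name="screening",
        components=[
            ("lipidoid", lipidoid_mw),
            ("DOPE", STANDARD_MW["DOPE"]),
            ("cholesterol", STANDARD_MW["cholesterol"]),
            ("DMG-PEG2000", STANDARD_MW["DMG-PEG2000"]),
        ],
        weight_ratio=[16.0, 10.0, 10.0, 3.0],
        lipidoid_to_rna_weight=10.0,
    ).validate()


def optimized_formulation(lipidoid_mw: float) -> FormulationSpec:
    """The optimized lead recipe F5: molar ratio 40/10/48.5/1.5.

    The cholesterol percentage is recorded in two conflicting variants in
    common sources (48.5 vs 48.8); 48.5 is used because only it sums to
    100, and the discrepancy is kept as a validation note.
    """
    spec = FormulationSpec(
        name="F5",
        components=[
            ("lipidoid", lipidoid_mw),
            ("DOPE", STANDARD_MW["DOPE"]),
            ("cholesterol", STANDARD_MW["cholesterol"]),
            ("DMG-PEG2000", STANDARD_MW["DMG-PEG2000"]),
        ],
        molar_ratio=[40.0, 10.0, 48.5, 1.5],
        lipidoid_to_rna_weight=10.0,
        notes=[
            "cholesterol molar % recorded as both 48.5 and 48.8; "
            "48.5 adopted (sums to 100)"
        ],
    )
    return spec.validate()
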