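"""Cell volume to carbon conversion and per-liter concentration helpers.

Cellular carbon follows the allometric power law C = a * V**b (C in pg,
V in um^3), with separate coefficients for diatoms, whose vacuole
dilutes carbon density, and for other protists. The default
coefficients are the widely used log-log regressions

    non-diatom protists: log10 C = -0.665 + 0.939 * log10 V
    diatoms:             log10 C = -0.541 + 0.811 * log10 V

and are shipped as editable configuration rather than constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .taxonomy import DIATOM_LUMP

__all__ = [
    "CarbonModel",
    "carbon_per_cell",
    "concentrations",
    "group_for_class",
    "crossing_volume",
    "DIATOM_CLASSES",
]

#: Whitelist classes treated as diatoms for carbon conversion.
DIATOM_CLASSES = frozenset(
    {"Bacillariophyceae", DIATOM_LUMP, "Coscinodiscophyceae", "Mediophyceae"}
)


@dataclass(frozen=True)
class CarbonModel:
    """Per-group power-law coefficients (a in pg at V=1 um^3, b exponent)."""

    groups: dict = field(
        default_factory=lambda: {
            "non_diatom_protist": (10 ** -0.665, 0.939),
            "diatom": (10 ** -0.541, 0.811),
        }
    )

    def __post_init__(self) -> None:
        for group, (a, b) in self.groups.items():
            if a <= 0:
                raise ValueError(f"group {group!r}: coefficient a must be > 0")
            if not 0 < b <= 1.2:
                raise ValueError(f"group {group!r}: exponent b must be in (0, 1.2]")

    @classmethod
    def from_dict(cls, data: dict) -> "CarbonModel":
        """Build from a config mapping ``{group: {a: ..., b: ...}}``."""
        if not data:
            return cls()
        groups = {}
        for group, coef in data.items():
            if isinstance(coef, dict):
                groups[group] = (float(coef["a"]), float(coef["b"]))
            else:
                a, b = coef
                groups[group] = (float(a), float(b))
        return cls(groups)

    def coefficients(self, group: str) -> tuple[float, float]:
        try:
            return self.groups[group]
        except KeyError:
            raise KeyError(f"unknown carbon-model group {group!r}") from None


def group_for_class(class_name: str) -> str:
    """Map a phytoplankton class to its carbon-model group."""
    return "diatom" if class_name in DIATOM_CLASSES else "non_diatom_protist"


def carbon_per_cell(volume_um3, group: str, model: CarbonModel | None = None):
    """Cellular carbon (pg) for a cell volume (um^3): C = a * V**b.

    Scalar or array volumes; volumes must be strictly positive.
    """
    model = model or CarbonModel()
    a, b = model.coefficients(group)
    v = np.asarray(volume_um3, dtype=float)
    if (v <= 0).any():
        raise ValueError("cell volume must be > 0")
    out = a * v ** b
    return float(out) if np.isscalar(volume_um3) else out


def concentrations(cells_per_liter, volume_um3, group: str, model: CarbonModel | None = None):
    """Per-liter biovolume (um^3/L) and carbon (ugC/L) from cell counts.

    biovolume = c * V; carbon = c * C(V) * 1e-6 (pg -> ug).
    """
    c = np.asarray(cells_per_liter, dtype=float)
    if (c < 0).any():
        raise ValueError("cells_per_liter must be >= 0")
    biovolume = c * np.asarray(volume_um3, dtype=float)
    carbon = c * carbon_per_cell(volume_um3, group, model) * 1e-6
    if np.isscalar(cells_per_liter):
        return float(biovolume), float(carbon)
    return biovolume, carbon


def crossing_volume(model: CarbonModel | None = None,
                    group_a: str = "diatom", group_b: str = "non_diatom_protist") -> float:
    """Volume at which the two group curves cross: (a2/a1)^(1/(b1-b2))."""
    model = model or CarbonModel()
    a1, b1 = model.coefficients(group_a)
    a2, b2 = model.coefficients(group_b)
    if b1 == b2:
        raise ValueError("curves with equal exponents do not cross uniquely")
    return (a2 / a1) ** (1.0 / (b1 - b2))
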