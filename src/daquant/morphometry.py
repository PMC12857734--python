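"""Dendritic spine classification and density normalization.

Spines are split into thin and mushroom classes at a 350 nm 2D head
diameter (the boundary itself is assigned mushroom, a fixed tie-break);
densities are reported per 10 µm of dendrite, and axonal varicosity counts
are normalized to a 10-µm-side cube of tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DendriteSegment",
    "CLASS_BOUNDARY_NM",
    "classify_spines",
    "spine_density",
    "varicosity_density",
]

CLASS_BOUNDARY_NM = 350.0

# Typical analyzed segments are 50-70 µm; lengths far outside that range are
# suspicious inputs and get a warning, not an error.
_PLAUSIBLE_LENGTH_UM = (10.0, 200.0)


@dataclass(frozen=True)
class DendriteSegment:
    """One traced dendritic segment and its spine measurement table."""

    dendrite_id: str
    length_um: float
    spines: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("length_um must be positive")
        lo, hi = _PLAUSIBLE_LENGTH_UM
        if not lo <= self.length_um <= hi:
            warnings.warn(
                f"dendrite {self.dendrite_id}: length {self.length_um} um is "
                f"outside the plausible analysis range [{lo}, {hi}] um",
                UserWarning,
                stacklevel=2,
            )


def classify_spines(records: pd.DataFrame) -> pd.DataFrame:
    """Assign each spine to thin (< 350 nm head diameter) or mushroom (>= 350 nm).

    Returns a copy of the table with a ``spine_class`` column.
    """
    diam = np.asarray(records["head_diameter_nm"], dtype=float)
    if np.any(diam <= 0):
        raise ValueError("head diameters must be positive")
    out = records.copy()
    out["spine_class"] = np.where(diam < CLASS_BOUNDARY_NM, "thin", "mushroom")
    return out


def spine_density(segment: DendriteSegment) -> dict[str, float]:
    """Spine densities per 10 µm of dendrite: total, thin, mushroom.

    density_class = 10 × count_class / length_um; total = thin + mushroom.
    An empty spine table yields zero densities.
    """
    if segment.spines.empty:
        counts = {"thin": 0, "mushroom": 0}
    else:
        table = segment.spines
        if "spine_class" not in table.columns:
            table = classify_spines(table)
        vc = table["spine_class"].value_counts()
        counts = {c: int(vc.get(c, 0)) for c in ("thin", "mushroom")}
    per10 = {c: 10.0 * n / segment.length_um for c, n in counts.items()}
    per10["total"] = per10["thin"] + per10["mushroom"]
    return per10


def varicosity_density(count: int, volume_dims_um: tuple[float, float, float]) -> float:
    """Varicosity count normalized to a 10-µm-side cube (1000 µm³).

    density = count × 1000 / (x·y·z) for stack dimensions in µm.
    """
    x, y, z = volume_dims_um
    if x <= 0 or y <= 0 or z <= 0:
        raise ValueError("volume dimensions must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count * 1000.0 / (x * y * z)
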