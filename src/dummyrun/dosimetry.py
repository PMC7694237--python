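"""DVH computation and dose summary metrics: mean dose, V_x, relative nodal dose.

Voxels are treated as equal-volume (masks are voxelized inputs; no
partial-volume weighting). V_x follows the strict "receiving more than
x Gy" convention; an inclusive variant is available. Relative nodal dose
(RND) is the mean dose in a nodal station divided by the prescription dose
— a plain ratio on physical dose by default, with EQD2 left to the caller's
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, DoseGrid, FractionationScheme

__all__ = [
    "DVH",
    "NodalDoseRecord",
    "cumulative_dvh",
    "volume_receiving",
    "mean_structure_dose",
    "relative_nodal_dose",
]


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure.

    ``cumulative_volume_fraction[k]`` is the fraction of the structure's
    volume receiving at least ``bin_edges[k]`` Gy; it starts at 1 for the
    0 Gy edge and is non-increasing.
    """

    structure_name: str
    bin_edges: np.ndarray  # Gy, ascending from 0
    cumulative_volume_fraction: np.ndarray  # in [0, 1], non-increasing

    def volume_fraction_at(self, dose_gy: float) -> float:
        """Linear interpolation of the cumulative curve at ``dose_gy``."""
        return float(
            np.interp(dose_gy, self.bin_edges, self.cumulative_volume_fraction)
        )


@dataclass
class NodalDoseRecord:
    """Mean dose and relative nodal dose (RND) for one station of one plan."""

    institution_id: str
    case_id: str
    arm: str
    station: str
    mean_dose: float  # Gy
    rnd: float  # mean_dose / prescription, unitless


def _masked(dose: DoseGrid, mask: BinaryMask, op: str) -> np.ndarray:
    if dose.geometry != mask.geometry:
        raise ValueError(f"{op}: dose and mask geometries are incompatible")
    vals = dose.values[mask.values]
    if vals.size == 0:
        raise ValueError(f"{op}: structure mask is empty")
    return vals


def cumulative_dvh(
    dose: DoseGrid,
    mask: BinaryMask,
    bin_width: float = 0.1,
    structure_name: str = "",
) -> DVH:
    """Cumulative DVH with edges from 0 to max dose plus one bin."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = _masked(dose, mask, "cumulative_dvh")
    top = float(vals.max()) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    # fraction of voxels with dose >= edge
    frac = 1.0 - np.searchsorted(np.sort(vals), edges, side="left") / vals.size
    return DVH(structure_name, edges, frac)


def volume_receiving(
    dose: DoseGrid,
    mask: BinaryMask,
    threshold: float,
    inclusive: bool = False,
) -> float:
    """Percent of structure volume receiving more than ``threshold`` Gy.

    Strict ">" by default; set ``inclusive`` for ">=".
    """
    vals = _masked(dose, mask, "volume_receiving")
    hit = vals >= threshold if inclusive else vals > threshold
    return 100.0 * float(np.count_nonzero(hit)) / vals.size


def mean_structure_dose(dose: DoseGrid, mask: BinaryMask) -> float:
    """Unweighted mean dose (Gy) over the masked voxels."""
    return float(_masked(dose, mask, "mean_structure_dose").mean())


def relative_nodal_dose(
    dose: DoseGrid,
    node_mask: BinaryMask,
    scheme: FractionationScheme,
    institution_id: str = "",
    case_id: str = "",
    arm: str = "",
    station: str = "",
) -> NodalDoseRecord:
    """Mean station dose divided by the prescription dose."""
    mean = mean_structure_dose(dose, node_mask)
    return NodalDoseRecord(
        institution_id=institution_id,
        case_id=case_id,
        arm=arm,
        station=station,
        mean_dose=mean,
        rnd=mean / scheme.total_dose,
    )
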