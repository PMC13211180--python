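"""Deterministic conversions from raw assay readouts to reporting units.

Covers the conversions whose constants are fully determined: percent cell
viability from counts, glutathione S-transferase activity from CDNB kinetics
(extinction coefficient 9.6 mM^-1 cm^-1 at 340 nm), and superoxide dismutase
units from pyrogallol-autoxidation inhibition (1 U = 50% inhibition, linear
interpolation). GPx activity and MDA concentration enter the pipeline as
already-computed values; their wet-lab calibrations are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


@dataclass(frozen=True)
class AssayConstants:
    #: CDNB-conjugate extinction coefficient at 340 nm, per mM per cm.
    epsilon_cdnb: float = 9.6
    #: Fraction of autoxidation inhibited by one SOD unit.
    sod_unit_inhibition: float = 0.5

    def __post_init__(self):
        if not (self.epsilon_cdnb > 0 and self.sod_unit_inhibition > 0):
            raise ValueError("assay constants must be strictly positive")


CONSTANTS = AssayConstants()


def cell_viability(viable_count: int, total_count: int) -> float:
    """Percent viable cells: 100 * viable / total.

    Raises
    ------
    ValueError
        If ``total_count`` is not positive or ``viable_count`` exceeds it.
    """
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if viable_count < 0 or viable_count > total_count:
        raise ValueError("viable_count must lie in [0, total_count]")
    return 100.0 * viable_count / total_count


def gst_activity(
    delta_a340_per_min: float,
    path_cm: float = 1.0,
    protein_ug_per_ml: float = 1.0,
    constants: AssayConstants = CONSTANTS,
) -> float:
    """GST specific activity in nmol CDNB conjugated per (ug protein * min).

    The absorbance rate is converted with Beer–Lambert:
    rate[mM/min] = dA/(epsilon * path); 1 mM = 1000 nmol/mL; the volumetric
    rate is then normalised by protein concentration. A negative rate
    (evaporation/baseline drift) clamps to zero with a warning.
    """
    if path_cm <= 0 or protein_ug_per_ml <= 0:
        raise ValueError("path_cm and protein_ug_per_ml must be positive")
    if delta_a340_per_min < 0:
        warnings.warn("negative absorbance rate clamped to 0", stacklevel=2)
        delta_a340_per_min = 0.0
    rate_mm_per_min = delta_a340_per_min / (constants.epsilon_cdnb * path_cm)
    rate_nmol_per_ml_min = rate_mm_per_min * 1000.0
    return rate_nmol_per_ml_min / protein_ug_per_ml


def sod_units(inhibition_fraction: float, constants: AssayConstants = CONSTANTS) -> float:
    """SOD activity in U/mL from the inhibited fraction of autoxidation.

    One unit is the amount inhibiting half the autoxidation rate; activity is
    interpolated linearly through (0 -> 0 U, 0.5 -> 1 U), the standard
    pyrogallol-assay convention. Complete inhibition lies outside the linear
    range and is rejected. Per-mg-protein normalisation is the caller's.
    """
    if not (0.0 <= inhibition_fraction < 1.0):
        raise ValueError("inhibition_fraction must lie in [0, 1)")
    return inhibition_fraction / constants.sod_unit_inhibition
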