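"""Open-beam cross-plane profile analysis.

A profile normalized at the central beam axis (CAX) is partitioned into
three regions by dose level: central (>= 80% of CAX, the flattened area),
penumbra (between 20% and 80%, the field-edge fall-off) and out-of-field
(<= 20%).  Calculated-vs-measured agreement is quantified per region with
the Venselaar curve-quality metrics:

    delta              = 100% * (D_calc - D_meas) / D_meas          (central)
    delta_out_of_field = 100% * (D_calc - D_meas) / D_meas,CAX
    penumbra DTA       = lateral distance between iso-level crossings (mm)

Boundary assignment: exactly 80% is central, exactly 20% is out-of-field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InvalidParameterError

__all__ = [
    "Profile", "RegionReport",
    "classify_regions", "delta_dose", "delta_out_of_field", "penumbra_dta",
    "compare_profiles",
    "CENTRAL", "PENUMBRA", "OUT_OF_FIELD",
]

CENTRAL = "central"
PENUMBRA = "penumbra"
OUT_OF_FIELD = "out_of_field"


@dataclass
class Profile:
    """Cross-plane dose profile, normalized at the CAX.

    ``positions`` (mm) strictly increasing; ``values`` relative dose with
    CAX = 100 (or any positive ``cax_value`` used as the normalization dose).
    """

    positions: np.ndarray
    values: np.ndarray
    cax_value: float = 100.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.cax_value <= 0:
            raise ValueError("cax_value must be positive")


@dataclass
class RegionReport:
    """Per-region deviation summary of a calculated-vs-measured profile pair."""

    labels: np.ndarray            # region label per sample (of the measured)
    delta_central: float          # mean Venselaar delta over central samples, %
    delta_central_sd: float
    delta_out_of_field: float     # mean out-of-field delta, %
    delta_out_of_field_sd: float
    penumbra_dta: float           # mm, averaged over both field edges


def classify_regions(profile: Profile) -> np.ndarray:
    """Label every sample central / penumbra / out_of_field (exhaustive and
    exclusive): >= 80% of CAX central, <= 20% out-of-field, else penumbra."""
    rel = profile.values / profile.cax_value * 100.0
    labels = np.where(
        rel >= 80.0, CENTRAL, np.where(rel <= 20.0, OUT_OF_FIELD, PENUMBRA)
    )
    return labels


def delta_dose(calculated: float, measured: float) -> float:
    """Venselaar signed percent difference, local denominator."""
    if measured <= 0:
        raise InvalidParameterError(
            "measured dose must be positive (use delta_out_of_field "
            "for near-zero doses)"
        )
    return 100.0 * (calculated - measured) / measured


def delta_out_of_field(calculated: float, measured: float,
                       cax_measured: float) -> float:
    """Venselaar out-of-field difference, normalized to the measured CAX."""
    if cax_measured <= 0:
        raise InvalidParameterError("cax_measured must be positive")
    return 100.0 * (calculated - measured) / cax_measured


def _level_crossings(profile: Profile, level: float) -> list[float]:
    """Positions where the (linearly interpolated) profile crosses
    ``level`` percent of CAX, one per field edge (rising then falling)."""
    rel = profile.values / profile.cax_value * 100.0
    x = profile.positions
    above = rel >= level
    crossings: list[float] = []
    for i in range(len(x) - 1):
        if above[i] != above[i + 1]:
            f = (level - rel[i]) / (rel[i + 1] - rel[i])
            crossings.append(float(x[i] + f * (x[i + 1] - x[i])))
    return crossings


def penumbra_dta(calculated: Profile, measured: Profile,
                 level: float = 50.0) -> float:
    """Distance to agreement (mm) between the iso-level crossings of the two
    profiles, averaged over both field edges.

    ``level`` is the iso-dose level in percent of CAX (default 50, within
    the 20-80% penumbra band).
    """
    if not (0 < level < 100):
        raise InvalidParameterError("level must be in (0, 100) percent")
    c = _level_crossings(calculated, level)
    m = _level_crossings(measured, level)
    if not c or not m:
        raise GeometryError(f"profile never crosses the {level}% level")
    # pair the outermost rising and falling crossings (left/right field edges)
    edges = []
    if len(c) >= 1 and len(m) >= 1:
        edges.append(abs(c[0] - m[0]))
    if len(c) >= 2 and len(m) >= 2:
        edges.append(abs(c[-1] - m[-1]))
    return float(np.mean(edges))


def compare_profiles(calculated: Profile, measured: Profile,
                     level: float = 50.0) -> RegionReport:
    """Region-resolved deviation report for a calculated/measured pair.

    Both profiles must be sampled at the same positions; the regions are
    taken from the measured profile (the reference).
    """
    if not np.allclose(calculated.positions, measured.positions):
        raise GeometryError("profiles must share sample positions")
    labels = classify_regions(measured)
    cen = labels == CENTRAL
    oof = labels == OUT_OF_FIELD
    d_cen = np.array([
        delta_dose(c, m) for c, m in
        zip(calculated.values[cen], measured.values[cen])
    ]) if cen.any() else np.array([np.nan])
    d_oof = np.array([
        delta_out_of_field(c, m, measured.cax_value) for c, m in
        zip(calculated.values[oof], measured.values[oof])
    ]) if oof.any() else np.array([np.nan])
    return RegionReport(
        labels=labels,
        delta_central=float(np.mean(d_cen)),
        delta_central_sd=float(np.std(d_cen)),
        delta_out_of_field=float(np.mean(d_oof)),
        delta_out_of_field_sd=float(np.std(d_oof)),
        penumbra_dta=penumbra_dta(calculated, measured, level=level),
    )
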