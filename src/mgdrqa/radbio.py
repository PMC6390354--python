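"""DVH construction, DVH metrics, EUD, TCP and NTCP models.

TCP uses the EUD-based logistic

    TCP = 1 / (1 + (TCD50 / EUD)^(4*gamma50))

where EUD is the generalized-mean dose ``(sum dv_i * D_i^a)^(1/a)`` over the
differential DVH (a < 0 for tumors emphasizes cold spots) and gamma50 is the
normalized dose-response slope at TCD50.

NTCP uses the relative seriality model over the M bins of the differential
DVH:

    NTCP = [ 1 - prod_i (1 - P(D_i)^s)^(dv_i) ]^(1/s)
    P(D) = 2^( -exp( e * gamma * (1 - D / D50) ) )

with s the relative seriality parameter (s -> 1 serial, s -> 0 parallel);
``e`` is Euler's number, so a uniform organ dose of D50 gives P = 1/2 and
NTCP = 1/2 for every s.

DVH curves carry a representative dose per bin (the mean of the voxel doses
that fell into it) so that generalized means over the curve are exact for
piecewise-uniform dose distributions, not just accurate to half a bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .errors import DegenerateInputError, InvalidParameterError
from .grids import DoseGrid, StructureMask

__all__ = [
    "DVHCurve", "TCPParams", "NTCPParams",
    "build_dvh", "metric_D", "metric_V", "metric_Dmean",
    "eud", "tcp", "ntcp_relative_seriality",
    "load_registry", "default_registry",
]


@dataclass
class DVHCurve:
    """Differential + cumulative dose-volume histogram.

    ``bin_edges`` has M+1 entries (Gy); ``differential`` the fractional
    volume per bin (sums to 1); ``bin_doses`` a representative dose per bin
    (in-bin mean where occupied, bin center otherwise); ``cumulative`` the
    fraction of volume receiving at least each edge dose (M+1 entries,
    non-increasing, starts at 1).
    """

    bin_edges: np.ndarray
    differential: np.ndarray
    bin_doses: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        s = float(self.differential.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"differential DVH sums to {s}, not 1")
        if np.any(np.diff(self.cumulative) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")


@dataclass(frozen=True)
class TCPParams:
    """EUD-based logistic TCP parameters."""

    tcd50: float          # dose for 50% control probability, Gy
    gamma50: float        # normalized response slope at TCD50
    eud_a: float = -10.0  # volume-effect exponent (negative for tumors)

    def __post_init__(self) -> None:
        if self.tcd50 <= 0:
            raise InvalidParameterError("tcd50 must be positive")
        if self.gamma50 <= 0:
            raise InvalidParameterError("gamma50 must be positive")


@dataclass(frozen=True)
class NTCPParams:
    """Relative seriality NTCP parameters."""

    d50: float    # dose for 50% complication probability, Gy
    gamma: float  # maximum normalized response slope
    s: float      # relative seriality (1 serial, -> 0 parallel)

    def __post_init__(self) -> None:
        if self.d50 <= 0:
            raise InvalidParameterError("d50 must be positive")
        if self.gamma <= 0:
            raise InvalidParameterError("gamma must be positive")
        if self.s <= 0:
            raise InvalidParameterError("s must be positive")


def build_dvh(dose: DoseGrid, mask: StructureMask,
              bin_width: float = 0.01) -> DVHCurve:
    """Voxel-counting DVH of the in-mask doses with the given bin width (Gy)."""
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    mask.require_congruent(dose)
    doses = dose.values[mask.mask]
    if doses.size == 0:
        raise DegenerateInputError(f"structure '{mask.name}' mask is empty")
    top = max(float(doses.max()), bin_width)
    n_bins = int(np.ceil(top / bin_width + 1e-9)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(doses, bins=edges)
    dose_sums, _ = np.histogram(doses, bins=edges, weights=doses)
    differential = counts / doses.size
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_doses = np.where(counts > 0, dose_sums / np.maximum(counts, 1), centers)
    cumulative = np.concatenate([
        np.cumsum(differential[::-1])[::-1], [0.0]
    ])
    return DVHCurve(bin_edges=edges, differential=differential,
                    bin_doses=bin_doses, cumulative=cumulative)


def metric_D(curve: DVHCurve, volume_fraction: float) -> float:
    """D_x%: greatest dose (Gy) still covering ``volume_fraction`` percent of
    the volume, linearly interpolated on the cumulative curve (>= convention).
    """
    if not (0 < volume_fraction <= 100):
        raise InvalidParameterError("volume_fraction must be in (0, 100]")
    q = volume_fraction / 100.0
    c = curve.cumulative
    e = curve.bin_edges
    idx = np.nonzero(c >= q - 1e-15)[0]
    if idx.size == 0:
        return 0.0
    j = int(idx[-1])
    if j == len(e) - 1:
        return float(e[-1])
    drop = c[j] - c[j + 1]
    if drop <= 0:
        return float(e[j])
    frac = (c[j] - q) / drop
    return float(e[j] + frac * (e[j + 1] - e[j]))


def metric_V(curve: DVHCurve, dose_level: float) -> float:
    """V_xGy: percent of the volume receiving at least ``dose_level`` Gy,
    linearly interpolated on the cumulative curve."""
    if dose_level < 0:
        raise InvalidParameterError("dose_level must be non-negative")
    e = curve.bin_edges
    c = curve.cumulative
    if dose_level >= e[-1]:
        return 0.0
    return float(100.0 * np.interp(dose_level, e, c))


def metric_Dmean(dose: DoseGrid, mask: StructureMask) -> float:
    """Arithmetic mean in-mask dose (Gy)."""
    mask.require_congruent(dose)
    doses = dose.values[mask.mask]
    if doses.size == 0:
        raise DegenerateInputError(f"structure '{mask.name}' mask is empty")
    return float(doses.mean())


def eud(curve: DVHCurve, a: float, dose_floor: float = 0.01) -> float:
    """Generalized-mean (equivalent uniform) dose over the differential DVH.

    For a < 0 any zero-dose bin would force EUD -> 0; bin doses are clamped
    to ``dose_floor`` (Gy) first, a numerical guard for that clinically
    degenerate limit.
    """
    if a == 0:
        raise InvalidParameterError("EUD exponent a must be nonzero")
    occ = curve.differential > 0
    dv = curve.differential[occ]
    d = np.maximum(curve.bin_doses[occ], dose_floor if a < 0 else 0.0)
    d_max = float(d.max())
    if d_max <= 0:
        return 0.0
    # normalize by the max dose so d^a cannot overflow for large |a|
    return float(d_max * np.sum(dv * (d / d_max) ** a) ** (1.0 / a))


def tcp(eud_dose: float, params: TCPParams) -> float:
    """EUD-based logistic tumor control probability in (0, 1)."""
    if eud_dose <= 0:
        raise InvalidParameterError("EUD dose must be positive")
    return float(1.0 / (1.0 + (params.tcd50 / eud_dose) ** (4.0 * params.gamma50)))


def ntcp_relative_seriality(curve: DVHCurve, params: NTCPParams) -> float:
    """Relative seriality NTCP over the differential DVH bins."""
    s = float(curve.differential.sum())
    if abs(s - 1.0) > 1e-6:
        raise InvalidParameterError(
            f"differential DVH must be normalized (sums to {s})"
        )
    occ = curve.differential > 0
    dv = curve.differential[occ]
    d = curve.bin_doses[occ]
    # P(D) = 2^{-exp(e*gamma*(1 - D/D50))}
    p = np.exp(-np.log(2.0) * np.exp(np.e * params.gamma * (1.0 - d / params.d50)))
    p_s = np.minimum(p, 1.0) ** params.s
    if np.any(p_s >= 1.0):
        return 1.0
    # log-space product; expm1/log1p keep the uniform-dose identity exact
    log_prod = np.sum(dv * np.log1p(-p_s))
    inner = -np.expm1(log_prod)          # 1 - prod (1 - P^s)^dv
    return float(np.clip(inner ** (1.0 / params.s), 0.0, 1.0))


# -- parameter registry -----------------------------------------------------

def load_registry(path=None) -> dict:
    """Load the tissue-parameter registry (structure -> model parameters).

    Without ``path`` the registry shipped with the package is used.  Returns
    a dict ``{structure: {"model": ..., "params": TCPParams|NTCPParams,
    "endpoint": ...}}``.
    """
    if path is None:
        text = resources.files("mgdrqa.data").joinpath(
            "radiobio_params.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out: dict = {}
    for name, entry in raw["structures"].items():
        model = entry["model"]
        if model == "tcp_eud":
            params = TCPParams(tcd50=float(entry["tcd50"]),
                               gamma50=float(entry["gamma50"]),
                               eud_a=float(entry["eud_a"]))
        elif model == "relative_seriality":
            params = NTCPParams(d50=float(entry["d50"]),
                                gamma=float(entry["gamma"]),
                                s=float(entry["s"]))
        else:
            raise InvalidParameterError(f"unknown model '{model}' for {name}")
        out[name] = {"model": model, "params": params,
                     "endpoint": entry.get("endpoint", "")}
    return out


def default_registry() -> dict:
    return load_registry()
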