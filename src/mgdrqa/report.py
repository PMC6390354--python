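"""End-to-end QA run and the comparison report.

``run_qa`` executes the whole chain on a plan bundle:

    per-beam error map -> ray-traced reconstruction -> predicted total dose
    -> 2D gamma per beam (10% lower threshold)
    -> 3D and per-organ gamma (3% lower threshold)
    -> DVH metrics, TCP and NTCP for planned and predicted doses

and collects everything into a :class:`QAReport` whose layout mirrors the
standard QA summary: a per-criteria 2D GPR table, a per-organ 3D GPR table,
and a planned/predicted/deviation table of clinically relevant indices
(PTV D95% and TCP, lung V5Gy / V20Gy and NTCP, heart Dmean and NTCP).
Deviations are always predicted minus planned.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import __version__
from .errors import UndefinedRateError
from .gamma import GammaCriteria, gamma_field, passing_rate
from .grids import PlanBundle
from .mgdr import compute_error_map, predict_total, reconstruct_beam
from .radbio import (
    build_dvh, eud, metric_D, metric_Dmean, metric_V,
    ntcp_relative_seriality, tcp, load_registry,
)

__all__ = ["QAConfig", "QAReport", "run_qa", "export_report"]

DEFAULT_CRITERIA = ((3.0, 3.0), (3.0, 2.0), (2.0, 2.0))


@dataclass(frozen=True)
class QAConfig:
    """Configuration of the QA chain.

    ``criteria`` are (dose %, DTA mm) pairs evaluated for both 2D and 3D
    analysis; the lower thresholds follow the usual convention of 10% for
    detector-plane QA and 3% for 3D patient-dose comparison.  The gamma
    interpolation step is DTA/10 in 2D; in 3D it is DTA/5, sub-voxel on a
    2-mm dose grid and converged well below the reporting precision.
    """

    criteria: tuple = DEFAULT_CRITERIA
    threshold_2d: float = 10.0
    threshold_3d: float = 3.0
    min_dose_fraction: float = 0.05
    clamp: tuple = (0.5, 2.0)
    dvh_bin_width: float = 0.05
    interp_step_2d: float = 0.1
    interp_step_3d: float = 0.2
    registry_path: str | None = None
    organs: tuple = ("PTV", "ipsilateral_lung", "heart")
    seed: int | None = None

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class QAReport:
    """Structured result of one QA run."""

    gpr_2d: dict          # beam -> criteria label -> {gpr, evaluated}
    gpr_2d_mean: dict     # criteria label -> mean over beams
    gpr_3d: dict          # criteria label -> {total, evaluated, per_organ}
    indices: dict         # planned / predicted / deviation index tables
    reconstruction: dict  # per-beam diagnostics
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _label(c: tuple) -> str:
    return f"{c[0]:g}%/{c[1]:g}mm"


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(float(x), nd))


def _indices_for(dose, bundle: PlanBundle, registry, bin_width: float) -> dict:
    """Clinically relevant dose-volume indices of one 3D dose distribution."""
    out: dict = {}
    ptv = bundle.structure("PTV")
    lung = bundle.structure("ipsilateral_lung")
    heart = bundle.structure("heart")

    dvh_ptv = build_dvh(dose, ptv, bin_width)
    dvh_lung = build_dvh(dose, lung, bin_width)
    dvh_heart = build_dvh(dose, heart, bin_width)

    out["ptv_d95_gy"] = _round(metric_D(dvh_ptv, 95.0))
    out["lung_v5gy_pct"] = _round(metric_V(dvh_lung, 5.0))
    out["lung_v20gy_pct"] = _round(metric_V(dvh_lung, 20.0))
    out["heart_dmean_gy"] = _round(metric_Dmean(dose, heart))

    p = registry["PTV"]["params"]
    ptv_eud = eud(dvh_ptv, p.eud_a)
    out["ptv_eud_gy"] = _round(ptv_eud)
    out["ptv_tcp"] = _round(tcp(ptv_eud, p))
    out["lung_ntcp"] = _round(
        ntcp_relative_seriality(dvh_lung, registry["ipsilateral_lung"]["params"])
    )
    out["heart_ntcp"] = _round(
        ntcp_relative_seriality(dvh_heart, registry["heart"]["params"])
    )
    return out


def run_qa(bundle: PlanBundle, config: QAConfig = QAConfig()) -> QAReport:
    """Execute the full measurement-guided QA chain on a plan bundle."""
    registry = load_registry(config.registry_path)

    # --- per-beam 2D gamma (measured is the reference) and reconstruction
    gpr_2d: dict = {}
    recon_info: dict = {}
    predicted_beams = []
    for beam in bundle.beams:
        emap = compute_error_map(
            beam.planned_planar, beam.measured_planar,
            min_dose_fraction=config.min_dose_fraction,
            sad=beam.geometry.sad,
        )
        pred, info = reconstruct_beam(
            beam.planned_dose, emap, beam.geometry,
            clamp=config.clamp, return_info=True,
        )
        predicted_beams.append(pred)
        recon_info[beam.name] = {
            "out_of_map_rays": info.n_out_of_map,
            "clamped_ratios": info.n_clamped,
        }
        gpr_2d[beam.name] = {}
        for c in config.criteria:
            crit = GammaCriteria(
                dose_tolerance=c[0], dta=c[1],
                lower_threshold=config.threshold_2d,
                interp_step_fraction=config.interp_step_2d,
            )
            res = gamma_field(beam.measured_planar, beam.planned_planar, crit)
            gpr_2d[beam.name][_label(c)] = {
                "gpr_pct": _round(res.passing_rate, 4),
                "evaluated": res.evaluated_count,
            }

    gpr_2d_mean = {
        _label(c): _round(float(np.mean(
            [gpr_2d[b.name][_label(c)]["gpr_pct"] for b in bundle.beams]
        )), 4)
        for c in config.criteria
    }

    predicted_total = predict_total(predicted_beams)

    # --- 3D gamma, planned total as reference
    gpr_3d: dict = {}
    for c in config.criteria:
        crit = GammaCriteria(
            dose_tolerance=c[0], dta=c[1],
            lower_threshold=config.threshold_3d,
            interp_step_fraction=config.interp_step_3d,
        )
        res = gamma_field(bundle.total_planned, predicted_total, crit)
        per_organ = {}
        for organ in config.organs:
            try:
                per_organ[organ] = _round(
                    passing_rate(res, bundle.structure(organ)), 4)
            except UndefinedRateError:
                per_organ[organ] = None
        gpr_3d[_label(c)] = {
            "total_pct": _round(res.passing_rate, 4),
            "evaluated": res.evaluated_count,
            "per_organ_pct": per_organ,
        }

    # --- clinically relevant indices
    planned_idx = _indices_for(bundle.total_planned, bundle, registry,
                               config.dvh_bin_width)
    predicted_idx = _indices_for(predicted_total, bundle, registry,
                                 config.dvh_bin_width)
    deviation = {k: _round(predicted_idx[k] - planned_idx[k])
                 for k in planned_idx}

    provenance = {
        "package": "mgdrqa",
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "prescription_gy": bundle.prescription_dose,
        "n_beams": len(bundle.beams),
    }
    return QAReport(
        gpr_2d=gpr_2d,
        gpr_2d_mean=gpr_2d_mean,
        gpr_3d=gpr_3d,
        indices={"planned": planned_idx, "predicted": predicted_idx,
                 "deviation": deviation},
        reconstruction=recon_info,
        provenance=provenance,
    )


def export_report(report: QAReport, path, fmt: str = "json") -> None:
    """Write the report as json (lossless), tsv (tabular) or text."""
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, sort_keys=True, indent=2)
            fh.write("\n")
    elif fmt == "tsv":
        lines = ["section\tname\tcriteria\tvalue"]
        for beam, per_crit in sorted(report.gpr_2d.items()):
            for lab, entry in per_crit.items():
                lines.append(f"gpr_2d\t{beam}\t{lab}\t{entry['gpr_pct']}")
        for lab, entry in report.gpr_3d.items():
            lines.append(f"gpr_3d\ttotal\t{lab}\t{entry['total_pct']}")
            for organ, v in entry["per_organ_pct"].items():
                lines.append(f"gpr_3d\t{organ}\t{lab}\t{v}")
        for table in ("planned", "predicted", "deviation"):
            for k, v in report.indices[table].items():
                lines.append(f"index\t{k}\t{table}\t{v}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    elif fmt == "text":
        with open(path, "w") as fh:
            fh.write(format_text(report))
    else:
        raise ValueError(f"unknown report format '{fmt}'")


def format_text(report: QAReport) -> str:
    out = ["=== Measurement-guided QA report ==="]
    out.append("-- provenance --")
    for k, v in sorted(report.provenance.items()):
        out.append(f"  {k}: {v}")
    out.append("-- per-beam 2D GPR (%) --")
    for beam, per_crit in sorted(report.gpr_2d.items()):
        row = ", ".join(f"{lab}: {e['gpr_pct']}" for lab, e in per_crit.items())
        out.append(f"  {beam}: {row}")
    out.append("  mean: " + ", ".join(
        f"{lab}: {v}" for lab, v in report.gpr_2d_mean.items()))
    out.append("-- predicted 3D GPR (%) --")
    for lab, entry in report.gpr_3d.items():
        organs = ", ".join(f"{o}: {v}" for o, v in
                           entry["per_organ_pct"].items())
        out.append(f"  {lab}: total {entry['total_pct']} | {organs}")
    out.append("-- clinically relevant indices (planned / predicted / "
               "deviation) --")
    for k in report.indices["planned"]:
        out.append(
            f"  {k}: {report.indices['planned'][k]} / "
            f"{report.indices['predicted'][k]} / "
            f"{report.indices['deviation'][k]}"
        )
    return "\n".join(out) + "\n"
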