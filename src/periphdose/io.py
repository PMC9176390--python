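"""File formats, run configuration, validation and the end-to-end runner.

All interchange formats are plain text — CSV for tables, JSON for the
calibration set, YAML for the registry/assignment and run configuration.
Numeric CSV output keeps full precision; rounded, human-readable reporting
is left to the CLI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conversion import ConversionTable, load_qk, read_coefficient_csv
from .errors import InvalidDomainError, PeriphdoseError, UnresolvedAssignmentError
from .organs import (
    OrganAssignment,
    OrganDose,
    PhantomPoint,
    default_assignment,
    dose_vs_distance,
    organ_equivalent_dose,
)
from .pipeline import PointDose, UncertaintyBudget, point_dose_chain
from .spectra import read_spectrum_csv
from .tld import CalibrationSet, TLDPairReading
from .unfolding import ResponseMatrix, SphereCountSet
from .spectra import EnergyGrid

__all__ = [
    "RunConfig",
    "read_tld_csv",
    "write_tld_csv",
    "read_counts_csv",
    "write_counts_csv",
    "read_response_csv",
    "write_response_csv",
    "read_calibration_json",
    "write_calibration_json",
    "read_phantom_yaml",
    "write_phantom_yaml",
    "write_point_dose_csv",
    "write_organ_dose_csv",
    "validate_inputs",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# readers / writers

def read_tld_csv(path) -> list[TLDPairReading]:
    df = pd.read_csv(path, comment="#")
    required = {"point_id", "r600_au", "r700_au"}
    if not required.issubset(df.columns):
        raise InvalidDomainError(f"{path}: expected columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            TLDPairReading(
                point_id=int(row["point_id"]),
                r600=float(row["r600_au"]),
                r700=float(row["r700_au"]),
                u_r600=float(row.get("u_r600", 0.0) or 0.0),
                u_r700=float(row.get("u_r700", 0.0) or 0.0),
            )
        )
    return out


def write_tld_csv(readings: list[TLDPairReading], path) -> None:
    pd.DataFrame(
        [
            {
                "point_id": r.point_id,
                "r600_au": r.r600,
                "r700_au": r.r700,
                "u_r600": r.u_r600,
                "u_r700": r.u_r700,
            }
            for r in readings
        ]
    ).to_csv(path, index=False, lineterminator="\n")


def read_counts_csv(path) -> SphereCountSet:
    df = pd.read_csv(path, comment="#")
    required = {"sphere_id", "count_rate", "u_count"}
    if not required.issubset(df.columns):
        raise InvalidDomainError(f"{path}: expected columns {sorted(required)}")
    return SphereCountSet(
        df["sphere_id"].astype(str).tolist(),
        df["count_rate"].to_numpy(float),
        df["u_count"].to_numpy(float),
    )


def write_counts_csv(counts: SphereCountSet, path) -> None:
    pd.DataFrame(
        {
            "sphere_id": counts.sphere_ids,
            "count_rate": counts.counts,
            "u_count": counts.uncertainties,
        }
    ).to_csv(path, index=False, lineterminator="\n")


def write_response_csv(rm: ResponseMatrix, path) -> None:
    """First column sphere id, one column per bin headed by its lower edge;
    the final edge is carried in a comment line."""
    cols = [f"{e:.8g}" for e in rm.grid.edges[:-1]]
    df = pd.DataFrame(rm.response, columns=cols)
    df.insert(0, "sphere_id", rm.sphere_ids)
    with open(path, "w") as fh:
        fh.write(f"# last_edge: {rm.grid.edges[-1]:.8g}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_response_csv(path) -> ResponseMatrix:
    last_edge = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "last_edge:" in line:
                last_edge = float(line.split("last_edge:")[1])
            if not line.startswith("#"):
                break
    if last_edge is None:
        raise InvalidDomainError(f"{path}: missing '# last_edge:' header")
    df = pd.read_csv(path, comment="#")
    ids = df["sphere_id"].astype(str).tolist()
    lowers = np.array([float(c) for c in df.columns[1:]])
    grid = EnergyGrid(np.concatenate((lowers, [last_edge])))
    return ResponseMatrix(ids, grid, df.iloc[:, 1:].to_numpy(float))


def read_calibration_json(path) -> CalibrationSet:
    with open(path) as fh:
        data = json.load(fh)
    return CalibrationSet(**data)


def write_calibration_json(calib: CalibrationSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "f_n": calib.f_n,
                "u_f_n_rel": calib.u_f_n_rel,
                "f700_gamma": calib.f700_gamma,
                "u_f700_rel": calib.u_f700_rel,
                "f600_gamma": calib.f600_gamma,
                "u_f600_rel": calib.u_f600_rel,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def write_phantom_yaml(assignment: OrganAssignment, path) -> None:
    data = {
        "points": [
            {"id": p.id, "label": p.label, "distance_cc_cm": p.distance_cc_cm}
            for p in assignment.registry.values()
        ],
        "organs": {k: list(v) for k, v in assignment.organs.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_phantom_yaml(path) -> OrganAssignment:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    registry = {
        int(p["id"]): PhantomPoint(int(p["id"]), str(p["label"]), float(p["distance_cc_cm"]))
        for p in data["points"]
    }
    organs = {str(k): [int(x) for x in v] for k, v in data["organs"].items()}
    return OrganAssignment(organs=organs, registry=registry)


def write_point_dose_csv(point_doses: list[PointDose], registry, path) -> None:
    rows = []
    for p in point_doses:
        rows.append(
            {
                "point_id": p.point_id,
                "distance_cm": registry[p.point_id].distance_cc_cm,
                "h_gamma_msv": p.h_gamma,
                "u_h_gamma": p.u_gamma,
                "h_neutron_msv": p.h_neutron,
                "u_h_neutron": p.u_neutron,
                "h_total_msv": p.h_total,
                "u_h_total": p.u_total,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "point_id",
            "distance_cm",
            "h_gamma_msv",
            "u_h_gamma",
            "h_neutron_msv",
            "u_h_neutron",
            "h_total_msv",
            "u_h_total",
        ],
    ).to_csv(path, index=False, lineterminator="\n")


def write_organ_dose_csv(organ_doses: list[OrganDose], path) -> None:
    pd.DataFrame(
        [
            {
                "organ": o.organ,
                "h_msv_per_gy": o.h_equivalent,
                "u": o.u,
                "n_points": o.n_points,
            }
            for o in organ_doses
        ]
    ).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Paths and knobs for an end-to-end pipeline run.

    Unset paths fall back to the bundled defaults (calibration factors,
    phantom registry/assignment, Q·k table).
    """

    tld_csv: str | Path = "tld.csv"
    spectra_dir: str | Path = "spectra"
    calibration: str | Path | None = None
    phantom: str | Path | None = None
    qk_table: str | Path | None = None
    budget: dict = dc_field(default_factory=dict)
    seed: int = 0
    outdir: str | Path = "out"
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        base = Path(path).parent
        for attr in ("tld_csv", "spectra_dir", "calibration", "phantom", "qk_table", "outdir"):
            v = getattr(cfg, attr)
            if v is not None and not Path(v).is_absolute():
                setattr(cfg, attr, base / v)
        return cfg

    def load_calibration(self) -> CalibrationSet:
        return read_calibration_json(self.calibration) if self.calibration else CalibrationSet()

    def load_assignment(self) -> OrganAssignment:
        return read_phantom_yaml(self.phantom) if self.phantom else default_assignment()

    def load_qk(self) -> ConversionTable:
        return read_coefficient_csv(self.qk_table, "qk") if self.qk_table else load_qk()

    def load_budget(self) -> UncertaintyBudget:
        return UncertaintyBudget(**self.budget)


# ---------------------------------------------------------------------------
# validation

def validate_inputs(config: RunConfig) -> list[str]:
    """Schema/consistency check of every referenced input; returns violations.

    Never raises on bad content and never mutates inputs — each problem is
    one entry naming the file and the offence.
    """
    violations: list[str] = []

    tld_path = Path(config.tld_csv)
    readings: list[TLDPairReading] = []
    if not tld_path.exists():
        violations.append(f"{tld_path}: missing TLD file")
    else:
        try:
            readings = read_tld_csv(tld_path)
        except Exception as exc:  # noqa: BLE001 - report, not raise
            violations.append(f"{tld_path}: {exc}")

    spectra_dir = Path(config.spectra_dir)
    if not spectra_dir.is_dir():
        violations.append(f"{spectra_dir}: missing spectra directory")
    else:
        for r in readings:
            spath = spectra_dir / f"point_{r.point_id}.csv"
            if not spath.exists():
                violations.append(f"{spath}: missing spectrum for point {r.point_id}")
                continue
            try:
                spec = read_spectrum_csv(spath)
            except Exception as exc:  # noqa: BLE001
                violations.append(f"{spath}: {exc}")
                continue
            if spec.total() <= 0.0:
                violations.append(f"{spath}: zero total fluence")

    if config.calibration:
        try:
            config.load_calibration()
        except Exception as exc:  # noqa: BLE001
            violations.append(f"{config.calibration}: {exc}")
    if config.phantom:
        try:
            config.load_assignment()
        except Exception as exc:  # noqa: BLE001
            violations.append(f"{config.phantom}: {exc}")
    if config.qk_table:
        try:
            config.load_qk()
        except Exception as exc:  # noqa: BLE001
            violations.append(f"{config.qk_table}: {exc}")
    try:
        config.load_budget()
    except Exception as exc:  # noqa: BLE001
        violations.append(f"budget: {exc}")
    return violations


# ---------------------------------------------------------------------------
# end-to-end run

def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """TLD readouts + per-point unit spectra → point doses → organ doses.

    Writes ``point_doses.csv``, ``organ_doses.csv`` and ``run.log`` into the
    output directory and returns their paths.  Missing per-point spectra are
    reported together in one error.
    """
    calib = config.load_calibration()
    assignment = config.load_assignment()
    qk = config.load_qk()
    budget = config.load_budget()
    readings = read_tld_csv(config.tld_csv)
    spectra_dir = Path(config.spectra_dir)

    missing = [
        r.point_id
        for r in readings
        if not (spectra_dir / f"point_{r.point_id}.csv").exists()
    ]
    if missing:
        raise UnresolvedAssignmentError(
            f"missing unit spectra for point(s) {missing} in {spectra_dir}"
        )

    warnings_log: list[str] = []
    point_doses = []
    for r in readings:
        spec = read_spectrum_csv(spectra_dir / f"point_{r.point_id}.csv")
        if spec.normalization != "unit":
            from .spectra import normalize

            spec = normalize(spec)
            warnings_log.append(f"point {r.point_id}: spectrum renormalized to unit")
        try:
            point_doses.append(point_dose_chain(r, spec, qk, calib, budget))
        except PeriphdoseError as exc:
            raise PeriphdoseError(f"point {r.point_id}: {exc}") from exc

    organ_doses = organ_equivalent_dose(point_doses, assignment)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    point_path = outdir / "point_doses.csv"
    organ_path = outdir / "organ_doses.csv"
    log_path = outdir / "run.log"
    write_point_dose_csv(point_doses, assignment.registry, point_path)
    write_organ_dose_csv(organ_doses, organ_path)
    distance_table = dose_vs_distance(point_doses, assignment.registry)
    distance_table.to_csv(outdir / "dose_vs_distance.csv", index=False, lineterminator="\n")
    with open(log_path, "w") as fh:
        fh.write(f"periphdose {__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"tld: {config.tld_csv}\nspectra: {config.spectra_dir}\n")
        fh.write(f"points: {len(point_doses)}\norgans: {len(organ_doses)}\n")
        for w in warnings_log:
            fh.write(f"warning: {w}\n")
    return {"point_doses": point_path, "organ_doses": organ_path, "log": log_path}
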