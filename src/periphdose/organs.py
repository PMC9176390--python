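"""Phantom point registry and point-to-organ equivalent-dose aggregation.

Organs in the anthropomorphic phantom are represented by small sets of
instrumented detector points; the organ equivalent dose is the equal-weight
arithmetic mean of the total dose equivalent at its points, with the
uncertainty of the mean propagated assuming independent points,
u = sqrt(Σ uᵢ²) / n.  An optional ``correlated_model`` toggle treats the
transport-model systematic as fully correlated across points: it is removed
from each point in quadrature, the mean is propagated, and the component is
re-applied to the averaged neutron dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidDomainError, UnresolvedAssignmentError
from .pipeline import PointDose

__all__ = [
    "PhantomPoint",
    "OrganAssignment",
    "OrganDose",
    "default_registry",
    "default_assignment",
    "organ_equivalent_dose",
    "dose_vs_distance",
]


@dataclass(frozen=True)
class PhantomPoint:
    """One instrumented hole: id, anatomical label, cranio-caudal distance to iso."""

    id: int
    label: str
    distance_cc_cm: float

    def __post_init__(self) -> None:
        if self.distance_cc_cm < 0.0:
            raise InvalidDomainError("distances must be non-negative")


# 16 detector positions of the adult female phantom; distances are to the
# head-treatment isocenter along the cranio-caudal axis.
_REGISTRY_ROWS = [
    (1, "Head up", 9.0),
    (2, "Head medium", 0.0),
    (3, "Head down", 8.0),
    (4, "Neck", 17.0),
    (5, "Right breast", 31.0),
    (6, "Left breast", 31.0),
    (7, "Right thorax lung", 42.0),
    (8, "Left thorax lung", 42.0),
    (9, "Thorax spine", 52.0),
    (10, "Pelvis up", 71.0),
    (11, "Pelvis medium", 79.0),
    (12, "Pelvis down", 89.0),
    (13, "Right leg", 127.0),
    (14, "Left leg", 127.0),
    (15, "Skin", 92.0),
    (16, "Mediastine", 42.0),
]

_ASSIGNMENT = {
    "thyroid": [4],
    "esophagus": [4, 9, 16],
    "lung": [7, 8],
    "breast": [5, 6, 15],
    "stomach": [9, 11, 16],
    "liver": [9, 10, 11, 16],
    "colon": [11, 12],
    "urinary bladder": [10],
    "ovary": [11, 12],
    "prostate": [11, 12],
    "uterus": [11, 12],
}


def default_registry() -> dict[int, PhantomPoint]:
    """The 16-point phantom registry keyed by point id."""
    return {pid: PhantomPoint(pid, label, d) for pid, label, d in _REGISTRY_ROWS}


@dataclass
class OrganAssignment:
    """Organ name → contributing point ids, validated against a registry."""

    organs: dict[str, list[int]] = field(default_factory=lambda: {
        k: list(v) for k, v in _ASSIGNMENT.items()
    })
    registry: dict[int, PhantomPoint] = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        for organ, pts in self.organs.items():
            if not pts:
                raise InvalidDomainError(f"organ {organ!r} has an empty point list")
            for pid in pts:
                if pid not in self.registry:
                    raise UnresolvedAssignmentError(
                        f"organ {organ!r} references unknown point {pid}"
                    )


def default_assignment() -> OrganAssignment:
    return OrganAssignment()


@dataclass(frozen=True)
class OrganDose:
    organ: str
    h_equivalent: float  # mSv per treatment Gy
    u: float
    point_ids: tuple[int, ...]

    @property
    def n_points(self) -> int:
        return len(self.point_ids)

    def __post_init__(self) -> None:
        if self.h_equivalent < 0.0 or self.u < 0.0:
            raise InvalidDomainError("organ dose and uncertainty must be non-negative")


def organ_equivalent_dose(
    point_doses: list[PointDose],
    assignment: OrganAssignment | None = None,
    correlated_model: bool = False,
    model_rel: float = 0.20,
) -> list[OrganDose]:
    """Average total dose equivalents over each organ's contributing points.

    Raises :class:`UnresolvedAssignmentError` naming the organ and point if a
    required point dose is missing.
    """
    assignment = assignment or default_assignment()
    by_id = {pd_.point_id: pd_ for pd_ in point_doses}
    out = []
    for organ, pts in assignment.organs.items():
        missing = [p for p in pts if p not in by_id]
        if missing:
            raise UnresolvedAssignmentError(
                f"organ {organ!r}: no point dose for point(s) {missing}"
            )
        n = len(pts)
        mean = sum(by_id[p].h_total for p in pts) / n
        if correlated_model:
            # strip the correlated model term per point, then re-apply to the mean
            var_uncorr = 0.0
            for p in pts:
                pdos = by_id[p]
                model_term = model_rel * pdos.h_neutron
                var_uncorr += max(pdos.u_total**2 - model_term**2, 0.0)
            mean_hn = sum(by_id[p].h_neutron for p in pts) / n
            u = math.sqrt(var_uncorr / n**2 + (model_rel * mean_hn) ** 2)
        else:
            u = math.sqrt(sum(by_id[p].u_total**2 for p in pts)) / n
        out.append(OrganDose(organ, mean, u, tuple(pts)))
    return out


def dose_vs_distance(
    point_doses: list[PointDose],
    registry: dict[int, PhantomPoint] | None = None,
) -> pd.DataFrame:
    """Table of doses versus cranio-caudal distance, sorted by distance.

    Ties keep their input order (stable sort), one row per point.
    """
    registry = registry if registry is not None else default_registry()
    rows = []
    for pdos in point_doses:
        if pdos.point_id not in registry:
            raise UnresolvedAssignmentError(f"unknown point id {pdos.point_id!r}")
        rows.append(
            {
                "point_id": pdos.point_id,
                "distance_cc_cm": registry[pdos.point_id].distance_cc_cm,
                "h_gamma": pdos.h_gamma,
                "h_neutron": pdos.h_neutron,
                "h_total": pdos.h_total,
            }
        )
    df = pd.DataFrame(
        rows, columns=["point_id", "distance_cc_cm", "h_gamma", "h_neutron", "h_total"]
    )
    if not df.empty:
        df = df.sort_values("distance_cc_cm", kind="stable", ignore_index=True)
    return df
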