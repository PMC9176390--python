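"""Energy-dependent conversion-coefficient tables and the folding operator.

A :class:`ConversionTable` is a node curve (energy, value) interpolated
log-log — the coefficients span orders of magnitude over eleven energy
decades — with linear-in-value interpolation across zero-valued nodes and
constant extension above the last node (the bundled kerma-based data stop at
150 MeV while spectra reach 200 MeV).

``fold`` evaluates the dose integral as a bin sum: per-bin fluence times the
coefficient at the geometric bin midpoint.  For a unit spectrum the result is
the fluence-averaged coefficient (pSv·cm² for the bundled tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DegenerateSpectrumError, InvalidDomainError, OutOfRangeError
from .spectra import NeutronSpectrum

__all__ = [
    "ConversionTable",
    "coefficient_at",
    "fold",
    "dose_avg_energy",
    "load_qk",
    "load_hstar",
    "read_coefficient_csv",
    "write_coefficient_csv",
]

KINDS = ("qk", "hstar", "kerma", "quality")

#: Minimum span (MeV) the dose-equivalent tables must cover.
_REQUIRED_SPAN = {"qk": (1e-9, 150.0), "hstar": (1e-9, 150.0)}


@dataclass
class ConversionTable:
    """Energy-indexed coefficient curve with a log-log interpolation contract."""

    kind: str
    energies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidDomainError(f"unknown table kind {self.kind!r}")
        self.energies = np.asarray(self.energies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.energies.size < 2 or self.energies.shape != self.values.shape:
            raise InvalidDomainError("table needs >= 2 (energy, value) nodes")
        if np.any(np.diff(self.energies) <= 0.0):
            raise InvalidDomainError("node energies must be strictly increasing")
        if np.any(self.values < 0.0):
            raise InvalidDomainError("coefficient values must be non-negative")
        span = _REQUIRED_SPAN.get(self.kind)
        if span and (self.energies[0] > span[0] or self.energies[-1] < span[1]):
            raise InvalidDomainError(
                f"{self.kind} table must cover at least {span[0]}-{span[1]} MeV"
            )

    @property
    def valid_range(self) -> tuple[float, float]:
        return float(self.energies[0]), float(self.energies[-1])


def coefficient_at(table: ConversionTable, e) -> float | np.ndarray:
    """Interpolated coefficient at energy ``e`` (MeV); scalar or array.

    Log-log between nodes, exact at nodes, linear in value where a segment
    touches a zero node, constant above the last node.  Below the first node
    is an error.
    """
    e_arr = np.atleast_1d(np.asarray(e, dtype=float))
    if np.any(e_arr < table.energies[0] * (1.0 - 1e-12)):
        raise OutOfRangeError(
            f"energy below table range (first node {table.energies[0]:g} MeV)"
        )
    loge_nodes = np.log(table.energies)
    loge = np.minimum(np.log(e_arr), loge_nodes[-1])  # constant extension above
    idx = np.clip(
        np.searchsorted(loge_nodes, loge, side="right") - 1, 0, loge_nodes.size - 2
    )
    vl, vr = table.values[idx], table.values[idx + 1]
    t = (loge - loge_nodes[idx]) / (loge_nodes[idx + 1] - loge_nodes[idx])
    lin = (1.0 - t) * vl + t * vr
    both_pos = (vl > 0.0) & (vr > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglog = np.exp((1.0 - t) * np.log(np.where(vl > 0, vl, 1.0)) +
                        t * np.log(np.where(vr > 0, vr, 1.0)))
    out = np.where(both_pos, loglog, lin)
    return float(out[0]) if np.isscalar(e) or np.asarray(e).ndim == 0 else out


def fold(spec: NeutronSpectrum, table: ConversionTable) -> float:
    """Σ bin_fluence × coefficient(geometric midpoint), in table × spectrum units."""
    mids = spec.grid.midpoints
    below = (spec.bin_fluence > 0.0) & (mids < table.energies[0] * (1.0 - 1e-12))
    if np.any(below):
        raise OutOfRangeError(
            "spectrum support below table range in bins "
            f"{np.flatnonzero(below).tolist()}"
        )
    coeff = np.zeros_like(mids)
    active = spec.bin_fluence > 0.0
    if np.any(active):
        coeff[active] = coefficient_at(table, mids[active])
    return float(np.dot(spec.bin_fluence, coeff))


def dose_avg_energy(spec: NeutronSpectrum, table: ConversionTable) -> float:
    """Mean bin-midpoint energy weighted by fluence × coefficient, MeV."""
    mids = spec.grid.midpoints
    w = spec.bin_fluence * coefficient_at(table, mids)
    denom = w.sum()
    if denom <= 0.0:
        raise DegenerateSpectrumError("zero folded value; dose-averaged energy undefined")
    return float(np.dot(w, mids) / denom)


# ---------------------------------------------------------------------------
# CSV interface: `energy_mev,value` with a comment header naming kind/units.

def read_coefficient_csv(path, kind: str | None = None) -> ConversionTable:
    header_kind = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "kind:" in line:
                header_kind = line.split("kind:")[1].strip()
    df = pd.read_csv(path, comment="#")
    if not {"energy_mev", "value"}.issubset(df.columns):
        raise InvalidDomainError(f"{path}: expected columns energy_mev,value")
    kind = kind or header_kind
    if kind is None:
        raise InvalidDomainError(f"{path}: no '# kind:' header and no kind given")
    return ConversionTable(kind, df["energy_mev"].to_numpy(float), df["value"].to_numpy(float))


def write_coefficient_csv(table: ConversionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind: {table.kind}\n# units: energy MeV, coefficient pSv cm^2\n")
        pd.DataFrame({"energy_mev": table.energies, "value": table.values}).to_csv(
            fh, index=False, lineterminator="\n"
        )


def _load_bundled(name: str, kind: str) -> ConversionTable:
    ref = resources.files("periphdose").joinpath("data", name)
    with resources.as_file(ref) as path:
        return read_coefficient_csv(path, kind)


def load_qk() -> ConversionTable:
    """Bundled Q(E)·k(E) point dose-equivalent coefficients, pSv·cm²."""
    return _load_bundled("qk_soft_tissue.csv", "qk")


def load_hstar() -> ConversionTable:
    """Bundled ambient dose equivalent coefficients h*(10)(E), pSv·cm²."""
    return _load_bundled("hstar_ambient.csv", "hstar")
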