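"""Constitutive description of the phantom wall materials.

Turns uniaxial tensile stress--strain records into elastic moduli in two
forms: a single constant modulus ``E_const`` from a linear fit over the
physiological strain window, and a strain-dependent modulus ``E(eps_m)``
tabulated as piecewise difference quotients of the averaged curve.  The
scalar strain metric ``eps_m`` combines the volumetric strain (first
invariant) and the shear strain (a deviatoric second-invariant measure)

    eps_m = gamma / (sqrt(2) (1 + nu)) + |eps_vol| / (3 (1 - 2 nu))

so that a single non-negative number indexes the modulus table regardless
of the local deformation mode.

Strains are dimensionless fractions throughout; stresses and moduli are in
MPa.  Engineering stress/strain is assumed (no true-stress conversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "StressStrainCurve",
    "ModulusTable",
    "StrainState",
    "MaterialSpec",
    "InsufficientDataError",
    "piecewise_schedule",
    "fit_constant_modulus",
    "average_curves",
    "piecewise_modulus",
    "volumetric_strain",
    "shear_strain",
    "strain_metric",
    "evaluate_modulus",
]


class InsufficientDataError(ValueError):
    """Raised when a fit window contains too few points."""


@dataclass(frozen=True)
class StressStrainCurve:
    """One tensile specimen's strain/stress record.

    Parameters
    ----------
    strain : array-like
        Engineering strain as a dimensionless fraction, strictly
        increasing, first value >= 0.
    stress : array-like
        Engineering stress in MPa, same length as ``strain``.
    specimen_id, material : str
        Labels carried through averaging and fitting.
    """

    strain: np.ndarray
    stress: np.ndarray
    specimen_id: str = ""
    material: str = ""

    def __post_init__(self) -> None:
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)
        if strain.ndim != 1 or stress.ndim != 1 or strain.size != stress.size:
            raise ValueError("strain and stress must be 1-D arrays of equal length")
        if strain.size < 3:
            raise ValueError("a stress-strain curve needs at least 3 points")
        if strain[0] < 0:
            raise ValueError("strain must start at a non-negative value")
        if not np.all(np.diff(strain) > 0):
            raise ValueError("strain must be strictly increasing")
        if not np.all(np.isfinite(stress)):
            raise ValueError("stress must be finite")

    @property
    def strain_range(self) -> tuple[float, float]:
        return float(self.strain[0]), float(self.strain[-1])

    def interpolate(self, strain: np.ndarray) -> np.ndarray:
        """Linearly interpolated stress at the given strain values."""
        return np.interp(np.asarray(strain, dtype=float), self.strain, self.stress)


@dataclass(frozen=True)
class ModulusTable:
    """Strain-dependent modulus ``E(eps_m)`` as interpolable nodes.

    Nodes are (strain-metric value, modulus MPa) pairs with strictly
    increasing strains and positive moduli.  Evaluation between nodes is
    piecewise linear; outside the node range the first/last value is held.
    """

    strains: np.ndarray
    moduli: np.ndarray
    built_from: str = ""

    def __post_init__(self) -> None:
        strains = np.asarray(self.strains, dtype=float)
        moduli = np.asarray(self.moduli, dtype=float)
        object.__setattr__(self, "strains", strains)
        object.__setattr__(self, "moduli", moduli)
        if strains.size == 0:
            raise ValueError("modulus table must contain at least one node")
        if strains.size != moduli.size:
            raise ValueError("strains and moduli must have equal length")
        if strains.size > 1 and not np.all(np.diff(strains) > 0):
            raise ValueError("node strains must be strictly increasing")
        if not np.all(moduli > 0):
            raise ValueError("all moduli must be positive")

    def __call__(self, eps_m):
        """Piecewise-linear interpolation, clamped outside the node range."""
        return np.interp(eps_m, self.strains, self.moduli)

    @property
    def nodes(self) -> list[tuple[float, float]]:
        return list(zip(self.strains.tolist(), self.moduli.tolist()))


@dataclass(frozen=True)
class StrainState:
    """Six unique components of a symmetric small-strain tensor."""

    e_xx: float = 0.0
    e_yy: float = 0.0
    e_zz: float = 0.0
    e_xy: float = 0.0
    e_xz: float = 0.0
    e_yz: float = 0.0

    def __post_init__(self) -> None:
        comps = (self.e_xx, self.e_yy, self.e_zz, self.e_xy, self.e_xz, self.e_yz)
        if not all(np.isfinite(c) for c in comps):
            raise ValueError("strain components must be finite")

    def tensor(self) -> np.ndarray:
        """The full symmetric 3x3 tensor."""
        return np.array(
            [
                [self.e_xx, self.e_xy, self.e_xz],
                [self.e_xy, self.e_yy, self.e_yz],
                [self.e_xz, self.e_yz, self.e_zz],
            ]
        )

    def scaled(self, k: float) -> "StrainState":
        return StrainState(
            k * self.e_xx, k * self.e_yy, k * self.e_zz,
            k * self.e_xy, k * self.e_xz, k * self.e_yz,
        )


@dataclass(frozen=True)
class MaterialSpec:
    """Linear elastic material with constant or strain-dependent modulus.

    ``mode='constant'`` uses ``E_const`` everywhere; ``mode='table'``
    evaluates the modulus from a :class:`ModulusTable` at the local strain
    metric.  Poisson ratio defaults to 0.4 (nearly incompressible without
    the numerical pathologies of 0.5); density is metadata only.
    """

    mode: Literal["constant", "table"]
    E_const: float | None = None
    table: ModulusTable | None = None
    nu: float = 0.4
    density: float = 1.07e3

    def __post_init__(self) -> None:
        if not 0.0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must satisfy 0 < nu < 0.5")
        if self.mode == "constant":
            if self.E_const is None or self.E_const <= 0:
                raise ValueError("constant mode requires E_const > 0")
        elif self.mode == "table":
            if self.table is None:
                raise ValueError("table mode requires a ModulusTable")
        else:
            raise ValueError(f"unknown material mode {self.mode!r}")

    @classmethod
    def constant(cls, E_const: float, nu: float = 0.4, **kw) -> "MaterialSpec":
        return cls(mode="constant", E_const=E_const, nu=nu, **kw)

    @classmethod
    def from_table(cls, table: ModulusTable, nu: float = 0.4, **kw) -> "MaterialSpec":
        return cls(mode="table", table=table, nu=nu, **kw)


# Tangent-modulus tabulation schedule: strain edges advance in 0.2% steps
# up to 10% strain and in 5% steps from 10% to 100%.
_FINE_STEP = 0.002
_FINE_END = 0.100
_COARSE_STEP = 0.05
_COARSE_END = 1.00


def piecewise_schedule() -> np.ndarray:
    """Strain edges of the difference-quotient schedule (69 edges, 68 intervals)."""
    fine = np.round(np.arange(0.0, _FINE_END + _FINE_STEP / 2, _FINE_STEP), 10)
    coarse = np.round(
        np.arange(_FINE_END + _COARSE_STEP, _COARSE_END + _COARSE_STEP / 2, _COARSE_STEP), 10
    )
    return np.concatenate([fine, coarse])


def fit_constant_modulus(
    curve: StressStrainCurve,
    strain_cap: float = 0.20,
    through_origin: bool = False,
) -> float:
    """Constant modulus from a linear trendline up to ``strain_cap`` strain.

    Ordinary least squares with a free intercept by default (the
    spreadsheet-trendline convention); set ``through_origin`` to force a
    zero intercept.  Returns the slope in MPa.
    """
    mask = curve.strain <= strain_cap
    if int(mask.sum()) < 3:
        raise InsufficientDataError(
            f"need >= 3 points with strain <= {strain_cap}, found {int(mask.sum())}"
        )
    x = curve.strain[mask]
    y = curve.stress[mask]
    if through_origin:
        return float(np.dot(x, y) / np.dot(x, x))
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def average_curves(
    curves: Sequence[StressStrainCurve],
    grid_step: float = 0.001,
) -> tuple[StressStrainCurve, np.ndarray]:
    """Average several specimen curves on a common strain grid.

    Each curve is linearly interpolated onto a uniform grid spanning the
    intersection of all strain ranges; the pointwise mean curve and the
    pointwise population standard deviation are returned.
    """
    if len(curves) == 0:
        raise ValueError("average_curves requires at least one curve")
    lo = max(c.strain[0] for c in curves)
    hi = min(c.strain[-1] for c in curves)
    if hi <= lo:
        raise ValueError("curves have disjoint strain ranges; nothing to average")
    n = max(int(np.floor((hi - lo) / grid_step)) + 1, 3)
    grid = lo + grid_step * np.arange(n)
    grid = grid[grid <= hi + 1e-12]
    if grid[-1] < hi - 1e-12:
        grid = np.append(grid, hi)
    stacked = np.vstack([c.interpolate(grid) for c in curves])
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)  # population SD over specimens
    materials = {c.material for c in curves}
    label = materials.pop() if len(materials) == 1 else "mixed"
    avg = StressStrainCurve(grid, mean, specimen_id="average", material=label)
    return avg, sd


def piecewise_modulus(curve: StressStrainCurve, built_from: str = "paper-0.2/5") -> ModulusTable:
    """Tangent modulus table from difference quotients of a curve.

    For every schedule interval [e_i, e_{i+1}] fully inside the curve's
    strain range, the node is (interval midpoint, (sigma(e_{i+1}) -
    sigma(e_i)) / (e_{i+1} - e_i)) with sigma linearly interpolated.
    Intervals beyond the curve's range are omitted.
    """
    edges = piecewise_schedule()
    lo, hi = curve.strain_range
    keep = (edges[:-1] >= lo - 1e-12) & (edges[1:] <= hi + 1e-12)
    if not keep.any():
        raise ValueError("curve does not span the first schedule interval")
    e0 = edges[:-1][keep]
    e1 = edges[1:][keep]
    s0 = curve.interpolate(e0)
    s1 = curve.interpolate(e1)
    moduli = (s1 - s0) / (e1 - e0)
    mids = 0.5 * (e0 + e1)
    return ModulusTable(mids, moduli, built_from=built_from)


def volumetric_strain(s: StrainState) -> float:
    """First invariant trace(eps): relative volume change."""
    return s.e_xx + s.e_yy + s.e_zz


def shear_strain(s: StrainState) -> float:
    """Shear strain gamma = sqrt(2 dev(eps):dev(eps)).

    The deviator dev(eps) = eps - trace(eps)/3 I captures the shape change;
    ':' is the Frobenius double-dot product over all nine entries.
    """
    eps = s.tensor()
    dev = eps - np.trace(eps) / 3.0 * np.eye(3)
    return float(np.sqrt(2.0 * np.sum(dev * dev)))


def strain_metric(s: StrainState, nu: float = 0.4) -> float:
    """Scalar strain metric combining shear and volumetric contributions.

    eps_m = gamma / (sqrt(2) (1 + nu)) + |eps_vol| / (3 (1 - 2 nu)).
    Always >= 0; zero only for the zero tensor.
    """
    if not 0.0 < nu < 0.5:
        raise ValueError("strain_metric requires 0 < nu < 0.5")
    gamma = shear_strain(s)
    eps_vol = volumetric_strain(s)
    return gamma / (np.sqrt(2.0) * (1.0 + nu)) + abs(eps_vol) / (3.0 * (1.0 - 2.0 * nu))


def evaluate_modulus(mat: MaterialSpec, epsilon_m) -> float | np.ndarray:
    """Modulus at a given strain-metric value.

    Constant mode returns ``E_const``; table mode interpolates linearly
    between nodes with clamped extrapolation.  Accepts scalars or arrays.
    """
    if mat.mode == "constant":
        if np.ndim(epsilon_m) == 0:
            return float(mat.E_const)
        return np.full(np.shape(epsilon_m), float(mat.E_const))
    out = mat.table(epsilon_m)
    return float(out) if np.ndim(epsilon_m) == 0 else out
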