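"""Synthetic experiments with the statistical structure the analysis assumes.

Generates (i) uniaxial tensile specimen curves from a ground-truth
material law plus Gaussian stress noise, (ii) stenotic slice-stack vessel
geometries, (iii) syringe-pump pressure--volume experiments (fixed-volume
injection steps, pressure read-out noise, optional slow leak), and
(iv) projected-diameter series at marker sites.  All generators are pure
functions of their inputs and a seed, so every pipeline stage can be
tested by round-trip parameter recovery without any laboratory data.

Two material presets shape the ground truth after the qualitative
behavior of the phantom materials: ``pvah_like`` has a nearly flat tangent
modulus around 0.31 MPa over the working strain range (polyvinyl-alcohol
hydrogel), while ``silicone_like`` softens markedly between 10% and 40%
strain.  Preset parameters are conventional defaults, not measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .characterization import DiameterSeries, PVMeasurement
from .inflation import VesselGeometry, vessel_pv_curve
from .material import MaterialSpec, StressStrainCurve

__all__ = [
    "MaterialLaw",
    "ExperimentConfig",
    "pvah_like",
    "silicone_like",
    "gen_tensile_dataset",
    "gen_vessel_geometry",
    "gen_pv_experiment",
    "gen_diameter_series",
]


@dataclass(frozen=True)
class MaterialLaw:
    """Ground-truth stress--strain law sigma(eps) for specimen synthesis.

    Kinds:
      * ``linear``      sigma = E0 eps
      * ``polynomial``  sigma = sum_i c_i eps^i with c_0 = 0
      * ``softening``   exponentially relaxing tangent modulus
                        E_t(eps) = E_inf + (E0 - E_inf) exp(-eps/eps_c),
                        sigma = E_inf eps + (E0 - E_inf) eps_c (1 - exp(-eps/eps_c))

    sigma(0) = 0 and sigma non-decreasing on [0, max_strain] are required.
    """

    kind: Literal["linear", "polynomial", "softening"]
    E0: float = 0.31  # MPa, initial tangent modulus
    E_inf: float = 0.31  # MPa, asymptotic tangent modulus (softening)
    eps_c: float = 0.2  # strain scale of softening
    coefficients: tuple[float, ...] = ()  # polynomial c_1, c_2, ... (c_0 = 0 implied)
    max_strain: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.max_strain <= 0:
            raise ValueError("max_strain must be positive")
        if self.kind == "softening" and (self.E0 <= 0 or self.E_inf <= 0 or self.eps_c <= 0):
            raise ValueError("softening law requires positive E0, E_inf, eps_c")
        if self.kind == "linear" and self.E0 <= 0:
            raise ValueError("linear law requires E0 > 0")
        if self.kind == "polynomial" and not self.coefficients:
            raise ValueError("polynomial law requires coefficients")
        eps = np.linspace(0.0, self.max_strain, 201)
        sig = self.stress(eps)
        if abs(float(self.stress(0.0))) > 1e-12:
            raise ValueError("law must satisfy sigma(0) = 0")
        if np.any(np.diff(sig) < -1e-12):
            raise ValueError("law must be non-decreasing on its valid range")

    def stress(self, eps):
        """Stress (MPa) at the given strain(s)."""
        eps = np.asarray(eps, dtype=float)
        if self.kind == "linear":
            out = self.E0 * eps
        elif self.kind == "polynomial":
            out = np.zeros_like(eps)
            for i, c in enumerate(self.coefficients, start=1):
                out = out + c * eps**i
        else:  # softening
            dE = self.E0 - self.E_inf
            out = self.E_inf * eps + dE * self.eps_c * (1.0 - np.exp(-eps / self.eps_c))
        return out if out.ndim else float(out)

    def tangent_modulus(self, eps):
        eps = np.asarray(eps, dtype=float)
        if self.kind == "linear":
            out = np.full_like(eps, self.E0)
        elif self.kind == "polynomial":
            out = np.zeros_like(eps)
            for i, c in enumerate(self.coefficients, start=1):
                out = out + i * c * eps ** (i - 1)
        else:
            out = self.E_inf + (self.E0 - self.E_inf) * np.exp(-eps / self.eps_c)
        return out if out.ndim else float(out)


def pvah_like() -> MaterialLaw:
    """Hydrogel-like preset: tangent modulus nearly flat near 0.31 MPa."""
    return MaterialLaw(kind="softening", E0=0.33, E_inf=0.30, eps_c=0.15, name="pvah-like")


def silicone_like() -> MaterialLaw:
    """Silicone-like preset: tangent modulus decreasing over 10-40% strain."""
    return MaterialLaw(kind="softening", E0=0.40, E_inf=0.14, eps_c=0.22, name="silicone-like")


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs of the simulated experiments.

    Noise magnitudes are assumptions (the measurement protocol does not
    quantify them): 0.005 MPa stress, 0.5 mmHg pressure, 0.05 mm diameter.
    ``injection_step`` mirrors the 1-mm^3 syringe-pump increments;
    ``leak_rate`` is a constant volume loss per step emulating a slow leak.
    """

    n_specimens: int = 5
    stress_noise_sd: float = 0.005  # MPa
    strain_step: float = 0.001  # strain grid of tensile records
    injection_step: float = 1.0  # mm^3
    pressure_noise_sd: float = 0.5  # mmHg
    diameter_noise_sd: float = 0.05  # mm
    leak_rate: float = 0.0  # mm^3 lost per injection step
    max_pressure: float = 160.0  # mmHg, truncation limit of the inflation run
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.stress_noise_sd, self.pressure_noise_sd, self.diameter_noise_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.leak_rate < 0:
            raise ValueError("leak rate must be non-negative")
        if self.n_specimens < 1 or self.injection_step <= 0 or self.strain_step <= 0:
            raise ValueError("invalid experiment configuration")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_tensile_dataset(law: MaterialLaw, cfg: ExperimentConfig) -> list[StressStrainCurve]:
    """Synthetic tensile specimens: law stress on a strain grid + iid noise."""
    rng = cfg.rng()
    eps = np.arange(0.0, law.max_strain + cfg.strain_step / 2, cfg.strain_step)
    truth = law.stress(eps)
    curves = []
    for i in range(cfg.n_specimens):
        noise = rng.normal(0.0, cfg.stress_noise_sd, eps.size) if cfg.stress_noise_sd > 0 else 0.0
        curves.append(
            StressStrainCurve(
                strain=eps,
                stress=truth + noise,
                specimen_id=f"S{i + 1}",
                material=law.name or law.kind,
            )
        )
    return curves


def gen_vessel_geometry(
    length: float = 60.0,
    base_radius: float = 3.0,
    base_thickness: float = 1.0,
    stenosis: tuple[float, float, float] | None = None,
    taper: float = 0.0,
    station_spacing: float = 1.0,
) -> VesselGeometry:
    """Slice-stack tube with an optional stenosis.

    ``stenosis = (center_z mm, severity fraction, width mm)`` narrows the
    lumen by a Gaussian bump: at the center station the inner radius is
    (1 - severity) x base_radius.  The outer radius stays smooth (the
    plaque thickens the wall inward, as in arterial disease), so the wall
    thickness rises where the lumen narrows.  ``taper`` reduces the inner
    radius linearly by that fraction from inlet to outlet.  Markers: CCA
    near the inlet, ICA and ECA toward the outlet, ICAs at the most
    stenotic station (vessel midpoint if no stenosis).
    """
    if length <= 0 or base_radius <= 0 or base_thickness <= 0 or station_spacing <= 0:
        raise ValueError("length, radii and spacing must be positive")
    z = np.arange(0.0, length + station_spacing / 2, station_spacing)
    r_in = np.full(z.size, base_radius)
    if taper:
        r_in = r_in * (1.0 - taper * z / length)
    outer = r_in + base_thickness
    if stenosis is not None:
        center, severity, width = stenosis
        if not 0.0 <= severity < 0.95:
            raise ValueError("stenosis severity must be in [0, 0.95)")
        if width <= 0:
            raise ValueError("stenosis width must be positive")
        bump = severity * np.exp(-0.5 * ((z - center) / width) ** 2)
        r_in = r_in * (1.0 - bump)
    thickness = outer - r_in

    n = z.size
    stenotic_idx = int(np.argmin(r_in)) if stenosis is not None else n // 2
    markers = {
        "CCA": max(1, int(round(0.1 * (n - 1)))),
        "ICA": int(round(0.75 * (n - 1))),
        "ECA": int(round(0.9 * (n - 1))),
        "ICAs": stenotic_idx,
    }
    return VesselGeometry(z=z, inner_radius=r_in, thickness=thickness, site_markers=markers)


def _pressure_at_volume(
    geom: VesselGeometry,
    mat: MaterialSpec,
    target_volume: float,
    p_hi: float,
    xtol: float = 1e-6,
) -> float:
    """Invert the monotone model P-V relation: find p with V(p) = target."""

    def f(p: float) -> float:
        res = vessel_pv_curve(geom, mat, [p])
        return float(res.volumes[0]) - target_volume

    if f(0.0) >= 0.0:
        return 0.0
    if f(p_hi) < 0.0:
        raise ValueError("target volume above the model volume at max pressure")
    return float(brentq(f, 0.0, p_hi, xtol=xtol))


def gen_pv_experiment(
    geom: VesselGeometry,
    mat: MaterialSpec,
    Pd_start: float = 70.0,
    cfg: ExperimentConfig = ExperimentConfig(),
    n_steps: int | None = None,
) -> PVMeasurement:
    """Simulated syringe-pump compliance experiment.

    The vessel starts pressurized at ``Pd_start`` (baseline volume
    V(Pd_start)).  Each step injects ``cfg.injection_step`` mm^3; the
    equilibrium pressure is found by inverting the model's monotone
    pressure--volume relation (bisection to 1e-6 mmHg), a constant
    ``cfg.leak_rate`` volume per step is subtracted, and Gaussian read-out
    noise is added to the recorded pressure.  The experiment stops when
    the equilibrium pressure would exceed ``cfg.max_pressure`` (a warning
    marks the truncation) or after ``n_steps`` injections.
    """
    rng = cfg.rng()
    res0 = vessel_pv_curve(geom, mat, [Pd_start])
    V0 = float(res0.volumes[0])
    v_max = float(vessel_pv_curve(geom, mat, [cfg.max_pressure]).volumes[0])

    if n_steps is None:
        n_steps = int(np.ceil((v_max - V0) / cfg.injection_step)) + 5

    injected: list[float] = []
    pressures: list[float] = []
    contained = V0
    truncated = False
    for k in range(1, n_steps + 1):
        contained += cfg.injection_step - cfg.leak_rate
        if contained > v_max:
            truncated = True
            break
        p = _pressure_at_volume(geom, mat, contained, cfg.max_pressure)
        noise = rng.normal(0.0, cfg.pressure_noise_sd) if cfg.pressure_noise_sd > 0 else 0.0
        injected.append(k * cfg.injection_step)
        pressures.append(p + noise)
    if truncated:
        warnings.warn(
            f"experiment truncated at {len(injected)} steps: target volume exceeds "
            f"the model volume at {cfg.max_pressure} mmHg",
            stacklevel=2,
        )
    if len(injected) < 2:
        raise ValueError("experiment produced fewer than 2 records (material too rigid?)")
    return PVMeasurement(
        injected=np.asarray(injected),
        pressure=np.asarray(pressures),
        baseline_volume=V0,
    )


def gen_diameter_series(
    geom: VesselGeometry,
    mat: MaterialSpec,
    site: str,
    pressures: Sequence[float],
    noise_sd: float = 0.05,
    seed: int | None = None,
) -> DiameterSeries:
    """Model diameters at a marker site plus Gaussian measurement noise."""
    if site not in geom.site_markers:
        raise KeyError(f"unknown marker site {site!r}")
    pressures = np.asarray(list(pressures), dtype=float)
    res = vessel_pv_curve(geom, mat, np.sort(pressures))
    order = np.argsort(pressures, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    idx = geom.site_markers[site]
    d = res.station_diameters[inv, idx]
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, d.size) if noise_sd > 0 else 0.0
    return DiameterSeries(site=site, pressure=pressures, diameter=d + noise)
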