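"""Experimental characterization metrics for compliant vessel phantoms.

Implements the measurement-side analysis: volumetric compliance from a
syringe-pump pressure--volume log,

    C   = (V_s - V_d) / (P_s - P_d)                      [mm^3 / mmHg]
    C_V = C / V_d x 100                                  [% / mmHg]

diameter distensibility from a pressure--diameter series at a marker site,

    C_D = (D_s - D_d) / (D_d (P_s - P_d)) x 100          [% / mmHg]

effective diameter of a (possibly non-circular) lumen cross-section
(D_eff = perimeter / pi), wall-thickness summary statistics over the
slice x circumferential-position measurement grid, and normality-routed
two-group / one-sample comparisons.

Diastolic/systolic states default to 74 and 130 mmHg (a 56-mmHg clinical
pulse pressure).  Endpoint volumes and diameters are taken from
interpolation (volume) or an OLS pressure regression (diameter) rather
than nearest raw samples, because the injection grid rarely lands exactly
on the endpoint pressures.  Standard deviations are population SDs
(divide by n) by default, with ``ddof=1`` available via a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PVMeasurement",
    "DiameterSeries",
    "ThicknessGrid",
    "ComplianceReport",
    "DistensibilityResult",
    "GroupComparison",
    "compliance_from_pv",
    "distensibility_from_series",
    "effective_diameter",
    "thickness_stats",
    "compare_groups",
]

DEFAULT_PD = 74.0  # mmHg, diastolic
DEFAULT_PS = 130.0  # mmHg, systolic

_POSITIONS = tuple(f"P{i}" for i in range(1, 9))


@dataclass(frozen=True)
class PVMeasurement:
    """Injected-volume vs pressure log of one compliance experiment.

    ``injected`` is the cumulative injected volume in mm^3 (strictly
    increasing, nominally 1-mm^3 steps); ``pressure`` the recorded pressure
    in mmHg; ``baseline_volume`` the contained volume at the first record.
    """

    injected: np.ndarray
    pressure: np.ndarray
    baseline_volume: float

    def __post_init__(self) -> None:
        inj = np.asarray(self.injected, dtype=float)
        pres = np.asarray(self.pressure, dtype=float)
        object.__setattr__(self, "injected", inj)
        object.__setattr__(self, "pressure", pres)
        if inj.size != pres.size or inj.size < 2:
            raise ValueError("need >= 2 records of equal length")
        if not np.all(np.diff(inj) > 0):
            raise ValueError("injected volume must be strictly increasing")
        if not np.all(np.isfinite(pres)):
            raise ValueError("pressures must be finite")
        if self.baseline_volume < 0:
            raise ValueError("baseline volume must be non-negative")

    @property
    def volume(self) -> np.ndarray:
        """Total contained volume per record (baseline + injected)."""
        return self.baseline_volume + self.injected


@dataclass(frozen=True)
class DiameterSeries:
    """Projected-diameter measurements at one marker site vs pressure."""

    site: str
    pressure: np.ndarray
    diameter: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pressure, dtype=float)
        d = np.asarray(self.diameter, dtype=float)
        object.__setattr__(self, "pressure", p)
        object.__setattr__(self, "diameter", d)
        if p.size != d.size or p.size < 3:
            raise ValueError("need >= 3 (pressure, diameter) records")
        if not np.all(d > 0):
            raise ValueError("diameters must be positive")


@dataclass(frozen=True)
class ThicknessGrid:
    """Wall-thickness measurements: model x branch x slice x position.

    The measurement protocol records thickness at eight circumferential
    positions (P1-P8) across ten 1-mm slices per branch.
    """

    table: pd.DataFrame  # columns: model_id, branch, slice, position, thickness_mm

    REQUIRED = ("model_id", "branch", "slice", "position", "thickness_mm")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"thickness grid missing columns: {missing}")
        if not df["position"].isin(_POSITIONS).all():
            bad = sorted(set(df["position"]) - set(_POSITIONS))
            raise ValueError(f"positions outside P1-P8: {bad}")
        if not (df["thickness_mm"] > 0).all():
            raise ValueError("thickness must be positive")
        object.__setattr__(self, "table", df)


@dataclass(frozen=True)
class ComplianceReport:
    """Compliance metrics of one vessel, experimental or model-predicted."""

    C: float  # mm^3 / mmHg
    C_V: float  # % / mmHg
    C_D: Mapping[str, float] = field(default_factory=dict)  # % / mmHg per site
    Pd: float = DEFAULT_PD
    Ps: float = DEFAULT_PS
    provenance: str = "experimental"
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "C_mm3_per_mmHg": self.C,
            "C_V_pct_per_mmHg": self.C_V,
            "C_D_pct_per_mmHg": dict(self.C_D),
            "Pd_mmHg": self.Pd,
            "Ps_mmHg": self.Ps,
            "provenance": self.provenance,
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class DistensibilityResult:
    """C_D with the regression diagnostics behind it."""

    site: str
    C_D: float  # % / mmHg
    D_d: float  # mm, fitted at Pd
    D_s: float  # mm, fitted at Ps
    slope: float  # mm / mmHg
    intercept: float  # mm
    residual_sd: float  # mm, population SD of residuals
    outlier_mask: np.ndarray  # |residual| > 3 SD; flagged, never dropped
    Pd: float = DEFAULT_PD
    Ps: float = DEFAULT_PS

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_mask.sum())


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of a normality-routed hypothesis test."""

    test: str
    p_value: float
    significant: bool
    statistic: float
    shapiro_p: tuple[float, ...]
    alpha: float = 0.05


def compliance_from_pv(
    m: PVMeasurement,
    Pd: float = DEFAULT_PD,
    Ps: float = DEFAULT_PS,
) -> ComplianceReport:
    """Compliance and volumetric compliance from a pressure--volume log.

    V_d and V_s are obtained by piecewise-linear interpolation of volume
    against pressure at the endpoint pressures.  If the recorded pressure
    is not monotone (read-out noise), records are sorted and a warning is
    issued with an ``isotonic-cleanup`` flag on the report; interpolation
    then uses the sorted sequence.
    """
    if not Ps > Pd:
        raise ValueError("require Ps > Pd")
    p = m.pressure
    v = m.volume
    flags: list[str] = []
    if not np.all(np.diff(p) > 0):
        warnings.warn(
            "pressure log is not strictly monotone; sorting before interpolation",
            stacklevel=2,
        )
        flags.append("isotonic-cleanup")
        order = np.argsort(p, kind="stable")
        p, v = p[order], v[order]
    if Pd < p[0] or Ps > p[-1]:
        raise ValueError(
            f"[{Pd}, {Ps}] mmHg outside measured pressure range [{p[0]:.3g}, {p[-1]:.3g}]"
        )
    V_d = float(np.interp(Pd, p, v))
    V_s = float(np.interp(Ps, p, v))
    C = (V_s - V_d) / (Ps - Pd)
    C_V = C / V_d * 100.0
    return ComplianceReport(
        C=C, C_V=C_V, C_D={}, Pd=Pd, Ps=Ps, provenance="experimental", flags=tuple(flags)
    )


def distensibility_from_series(
    s: DiameterSeries,
    Pd: float = DEFAULT_PD,
    Ps: float = DEFAULT_PS,
) -> DistensibilityResult:
    """Diameter distensibility from a pressure--diameter series.

    An OLS line D = alpha + beta p is fitted to all records; residuals
    beyond three residual SDs are flagged (but retained in the fit), and
    the endpoint diameters are read off the fitted line.
    """
    if not Ps > Pd:
        raise ValueError("require Ps > Pd")
    res = stats.linregress(s.pressure, s.diameter)
    fitted = res.intercept + res.slope * s.pressure
    resid = s.diameter - fitted
    sd = float(np.std(resid))  # population SD
    # an exactly linear series leaves only rounding noise; below this floor
    # the 3-SD rule would flag machine epsilon as outliers
    sd_floor = 1e-9 * float(np.max(np.abs(s.diameter)))
    if sd > sd_floor:
        outliers = np.abs(resid) > 3.0 * sd
    else:
        outliers = np.zeros(resid.size, dtype=bool)
    lo, hi = float(np.min(s.pressure)), float(np.max(s.pressure))
    if Pd < lo or Ps > hi:
        warnings.warn(
            f"series covers [{lo:.3g}, {hi:.3g}] mmHg; endpoint diameters are "
            "regression extrapolations",
            stacklevel=2,
        )
    D_d = float(res.intercept + res.slope * Pd)
    D_s = float(res.intercept + res.slope * Ps)
    C_D = (D_s - D_d) / (D_d * (Ps - Pd)) * 100.0
    return DistensibilityResult(
        site=s.site,
        C_D=float(C_D),
        D_d=D_d,
        D_s=D_s,
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=sd,
        outlier_mask=outliers,
        Pd=Pd,
        Ps=Ps,
    )


def effective_diameter(perimeter: float) -> float:
    """Effective diameter of a lumen cross-section: D_eff = perimeter / pi."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return perimeter / np.pi


def thickness_stats(
    g: ThicknessGrid,
    reference: Mapping[str, float] | None = None,
    ddof: int = 0,
) -> pd.DataFrame:
    """Per-branch wall-thickness mean, SD and percentage error vs reference.

    Pooled over all models, slices and positions per branch.  SD is the
    population SD (``ddof=0``) by default.  ``reference`` maps branch to a
    reference thickness (mm); percentage error is
    |mean - reference| / reference x 100.
    """
    df = g.table
    rows = []
    for branch, grp in df.groupby("branch", sort=True):
        t = grp["thickness_mm"].to_numpy()
        if t.size == 0:
            raise ValueError(f"no entries for branch {branch!r}")
        mean = float(np.mean(t))
        sd = float(np.std(t, ddof=ddof))
        row = {"branch": branch, "n": t.size, "mean_mm": mean, "sd_mm": sd}
        if reference is not None and branch in reference:
            ref = float(reference[branch])
            row["reference_mm"] = ref
            row["pct_error"] = abs(mean - ref) / ref * 100.0
        rows.append(row)
    if not rows:
        raise ValueError("thickness grid is empty")
    return pd.DataFrame(rows).set_index("branch")


def compare_groups(
    a: Sequence[float],
    b,
    alpha: float = 0.05,
    paired: bool = False,
) -> GroupComparison:
    """Normality-routed comparison of two samples or a sample vs constant.

    Shapiro--Wilk at ``alpha`` on each sample routes normally distributed
    data to a Welch two-sample t-test (or one-sample t against a constant)
    and non-normal data to Mann--Whitney (or Wilcoxon signed-rank for
    one-sample / paired designs).  Two-tailed p-values; no multiplicity
    correction is applied.
    """
    a = np.asarray(a, dtype=float)
    if a.size < 3:
        raise ValueError("need n >= 3 per sample for normality testing")
    one_sample = np.ndim(b) == 0
    if not one_sample:
        b = np.asarray(b, dtype=float)
        if b.size < 3:
            raise ValueError("need n >= 3 per sample for normality testing")

    if one_sample:
        const = float(b)
        if np.std(a) == 0:
            return GroupComparison("degenerate", float("nan"), False, float("nan"), (float("nan"),), alpha)
        sw_a = stats.shapiro(a).pvalue
        normal = sw_a > alpha
        if normal:
            res = stats.ttest_1samp(a, const)
            return GroupComparison("one-sample-t", float(res.pvalue), res.pvalue <= alpha, float(res.statistic), (float(sw_a),), alpha)
        res = stats.wilcoxon(a - const)
        return GroupComparison("wilcoxon-signed-rank", float(res.pvalue), res.pvalue <= alpha, float(res.statistic), (float(sw_a),), alpha)

    if np.std(a) == 0 and np.std(b) == 0:
        if np.mean(a) == np.mean(b):
            return GroupComparison("degenerate", float("nan"), False, float("nan"), (float("nan"), float("nan")), alpha)
        return GroupComparison("degenerate", float("nan"), False, float("nan"), (float("nan"), float("nan")), alpha)

    sw_a = stats.shapiro(a).pvalue if np.std(a) > 0 else 0.0
    sw_b = stats.shapiro(b).pvalue if np.std(b) > 0 else 0.0
    normal = sw_a > alpha and sw_b > alpha
    if paired:
        if normal:
            res = stats.ttest_rel(a, b)
            return GroupComparison("paired-t", float(res.pvalue), res.pvalue <= alpha, float(res.statistic), (float(sw_a), float(sw_b)), alpha)
        res = stats.wilcoxon(a, b)
        return GroupComparison("wilcoxon-signed-rank", float(res.pvalue), res.pvalue <= alpha, float(res.statistic), (float(sw_a), float(sw_b)), alpha)
    if normal:
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparison("welch-t", float(res.pvalue), res.pvalue <= alpha, float(res.statistic), (float(sw_a), float(sw_b)), alpha)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison("mann-whitney", float(res.pvalue), res.pvalue <= alpha, float(res.statistic), (float(sw_a), float(sw_b)), alpha)
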