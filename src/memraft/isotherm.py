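"""Langmuir surface-pressure/area (pi-A) isotherm analysis.

A compression isotherm records surface pressure pi (mN/m) against mean
molecular area A (A^2/molecule).  From each curve we extract:

* the collapse point (pi_c, A_c) where the film fails and the curve
  flattens into a plateau;
* the limiting molecular area A_0: the zero-pressure extrapolation of an
  ordinary least-squares fit to the linear condensed branch;
* the in-plane compressibility modulus curve Cs^-1(pi) = -A * dpi/dA;
* across a composition series, the slope of A(pi) versus additive mole
  fraction at fixed pi -- negative slopes indicate film condensation by
  the additive, positive slopes film expansion.

Collapse detection is heuristic (no universal definition exists): the
running slope dpi/dA, smoothed over a small window, is compared against
the steepest condensed-branch slope; collapse is called where the slope
magnitude drops below a configurable fraction of it.  The method tag in
the output records which rule fired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .errors import AnalysisError


@dataclass
class Isotherm:
    """One pi-A compression sweep at a fixed additive mole fraction."""

    area_A2: np.ndarray
    pi_mN_m: np.ndarray
    mole_fraction: float = 0.0
    replicate: object = 0

    def __post_init__(self) -> None:
        self.area_A2 = np.asarray(self.area_A2, dtype=float)
        self.pi_mN_m = np.asarray(self.pi_mN_m, dtype=float)
        if self.area_A2.shape != self.pi_mN_m.shape or self.area_A2.ndim != 1:
            raise ValueError("area and pressure must be equal-length 1-D arrays")
        order = np.argsort(-self.area_A2)  # compression order: area decreasing
        self.area_A2 = self.area_A2[order]
        self.pi_mN_m = self.pi_mN_m[order]
        if len(np.unique(self.area_A2)) != len(self.area_A2):
            raise ValueError("areas must be strictly monotone within a sweep")

    def __len__(self) -> int:
        return len(self.area_A2)


@dataclass
class IsothermFeatures:
    limiting_area: float  # A^2/molecule
    collapse_pressure: float  # mN/m
    collapse_area: float  # A^2/molecule
    condensed_slope: float  # mN/m per A^2 (dpi/dA, negative on compression)
    fit_r2: float
    collapse_method: str
    cs_inverse_area: np.ndarray = field(default=None, repr=False)  # type: ignore
    cs_inverse: np.ndarray = field(default=None, repr=False)  # type: ignore


def _smoothed(iso: Isotherm, window: int | None = None) -> np.ndarray:
    """Savitzky-Golay-smoothed pi along the compression sweep."""
    n = len(iso)
    if window is None:
        window = max(5, (n // 20) | 1)
    w = min(window, n if n % 2 else n - 1)
    if w < 3:
        return iso.pi_mN_m
    return signal.savgol_filter(iso.pi_mN_m, w, polyorder=min(2, w - 1), mode="interp")


def _smoothed_slope(iso: Isotherm, window: int | None = None) -> np.ndarray:
    """Smoothed running dpi/dA along the compression sweep."""
    return np.gradient(_smoothed(iso, window), iso.area_A2)


def collapse_point(
    iso: Isotherm, slope_fraction: float = 0.10, window: int | None = None
) -> tuple[float, float, str]:
    """Locate the collapse point of a compression isotherm.

    The condensed-branch slope is estimated by OLS over the rising section
    between 40 % and 90 % of the maximum (smoothed) pressure; collapse is
    the first later point where the smoothed running slope magnitude drops
    below ``slope_fraction`` of it.  Returns ``(pi_c, A_c, method)`` with
    ``method = "slope-drop"`` when the plateau criterion fired and
    ``"no-collapse-plateau"`` when the curve kept rising and the global
    pressure maximum was returned instead.
    """
    if len(iso) < 5:
        raise AnalysisError("need at least 5 points to locate collapse")
    pi_s = _smoothed(iso, window)
    slope = np.gradient(pi_s, iso.area_A2)
    pi_max = pi_s.max()
    if pi_max <= 0:
        raise AnalysisError("isotherm carries no positive surface pressure")
    branch = (pi_s >= 0.4 * pi_max) & (pi_s <= 0.9 * pi_max)
    i_no_plateau = int(np.argmax(iso.pi_mN_m))
    fallback = (
        float(iso.pi_mN_m[i_no_plateau]),
        float(iso.area_A2[i_no_plateau]),
        "no-collapse-plateau",
    )
    if branch.sum() < 2:
        return fallback
    res = stats.linregress(iso.area_A2[branch], pi_s[branch])
    if res.slope >= 0:
        return fallback
    start = int(np.flatnonzero(branch)[-1]) + 1
    after = np.flatnonzero(np.abs(slope[start:]) < slope_fraction * np.abs(res.slope))
    if after.size:
        k = start + int(after[0])
        return float(pi_s[k]), float(iso.area_A2[k]), "slope-drop"
    return fallback


def limiting_area(
    iso: Isotherm, fit_band: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """Zero-pressure extrapolation of the linear condensed branch.

    ``fit_band`` is the (pi_lo, pi_hi) window used for the OLS fit; the
    default spans 60 % to 95 % of the collapse pressure.  Returns
    ``(A_0, slope, r^2)`` with the slope in mN/m per A^2.
    """
    pi_c, a_c, _ = collapse_point(iso)
    if fit_band is None:
        fit_band = (0.60 * pi_c, 0.95 * pi_c)
    lo, hi = fit_band
    mask = (iso.pi_mN_m >= lo) & (iso.pi_mN_m <= hi) & (iso.area_A2 >= a_c)
    if mask.sum() < 5:
        raise AnalysisError(
            f"only {int(mask.sum())} points in fit band pi=[{lo:.2f}, {hi:.2f}] "
            "mN/m; widen the band or densify the sweep (need >= 5)"
        )
    res = stats.linregress(iso.area_A2[mask], iso.pi_mN_m[mask])
    if res.slope == 0:
        raise AnalysisError("condensed branch has zero slope; cannot extrapolate")
    a0 = -res.intercept / res.slope
    return float(a0), float(res.slope), float(res.rvalue**2)


def cs_inverse(iso: Isotherm, window: int = 5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compressibility-modulus curve Cs^-1 = -A * dpi/dA.

    Returns ``(area, pi, cs_inverse)`` arrays along the compression sweep,
    in mN/m.
    """
    slope = _smoothed_slope(iso, window)
    return iso.area_A2, iso.pi_mN_m, -iso.area_A2 * slope


def analyze_isotherm(iso: Isotherm, fit_band=None, slope_fraction: float = 0.10) -> IsothermFeatures:
    """Full single-curve feature extraction."""
    pi_c, a_c, method = collapse_point(iso, slope_fraction=slope_fraction)
    a0, slope, r2 = limiting_area(iso, fit_band)
    area, _, csi = cs_inverse(iso)
    return IsothermFeatures(
        limiting_area=a0,
        collapse_pressure=pi_c,
        collapse_area=a_c,
        condensed_slope=slope,
        fit_r2=r2,
        collapse_method=method,
        cs_inverse_area=area,
        cs_inverse=csi,
    )


@dataclass
class MixingSlope:
    pi_mN_m: float
    slope_A2_per_fraction: float
    slope_se: float
    interpretation: str  # "condensing" | "expanding" | "ideal"
    n_fractions: int
    excluded_fractions: tuple = ()


def area_at_pressure(iso: Isotherm, pi: float) -> float:
    """Mean molecular area at surface pressure ``pi`` on the rising branch.

    Interpolates A(pi) over the monotone pre-collapse section.  Raises
    :class:`AnalysisError` when ``pi`` exceeds the curve's collapse pressure.
    """
    pi_c, a_c, _ = collapse_point(iso)
    if pi > pi_c:
        raise AnalysisError(f"pi={pi} mN/m above collapse ({pi_c:.2f} mN/m)")
    # rising branch in compression order: pi increases as area decreases
    mask = iso.area_A2 >= a_c
    p = iso.pi_mN_m[mask]
    a = iso.area_A2[mask]
    order = np.argsort(p, kind="stable")
    return float(np.interp(pi, p[order], a[order]))


def mixing_slope(
    isotherms: list[Isotherm], pi_list: list[float]
) -> list[MixingSlope]:
    """Slope of mean molecular area versus additive mole fraction at fixed pi.

    Curves sharing a mole fraction (replicates) are averaged after
    interpolating A(pi).  Requires at least three mole fractions including
    the pure film (fraction 0).  Negative slope = condensation; positive =
    expansion.
    """
    fracs = sorted({iso.mole_fraction for iso in isotherms})
    if len(fracs) < 3:
        raise AnalysisError("mixing_slope needs >= 3 mole fractions")
    if 0.0 not in fracs:
        raise AnalysisError("mixing_slope requires the pure film (fraction 0)")
    out = []
    for pi in pi_list:
        xs, ys, excluded = [], [], []
        for frac in fracs:
            areas = []
            for iso in isotherms:
                if iso.mole_fraction != frac:
                    continue
                try:
                    areas.append(area_at_pressure(iso, pi))
                except AnalysisError:
                    excluded.append(frac)
            if areas:
                xs.append(frac)
                ys.append(float(np.mean(areas)))
        if excluded:
            warnings.warn(
                f"pi={pi} mN/m above collapse for fractions {sorted(set(excluded))}; "
                "those curves were excluded",
                stacklevel=2,
            )
        if len(xs) < 3:
            raise AnalysisError(f"fewer than 3 usable fractions at pi={pi} mN/m")
        res = stats.linregress(xs, ys)
        slope, se = float(res.slope), float(res.stderr)
        label = "condensing" if slope < 0 else ("expanding" if slope > 0 else "ideal")
        out.append(
            MixingSlope(
                pi_mN_m=float(pi),
                slope_A2_per_fraction=slope,
                slope_se=se,
                interpretation=label,
                n_fractions=len(xs),
                excluded_fractions=tuple(sorted(set(excluded))),
            )
        )
    return out
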