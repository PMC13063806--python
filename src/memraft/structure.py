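"""Bilayer structural metrics and depth-region analysis.

Covers leaflet assignment, area per lipid (APL), bilayer thickness, the
area compressibility modulus K_A from box-area fluctuations, mass density
profiles along the membrane normal, and the five-region depth scheme used
to localize ligands:

    1  bulk water
    2  low-density headgroup periphery
    3  high-density headgroup / glycerol band
    4  high-density acyl-chain region
    5  low-density bilayer center

APL is the projected box area divided by the lipids per leaflet (for
homogeneous or well-mixed leaflets this equals the Voronoi mean); bilayer
thickness is the separation of the mean headgroup reference planes
(phosphorus for phospholipids, hydroxyl oxygen for sterols).  K_A uses
the standard equilibrium fluctuation estimator K_A = k_B T <A> / var(A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .synthetic import KB
from .trajectory import Frame, Topology, Trajectory


@dataclass
class MembraneMetrics:
    apl_nm2: float
    apl_sd: float
    thickness_nm: float
    thickness_sd: float
    k_a_N_per_m: float | None
    n_frames_used: int


def assign_leaflets(frame: Frame, topology: Topology) -> pd.DataFrame:
    """Label each lipid upper/lower by its reference atom's side of the midplane.

    The midplane is the mean reference-atom z.  A reference atom exactly at
    the midplane is assigned to the upper leaflet (tie-break convention,
    logged as a warning).  Returns a per-lipid table with columns
    ``residue_id``, ``species``, ``atom_index``, ``leaflet``.
    """
    refs = topology.reference_atoms()
    z = frame.coordinates[refs["atom_index"].to_numpy(), 2]
    midplane = float(z.mean())
    at_mid = z == midplane
    if at_mid.any():
        warnings.warn(
            f"{int(at_mid.sum())} reference atom(s) exactly at the midplane; "
            "assigned to the upper leaflet",
            stacklevel=2,
        )
    out = refs[["residue_id", "species", "atom_index"]].copy()
    out["leaflet"] = np.where(z >= midplane, "upper", "lower")
    return out


def _leaflet_counts(leaflets: pd.DataFrame) -> tuple[int, int]:
    n_up = int((leaflets["leaflet"] == "upper").sum())
    n_lo = int((leaflets["leaflet"] == "lower").sum())
    if n_up == 0 or n_lo == 0:
        raise AnalysisError("one leaflet has no lipids; cannot compute bilayer metrics")
    return n_up, n_lo


def area_per_lipid(traj: Trajectory, topology: Topology) -> tuple[float, float, np.ndarray]:
    """Per-frame APL averaged over leaflets; returns (mean, sd, series) in nm^2."""
    leaflets = assign_leaflets(traj.frame(0), topology)
    n_up, n_lo = _leaflet_counts(leaflets)
    series = traj.areas * 0.5 * (1.0 / n_up + 1.0 / n_lo)
    sd = float(np.std(series, ddof=1)) if traj.n_frames > 1 else 0.0
    return float(series.mean()), sd, series


def bilayer_thickness(traj: Trajectory, topology: Topology) -> tuple[float, float, np.ndarray]:
    """Reference-plane separation per frame; returns (mean, sd, series) in nm."""
    leaflets = assign_leaflets(traj.frame(0), topology)
    _leaflet_counts(leaflets)
    idx = leaflets["atom_index"].to_numpy()
    upper = idx[(leaflets["leaflet"] == "upper").to_numpy()]
    lower = idx[(leaflets["leaflet"] == "lower").to_numpy()]
    series = traj.coordinates[:, upper, 2].mean(axis=1) - traj.coordinates[
        :, lower, 2
    ].mean(axis=1)
    sd = float(np.std(series, ddof=1)) if traj.n_frames > 1 else 0.0
    return float(series.mean()), sd, series


def area_compressibility(
    area_series_nm2: np.ndarray, temperature: float
) -> tuple[float, dict]:
    """Area compressibility modulus from box-area fluctuations.

    K_A = k_B T <A> / var(A), with areas in nm^2; the result is in N/m.
    Requires at least 100 frames and a non-degenerate series.
    """
    a = np.asarray(area_series_nm2, dtype=float)
    if a.size < 100:
        raise AnalysisError(f"need >= 100 frames for K_A; got {a.size}")
    if temperature <= 0:
        raise AnalysisError("temperature must be positive")
    mean = float(a.mean())
    var = float(a.var(ddof=1))
    if var == 0:
        raise AnalysisError("degenerate area series (zero variance)")
    # <A> in m^2 carries 1e-18, var(A) in m^4 carries 1e-36 -> net 1e18
    k_a = KB * temperature * mean / var * 1e18
    meta = {
        "mean_area_nm2": mean,
        "var_area_nm4": var,
        "temperature_K": temperature,
        "n_frames": int(a.size),
        "units": "N/m via K_A = kB*T*<A>/var(A), areas nm^2 -> m^2 (x1e-18)",
    }
    return k_a, meta


@dataclass
class DensityProfile:
    """Frame-averaged mass density along the membrane normal, midplane-centered."""

    z_centers_nm: np.ndarray
    density_kg_m3: np.ndarray
    bin_width_nm: float
    selection: str = ""


_AMU_PER_NM3_IN_KG_M3 = 1.66053906660  # 1 amu/nm^3 = 1.6605... kg/m^3


def mass_density_profile(
    traj: Trajectory,
    topology: Topology,
    selection: np.ndarray,
    bin_width_nm: float = 0.1,
    selection_label: str = "",
) -> DensityProfile:
    """Mass density of a selection along z, re-centered on the bilayer midplane.

    Per frame, selection atom masses are histogrammed against z minus the
    frame's midplane (mean reference-atom z) and converted to kg/m^3 with
    the frame's bin volume; profiles are then frame-averaged.
    """
    selection = np.asarray(selection)
    if selection.size == 0:
        raise AnalysisError("empty selection for density profile")
    if bin_width_nm <= 0:
        raise AnalysisError("bin_width must be positive")
    refs = topology.reference_atoms()
    ref_idx = refs["atom_index"].to_numpy()
    masses = topology.table["mass_amu"].to_numpy()[selection]

    box_z = float(traj.boxes[0, 2])
    n_bins = max(int(np.round(box_z / bin_width_nm)), 1)
    edges = np.linspace(-box_z / 2.0, box_z / 2.0, n_bins + 1)
    width = edges[1] - edges[0]

    acc = np.zeros(n_bins)
    for t in range(traj.n_frames):
        mid = traj.coordinates[t, ref_idx, 2].mean()
        z_rel = traj.coordinates[t, selection, 2] - mid
        hist, _ = np.histogram(z_rel, bins=edges, weights=masses)
        vol = traj.boxes[t, 0] * traj.boxes[t, 1] * width  # nm^3
        acc += hist / vol * _AMU_PER_NM3_IN_KG_M3
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, acc / traj.n_frames, width, selection_label)


@dataclass
class RegionScheme:
    """Five depth regions delimited by four |z| boundaries (nm from midplane).

    ``boundaries`` = (b45, b34, b23, b12), strictly increasing: region 5
    (bilayer center) for |z| < b45, region 4 up to b34, region 3 up to
    b23, region 2 up to b12, region 1 (bulk water) beyond.
    """

    boundaries: tuple[float, float, float, float]
    labels = {
        1: "bulk water",
        2: "low-density headgroup periphery",
        3: "high-density headgroup/glycerol",
        4: "high-density acyl chain",
        5: "low-density bilayer center",
    }

    def __post_init__(self) -> None:
        b = self.boundaries
        if not (0 < b[0] < b[1] < b[2] < b[3]):
            raise AnalysisError(
                f"region boundaries must be strictly increasing and positive: {b}"
            )

    def region_of(self, z_nm: float) -> int:
        az = abs(float(z_nm))
        b45, b34, b23, b12 = self.boundaries
        if az < b45:
            return 5
        if az < b34:
            return 4
        if az < b23:
            return 3
        if az < b12:
            return 2
        return 1


def _fold(profile: DensityProfile) -> tuple[np.ndarray, np.ndarray]:
    """Fold a profile onto |z|, averaging the two leaflets."""
    z = profile.z_centers_nm
    d = profile.density_kg_m3
    az = np.abs(z)
    grid = np.unique(np.round(az, 9))
    folded = np.array([d[np.isclose(az, g)].mean() for g in grid])
    return grid, folded


def _cross_up(x: np.ndarray, y: np.ndarray, level: float, start: int = 0) -> float | None:
    """First x >= x[start] where y crosses the level from below (interpolated)."""
    for i in range(max(start, 1), len(x)):
        if y[i - 1] < level <= y[i]:
            f = (level - y[i - 1]) / (y[i] - y[i - 1])
            return float(x[i - 1] + f * (x[i] - x[i - 1]))
    return None


def classify_regions(
    headgroup: DensityProfile,
    tails: DensityProfile,
    water: DensityProfile | None = None,
    smooth_nm: float = 0.15,
) -> RegionScheme:
    """Derive the five-region boundaries from lipid density profiles.

    Boundaries (symmetric in |z|, outward from the midplane):

    * 4|5 -- half-rise of the tail density out of its central trough;
    * 3|4 -- headgroup/tail density crossover;
    * 2|3 -- outer half-maximum shoulder of the headgroup band;
    * 1|2 -- water/headgroup crossover when a water profile is supplied,
      else the point where the headgroup density decays to 2 % of its peak.

    Folded profiles are Gaussian-smoothed (sigma ``smooth_nm``) first so
    that coarse-grained, delta-like bead profiles form contiguous bands;
    set ``smooth_nm=0`` for already-smooth atomistic profiles.
    """
    if not np.allclose(headgroup.z_centers_nm, tails.z_centers_nm):
        raise AnalysisError("profiles must share a common z grid")
    z, head = _fold(headgroup)
    _, tail = _fold(tails)
    if smooth_nm > 0:
        from scipy.ndimage import gaussian_filter1d

        sigma = smooth_nm / headgroup.bin_width_nm
        head = gaussian_filter1d(head, sigma, mode="nearest")
        tail = gaussian_filter1d(tail, sigma, mode="nearest")
    if head.max() <= 0 or tail.max() <= 0:
        raise AnalysisError("non-overlapping or empty profiles")

    # 4|5: tail density half-rise out of the central trough
    trough, peak_t = tail[0], tail.max()
    if peak_t - trough <= 0:
        raise AnalysisError("tail profile has no central trough")
    b45 = _cross_up(z, tail, 0.5 * (trough + peak_t))
    if b45 is None:
        raise AnalysisError("could not locate the 4|5 boundary")

    # 3|4: head/tail crossover beyond the tail-dominant core
    diff = head - tail
    i_tail_peak = int(np.argmax(tail))
    b34 = _cross_up(z, diff, 0.0, start=max(i_tail_peak, 1))
    if b34 is None or b34 <= b45:
        raise AnalysisError("could not locate the 3|4 boundary (head/tail crossover)")

    # 2|3: outer half-max of the headgroup band
    i_head_peak = int(np.argmax(head))
    b23 = None
    level = 0.5 * head.max()
    for i in range(i_head_peak + 1, len(z)):
        if head[i - 1] >= level >= head[i] and head[i - 1] != head[i]:
            f = (level - head[i - 1]) / (head[i] - head[i - 1])
            b23 = float(z[i - 1] + f * (z[i] - z[i - 1]))
            break
    if b23 is None or b23 <= b34:
        raise AnalysisError("could not locate the 2|3 boundary (headgroup shoulder)")

    # 1|2: water crossover, or headgroup decay to 2% of peak
    b12 = None
    if water is not None:
        _, wat = _fold(water)
        if smooth_nm > 0:
            from scipy.ndimage import gaussian_filter1d

            wat = gaussian_filter1d(wat, smooth_nm / water.bin_width_nm, mode="nearest")
        for i in range(i_head_peak + 1, len(z)):
            if (wat[i - 1] - head[i - 1]) * (wat[i] - head[i]) <= 0 and wat[i] >= head[i]:
                b12 = float(z[i])
                break
    if b12 is None:
        level = 0.02 * head.max()
        for i in range(i_head_peak + 1, len(z)):
            if head[i] <= level:
                b12 = float(z[i])
                break
    if b12 is None or b12 <= b23:
        b12 = float(z[-1])  # headgroup extends to the box edge; region 1 vanishes
    if b12 <= b23:
        raise AnalysisError("region boundaries are not strictly ordered")
    return RegionScheme((b45, b34, b23, b12))


def locate_ligand(
    ligand: DensityProfile, scheme: RegionScheme
) -> tuple[dict[int, float], int]:
    """Region occupancy fractions and the region containing the density peak."""
    d = ligand.density_kg_m3
    total = d.sum()
    if total <= 0:
        raise AnalysisError("ligand profile carries no mass")
    occ = {r: 0.0 for r in (1, 2, 3, 4, 5)}
    for zc, dv in zip(ligand.z_centers_nm, d):
        occ[scheme.region_of(zc)] += float(dv)
    occ = {r: v / total for r, v in occ.items()}
    peak_region = scheme.region_of(ligand.z_centers_nm[int(np.argmax(d))])
    return occ, peak_region


def membrane_metrics(
    traj: Trajectory, topology: Topology, temperature: float | None = None
) -> MembraneMetrics:
    """Convenience wrapper: APL, thickness and (if T given) K_A in one call."""
    apl, apl_sd, _ = area_per_lipid(traj, topology)
    th, th_sd, _ = bilayer_thickness(traj, topology)
    k_a = None
    if temperature is not None and traj.n_frames >= 100:
        try:
            k_a, _ = area_compressibility(traj.areas, temperature)
        except AnalysisError:
            k_a = None
    return MembraneMetrics(apl, apl_sd, th, th_sd, k_a, traj.n_frames)
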