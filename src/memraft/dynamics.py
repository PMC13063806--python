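"""Lateral diffusion analysis: unwrapping, MSD curves and Einstein fits.

The lateral diffusion coefficient D_xy of a lipid follows from the 2-D
Einstein relation MSD(tau) = 4 D tau, fitted by ordinary least squares
over a lag window (default 10-200 ns, configurable because synthetic runs
may be shorter).  Trajectories are first unwrapped under periodic
boundaries by nearest-image accumulation of per-frame displacements;
optional per-leaflet center-of-mass drift removal is on by default.
Diffusion coefficients are reported in cm^2/s (1 nm^2/ns = 1e-5 cm^2/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .structure import assign_leaflets
from .synthetic import CM2_PER_S_PER_NM2_PER_NS
from .trajectory import Topology, Trajectory, minimum_image


@dataclass
class Tracks:
    """Continuous (unwrapped) lateral tracks of selected molecules."""

    xy: np.ndarray  # (n_frames, n_molecules, 2), nm
    species: np.ndarray  # (n_molecules,)
    residue_ids: np.ndarray  # (n_molecules,)
    times: np.ndarray  # (n_frames,), ns

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.xy.shape[1]


@dataclass
class MSDCurve:
    """MSD(tau): ensemble (1-D) or per-molecule (2-D, lags x molecules)."""

    lag_ns: np.ndarray
    msd_nm2: np.ndarray
    n_origin_pairs: np.ndarray
    selection: str = ""

    @property
    def per_molecule(self) -> bool:
        return self.msd_nm2.ndim == 2


@dataclass
class DiffusionResult:
    d_cm2_s: float
    slope_nm2_ns: float
    intercept_nm2: float
    r2: float
    window_ns: tuple[float, float]
    per_molecule: pd.DataFrame | None = None  # residue_id, species, d_cm2_s, r2


def unwrap_lateral(
    traj: Trajectory,
    topology: Topology,
    selection: np.ndarray | None = None,
    remove_com_drift: bool = True,
    max_step_fraction: float = 0.9,
) -> Tracks:
    """Nearest-image accumulation of lateral displacements.

    ``selection`` defaults to the per-lipid headgroup reference atoms.
    With ``remove_com_drift`` the mean per-frame displacement of each
    leaflet is subtracted before accumulation, removing collective motion.
    Nearest-image accumulation assumes every true per-frame displacement
    stays below half a box edge; since displacements at or beyond that
    limit are aliased and unobservable, any apparent step exceeding
    ``max_step_fraction`` of the half-box is treated as evidence of
    undersampling and raises with advice to sample more densely.
    """
    refs = topology.reference_atoms()
    if selection is None:
        sel = refs["atom_index"].to_numpy()
        species = refs["species"].to_numpy()
        res_ids = refs["residue_id"].to_numpy()
    else:
        sel = np.asarray(selection)
        species = topology.table["species"].to_numpy()[sel]
        res_ids = topology.table["residue_id"].to_numpy()[sel]
    if sel.size == 0:
        raise AnalysisError("empty selection for unwrapping")

    xy = traj.coordinates[:, sel, :2]
    boxes = traj.boxes[:, None, :2]
    steps = minimum_image(np.diff(xy, axis=0), boxes[1:])
    max_step = np.abs(steps).max(initial=0.0)
    limit = max_step_fraction * float(boxes.min()) / 2.0
    if max_step >= limit:
        raise AnalysisError(
            f"per-frame displacement {max_step:.3f} nm reaches "
            f"{max_step_fraction:.0%} of half the box edge; displacements "
            "this large alias under periodic wrapping -- sample the "
            "trajectory more densely"
        )

    if remove_com_drift:
        leaflets = assign_leaflets(traj.frame(0), topology)
        lmap = dict(zip(leaflets["residue_id"], leaflets["leaflet"]))
        labels = np.array([lmap.get(r, "upper") for r in res_ids])
        for lab in np.unique(labels):
            m = labels == lab
            steps[:, m, :] -= steps[:, m, :].mean(axis=1, keepdims=True)

    tracks = np.concatenate(
        [xy[:1], xy[:1] + np.cumsum(steps, axis=0)], axis=0
    )
    return Tracks(tracks, species, res_ids, traj.times.copy())


def msd(
    tracks: Tracks,
    lags: np.ndarray | None = None,
    max_lag: int | None = None,
    origin_stride: int = 1,
    per_molecule: bool = False,
    selection: str = "",
) -> MSDCurve:
    """Time- and ensemble-averaged MSD over strided origins.

    ``lags`` are frame counts (integers); default every lag up to
    ``max_lag`` (or a quarter of the track length).  ``origin_stride``
    thins the time origins.  With ``per_molecule`` the average over
    molecules is kept separate (lags x molecules matrix).
    """
    n = tracks.n_frames
    if lags is None:
        if max_lag is None:
            max_lag = max(n // 4, 1)
        if max_lag >= n:
            raise AnalysisError(f"max_lag {max_lag} must be < track length {n}")
        lags = np.arange(0, max_lag + 1)
    lags = np.asarray(lags, dtype=int)
    if lags.max(initial=0) >= n:
        raise AnalysisError("requested lag beyond track length")
    if tracks.n_molecules == 0:
        raise AnalysisError("no molecules in tracks")

    shape = (len(lags), tracks.n_molecules) if per_molecule else (len(lags),)
    out = np.zeros(shape)
    n_pairs = np.zeros(len(lags), dtype=int)
    xy = tracks.xy
    for i, lag in enumerate(lags):
        if lag == 0:
            n_pairs[i] = ((n - 1) // origin_stride + 1) * tracks.n_molecules
            continue
        disp = xy[lag:][::origin_stride] - xy[:-lag][::origin_stride]
        sq = (disp**2).sum(axis=-1)  # (n_origins, n_molecules)
        n_pairs[i] = sq.shape[0] * tracks.n_molecules
        out[i] = sq.mean(axis=0) if per_molecule else sq.mean()
    return MSDCurve(lags * tracks.dt, out, n_pairs, selection)


def fit_diffusion(
    curve: MSDCurve,
    window_ns: tuple[float, float],
    tracks: Tracks | None = None,
    r2_warn: float = 0.98,
) -> DiffusionResult:
    """OLS fit of MSD on lag time within a window; D_xy = slope / 4.

    For a per-molecule curve, each molecule is fitted with the same window
    and the ensemble result is the fit of the molecule-mean MSD; the
    per-molecule table (negative slopes retained) is attached when
    ``tracks`` supplies identities.
    """
    lo, hi = window_ns
    mask = (curve.lag_ns >= lo) & (curve.lag_ns <= hi)
    if mask.sum() < 2:
        raise AnalysisError(
            f"fit window [{lo}, {hi}] ns holds {int(mask.sum())} points; "
            f"available lags span [{curve.lag_ns.min():.3g}, "
            f"{curve.lag_ns.max():.3g}] ns"
        )
    tau = curve.lag_ns[mask]

    def _fit(y: np.ndarray) -> tuple[float, float, float]:
        res = stats.linregress(tau, y)
        r2 = float(res.rvalue**2) if np.std(y) > 0 else 1.0
        return float(res.slope), float(res.intercept), r2

    if curve.per_molecule:
        ens = curve.msd_nm2[mask].mean(axis=1)
        slope, intercept, r2 = _fit(ens)
        rows = []
        for m in range(curve.msd_nm2.shape[1]):
            s_m, _, r2_m = _fit(curve.msd_nm2[mask][:, m])
            rows.append(
                {
                    "residue_id": tracks.residue_ids[m] if tracks is not None else m,
                    "species": tracks.species[m] if tracks is not None else "",
                    "d_cm2_s": s_m / 4.0 * CM2_PER_S_PER_NM2_PER_NS,
                    "r2": r2_m,
                }
            )
        per_mol = pd.DataFrame(rows)
    else:
        slope, intercept, r2 = _fit(curve.msd_nm2[mask])
        per_mol = None

    if r2 < r2_warn:
        warnings.warn(
            f"MSD fit r^2 = {r2:.4f} below {r2_warn}; the curve may not be "
            "linear over the chosen window",
            stacklevel=2,
        )
    return DiffusionResult(
        d_cm2_s=slope / 4.0 * CM2_PER_S_PER_NM2_PER_NS,
        slope_nm2_ns=slope,
        intercept_nm2=intercept,
        r2=r2,
        window_ns=(float(lo), float(hi)),
        per_molecule=per_mol,
    )


def species_diffusion(
    tracks: Tracks,
    window_ns: tuple[float, float],
    lags: np.ndarray | None = None,
    origin_stride: int = 1,
) -> pd.DataFrame:
    """Per-species D_xy: ensemble fit plus per-molecule mean +/- sd.

    Returns one row per species with columns ``d_cm2_s`` (ensemble fit),
    ``d_mean_cm2_s``/``d_sd_cm2_s`` (over per-molecule fits), ``n_molecules``
    and ``r2``.
    """
    if lags is None:
        hi_frames = int(np.ceil(window_ns[1] / tracks.dt))
        lags = np.unique(
            np.linspace(0, min(hi_frames, tracks.n_frames - 1), 101).astype(int)
        )
    rows = []
    for sp in np.unique(tracks.species):
        m = tracks.species == sp
        sub = Tracks(tracks.xy[:, m], tracks.species[m], tracks.residue_ids[m], tracks.times)
        curve = msd(sub, lags=lags, origin_stride=origin_stride, per_molecule=True, selection=sp)
        fit = fit_diffusion(curve, window_ns, tracks=sub)
        d_per = fit.per_molecule["d_cm2_s"]
        rows.append(
            {
                "species": sp,
                "d_cm2_s": fit.d_cm2_s,
                "d_mean_cm2_s": float(d_per.mean()),
                "d_sd_cm2_s": float(d_per.std(ddof=1)) if len(d_per) > 1 else 0.0,
                "n_molecules": int(m.sum()),
                "r2": fit.r2,
            }
        )
    return pd.DataFrame(rows)
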