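"""Ligand-membrane interaction machinery.

Implements geometric hydrogen-bond detection (donor-acceptor distance and
donor-hydrogen-acceptor angle criteria), heavy-atom contact counting per
lipid species/subregion, minimum-distance traces, the cumulative
strong-binding-time statistic, and Shrake-Rupley SASA partitioning of a
ligand surface between lipid headgroups, lipid tails and solvent.

Boundary conventions, fixed once and documented: a contact requires a
minimum-image distance strictly *below* the cutoff; "exceeds threshold"
for the binding time is strict (>); the H-bond criterion is inclusive
(distance <= d_cut and angle >= angle_cut).  All pair distances respect
the minimum-image convention in rectangular periodic boxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import AnalysisError, TopologyError
from .trajectory import (
    HEADGROUP_SUBREGIONS,
    Frame,
    Topology,
    Trajectory,
    minimum_image,
    wrap,
)


@dataclass
class ContactSeries:
    """Per-frame contact counts for one (group pair, cutoff) key."""

    counts: np.ndarray  # (n_frames,) nonnegative integers
    dt: float  # ns between frames
    cutoff_nm: float
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.counts)


@dataclass
class BindingTimeResult:
    """Cumulative time the contact count stays above the threshold."""

    strong_binding_time_ns: float
    threshold: int
    cutoff_nm: float
    n_frames_above: int
    n_frames_total: int
    label: str = ""


@dataclass
class SasaPartition:
    """Shrake-Rupley ligand surface area split by what it touches (A^2)."""

    total_A2: float
    headgroup_A2: float
    tail_A2: float
    solvent_A2: float
    probe_radius_nm: float
    n_points: int


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    d_cut_nm: float = 0.30,
    angle_cut_deg: float = 150.0,
    pair_filter=None,
    exclude_same_residue: bool = True,
) -> pd.DataFrame:
    """Geometric hydrogen-bond detection on one frame.

    A bond is recorded iff the donor-acceptor minimum-image distance is
    <= ``d_cut_nm`` *and* the donor-hydrogen-acceptor angle is >=
    ``angle_cut_deg``.  ``pair_filter(donor_species, acceptor_species)``
    optionally restricts which species pairs are considered (e.g. only
    ligand-PSM, or PSM-CHOL).

    Returns a DataFrame with one row per (hydrogen, acceptor) bond:
    donor/hydrogen/acceptor ids and names, species, distance (nm) and
    angle (deg).
    """
    tab = topology.table
    acceptors = topology.acceptors()
    hydrogens = topology.hydrogens()
    if len(acceptors) == 0 or len(hydrogens) == 0:
        return _empty_hbond_table()

    box = frame.box
    pts = wrap(frame.coordinates, box)
    tree = cKDTree(pts[acceptors], boxsize=box)

    donor_idx = np.array(
        [topology.donor_index_of_hydrogen(int(h)) for h in hydrogens]
    )
    if np.any(~tab.iloc[donor_idx]["is_donor"].to_numpy()):
        bad = hydrogens[~tab.iloc[donor_idx]["is_donor"].to_numpy()]
        raise TopologyError(
            f"hydrogens {tab.iloc[bad]['atom_id'].tolist()} bonded to "
            "non-donor heavy atoms"
        )

    res = tab["residue_id"].to_numpy()
    species = tab["species"].to_numpy()
    names = tab["atom_name"].to_numpy()
    ids = tab["atom_id"].to_numpy()

    candidates = tree.query_ball_point(pts[donor_idx], d_cut_nm)
    rows = []
    for hi, di, cand in zip(hydrogens, donor_idx, candidates):
        for c in cand:
            ai = int(acceptors[c])
            if ai == di:
                continue
            if exclude_same_residue and res[ai] == res[di]:
                continue
            if pair_filter is not None and not pair_filter(species[di], species[ai]):
                continue
            da = minimum_image(pts[ai] - pts[di], box)
            dist = float(np.linalg.norm(da))
            if dist > d_cut_nm:
                continue
            hd = minimum_image(pts[di] - pts[hi], box)
            ha = minimum_image(pts[ai] - pts[hi], box)
            cosang = hd.dot(ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < angle_cut_deg:
                continue
            rows.append(
                {
                    "donor_id": ids[di],
                    "hydrogen_id": ids[hi],
                    "acceptor_id": ids[ai],
                    "donor_name": names[di],
                    "acceptor_name": names[ai],
                    "donor_species": species[di],
                    "acceptor_species": species[ai],
                    "donor_residue": res[di],
                    "acceptor_residue": res[ai],
                    "distance_nm": dist,
                    "angle_deg": angle,
                }
            )
    return pd.DataFrame(rows) if rows else _empty_hbond_table()


def _empty_hbond_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "donor_id",
            "hydrogen_id",
            "acceptor_id",
            "donor_name",
            "acceptor_name",
            "donor_species",
            "acceptor_species",
            "donor_residue",
            "acceptor_residue",
            "distance_nm",
            "angle_deg",
        ]
    )


def hbonds_trajectory(traj: Trajectory, topology: Topology, **kw) -> pd.DataFrame:
    """Run :func:`detect_hbonds` over all frames, adding a ``frame`` column."""
    parts = []
    for i, frame in enumerate(traj):
        rec = detect_hbonds(frame, topology, **kw)
        rec.insert(0, "frame", i)
        parts.append(rec)
    return pd.concat(parts, ignore_index=True)


def hbond_count_by_pair(
    records: pd.DataFrame, n_frames: int, dedupe: bool = False
) -> pd.DataFrame:
    """Time-averaged H-bond counts per (donor species, acceptor species).

    With ``dedupe=True`` multiple hydrogens of the same donor bonded to the
    same acceptor count once per frame.
    """
    if records.empty:
        return pd.DataFrame(columns=["donor_species", "acceptor_species", "mean_count"])
    rec = records
    if dedupe:
        rec = rec.drop_duplicates(["frame", "donor_id", "acceptor_id"])
    g = (
        rec.groupby(["donor_species", "acceptor_species"])
        .size()
        .rename("mean_count")
        .reset_index()
    )
    g["mean_count"] = g["mean_count"] / float(n_frames)
    return g


def hbonds_per_hydroxyl(
    records: pd.DataFrame, n_frames: int, ligand_species: str
) -> pd.DataFrame:
    """Time-averaged ligand H-bond counts keyed by the ligand oxygen name.

    Bonds where the ligand donates are keyed by the donor oxygen's atom
    name; bonds where it accepts by the acceptor oxygen's name, so each
    hydroxyl's total engagement is reported under its oxygen index.
    """
    if records.empty:
        return pd.DataFrame(columns=["oxygen", "mean_count"])
    don = records[records["donor_species"] == ligand_species]
    acc = records[records["acceptor_species"] == ligand_species]
    keyed = pd.concat(
        [
            don["donor_name"].rename("oxygen"),
            acc["acceptor_name"].rename("oxygen"),
        ]
    )
    g = keyed.value_counts().rename("mean_count").rename_axis("oxygen").reset_index()
    g["mean_count"] = g["mean_count"] / float(n_frames)
    return g


# ---------------------------------------------------------------------------
# contacts and minimum distances
# ---------------------------------------------------------------------------


def _check_cutoff(cutoff: float, box: np.ndarray) -> None:
    if cutoff <= 0:
        raise AnalysisError("cutoff must be positive")
    if cutoff > float(np.min(box)) / 2.0:
        raise AnalysisError(
            f"cutoff {cutoff} nm exceeds half the smallest box edge "
            f"({np.min(box) / 2:.3f} nm); minimum-image counting is invalid"
        )


def _frame_contacts(
    pts: np.ndarray,
    box: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    cutoff: float,
    method: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into idx_a/idx_b) of all pairs with distance < cutoff."""
    if method == "grid":
        ta = cKDTree(pts[idx_a], boxsize=box)
        tb = cKDTree(pts[idx_b], boxsize=box)
        coo = ta.sparse_distance_matrix(tb, cutoff, output_type="coo_matrix")
        keep = coo.data < cutoff  # strict inequality
        return coo.row[keep], coo.col[keep]
    if method == "brute":
        delta = pts[idx_a][:, None, :] - pts[idx_b][None, :, :]
        delta = minimum_image(delta, box)
        dist = np.sqrt((delta**2).sum(-1))
        ia, ib = np.nonzero(dist < cutoff)
        return ia, ib
    raise ValueError("method must be 'grid' or 'brute'")


def count_contacts(
    traj: Trajectory,
    topology: Topology,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff_nm: float = 0.45,
    by_subregion: bool = False,
    heavy_only: bool = True,
    method: str = "grid",
    label: str = "",
):
    """Per-frame count of atom pairs (a in A, b in B) closer than the cutoff.

    ``group_a``/``group_b`` are positional atom indices.  With
    ``heavy_only`` (default) hydrogens are dropped from both groups before
    counting.  With ``by_subregion`` a dict of
    :class:`ContactSeries` keyed by the subregion tag of the B atom is
    returned instead of a single series.  ``method="brute"`` is the
    all-pairs reference path used as an oracle for the grid implementation.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise AnalysisError("contact groups must be non-empty")
    if heavy_only:
        group_a = topology.heavy_atoms(group_a)
        group_b = topology.heavy_atoms(group_b)
        if group_a.size == 0 or group_b.size == 0:
            raise AnalysisError("contact groups empty after removing hydrogens")
    dt = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 1.0
    sub_b = topology.table["subregion"].to_numpy()[group_b]

    if by_subregion:
        tags = sorted(set(sub_b))
        counts = {tag: np.zeros(traj.n_frames, dtype=np.int64) for tag in tags}
    else:
        total = np.zeros(traj.n_frames, dtype=np.int64)

    for t in range(traj.n_frames):
        box = traj.boxes[t]
        _check_cutoff(cutoff_nm, box)
        pts = wrap(traj.coordinates[t], box)
        ia, ib = _frame_contacts(pts, box, group_a, group_b, cutoff_nm, method)
        if by_subregion:
            for tag in counts:
                counts[tag][t] = int(np.sum(sub_b[ib] == tag))
        else:
            total[t] = len(ia)

    if by_subregion:
        return {
            tag: ContactSeries(c, dt, cutoff_nm, label=f"{label}:{tag}" if label else tag)
            for tag, c in counts.items()
        }
    return ContactSeries(total, dt, cutoff_nm, label=label)


def min_distance(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    method: str = "grid",
) -> np.ndarray:
    """Per-frame minimum minimum-image distance (nm) between two groups."""
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise AnalysisError("groups must be non-empty")
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        box = traj.boxes[t]
        pts = wrap(traj.coordinates[t], box)
        if method == "grid":
            tree = cKDTree(pts[group_b], boxsize=box)
            d, _ = tree.query(pts[group_a], k=1)
            out[t] = float(np.min(d))
        else:
            delta = minimum_image(pts[group_a][:, None, :] - pts[group_b][None, :, :], box)
            out[t] = float(np.sqrt((delta**2).sum(-1)).min())
    return out


def strong_binding_time(
    series: ContactSeries, threshold: int = 800, dt: float | None = None
) -> BindingTimeResult:
    """Cumulative time the contact count strictly exceeds the threshold.

    The statistic sums ``dt`` over frames with ``count > threshold``.  With
    ``threshold=-1`` it equals the full trajectory length.
    """
    dt = series.dt if dt is None else dt
    if dt <= 0:
        raise AnalysisError("dt must be positive")
    above = int(np.sum(series.counts > threshold))
    return BindingTimeResult(
        strong_binding_time_ns=above * dt,
        threshold=threshold,
        cutoff_nm=series.cutoff_nm,
        n_frames_above=above,
        n_frames_total=series.n_frames,
        label=series.label,
    )


# ---------------------------------------------------------------------------
# SASA partition (Shrake-Rupley)
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa_partition(
    frame: Frame,
    topology: Topology,
    ligand: np.ndarray,
    probe_radius_nm: float = 0.14,
    n_points: int = 960,
    attribution_tol_nm: float | None = None,
    environment: np.ndarray | None = None,
) -> SasaPartition:
    """Shrake-Rupley SASA of the ligand, partitioned by nearest neighbor class.

    Sphere points are placed on each ligand atom at radius vdW + probe; a
    point is exposed iff it lies inside no other inflated sphere.  Each
    exposed point is attributed to "headgroup" or "tail" when the nearest
    non-ligand inflated surface lies within ``attribution_tol_nm`` (default
    one probe diameter) and belongs to a headgroup-/tail-tagged atom;
    otherwise to solvent.  The three components sum to the total exactly
    (each point lands in one class).  Areas are reported in A^2.
    """
    ligand = np.asarray(ligand)
    if ligand.size == 0:
        raise AnalysisError("ligand selection is empty")
    if attribution_tol_nm is None:
        attribution_tol_nm = 2.0 * probe_radius_nm

    radii = topology.table["vdw_radius_nm"].to_numpy()
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise TopologyError("every atom needs a positive vdW radius")
    sub = topology.table["subregion"].to_numpy()

    box = frame.box
    pts = wrap(frame.coordinates, box)
    env = (
        np.setdiff1d(np.arange(topology.n_atoms), ligand)
        if environment is None
        else np.asarray(environment)
    )
    inflated = radii + probe_radius_nm
    unit = _sphere_points(n_points)

    all_idx = np.concatenate([ligand, env])
    tree = cKDTree(pts[all_idx], boxsize=box)
    max_r = float(inflated.max())

    is_lig = np.zeros(topology.n_atoms, dtype=bool)
    is_lig[ligand] = True
    head = np.isin(sub, list(HEADGROUP_SUBREGIONS))
    tail = sub == "tails"

    total = headg = tailg = solv = 0.0
    for i in ligand:
        ri = inflated[i]
        sphere = pts[i] + ri * unit  # may leave the box; use min-image dists
        # neighbors able to bury or touch points of this sphere
        neigh = all_idx[tree.query_ball_point(pts[i], ri + max_r + attribution_tol_nm)]
        neigh = neigh[neigh != i]
        if neigh.size:
            delta = minimum_image(
                sphere[:, None, :] - pts[neigh][None, :, :], box
            )
            dist = np.sqrt((delta**2).sum(-1))  # (n_points, n_neigh)
            buried = np.any(dist < inflated[neigh][None, :] - 1e-12, axis=1)
        else:
            dist = None
            buried = np.zeros(n_points, dtype=bool)
        exposed = ~buried
        n_exp = int(exposed.sum())
        if n_exp == 0:
            continue
        point_area = 4.0 * np.pi * ri**2 / n_points * 100.0  # nm^2 -> A^2
        total += n_exp * point_area
        if dist is not None:
            env_mask = ~is_lig[neigh]
            if env_mask.any():
                gap = dist[exposed][:, env_mask] - inflated[neigh][env_mask][None, :]
                nearest = np.argmin(gap, axis=1)
                near_gap = gap[np.arange(len(nearest)), nearest]
                env_neigh = neigh[env_mask]
                cls_atom = env_neigh[nearest]
                in_contact = near_gap <= attribution_tol_nm
                n_head = int(np.sum(in_contact & head[cls_atom]))
                n_tail = int(np.sum(in_contact & tail[cls_atom]))
                headg += n_head * point_area
                tailg += n_tail * point_area
                solv += (n_exp - n_head - n_tail) * point_area
                continue
        solv += n_exp * point_area
    return SasaPartition(
        total_A2=total,
        headgroup_A2=headg,
        tail_A2=tailg,
        solvent_A2=solv,
        probe_radius_nm=probe_radius_nm,
        n_points=n_points,
    )
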