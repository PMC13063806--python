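"""Synthetic membrane, dynamics, kinetics and isotherm generators.

Every generator here produces data with *known ground truth* so the
analysis modules can be tested quantitatively without running molecular
dynamics or wet-lab experiments:

* :func:`build_bilayer_config` -- a two-leaflet planar bilayer of coarse
  pseudo-lipids (4-8 beads each) on jittered lattices, with headgroup
  reference atoms, subregion tags and chemically consistent hydrogen-bond
  roles.  Default compositions mirror a liquid-disordered (Ld) membrane of
  40 POPC per leaflet and a liquid-ordered (Lo) membrane of 40 PSM + 80
  CHOL per leaflet (CHOL:PSM = 2:1).
* :func:`simulate_lateral_diffusion` -- free 2-D Brownian lateral motion
  with species-specific diffusion coefficients, optional stationary
  Gaussian box-area fluctuations targeting a chosen area compressibility
  modulus.
* :func:`simulate_binding_trace` -- a two-state (bound/unbound) Markov
  chain emitting noisy per-frame contact counts, returning the true
  cumulative bound time alongside.
* :func:`plant_hbond_geometries` -- donor-hydrogen-acceptor triplets
  placed deliberately inside or outside the geometric acceptance box,
  with a truth table.
* :func:`simulate_isotherm` -- parametric Langmuir pi-A curves with a
  linear condensed branch, collapse plateau and linear mixing shift.

All randomness flows through explicit per-spec seeds; the same seed gives
byte-identical output.  Pseudo-lipids are deliberately not chemically
detailed: the analyses only consume positions, masses, radii and tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpecError
from .interactions import ContactSeries
from .isotherm import Isotherm
from .trajectory import Frame, Topology, Trajectory, wrap

KB = 1.380649e-23  # J/K
#: 1 nm^2/ns expressed in cm^2/s
CM2_PER_S_PER_NM2_PER_NS = 1.0e-5

# ---------------------------------------------------------------------------
# pseudo-lipid templates
# ---------------------------------------------------------------------------
# Each bead: (atom_name, subregion, element, mass_amu, vdw_radius_nm,
#             is_donor, is_hydrogen, is_acceptor, z_offset_nm)
# z_offset is measured from the headgroup reference plane toward the
# bilayer midplane (positive = deeper).  Group masses sum to the molecular
# weight of the real lipid so density profiles carry realistic mass.

_PHOSPHOLIPID_TEMPLATES = {
    # POPC (MW ~760): phospho-oxygens are acceptor-only (no donor groups)
    "POPC": [
        ("N", "choline", "N", 87.0, 0.20, False, False, False, -0.10),
        ("P", "phosphate", "P", 123.0, 0.20, False, False, True, 0.00),
        ("C1", "glycerol", "C", 100.0, 0.20, False, False, True, 0.25),
        ("C2", "tails", "C", 150.0, 0.20, False, False, False, 0.60),
        ("C3", "tails", "C", 150.0, 0.20, False, False, False, 0.95),
        ("C4", "tails", "C", 150.0, 0.20, False, False, False, 1.30),
    ],
    # PSM (MW ~703): sphingosine backbone carries amide N-H / hydroxyl donors
    "PSM": [
        ("N", "choline", "N", 87.0, 0.20, False, False, False, -0.10),
        ("P", "phosphate", "P", 123.0, 0.20, False, False, True, 0.00),
        ("O1", "glycerol", "O", 42.0, 0.18, True, False, True, 0.25),
        ("H1", "glycerol", "H", 1.0, 0.12, False, True, False, 0.33),
        ("C2", "tails", "C", 150.0, 0.20, False, False, False, 0.60),
        ("C3", "tails", "C", 150.0, 0.20, False, False, False, 0.95),
        ("C4", "tails", "C", 150.0, 0.20, False, False, False, 1.30),
    ],
}

_STEROL_TEMPLATES = {
    # CHOL (MW ~387): hydroxyl oxygen is both donor and acceptor
    "CHOL": [
        ("O3", "sterol", "O", 16.0, 0.18, True, False, True, 0.00),
        ("H3", "sterol", "H", 1.0, 0.12, False, True, False, -0.08),
        ("C1", "tails", "C", 130.0, 0.20, False, False, False, 0.40),
        ("C2", "tails", "C", 130.0, 0.20, False, False, False, 0.75),
        ("C3", "tails", "C", 110.0, 0.20, False, False, False, 1.10),
    ],
}

LIPID_TEMPLATES = {**_PHOSPHOLIPID_TEMPLATES, **_STEROL_TEMPLATES}


@dataclass
class BilayerSpec:
    """Geometry of a two-leaflet planar bilayer of pseudo-lipids."""

    composition_per_leaflet: dict  # species -> count
    apl_target: float = 0.651  # nm^2 per lipid (Ld default)
    thickness_target: float = 3.90  # nm, reference-plane separation
    box_z: float = 9.0  # nm
    lattice_jitter: float = 0.05  # fraction of lattice spacing
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.composition_per_leaflet:
            raise SpecError("composition_per_leaflet must not be empty")
        for sp, n in self.composition_per_leaflet.items():
            if sp not in LIPID_TEMPLATES:
                raise SpecError(
                    f"unknown species {sp!r}; templates exist for "
                    f"{sorted(LIPID_TEMPLATES)}"
                )
            if int(n) <= 0:
                raise SpecError(f"count for {sp} must be positive")
        if self.apl_target <= 0:
            raise SpecError("apl_target must be positive")
        if self.thickness_target <= 0 or self.thickness_target >= self.box_z:
            raise SpecError("need 0 < thickness_target < box_z")

    @property
    def n_per_leaflet(self) -> int:
        return int(sum(self.composition_per_leaflet.values()))


def ld_spec(seed: int = 0, **kw) -> BilayerSpec:
    """Liquid-disordered default: 40 POPC per leaflet, APL 0.651 nm^2."""
    kw.setdefault("apl_target", 0.651)
    kw.setdefault("thickness_target", 3.90)
    return BilayerSpec({"POPC": 40}, seed=seed, **kw)


def lo_spec(seed: int = 0, **kw) -> BilayerSpec:
    """Liquid-ordered default: 40 PSM + 80 CHOL per leaflet (CHOL:PSM = 2)."""
    kw.setdefault("apl_target", 0.45)
    kw.setdefault("thickness_target", 4.4)
    return BilayerSpec({"PSM": 40, "CHOL": 80}, seed=seed, **kw)


def build_bilayer_config(spec: BilayerSpec) -> tuple[Frame, Topology]:
    """Build a single-frame bilayer configuration and its topology.

    Lipids sit on a jittered square lattice per leaflet; the projected box
    area is exactly ``n_per_leaflet * apl_target`` and the two reference
    planes are ``thickness_target`` apart, centered in the box.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_leaflet
    area = n * spec.apl_target
    lx = ly = float(np.sqrt(area))
    grid = int(np.ceil(np.sqrt(n)))
    spacing_x, spacing_y = lx / grid, ly / grid
    z_mid = spec.box_z / 2.0

    species_list = []
    for sp, cnt in spec.composition_per_leaflet.items():
        species_list += [sp] * int(cnt)

    rows, coords = [], []
    atom_id, residue_id = 1, 1
    for leaflet, zsign in (("upper", +1.0), ("lower", -1.0)):
        order = rng.permutation(n)  # interleave species on the lattice
        sites = [(i % grid, i // grid) for i in range(n)]
        for k in range(n):
            sp = species_list[order[k]]
            gx, gy = sites[k]
            x0 = (gx + 0.5) * spacing_x + rng.uniform(-1, 1) * spec.lattice_jitter * spacing_x
            y0 = (gy + 0.5) * spacing_y + rng.uniform(-1, 1) * spec.lattice_jitter * spacing_y
            z_ref = z_mid + zsign * spec.thickness_target / 2.0
            for name, sub, elem, mass, radius, don, hyd, acc, dz in LIPID_TEMPLATES[sp]:
                coords.append((x0, y0, z_ref - zsign * dz))
                rows.append(
                    {
                        "atom_id": atom_id,
                        "atom_name": name,
                        "residue_id": residue_id,
                        "species": sp,
                        "subregion": sub,
                        "element": elem,
                        "mass_amu": mass,
                        "vdw_radius_nm": radius,
                        "is_donor": don,
                        "is_hydrogen": hyd,
                        "is_acceptor": acc,
                        "donor_of": -1,
                        "leaflet_hint": leaflet,
                    }
                )
                atom_id += 1
            # hydrogens bond to the donor bead of the same residue
            res_rows = rows[-len(LIPID_TEMPLATES[sp]) :]
            donors = [r for r in res_rows if r["is_donor"]]
            for r in res_rows:
                if r["is_hydrogen"]:
                    if not donors:
                        raise SpecError(f"template {sp} has a hydrogen but no donor")
                    r["donor_of"] = donors[0]["atom_id"]
            residue_id += 1

    coords = np.array(coords)
    coords[:, :2] = np.mod(coords[:, :2], [lx, ly])
    frame = Frame(coords, np.array([lx, ly, spec.box_z]), time=0.0)
    topology = Topology(pd.DataFrame(rows))
    _check_overlaps(frame, topology)
    return frame, topology


def _check_overlaps(frame: Frame, topology: Topology, tol: float = 0.02) -> None:
    """Fail generation if atoms of different residues nearly coincide."""
    from scipy.spatial import cKDTree

    pts = wrap(frame.coordinates, frame.box)
    tree = cKDTree(pts, boxsize=frame.box)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    if len(pairs):
        res = topology.table["residue_id"].to_numpy()
        if np.any(res[pairs[:, 0]] != res[pairs[:, 1]]):
            raise SpecError("generated configuration has overlapping atoms")


def insert_ligand(
    frame: Frame,
    topology: Topology,
    depth_nm: float,
    species: str = "EC",
    n_hydroxyls: int = 4,
    n_core: int = 3,
    seed: int = 0,
    form_hbond: bool = False,
) -> tuple[Frame, Topology]:
    """Insert a compact polyphenol-like ligand at a depth above the midplane.

    The ligand is a cluster of ``n_core`` carbon beads plus ``n_hydroxyls``
    hydroxyl groups (donor+acceptor oxygen named O1..On with a bonded
    hydrogen), placed laterally at a spot clear of existing atoms at
    ``depth_nm`` from the bilayer midplane (positive = upper leaflet side).
    With ``form_hbond`` the first hydroxyl is posed in ideal geometry
    (0.28 nm donor-acceptor, collinear) toward the nearest lipid acceptor.
    Returns a new frame/topology pair with the ligand appended.
    """
    rng = np.random.default_rng(seed)
    z_mid = float(frame.coordinates[topology.reference_atoms()["atom_index"], 2].mean())
    # pick a lateral spot at least 0.25 nm from any existing atom
    center = None
    for _ in range(100):
        cand = np.array(
            [
                rng.uniform(0, frame.box[0]),
                rng.uniform(0, frame.box[1]),
                z_mid + depth_nm,
            ]
        )
        delta = frame.coordinates - cand
        delta -= frame.box * np.round(delta / frame.box)
        if np.sqrt((delta**2).sum(axis=1)).min() >= 0.25:
            center = cand
            break
    if center is None:
        raise SpecError("could not find a clear insertion site for the ligand")
    next_id = int(topology.table["atom_id"].max()) + 1
    res_id = int(topology.table["residue_id"].max()) + 1
    rows, coords = [], []

    def add(name, sub, elem, mass, rad, don, hyd, acc, parent, pos):
        nonlocal next_id
        coords.append(pos)
        rows.append(
            {
                "atom_id": next_id,
                "atom_name": name,
                "residue_id": res_id,
                "species": species,
                "subregion": sub,
                "element": elem,
                "mass_amu": mass,
                "vdw_radius_nm": rad,
                "is_donor": don,
                "is_hydrogen": hyd,
                "is_acceptor": acc,
                "donor_of": parent,
                "leaflet_hint": "",
            }
        )
        next_id += 1

    for i in range(n_core):
        add("C%d" % (i + 1), "ligand", "C", 40.0, 0.20, False, False, False, -1,
            center + rng.normal(0, 0.08, 3))
    for i in range(n_hydroxyls):
        if i == 0 and form_hbond:
            # pose the first hydroxyl toward the nearest lipid acceptor:
            # donor-acceptor 0.28 nm, hydrogen on the axis (180 deg angle)
            acc = topology.acceptors()
            delta = frame.coordinates[acc] - center
            delta -= frame.box * np.round(delta / frame.box)
            j = int(np.argmin((delta**2).sum(axis=1)))
            a_pos = center + delta[j]
            u = -delta[j] / np.linalg.norm(delta[j])
            o_pos = a_pos + 0.28 * u
            h_pos = a_pos + 0.18 * u
        else:
            o_pos = center + rng.normal(0, 0.15, 3)
            h_pos = o_pos + rng.normal(0, 0.05, 3) + [0.0, 0.0, 0.08]
        o_id = next_id
        add("O%d" % (i + 1), "ligand", "O", 17.0, 0.18, True, False, True, -1, o_pos)
        add("HO%d" % (i + 1), "ligand", "H", 1.0, 0.12, False, True, False, o_id, h_pos)

    new_coords = np.vstack([frame.coordinates, np.array(coords)])
    new_table = pd.concat([topology.table, pd.DataFrame(rows)], ignore_index=True)
    return Frame(new_coords, frame.box, frame.time), Topology(new_table)


# ---------------------------------------------------------------------------
# lateral dynamics
# ---------------------------------------------------------------------------


@dataclass
class DynamicsSpec:
    """Free 2-D Brownian lateral motion with optional box-area fluctuations.

    ``d_map`` gives per-species lateral diffusion coefficients in cm^2/s
    (converted internally via 1 cm^2/s = 1e5 nm^2/ns).  Area fluctuations
    are stationary Gaussian draws; give either ``(mean_nm2, variance_nm4)``
    directly via ``area_fluctuation`` or a target modulus via
    ``k_a_target`` (N/m) + ``temperature`` (K), in which case the variance
    is k_B * T * <A> / K_A.
    """

    d_map: dict  # species -> D in cm^2/s
    n_frames: int = 1000
    dt: float = 0.1  # ns per frame
    area_fluctuation: tuple[float, float] | None = None  # (mean nm^2, var nm^4)
    k_a_target: float | None = None  # N/m
    temperature: float = 310.0  # K
    z_jitter_sd: float = 0.01  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.d_map.values()):
            raise SpecError("diffusion coefficients must be >= 0")
        if self.dt <= 0:
            raise SpecError("dt must be positive")
        if self.n_frames < 1:
            raise SpecError("need at least one frame")
        if self.area_fluctuation is not None and self.area_fluctuation[1] < 0:
            raise SpecError("area variance must be >= 0")
        if self.k_a_target is not None and self.k_a_target <= 0:
            raise SpecError("k_a_target must be positive")


def simulate_lateral_diffusion(
    frame: Frame,
    topology: Topology,
    spec: DynamicsSpec,
    keep: str = "all",
) -> tuple[Trajectory, Topology]:
    """Propagate a bilayer configuration by free lateral Brownian motion.

    Each lipid moves rigidly; per-frame lateral steps are independent
    Gaussians with per-axis variance 2*D*dt.  Coordinates are wrapped into
    the periodic box each frame.  With ``keep="reference"`` only the
    per-lipid headgroup reference atoms are retained (memory-light mode
    for long diffusion runs); the matching reduced topology is returned.
    """
    if keep not in ("all", "reference"):
        raise ValueError("keep must be 'all' or 'reference'")
    rng = np.random.default_rng(spec.seed)
    refs = topology.reference_atoms()
    missing = set(refs["species"]) - set(spec.d_map)
    if missing:
        raise SpecError(f"d_map missing species {sorted(missing)}")

    if keep == "reference":
        atom_idx = refs["atom_index"].to_numpy()
        out_top = Topology(topology.table.iloc[atom_idx].reset_index(drop=True))
    else:
        atom_idx = np.arange(topology.n_atoms)
        out_top = topology

    # map every retained atom to its lipid (residue) index
    res_ids = refs["residue_id"].to_numpy()
    res_pos = {rid: i for i, rid in enumerate(res_ids)}
    atom_res = topology.table["residue_id"].to_numpy()[atom_idx]
    lipid_of_atom = np.array([res_pos.get(r, -1) for r in atom_res])
    n_lipids = len(res_ids)

    # per-lipid step standard deviation, nm per axis
    d_nm2_ns = np.array(
        [spec.d_map[sp] / CM2_PER_S_PER_NM2_PER_NS for sp in refs["species"]]
    )
    step_sd = np.sqrt(2.0 * d_nm2_ns * spec.dt)

    # box-area series
    base_area = frame.area
    if spec.k_a_target is not None:
        var = KB * spec.temperature * base_area * 1e18 / spec.k_a_target
        mean_area = base_area
    elif spec.area_fluctuation is not None:
        mean_area, var = spec.area_fluctuation
    else:
        mean_area, var = base_area, 0.0
    if var > 0:
        areas = rng.normal(mean_area, np.sqrt(var), spec.n_frames)
        areas = np.clip(areas, 0.1 * mean_area, None)
    else:
        areas = np.full(spec.n_frames, mean_area)

    coords0 = frame.coordinates[atom_idx]
    n_atoms = len(atom_idx)
    aspect = frame.box[1] / frame.box[0]

    # cumulative per-lipid lateral displacements
    steps = rng.standard_normal((spec.n_frames, n_lipids, 2)) * step_sd[None, :, None]
    steps[0] = 0.0
    walks = np.cumsum(steps, axis=0)

    zj = (
        rng.normal(0.0, spec.z_jitter_sd, (spec.n_frames, n_lipids))
        if spec.z_jitter_sd > 0
        else np.zeros((spec.n_frames, n_lipids))
    )

    valid = lipid_of_atom >= 0
    if var == 0 and np.isclose(mean_area, base_area):
        # constant box: fully vectorized propagation
        disp = np.zeros((spec.n_frames, n_atoms, 2))
        disp[:, valid, :] = walks[:, lipid_of_atom[valid], :]
        coords = np.repeat(coords0[None], spec.n_frames, axis=0)
        coords[:, :, :2] += disp
        coords[:, valid, 2] += zj[:, lipid_of_atom[valid]]
        coords = wrap(coords, frame.box)
        boxes = np.repeat(frame.box[None], spec.n_frames, axis=0)
        times = np.arange(spec.n_frames) * spec.dt
        return Trajectory(coords, boxes, times), out_top

    coords = np.empty((spec.n_frames, n_atoms, 3))
    boxes = np.empty((spec.n_frames, 3))
    disp_xy = np.zeros((n_atoms, 2))
    dz = np.zeros(n_atoms)
    for t in range(spec.n_frames):
        lx = float(np.sqrt(areas[t] / aspect))
        ly = lx * aspect
        box = np.array([lx, ly, frame.box[2]])
        scale = np.array([lx / frame.box[0], ly / frame.box[1]])
        disp_xy[valid] = walks[t][lipid_of_atom[valid]]
        dz[valid] = zj[t][lipid_of_atom[valid]]
        c = coords0.copy()
        c[:, :2] = (c[:, :2] + disp_xy) * scale  # affine rescale with the box
        c[:, 2] += dz
        c = wrap(c, box)
        coords[t] = c
        boxes[t] = box
    times = np.arange(spec.n_frames) * spec.dt
    return Trajectory(coords, boxes, times), out_top


# ---------------------------------------------------------------------------
# two-state binding kinetics
# ---------------------------------------------------------------------------


@dataclass
class BindingKineticsSpec:
    """Two-state (bound/unbound) Markov chain emitting contact counts."""

    k_on: float = 0.01  # 1/ns
    k_off: float = 0.005  # 1/ns
    contact_level_bound: float = 1000.0
    contact_level_unbound: float = 10.0
    dispersion: float = 50.0  # sd of per-frame count noise
    n_frames: int = 10000
    dt: float = 0.1  # ns
    start_state: str = "unbound"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise SpecError("rates must be >= 0")
        if self.contact_level_bound <= self.contact_level_unbound:
            raise SpecError("bound contact level must exceed unbound level")
        if min(self.contact_level_bound, self.contact_level_unbound) < 0:
            raise SpecError("contact levels must be >= 0")
        if self.dispersion < 0:
            raise SpecError("dispersion must be >= 0")
        if self.dt <= 0 or self.n_frames < 1:
            raise SpecError("need dt > 0 and n_frames >= 1")
        if self.start_state not in ("bound", "unbound"):
            raise SpecError("start_state must be 'bound' or 'unbound'")


def simulate_binding_trace(
    spec: BindingKineticsSpec,
) -> tuple[ContactSeries, np.ndarray, float]:
    """Simulate a contact-count time series with known bound time.

    Returns ``(series, states, true_bound_time_ns)`` where ``states`` is the
    per-frame bound indicator (1 = bound) and the true bound time counts
    frames spent in the bound state times ``dt``.
    """
    rng = np.random.default_rng(spec.seed)
    p_on = 1.0 - np.exp(-spec.k_on * spec.dt)
    p_off = 1.0 - np.exp(-spec.k_off * spec.dt)
    u = rng.random(spec.n_frames)
    states = np.empty(spec.n_frames, dtype=np.int8)
    s = 1 if spec.start_state == "bound" else 0
    for t in range(spec.n_frames):
        states[t] = s
        if s == 1 and u[t] < p_off:
            s = 0
        elif s == 0 and u[t] < p_on:
            s = 1
    levels = np.where(states == 1, spec.contact_level_bound, spec.contact_level_unbound)
    noise = rng.normal(0.0, spec.dispersion, spec.n_frames) if spec.dispersion > 0 else 0.0
    counts = np.maximum(np.round(levels + noise), 0.0).astype(np.int64)
    series = ContactSeries(counts=counts, dt=spec.dt, cutoff_nm=0.16, label="synthetic")
    true_time = float(states.sum()) * spec.dt
    return series, states, true_time


# ---------------------------------------------------------------------------
# planted hydrogen-bond geometries
# ---------------------------------------------------------------------------

_DH_BOND = 0.10  # nm, donor-hydrogen bond length


def plant_hbond_geometries(
    n_true: int,
    n_near_miss_distance: int,
    n_near_miss_angle: int,
    seed: int = 0,
    d_cut_nm: float = 0.30,
    angle_cut_deg: float = 150.0,
) -> tuple[Frame, Topology, pd.DataFrame]:
    """Place donor-H-acceptor triplets inside/outside the acceptance box.

    True positives draw D-A distance in (0.26, 0.295) nm and D-H-A angle in
    (152, 178) deg; distance near-misses draw distance in (0.305, 0.35) nm
    with a passing angle; angle near-misses draw angle in (100, 148) deg
    with a passing distance.  Margins keep every draw clear of the cutoff
    boundary.  Triplets are spread on a coarse grid (1.5 nm spacing) so no
    cross-triplet bond can form, then randomly oriented.

    Returns the frame, its topology, and a truth table with one row per
    triplet (``is_true``, planted distance and angle).
    """
    if min(n_true, n_near_miss_distance, n_near_miss_angle) < 0:
        raise SpecError("triplet counts must be >= 0")
    rng = np.random.default_rng(seed)
    n_total = n_true + n_near_miss_distance + n_near_miss_angle
    if n_total == 0:
        raise SpecError("need at least one triplet")

    labels = (
        ["true"] * n_true
        + ["near_distance"] * n_near_miss_distance
        + ["near_angle"] * n_near_miss_angle
    )
    rng.shuffle(labels)

    spacing = 1.5
    grid = int(np.ceil(n_total ** (1.0 / 3.0)))
    box = np.full(3, max(grid * spacing, 3.0))

    rows, coords, truth = [], [], []
    atom_id = 1
    margin = 0.005
    lo_d, hi_d = 0.26, d_cut_nm - margin
    lo_a, hi_a = angle_cut_deg + 2.0, 178.0
    for k, label in enumerate(labels):
        if label == "true":
            d = rng.uniform(lo_d, hi_d)
            ang = rng.uniform(lo_a, hi_a)
        elif label == "near_distance":
            d = rng.uniform(d_cut_nm + margin, d_cut_nm + 0.05)
            ang = rng.uniform(lo_a, hi_a)
        else:  # near_angle
            d = rng.uniform(lo_d, hi_d)
            ang = rng.uniform(100.0, angle_cut_deg - 2.0)

        # random orthonormal pair (u along D->H, w perpendicular)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        w = rng.standard_normal(3)
        w -= w.dot(u) * u
        w /= np.linalg.norm(w)

        gx, gy, gz = k % grid, (k // grid) % grid, k // (grid * grid)
        center = (np.array([gx, gy, gz]) + 0.5) * spacing

        theta = np.deg2rad(ang)
        r1 = _DH_BOND
        s = r1 * np.cos(theta) + np.sqrt(d**2 - (r1 * np.sin(theta)) ** 2)
        d_pos = center
        h_pos = center + r1 * u
        # H->A makes angle theta with H->D (= -u)
        a_pos = h_pos + s * (np.cos(theta) * (-u) + np.sin(theta) * w)

        # donor+hydrogen form one molecule, the acceptor another
        for name, pos, sub, elem, mass, rad, don, hyd, acc, parent, res in (
            ("OD", d_pos, "other", "O", 16.0, 0.18, True, False, False, -1, 2 * k + 1),
            ("HD", h_pos, "other", "H", 1.0, 0.12, False, True, False, atom_id, 2 * k + 1),
            ("OA", a_pos, "other", "O", 16.0, 0.18, False, False, True, -1, 2 * k + 2),
        ):
            coords.append(pos)
            rows.append(
                {
                    "atom_id": atom_id,
                    "atom_name": name,
                    "residue_id": res,
                    "species": "PLANT",
                    "subregion": sub,
                    "element": elem,
                    "mass_amu": mass,
                    "vdw_radius_nm": rad,
                    "is_donor": don,
                    "is_hydrogen": hyd,
                    "is_acceptor": acc,
                    "donor_of": parent,
                    "leaflet_hint": "",
                }
            )
            atom_id += 1
        truth.append(
            {
                "triplet": k,
                "donor_id": atom_id - 3,
                "hydrogen_id": atom_id - 2,
                "acceptor_id": atom_id - 1,
                "distance_nm": d,
                "angle_deg": ang,
                "kind": label,
                "is_true": label == "true",
            }
        )

    frame = Frame(np.array(coords), box, 0.0)
    topology = Topology(pd.DataFrame(rows))
    return frame, topology, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Langmuir isotherms
# ---------------------------------------------------------------------------


@dataclass
class IsothermSpec:
    """Parametric pi-A compression isotherm with collapse and mixing shift.

    The noise-free core is: pi = 0 in the gas phase (A above the lift-off
    area), a linear condensed branch pi = condensed_slope * (A0 - A), and a
    flat plateau at ``collapse_pressure``.  A nonzero additive mole
    fraction shifts the area axis by ``mixing_slope * mole_fraction``
    (negative = condensation).  Defaults mirror a POPC-like Ld film.
    """

    limiting_area: float = 84.8  # A^2/molecule (A0 at fraction 0)
    condensed_slope: float = 1.6  # mN/m per A^2
    collapse_pressure: float = 40.6  # mN/m
    mole_fraction: float = 0.0
    mixing_slope: float = 0.0  # A^2 per unit mole fraction
    noise_sd: float = 0.0  # mN/m
    n_points: int = 200
    area_min: float | None = None  # A^2; default 0.7 * collapse area
    area_max: float | None = None  # A^2; default 1.25 * A0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.limiting_area <= 0:
            raise SpecError("limiting_area must be positive")
        if self.collapse_pressure <= 0:
            raise SpecError("collapse_pressure must be positive")
        if self.condensed_slope <= 0:
            raise SpecError("condensed_slope must be positive")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.n_points < 10:
            raise SpecError("need at least 10 grid points")


def simulate_isotherm(spec: IsothermSpec, replicate: object = 0) -> Isotherm:
    """Generate one pi-A sweep from the parametric model."""
    rng = np.random.default_rng(spec.seed)
    a0 = spec.limiting_area + spec.mixing_slope * spec.mole_fraction
    if a0 <= 0:
        raise SpecError("mixing shift drove the limiting area non-positive")
    a_collapse = a0 - spec.collapse_pressure / spec.condensed_slope
    if a_collapse <= 0:
        raise SpecError("collapse area non-positive; lower collapse_pressure")
    a_max = spec.area_max if spec.area_max is not None else 1.25 * a0
    a_min = spec.area_min if spec.area_min is not None else 0.7 * a_collapse
    areas = np.linspace(a_max, a_min, spec.n_points)  # compression order
    pi = np.clip(spec.condensed_slope * (a0 - areas), 0.0, spec.collapse_pressure)
    if spec.noise_sd > 0:
        pi = np.clip(pi + rng.normal(0.0, spec.noise_sd, pi.shape), 0.0, None)
    return Isotherm(
        area_A2=areas,
        pi_mN_m=pi,
        mole_fraction=spec.mole_fraction,
        replicate=replicate,
    )
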