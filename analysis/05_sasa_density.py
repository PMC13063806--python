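#!/usr/bin/env python
"""Ligand localization: SASA partition and density-region occupancy.

A polyphenol-like ligand is inserted into the Ld membrane at two depths:
the headgroup/glycerol level and the acyl-chain level.  The Shrake-Rupley
partition reports how much of the ligand surface touches headgroup atoms
versus tail atoms; the mass-density profile places the ligand within the
five depth regions (1 = bulk water ... 5 = bilayer center).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from memraft import interactions as ia
from memraft import io as mio
from memraft import structure as st
from memraft import synthetic as sy
from memraft.trajectory import Trajectory

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

frame0, top0 = sy.build_bilayer_config(sy.ld_spec(seed=7))
spec = sy.DynamicsSpec({"POPC": 1.2e-7}, n_frames=200, dt=0.1, seed=8)
traj0, _ = sy.simulate_lateral_diffusion(frame0, top0, spec)
head = st.mass_density_profile(
    traj0, top0, top0.atoms_of_subregion("choline", "phosphate", "glycerol"), 0.1, "head"
)
tails = st.mass_density_profile(traj0, top0, top0.atoms_of_subregion("tails"), 0.1, "tails")
scheme = st.classify_regions(head, tails)
print("five-region boundaries (|z| nm from midplane):",
      [round(b, 2) for b in scheme.boundaries])

rows = []
for label, depth in (("headgroup level", 1.75), ("tail level", 0.9)):
    frame, top = sy.insert_ligand(frame0, top0, depth_nm=depth, species="EC", seed=9)
    lig = top.atoms_of_species("EC")
    part = ia.sasa_partition(frame, top, lig)
    lig_traj = Trajectory(frame.coordinates[None], frame.box[None])
    prof = st.mass_density_profile(lig_traj, top, lig, 0.1, "ligand")
    occ, peak = st.locate_ligand(prof, scheme)
    rows.append(
        {
            "placement": label,
            "depth_nm": depth,
            "sasa_total_A2": round(part.total_A2, 1),
            "sasa_headgroup_A2": round(part.headgroup_A2, 1),
            "sasa_tail_A2": round(part.tail_A2, 1),
            "sasa_solvent_A2": round(part.solvent_A2, 1),
            "peak_region": peak,
            "occupancy_region_3": round(occ[3], 2),
            "occupancy_region_4": round(occ[4], 2),
        }
    )

table = pd.DataFrame(rows)
mio.write_results(RESULTS / "sasa_density.tsv", table)
(RESULTS / "region_boundaries.json").write_text(
    json.dumps({"boundaries_nm": list(np.round(scheme.boundaries, 3))}, indent=2) + "\n"
)
print(table.to_string(index=False))
print(
    "\nA ligand at the headgroup level peaks in region 3 and its surface "
    "contacts mostly headgroup atoms; pushed to the chain level it peaks "
    "deeper (region 4) with more tail-contact area."
)
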