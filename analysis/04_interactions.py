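#!/usr/bin/env python
"""Hydrogen bonds, contacts and strong binding times.

Part 1 validates the geometric H-bond detector (3.0 A donor-acceptor
distance, 150 deg donor-H-acceptor angle) on planted geometries and
demonstrates per-hydroxyl accounting for a ligand inserted at the
headgroup level of the Ld membrane.

Part 2 counts ligand-lipid contacts per subregion and traces the
minimum ligand-membrane distance.

Part 3 computes the strong-binding-time statistic (cumulative time with
more than 800 tight contacts) on two-state kinetic traces and tabulates
fold changes of the published binding-time means versus EC.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from memraft import interactions as ia
from memraft import io as mio
from memraft import refdata
from memraft import stats as ms
from memraft import synthetic as sy
from memraft import validation as v
from memraft.trajectory import Trajectory

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

# --- Part 1: detector fidelity + per-hydroxyl demo -------------------------
fid = v.hbond_detector_fidelity(seed=1, n_seeds=20)
print(f"H-bond detector on planted geometries: precision={fid['precision']:.2f}, "
      f"recall={fid['recall']:.2f} over {fid['n_seeds']} seeds")

frame, top = sy.build_bilayer_config(sy.ld_spec(seed=4))
frame, top = sy.insert_ligand(frame, top, depth_nm=1.7, species="EC", seed=5,
                              form_hbond=True)
rec = ia.detect_hbonds(frame, top)
rec.insert(0, "frame", 0)
per_oh = ia.hbonds_per_hydroxyl(rec, n_frames=1, ligand_species="EC")
print(f"ligand H-bonds in one frame: {len(rec)}; engaged hydroxyls: "
      f"{per_oh['oxygen'].tolist() if not per_oh.empty else 'none'}")

# --- Part 2: contacts per subregion + minimum distance ---------------------
traj = Trajectory(frame.coordinates[None], frame.box[None])
lig = top.atoms_of_species("EC")
lip = top.atoms_of_subregion("choline", "phosphate", "glycerol", "tails")
split = ia.count_contacts(traj, top, lig, lip, cutoff_nm=0.6, by_subregion=True)
contact_rows = [
    {"subregion": tag, "contacts_within_0.6nm": int(s.counts[0])}
    for tag, s in sorted(split.items())
]
mind = ia.min_distance(traj, lig, lip)[0]
print("contacts by subregion:", {r["subregion"]: r["contacts_within_0.6nm"] for r in contact_rows})
print(f"minimum ligand-lipid distance: {mind:.3f} nm")

# --- Part 3: strong binding times ------------------------------------------
bt = v.binding_time_recovery(seed=1)
print(f"\nstrong-binding-time recovery: exact-trace error {bt['exact_recovery_err_ns']} ns; "
      f"noisy trace {bt['noisy_err_frames_per_transition']:.2f} misassigned frames/transition")

folds = ms.ratio_table(refdata.strong_binding_times(), control="EC")
mio.write_results(RESULTS / "binding_time_fold_changes.tsv", folds)
print("\nfold changes of published strong binding times vs EC:")
print(folds[["membrane", "lipid", "compound", "fold_change_1dp"]].to_string(index=False))
print(
    "\nDimeric polyphenols bind one to two orders of magnitude longer to the "
    "ordered (Lo) membrane's sphingomyelin than the monomer EC."
)
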