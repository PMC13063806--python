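"""Literature reference values used as worked-example inputs.

These are published results from an atomistic MD + Langmuir-balance study
of epicatechin (EC) and two dimeric polyphenols (ECG dimer, EGCG dimer)
interacting with liquid-disordered (Ld, POPC) and liquid-ordered (Lo,
PSM/CHOL 1:2) model membranes.  They serve as inputs for worked examples
and as targets that synthetic-data recovery is benchmarked against; they
are not computed by this package.
"""

from __future__ import annotations

import pandas as pd

#: Area compressibility moduli of the pure membranes, N/m.
K_A_LD = 1.08839
K_A_LO = 3.48643

#: Lateral diffusion coefficient of the pure Ld membrane, cm^2/s;
#: Lo-membrane lipids diffuse about a factor of 10 slower.
D_XY_LD = 1.20e-7
D_XY_LO = 1.20e-8

#: Pure Ld membrane structure (mean over 3 replicates).
APL_LD_NM2 = 0.651
THICKNESS_LD_NM = 3.90

#: Langmuir monolayer features of the pure films.
COLLAPSE_PI_LD = 40.6  # mN/m
LIMITING_AREA_LD = 84.8  # A^2/molecule
COLLAPSE_PI_LO = 53.0  # mN/m
LIMITING_AREA_LO = 43.1  # A^2/molecule


def strong_binding_times() -> pd.DataFrame:
    """Published strong lipid binding times (ns), mean +/- sd over n=3.

    The statistic is the cumulative time during which the number of tight
    (< 0.16 nm) polyphenol-lipid atom contacts exceeds 800.
    """
    rows = [
        ("Ld", "POPC", "EC", 109.2, 17.2),
        ("Ld", "POPC", "ECG_dimer", 236.0, 9.1),
        ("Ld", "POPC", "EGCG_dimer", 208.2, 41.1),
        ("Lo", "PSM", "EC", 12.8, 10.4),
        ("Lo", "PSM", "ECG_dimer", 184.7, 23.3),
        ("Lo", "PSM", "EGCG_dimer", 129.9, 44.3),
        ("Lo", "CHOL", "EC", 1.6, 0.4),
        ("Lo", "CHOL", "ECG_dimer", 1.5, 1.0),
        ("Lo", "CHOL", "EGCG_dimer", 10.6, 12.8),
    ]
    return pd.DataFrame(
        rows, columns=["membrane", "lipid", "compound", "mean_time_ns", "sd_time_ns"]
    )


def ld_structure_table() -> pd.DataFrame:
    """Published pure-Ld and polyphenol-treated structure/dynamics values."""
    rows = [
        ("APL_nm2", "Ld", 0.651, 0.002),
        ("APL_nm2", "EC", 0.640, 0.003),
        ("APL_nm2", "ECG_dimer", 0.645, 0.003),
        ("APL_nm2", "EGCG_dimer", 0.640, 0.004),
        ("thickness_nm", "Ld", 3.90, 0.01),
        ("thickness_nm", "EC", 3.91, 0.02),
        ("thickness_nm", "ECG_dimer", 3.90, 0.01),
        ("thickness_nm", "EGCG_dimer", 3.92, 0.03),
        ("D_xy_1e-7_cm2_s", "Ld", 1.20, 0.24),
        ("D_xy_1e-7_cm2_s", "EC", 0.72, 0.28),
        ("D_xy_1e-7_cm2_s", "ECG_dimer", 0.58, 0.09),
        ("D_xy_1e-7_cm2_s", "EGCG_dimer", 0.78, 0.13),
    ]
    return pd.DataFrame(rows, columns=["metric", "system", "mean", "sd"])
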