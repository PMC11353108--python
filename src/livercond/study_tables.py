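"""Bundled result tables from the clinical liver-conductivity study this
package reproduces the analysis of.

These are the literally printed values: group mean +/- SD of conductivity
at the five analysis frequencies, the published between-group ratio table,
per-tumor-type breakdowns, and the per-patient 1 MHz case table.  Three
cells in the printed tables are obvious typographical slips (a dropped
decimal point); they are encoded verbatim alongside a normalized numeric
value and flagged with ``typo_normalized`` — never silently corrected.

The tables serve two purposes: fixtures for recomputing the in-table
worked numbers (ratios of means, the 1 MHz omnibus comparison), and the
default targets for the synthetic cohort generator.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "group_summary_table",
    "printed_ratio_table",
    "tumor_type_table",
    "patient_table",
    "patient_groups_1mhz",
]

# (tissue_class, state, n, freq_khz, printed_mean, mean, printed_sd, sd)
_GROUP_ROWS = [
    ("normal", "in_vivo", 15, 3, "0.13", 0.13, "0.06", 0.06),
    ("normal", "in_vivo", 15, 30, "0.17", 0.17, "0.06", 0.06),
    ("normal", "in_vivo", 15, 300, "0.30", 0.30, "0.12", 0.12),
    ("normal", "in_vivo", 15, 607, "0.39", 0.39, "0.11", 0.11),
    ("normal", "in_vivo", 15, 1000, "0.49", 0.49, "0.10", 0.10),
    ("normal", "ex_vivo", 16, 3, "012", 0.12, "0.07", 0.07),  # dropped decimal point
    ("normal", "ex_vivo", 16, 30, "0.16", 0.16, "0.09", 0.09),
    ("normal", "ex_vivo", 16, 300, "0.26", 0.26, "0.10", 0.10),
    ("normal", "ex_vivo", 16, 607, "0.34", 0.34, "0.10", 0.10),
    ("normal", "ex_vivo", 16, 1000, "0.38", 0.38, "0.08", 0.08),
    ("tumor", "in_vivo", 16, 3, "0.41", 0.41, "0.10", 0.10),
    ("tumor", "in_vivo", 16, 30, "0.45", 0.45, "0.1", 0.10),
    ("tumor", "in_vivo", 16, 300, "0.57", 0.57, "0.12", 0.12),
    ("tumor", "in_vivo", 16, 607, "0.69", 0.69, "0.22", 0.22),
    ("tumor", "in_vivo", 16, 1000, "0.78", 0.78, "0.24", 0.24),
    ("tumor", "ex_vivo", 3, 3, "0.27", 0.27, "0.09", 0.09),
    ("tumor", "ex_vivo", 3, 30, "0.30", 0.30, "0.09", 0.09),
    ("tumor", "ex_vivo", 3, 300, "0.38", 0.38, "0.08", 0.08),
    ("tumor", "ex_vivo", 3, 607, "0.45", 0.45, "0.11", 0.11),
    ("tumor", "ex_vivo", 3, 1000, "0.54", 0.54, "0.14", 0.14),
    ("cirrhotic", "in_vivo", 3, 3, "0.09", 0.09, "0.01", 0.01),
    ("cirrhotic", "in_vivo", 3, 30, "0.11", 0.11, "0.02", 0.02),
    ("cirrhotic", "in_vivo", 3, 300, "0.22", 0.22, "0.02", 0.02),
    ("cirrhotic", "in_vivo", 3, 607, "0.31", 0.31, "0.009", 0.009),
    ("cirrhotic", "in_vivo", 3, 1000, "041", 0.41, "0.01", 0.01),  # dropped decimal point
    ("cirrhotic", "ex_vivo", 3, 3, "0.16", 0.16, "0.01", 0.01),
    ("cirrhotic", "ex_vivo", 3, 30, "0.18", 0.18, "0.02", 0.02),
    ("cirrhotic", "ex_vivo", 3, 300, "0.29", 0.29, "0.05", 0.05),
    ("cirrhotic", "ex_vivo", 3, 607, "0.35", 0.35, "0.07", 0.07),
    ("cirrhotic", "ex_vivo", 3, 1000, "0.40", 0.40, "0.08", 0.08),
]


def group_summary_table() -> pd.DataFrame:
    """Published group conductivity summary (S/m) at the five frequencies."""
    df = pd.DataFrame(
        _GROUP_ROWS,
        columns=[
            "tissue_class",
            "state",
            "n",
            "frequency_khz",
            "printed_mean",
            "mean",
            "printed_sd",
            "sd",
        ],
    )
    # the two dropped-decimal-point cells
    df["typo_normalized"] = df["printed_mean"].isin(["012", "041"])
    return df


def printed_ratio_table() -> pd.DataFrame:
    """Published between-group ratio table (ratio names as columns)."""
    rows = [
        (3, 3.2, 1.5, 2.1, 4.4, 3.0, 1.4),
        (30, 2.7, 1.5, 1.8, 3.8, 2.6, 1.4),
        (300, 1.9, 1.5, 1.2, 2.5, 1.7, 1.3),
        (607, 1.8, 1.5, 1.1, 2.2, 1.5, 1.3),
        (1000, 1.6, 1.4, 1.1, 1.9, 1.3, 1.2),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "frequency_khz",
            "Tin/Nin",
            "Tin/Tex",
            "Tex/Nin",
            "Tin/Cin",
            "Tex/Cin",
            "Nin/Cin",
        ],
    ).set_index("frequency_khz")


# (freq_khz, tumor_type, n, mean, sd-or-None)
_TUMOR_TYPE_ROWS = {
    "in_vivo": [
        (3, "CCA", 2, 0.35, None),
        (3, "HCC", 5, 0.42, 0.13),
        (3, "MET", 6, 0.41, 0.08),
        (30, "CCA", 2, 0.38, None),
        (30, "HCC", 5, 0.47, 0.15),
        (30, "MET", 5, 0.44, 0.08),
        (300, "CCA", 2, 0.53, None),
        (300, "HCC", 5, 0.60, 0.17),
        (300, "MET", 5, 0.52, 0.04),
        (607, "CCA", 1, 0.70, None),
        (607, "HCC", 5, 0.80, 0.30),
        (607, "MET", 4, 0.58, 0.10),
        (1000, "CCA", 1, 0.89, None),
        (1000, "HCC", 5, 0.88, 0.31),
        (1000, "MET", 5, 0.67, 0.14),
    ],
    "ex_vivo": [
        (3, "CCA", 1, 0.28, None),
        (3, "HCC", 6, 0.23, 0.09),
        (3, "MET", 6, 0.33, 0.07),
        (30, "CCA", 2, 0.30, None),
        (30, "HCC", 6, 0.25, 0.10),
        (30, "MET", 6, 0.36, 0.06),
        (300, "CCA", 2, 0.43, None),
        (300, "HCC", 6, 0.34, 0.11),
        (300, "MET", 5, 0.42, 0.03),
        (607, "CCA", 2, 0.58, None),
        (607, "HCC", 6, 0.41, 0.14),
        (607, "MET", 4, 0.51, 0.01),
        (1000, "CCA", 2, 0.73, None),
        (1000, "HCC", 6, 0.48, 0.17),
        (1000, "MET", 6, 0.60, 0.02),
    ],
}


def tumor_type_table(state: str) -> pd.DataFrame:
    """Published per-tumor-type conductivity summary for one state."""
    if state not in _TUMOR_TYPE_ROWS:
        raise KeyError(f"state must be in_vivo or ex_vivo, got {state!r}")
    return pd.DataFrame(
        _TUMOR_TYPE_ROWS[state],
        columns=["frequency_khz", "tumor_type", "n", "mean", "sd"],
    )


# Per-patient 1 MHz conductivities (S/m).  Blank printed cells are None.
# Patient 10's in vivo normal cell prints "043" (dropped decimal point);
# it is normalized to 0.43 and flagged below.
# (patient, disease, tumor_size_mm, cirrhotic,
#  in_vivo_normal, ex_vivo_normal, in_vivo_tumor, ex_vivo_tumor)
_PATIENT_ROWS = [
    (1, "CCA", "88x76x70", False, 0.71, 0.37, 0.9, 0.73),
    (2, "HCC", "67x50x45", False, 0.43, 0.54, None, 0.78),
    (3, "MET", "8x6x6", False, 0.43, None, 0.5, None),
    (4, "HCC", "27x20x16", True, 0.43, 0.50, 0.8, 0.45),
    (5, "HCC", "43x33x21", False, 0.43, 0.27, None, None),
    (6, "HCC", "19x19", False, 0.43, 0.74, None, None),
    (7, "MET", "35x25x31", False, 0.43, 0.31, 1.1, 0.63),
    (8, "MET", "40x24x37", False, 0.43, 0.67, 0.8, 0.62),
    (9, "HCC", "23x17x15", True, 0.43, 0.41, 0.7, None),
    (10, "MET", "24x20x26", False, 0.43, 0.29, 0.6, 0.62),
    (11, "HCC", "24x22x19", False, None, None, None, None),
    (12, "HCC", "33x25x22", True, 0.40, 0.32, 0.5, 0.28),
    (13, "MET", "22x16x13", False, 0.41, 0.35, 0.8, 0.61),
    (14, "MET", "26", False, 0.56, 0.38, 0.7, 0.44),
    (15, "HCC", "85x80x65", False, 0.60, 0.47, 1.1, 0.54),
    (16, "HCC", "10x7x6", False, 0.52, 0.42, 0.9, 0.34),
    (17, "HCC", "57x48x48", False, 0.72, 0.44, 1.4, 0.52),
    (18, "MET", "34x32x24", False, 0.45, 0.35, 0.7, 0.56),
    (19, "HCC", "10x1x1", False, 0.47, 0.04, 0.9, 0.44),
]


def patient_table() -> pd.DataFrame:
    """Published per-patient 1 MHz conductivity case table."""
    df = pd.DataFrame(
        _PATIENT_ROWS,
        columns=[
            "patient",
            "disease",
            "tumor_size_mm",
            "cirrhotic",
            "in_vivo_normal",
            "ex_vivo_normal",
            "in_vivo_tumor",
            "ex_vivo_tumor",
        ],
    )
    df["typo_normalized"] = df["patient"] == 10  # "043" cell read as 0.43
    return df


def patient_groups_1mhz() -> dict[str, list[float]]:
    """The four per-patient 1 MHz groups used for the omnibus comparison:
    in vivo normal restricted to non-cirrhotic patients, plus the in vivo
    tumor and both ex vivo columns (blank cells dropped)."""
    df = patient_table()
    non_cirr = df[~df["cirrhotic"]]
    return {
        "in_vivo_normal_non_cirrhotic": non_cirr["in_vivo_normal"].dropna().tolist(),
        "in_vivo_tumor": df["in_vivo_tumor"].dropna().tolist(),
        "ex_vivo_normal": df["ex_vivo_normal"].dropna().tolist(),
        "ex_vivo_tumor": df["ex_vivo_tumor"].dropna().tolist(),
    }
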