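"""Study design constants: factor levels, group sizes, and pairwise contrasts.

The analysis cohort is a 2x3 unbalanced factorial: central-nervous-system
tissue (motor cortex, spinal cord) crossed with disease state (control and
the two transcriptome-defined sporadic-ALS subtypes SALS1/SALS2).
"""
from __future__ import annotations

from typing import NamedTuple

import pandas as pd

TISSUES: tuple[str, ...] = ("motor_cortex", "spinal_cord")
STATES: tuple[str, ...] = ("CTRL", "SALS1", "SALS2")

#: Cohort group sizes: 41 motor cortex and 40 spinal cord samples.
TABLE1_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("motor_cortex", "SALS1"): 18,
    ("motor_cortex", "SALS2"): 13,
    ("motor_cortex", "CTRL"): 10,
    ("spinal_cord", "SALS1"): 17,
    ("spinal_cord", "SALS2"): 13,
    ("spinal_cord", "CTRL"): 10,
}


class Contrast(NamedTuple):
    """A pairwise comparison between two factorial cells.

    ``kind`` records which factor the contrast varies ("state" for
    disease-state comparisons within a tissue, "tissue" for tissue
    comparisons within a disease state); it determines which ANOVA
    effect gates DEG eligibility.
    """

    contrast_id: str
    group_a: tuple[str, str]  # (tissue, state) of the numerator group
    group_b: tuple[str, str]
    kind: str  # "state" | "tissue"


#: The seven pairwise comparisons of the study.
STUDY_CONTRASTS: tuple[Contrast, ...] = (
    Contrast("cortex_SALS1_vs_cortex_CTRL",
             ("motor_cortex", "SALS1"), ("motor_cortex", "CTRL"), "state"),
    Contrast("cortex_SALS2_vs_cortex_CTRL",
             ("motor_cortex", "SALS2"), ("motor_cortex", "CTRL"), "state"),
    Contrast("spinal_SALS1_vs_spinal_CTRL",
             ("spinal_cord", "SALS1"), ("spinal_cord", "CTRL"), "state"),
    Contrast("spinal_SALS2_vs_spinal_CTRL",
             ("spinal_cord", "SALS2"), ("spinal_cord", "CTRL"), "state"),
    Contrast("cortex_SALS1_vs_spinal_SALS1",
             ("motor_cortex", "SALS1"), ("spinal_cord", "SALS1"), "tissue"),
    Contrast("cortex_SALS2_vs_spinal_SALS2",
             ("motor_cortex", "SALS2"), ("spinal_cord", "SALS2"), "tissue"),
    Contrast("cortex_CTRL_vs_spinal_CTRL",
             ("motor_cortex", "CTRL"), ("spinal_cord", "CTRL"), "tissue"),
)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check that sample metadata has unique sample ids and both factor columns."""
    missing = {"tissue", "state"} - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata is missing required columns: {sorted(missing)}")
    if metadata.index.duplicated().any():
        dups = metadata.index[metadata.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    return metadata
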