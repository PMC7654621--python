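"""Packaged reference tables from the 12-genotype rice drought field trial.

These are the published per-genotype agronomic measurements and the
phytohormone-pathway DRG summary of that trial, carried here so that the
drought-tolerance index arithmetic and the pathway proportions can be
recomputed from first principles without any external download.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["rice_field_trial_traits", "hormone_drg_summary"]

# genotype, material, dead-leaf ratio, biomass (g) and yield per plant (g)
# under well-watered (W) and drought (D) fields; group is the published
# tolerant/susceptible assignment.
_TRIAL_ROWS = [
    # code, material, dead_leaf, biomass_W, biomass_D, yield_W, yield_D, group
    ("S3", "IAC1246", 0.241, 28.35, 19.64, 10.65, 7.89, "tolerant"),
    ("S6", "Hanhui-3", 0.359, 27.60, 19.23, 7.61, 1.17, "tolerant"),
    ("S9", "CICA4", 0.410, 13.67, 8.03, 6.34, 2.03, "susceptible"),
    ("S11", "Aimi", 0.405, 25.11, 17.56, 11.17, 7.82, "tolerant"),
    ("S12", "Zhonghan-3", 0.435, 19.78, 8.50, 9.49, 2.45, "susceptible"),
    ("S14", "Yunlu", 0.509, 19.70, 11.34, 7.41, 3.31, "susceptible"),
    ("S17", "Qingsizhan", 0.416, 20.79, 13.69, 10.49, 2.05, "tolerant"),
    ("S18", "IRAT109", 0.468, 16.45, 7.90, 8.56, 1.84, "susceptible"),
    ("S24", "IPECA0162", 0.366, 14.20, 6.93, 7.26, 1.51, "susceptible"),
    ("S26", "Bulebelle", 0.435, 18.17, 10.21, 9.27, 4.26, "susceptible"),
    ("S28", "Tresmes", 0.441, 29.88, 18.75, 13.30, 4.76, "tolerant"),
    ("S31", "Huhan-1B", 0.384, 26.14, 13.32, 11.76, 2.71, "tolerant"),
]


def rice_field_trial_traits() -> pd.DataFrame:
    """Per-genotype trait table of the reference field trial.

    Columns: ``genotype``, ``material``, ``dead_leaf_ratio``, ``biomass_W``,
    ``biomass_D``, ``yield_W``, ``yield_D``, ``published_group``.
    """
    return pd.DataFrame(
        _TRIAL_ROWS,
        columns=[
            "genotype",
            "material",
            "dead_leaf_ratio",
            "biomass_W",
            "biomass_D",
            "yield_W",
            "yield_D",
            "published_group",
        ],
    )


# Per-hormone DRG summary: total annotated genes, DRGs among them, and the
# group-distinguished DRGs split into tolerant-susceptible different,
# susceptible-specific and tolerant-specific. n_down counts downregulated
# DRGs where the trial reported them (gibberellin: 17 of 22).
_HORMONE_ROWS = [
    # hormone, n_total, n_drg, n_ts_different, n_sus_specific, n_tol_specific, n_down
    ("ABA", 29, 10, 1, 1, 0, None),
    ("auxin", 93, 35, 4, 12, 4, None),
    ("BR", 12, 5, 0, 3, 0, None),
    ("cytokinin", 28, 11, 1, 2, 2, None),
    ("ethylene", 148, 54, 6, 9, 6, None),
    ("SA", 68, 33, 8, 6, 1, None),
    ("GA", 42, 22, 3, 7, 1, 17),
    ("JA", 46, 15, 1, 5, 1, None),
    # The overall row counts unique genes; genes annotated to several
    # pathways appear once here, so it is not the column sum.
    ("overall", 428, 168, 20, 43, 14, None),
]


def hormone_drg_summary() -> pd.DataFrame:
    """Published phytohormone-pathway DRG counts of the reference trial."""
    return pd.DataFrame(
        _HORMONE_ROWS,
        columns=[
            "hormone",
            "n_total",
            "n_drg",
            "n_ts_different",
            "n_sus_specific",
            "n_tol_specific",
            "n_down",
        ],
    )
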