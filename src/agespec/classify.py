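"""Dual-threshold shared / age-specific probe taxonomy.

A probe is a DMP within a cohort when it passes q < alpha and
|delta beta| > resp_delta there.  Combining the two cohorts:

* shared            - DMP in both cohorts, same direction;
* opposing          - DMP in both cohorts, opposite directions (kept out
                      of the shared set and reported separately);
* infant_specific / adolescent_specific
                    - DMP in exactly one cohort AND truly unresponsive in
                      the other (|delta beta| < unresp_delta there);
* indeterminate     - DMP in exactly one cohort but the other cohort's
                      |delta beta| falls between unresp_delta and the DMP
                      threshold (fails the "truly unresponsive" rule);
* nonresponsive     - DMP in neither cohort.

The 2% unresponsiveness cutoff is read as an absolute value, |delta beta|
< 0.02.  The DMP overlap can optionally be formed with the disjunctive
rule (significance OR effect size) for Venn-style reproduction; the
conjunction is the default and the documented semantics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["PROBE_CLASSES", "classify_probes", "summarize_classes"]

logger = logging.getLogger("agespec")

PROBE_CLASSES = (
    "shared",
    "infant_specific",
    "adolescent_specific",
    "opposing",
    "indeterminate",
    "nonresponsive",
)


def _is_dmp(stats: pd.DataFrame, alpha: float, resp_delta: float, venn_mode: bool) -> np.ndarray:
    sig = stats["q"].to_numpy() < alpha
    big = stats["delta_beta"].abs().to_numpy() > resp_delta
    return (sig | big) if venn_mode else (sig & big)


def classify_probes(stats_infant: pd.DataFrame, stats_adol: pd.DataFrame,
                    alpha: float = 0.01, resp_delta: float = 0.05,
                    unresp_delta: float = 0.02, venn_mode: bool = False) -> pd.DataFrame:
    """Assign every probe exactly one class from the two cohorts' stats."""
    a = stats_infant.set_index("probe_id")
    b = stats_adol.set_index("probe_id")
    if set(a.index) != set(b.index):
        raise ValueError("the two stats tables cover different probe sets")
    b = b.loc[a.index]

    dmp_i = _is_dmp(a.reset_index(), alpha, resp_delta, venn_mode)
    dmp_a = _is_dmp(b.reset_index(), alpha, resp_delta, venn_mode)
    db_i = a["delta_beta"].to_numpy()
    db_a = b["delta_beta"].to_numpy()
    same_sign = np.sign(db_i) == np.sign(db_a)

    cls = np.full(len(a), "nonresponsive", dtype=object)
    both = dmp_i & dmp_a
    cls[both & same_sign] = "shared"
    cls[both & ~same_sign] = "opposing"
    only_i = dmp_i & ~dmp_a
    only_a = dmp_a & ~dmp_i
    cls[only_i & (np.abs(db_a) < unresp_delta)] = "infant_specific"
    cls[only_i & (np.abs(db_a) >= unresp_delta)] = "indeterminate"
    cls[only_a & (np.abs(db_i) < unresp_delta)] = "adolescent_specific"
    cls[only_a & (np.abs(db_i) >= unresp_delta)] = "indeterminate"

    return pd.DataFrame(
        {
            "probe_id": a.index.to_numpy(),
            "class": cls,
            "delta_beta_infant": db_i,
            "delta_beta_adolescent": db_a,
            "q_infant": a["q"].to_numpy(),
            "q_adolescent": b["q"].to_numpy(),
        }
    )


def summarize_classes(table: pd.DataFrame) -> pd.DataFrame:
    """Counts per class split by direction, with every class present.

    Direction uses the discovery cohort's delta-beta sign: the infant sign
    for infant_specific / opposing / shared (shared has equal signs by
    construction), the adolescent sign for adolescent_specific, and the
    larger-magnitude cohort's sign otherwise.
    """
    db_i = table["delta_beta_infant"].to_numpy()
    db_a = table["delta_beta_adolescent"].to_numpy()
    use_adol = (table["class"] == "adolescent_specific").to_numpy() | (
        ~np.isin(table["class"], ["infant_specific", "shared", "opposing"])
        & (np.abs(db_a) > np.abs(db_i))
    )
    sign = np.where(use_adol, db_a, db_i)
    rows = []
    for cls in PROBE_CLASSES:
        mask = (table["class"] == cls).to_numpy()
        n_hyper = int((mask & (sign > 0)).sum())
        n_hypo = int((mask & (sign <= 0)).sum())
        rows.append((cls, n_hyper + n_hypo, n_hyper, n_hypo))
    return pd.DataFrame(rows, columns=["class", "n", "n_hyper", "n_hypo"])
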