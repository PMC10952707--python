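"""DMR calling: gap clustering, Stouffer combination, FDR, dual-cutoff classes.

Candidate regions are maximal runs of manifest-adjacent probes whose
successive gaps do not exceed ``maxgap_bp`` (inclusive), never spanning a
chromosome boundary.  Each candidate with at least ``min_probes`` probes
gets an equal-weight Stouffer statistic over signed per-probe z-scores,

    z_i = Phi^{-1}(1 - p_i / 2) * sign(delta_beta_i),
    z_region = sum(z_i) / sqrt(n),

a two-sided normal region p, and BH adjustment across candidates.  A
region is reported as a DMR when q < alpha and the mean delta beta over
its probes exceeds ``min_mean_delta`` in magnitude.  This replaces a
kernel-smoothed region statistic with a transparent combination honoring
the same reporting criteria (probe count, mean effect, region FDR).

Age-specific region classes use the dual 5% / 2% cutoffs: a region called
in one cohort is cohort-specific when the same probes average under 2%
|delta beta| in the other cohort, shared when called in both cohorts with
overlapping spans and the same direction, otherwise unclassified.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["cluster_probes", "call_dmrs", "classify_dmrs", "regions_to_bed"]

logger = logging.getLogger("agespec")

_TINY = np.finfo(float).tiny


def cluster_probes(manifest: pd.DataFrame, probe_ids, maxgap_bp: int = 1000) -> list[pd.DataFrame]:
    """Maximal runs of probes with successive gaps <= maxgap_bp.

    Returns one DataFrame (probe_id, chrom, pos; position-sorted) per
    cluster.  An unsorted manifest is sorted internally with a log note.
    """
    probe_ids = list(probe_ids)
    sub = manifest[manifest["probe_id"].isin(set(probe_ids))][["probe_id", "chrom", "pos"]]
    sorted_ok = (
        sub.groupby("chrom", sort=False)["pos"].apply(lambda s: s.is_monotonic_increasing).all()
    )
    if not sorted_ok:
        logger.info("cluster_probes: manifest not position-sorted; sorting internally")
    sub = sub.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    clusters = []
    for _, chrom_df in sub.groupby("chrom", sort=False):
        pos = chrom_df["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > maxgap_bp) + 1
        for piece in np.split(np.arange(len(pos)), breaks):
            clusters.append(chrom_df.iloc[piece].reset_index(drop=True))
    return clusters


def stouffer_z(p: np.ndarray, signs: np.ndarray) -> float:
    """Equal-weight Stouffer combination of signed two-sided p-values."""
    p = np.clip(np.asarray(p, dtype=float), _TINY, 1.0)
    z = sps.norm.isf(p / 2.0) * np.asarray(signs, dtype=float)
    return float(z.sum() / np.sqrt(len(z)))


REGION_COLUMNS = (
    "region_id", "chrom", "start", "end", "probe_ids", "n_probes",
    "mean_delta_beta", "z_combined", "p_region", "q_region", "direction", "class",
)


def call_dmrs(clusters: list[pd.DataFrame], stats_table: pd.DataFrame,
              min_probes: int = 4, min_mean_delta: float = 0.05,
              alpha: float = 0.01, return_candidates: bool = False) -> pd.DataFrame:
    """Combine per-probe statistics into regions and apply the DMR gates.

    Returns only regions satisfying n >= min_probes, |mean delta beta| >
    min_mean_delta and q < alpha (1-based inclusive start/end); with
    ``return_candidates`` all candidate regions are returned with an
    ``is_dmr`` flag instead.
    """
    st = stats_table.set_index("probe_id")
    known = set(st.index)
    rows = []
    for cluster in clusters:
        if len(cluster) < min_probes:
            continue
        missing = set(cluster["probe_id"]) - known
        if missing:
            raise ValueError(f"cluster probes missing from stats: {sorted(missing)[:5]}")
        sub = st.loc[cluster["probe_id"]]
        p = sub["p"].to_numpy()
        if (p <= 0).any():
            logger.info("call_dmrs: clipping %d underflowed p-values", int((p <= 0).sum()))
        db = sub["delta_beta"].to_numpy()
        z = stouffer_z(p, np.where(db > 0, 1.0, -1.0))
        p_region = float(2.0 * sps.norm.sf(abs(z)))
        mean_db = float(db.mean())
        rows.append(
            {
                "chrom": cluster["chrom"].iloc[0],
                "start": int(cluster["pos"].min()),
                "end": int(cluster["pos"].max()),
                "probe_ids": ",".join(cluster["probe_id"]),
                "n_probes": len(cluster),
                "mean_delta_beta": mean_db,
                "z_combined": z,
                "p_region": p_region,
            }
        )
    if not rows:
        out = pd.DataFrame(columns=list(REGION_COLUMNS))
        return out
    cand = pd.DataFrame(rows)
    from agespec.differential import bh_adjust

    cand["q_region"] = bh_adjust(cand["p_region"].to_numpy())
    cand["direction"] = np.where(cand["mean_delta_beta"] > 0, "hyper", "hypo")
    cand["class"] = "unclassified"
    cand["is_dmr"] = (cand["q_region"] < alpha) & (cand["mean_delta_beta"].abs() > min_mean_delta)
    cand = cand.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    cand["region_id"] = [f"dmr{i:05d}" for i in range(len(cand))]
    if return_candidates:
        return cand.loc[:, list(REGION_COLUMNS) + ["is_dmr"]]
    out = cand[cand["is_dmr"]].drop(columns="is_dmr").reset_index(drop=True)
    _assert_region_invariants(out, min_probes, min_mean_delta, alpha)
    logger.info("call_dmrs: %d DMRs from %d candidates", len(out), len(cand))
    return out.loc[:, list(REGION_COLUMNS)]


def _assert_region_invariants(dmrs: pd.DataFrame, min_probes: int,
                              min_mean_delta: float, alpha: float) -> None:
    if len(dmrs) == 0:
        return
    assert (dmrs["n_probes"] >= min_probes).all()
    assert (dmrs["mean_delta_beta"].abs() > min_mean_delta).all()
    assert (dmrs["q_region"] < alpha).all()
    assert (dmrs["start"] <= dmrs["end"]).all()


def _other_cohort_mean_delta(region_row, stats_other: pd.DataFrame) -> float:
    st = stats_other.set_index("probe_id")
    probes = region_row["probe_ids"].split(",")
    return float(st.loc[probes, "delta_beta"].mean())


def classify_dmrs(dmrs_infant: pd.DataFrame, stats_adol: pd.DataFrame,
                  dmrs_adol: pd.DataFrame, stats_infant: pd.DataFrame,
                  unresp_delta: float = 0.02) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set the class column of both cohorts' DMR tables.

    shared: called in both cohorts with overlapping spans and the same
    direction; cohort-specific: the same probes average |delta beta| <
    unresp_delta in the other cohort; otherwise unclassified.
    """
    out_i = dmrs_infant.copy()
    out_a = dmrs_adol.copy()
    for out, other_dmrs, other_stats, own_label in (
        (out_i, out_a, stats_adol, "infant_specific"),
        (out_a, out_i, stats_infant, "adolescent_specific"),
    ):
        classes = []
        for _, row in out.iterrows():
            overlap = other_dmrs[
                (other_dmrs["chrom"] == row["chrom"])
                & (other_dmrs["start"] <= row["end"])
                & (other_dmrs["end"] >= row["start"])
                & (other_dmrs["direction"] == row["direction"])
            ]
            if len(overlap):
                classes.append("shared")
            elif abs(_other_cohort_mean_delta(row, other_stats)) < unresp_delta:
                classes.append(own_label)
            else:
                classes.append("unclassified")
        out["class"] = classes if len(out) else out.get("class", [])
    return out_i, out_a


def regions_to_bed(dmrs: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """Export DMRs as BED (0-based half-open; widens the 1-based span)."""
    from agespec.io_formats import header_comment

    with open(path, "w") as fh:
        fh.write(header_comment(config_hash) + "\n")
        for row in dmrs.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.region_id}"
                f"\t{row.mean_delta_beta:.4f}\t.\n"
            )
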