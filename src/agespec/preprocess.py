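"""Probe filtering, cross-dataset intersection, within-cohort scaling, PCA.

Scaling standardizes each probe within each cohort (dataset), which removes
the additive cohort-level technical offset exactly and lets the two
independently assayed cohorts be visualized together; PCA on the scaled
matrix is the standard QC view separating culture conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from agespec.io_formats import BetaMatrix

__all__ = [
    "FilterLog",
    "filter_probes",
    "intersect_common_probes",
    "scale_within_cohort",
    "pca",
]

logger = logging.getLogger("agespec")


@dataclass
class FilterLog:
    n_in: int
    n_removed_detection: int
    n_removed_blacklist: int
    n_blacklist_absent: int
    n_out: int


def filter_probes(beta: BetaMatrix, detection_p: pd.DataFrame | None = None,
                  blacklist: set[str] | None = None,
                  detection_threshold: float = 0.01) -> tuple[BetaMatrix, FilterLog]:
    """Drop probes with mean detection p above threshold and blacklist members.

    Blacklists (cross-reactive / SNP-associated / batch-affected probes) are
    supplied as plain id sets; ids absent from the matrix are ignored with a
    logged count.
    """
    blacklist = blacklist or set()
    keep = pd.Series(True, index=beta.probe_ids)
    n_det = 0
    if detection_p is not None:
        if not detection_p.index.equals(beta.probe_ids):
            detection_p = detection_p.reindex(beta.probe_ids)
            if detection_p.isna().any().any():
                raise ValueError("detection_p is not aligned to the beta matrix")
        high = detection_p.mean(axis=1) > detection_threshold
        n_det = int(high.sum())
        keep &= ~high
    present = keep.index.isin(blacklist)
    n_bl = int((keep & present).sum())
    n_absent = len(blacklist - set(beta.probe_ids))
    keep &= ~present
    out = BetaMatrix(beta.data.loc[keep], beta.config_hash)
    log = FilterLog(
        n_in=len(beta.probe_ids),
        n_removed_detection=n_det,
        n_removed_blacklist=n_bl,
        n_blacklist_absent=n_absent,
        n_out=len(out.probe_ids),
    )
    logger.info(
        "filter_probes: %d in, %d removed (detection), %d removed (blacklist, "
        "%d absent ids ignored), %d out",
        log.n_in, log.n_removed_detection, log.n_removed_blacklist,
        log.n_blacklist_absent, log.n_out,
    )
    return out, log


def intersect_common_probes(a: BetaMatrix, b: BetaMatrix) -> tuple[BetaMatrix, BetaMatrix]:
    """Restrict both matrices to their sorted common probe set, same row order."""
    common = sorted(set(a.probe_ids) & set(b.probe_ids))
    if not common:
        raise ValueError("no probes shared between the two matrices")
    logger.info("intersect_common_probes: %d common probes (%d / %d in)",
                len(common), len(a.probe_ids), len(b.probe_ids))
    return a.subset_probes(common), b.subset_probes(common)


def scale_within_cohort(beta: BetaMatrix, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per probe, per cohort: subtract the cohort mean and divide by the
    cohort sample standard deviation (n-1 denominator).

    Zero-variance rows map to all-zero within that cohort.  Returns a
    DataFrame shaped like the beta matrix.
    """
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    missing = set(beta.sample_ids) - set(sheet.index)
    if missing:
        raise ValueError(f"samples missing from sheet: {sorted(missing)[:5]}")
    cohorts = sheet.loc[beta.sample_ids, "cohort"]
    out = np.empty(beta.data.shape)
    values = beta.values
    for cohort in cohorts.unique():
        cols = np.flatnonzero((cohorts == cohort).to_numpy())
        if len(cols) < 2:
            raise ValueError(f"cohort {cohort!r} has fewer than 2 samples")
        sub = values[:, cols]
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        scaled = np.where(sd > 0, (sub - mean) / np.where(sd > 0, sd, 1.0), 0.0)
        out[:, cols] = scaled
    return pd.DataFrame(out, index=beta.probe_ids, columns=beta.sample_ids)


def pca(scaled: pd.DataFrame, n_components: int):
    """PCA of samples with probes as features, without re-centering.

    Returns (scores, variance_explained): scores is a samples x components
    DataFrame, variance_explained the fraction of total sum of squares per
    component (non-increasing).  The sign of each component is fixed so its
    probe-loading vector has a positive sum.
    """
    X = scaled.to_numpy(dtype=float).T  # samples x probes
    if np.isnan(X).any():
        raise ValueError("NaN in scaled matrix")
    n_components = int(n_components)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds min(n_samples, n_probes)")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.where(Vt.sum(axis=1) < 0, -1.0, 1.0)
    U = U * flip[None, :]
    total = float(np.sum(S**2))
    ve = (S**2 / total) if total > 0 else np.zeros_like(S)
    scores = U[:, :n_components] * S[:n_components]
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return (
        pd.DataFrame(scores, index=scaled.columns, columns=cols),
        ve[:n_components],
    )
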