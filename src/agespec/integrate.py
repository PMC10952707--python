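"""Cross-omic layers: chromatin concordance, cytokines, pathways, enrichment.

* DMP x ATAC direction concordance: a plain Pearson chi-square (df = 1, no
  continuity correction by default) on the 2x2 table of methylation
  direction against accessibility direction for DMPs overlapping
  direction-annotated peaks.
* Cytokine analysis: per-donor log2 activation fold changes, a two-sided
  Wilcoxon rank-sum comparison of fold changes between cohorts, and a
  Pearson correlation scan of DMPs within 1 Mb of each cytokine gene's TSS
  against per-sample cytokine output.
* Tri-omic pathway categorization: each pathway gene assigned its 2^3
  evidence cell (methylation / expression / accessibility).
* Gene-set enrichment: one-sided hypergeometric upper tail, with an
  optional probe-count bias-aware mode using the Wallenius noncentral
  hypergeometric distribution (genes carrying more probes are more likely
  to be picked by chance on an array).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from agespec.io_formats import BetaMatrix

__all__ = [
    "overlap_probes_peaks",
    "direction_concordance",
    "chi2_2x2",
    "cytokine_log2fc",
    "compare_cohort_fc",
    "correlate_probe_cytokine",
    "cytokine_tss_from_manifest",
    "categorize_pathway_genes",
    "enrichment_test",
]

logger = logging.getLogger("agespec")


# ---------------------------------------------------------------------------
# Probe / peak overlap
# ---------------------------------------------------------------------------

def _check_chrom_conventions(manifest_chroms, peak_chroms) -> None:
    m_pref = {str(c).startswith("chr") for c in manifest_chroms}
    p_pref = {str(c).startswith("chr") for c in peak_chroms}
    if m_pref and p_pref and m_pref != p_pref:
        raise ValueError(
            "chromosome naming mismatch between manifest and peaks "
            "('chr1' vs '1'); normalize names before overlapping"
        )


def overlap_probes_peaks(manifest: pd.DataFrame, probe_ids, peaks: pd.DataFrame) -> pd.DataFrame:
    """Assign probes to covering peaks.

    A probe at 1-based position p overlaps the 0-based half-open peak
    [start, end) iff start <= p - 1 < end.  A probe covered by several
    peaks is assigned the one whose midpoint is nearest (ties break to the
    lower start).  Returns a (probe_id, peak_name) frame.
    """
    if len(peaks) == 0:
        return pd.DataFrame(columns=["probe_id", "peak_index", "peak_name"])
    sub = manifest[manifest["probe_id"].isin(set(probe_ids))]
    _check_chrom_conventions(sub["chrom"].unique(), peaks["chrom"].unique())

    trees: dict[str, IntervalTree] = {}
    for chrom, chrom_peaks in peaks.groupby("chrom", sort=False):
        tree = IntervalTree()
        for idx, row in chrom_peaks.iterrows():
            tree.addi(int(row["start"]), int(row["end"]), idx)
        trees[chrom] = tree

    rows = []
    for probe, chrom, pos in zip(sub["probe_id"], sub["chrom"], sub["pos"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = tree[pos - 1]
        if not hits:
            continue
        best = min(
            hits,
            key=lambda iv: (abs((iv.begin + iv.end) / 2.0 - (pos - 1)), iv.begin),
        )
        rows.append((probe, best.data, peaks.at[best.data, "name"]))
    return pd.DataFrame(rows, columns=["probe_id", "peak_index", "peak_name"])


# ---------------------------------------------------------------------------
# Direction concordance
# ---------------------------------------------------------------------------

def chi2_2x2(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the optional Yates
    continuity correction subtracts N/2 from |ad - bc|.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("a zero marginal makes the chi-square test undefined")
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2.0, 0.0)
    chi2 = n * num**2 / margins
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def direction_concordance(dmps: pd.DataFrame, assignments: pd.DataFrame,
                          peaks: pd.DataFrame, yates: bool = False) -> dict:
    """2x2 methylation x accessibility direction table with chi-square.

    Rows: probe hyper / hypo; columns: peak accessibility loss / gain.
    Returns the table and test even when a zero marginal voids the test
    (chi2 / p are then NaN and 'error' carries the reason).
    """
    st = dmps.set_index("probe_id")
    merged = assignments[assignments["probe_id"].isin(st.index)]
    counts = np.zeros((2, 2), dtype=int)
    for probe, peak_idx in zip(merged["probe_id"], merged["peak_index"]):
        direction = peaks.at[peak_idx, "direction"]
        if direction not in ("gain", "loss"):
            continue
        i = 0 if st.at[probe, "delta_beta"] > 0 else 1  # hyper / hypo
        j = 0 if direction == "loss" else 1
        counts[i, j] += 1
    if counts.sum() == 0:
        raise ValueError("no DMP overlaps a direction-annotated peak")
    result = {
        "table": counts,
        "rows": ("hyper", "hypo"),
        "cols": ("loss", "gain"),
        "n": int(counts.sum()),
        "df": 1,
    }
    try:
        chi2, p = chi2_2x2(counts, yates=yates)
        result.update(chi2=chi2, p=p, error=None)
    except ValueError as exc:
        result.update(chi2=float("nan"), p=float("nan"), error=str(exc))
    return result


# ---------------------------------------------------------------------------
# Cytokines
# ---------------------------------------------------------------------------

def cytokine_log2fc(cyto: pd.DataFrame, sheet: pd.DataFrame,
                    floor: float | None = None) -> pd.DataFrame:
    """Per-donor, per-cytokine log2(activated / max(quiescent, floor)).

    ``floor`` guards against zero quiescent concentrations; by default it
    is the smallest positive observed concentration of each cytokine.
    Donors missing a condition are dropped with a log count.
    """
    if (cyto["concentration"] < 0).any():
        raise ValueError("negative concentration in cytokine table")
    meta = sheet.set_index("sample_id")[["donor_id", "cohort"]]
    merged = cyto.join(meta, on="sample_id")
    wide = merged.pivot_table(
        index=["donor_id", "cohort", "cytokine"], columns="condition",
        values="concentration", aggfunc="first",
    )
    n_dropped = int(wide.isna().any(axis=1).sum())
    if n_dropped:
        logger.info("cytokine_log2fc: dropped %d donor x cytokine rows missing a condition", n_dropped)
        wide = wide.dropna()
    rows = []
    for (donor, cohort, cytokine), row in wide.iterrows():
        if floor is None:
            positive = merged.loc[
                (merged["cytokine"] == cytokine) & (merged["concentration"] > 0),
                "concentration",
            ]
            f = float(positive.min()) if len(positive) else 1e-6
        else:
            f = float(floor)
            if f <= 0:
                raise ValueError("floor must be positive")
        denom = max(row["quiescent"], f)
        numer = max(row["activated"], f)
        rows.append((donor, cohort, cytokine, math.log2(numer / denom)))
    return pd.DataFrame(rows, columns=["donor_id", "cohort", "cytokine", "log2fc"])


def compare_cohort_fc(fc: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of log2 fold changes between cohorts.

    Exact null distribution for combined n <= 20, normal approximation
    with tie correction otherwise.  Direction is the sign of the median
    difference (adolescent - infant).  A cohort with fewer than 3 donors
    yields p = NaN with a warning.
    """
    rows = []
    for cytokine, sub in fc.groupby("cytokine", sort=True):
        x = sub.loc[sub["cohort"] == "adolescent", "log2fc"].to_numpy()
        y = sub.loc[sub["cohort"] == "infant", "log2fc"].to_numpy()
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"cytokine {cytokine!r} missing a cohort")
        med_diff = float(np.median(x) - np.median(y))
        direction = "adolescent" if med_diff > 0 else ("infant" if med_diff < 0 else "equal")
        if min(len(x), len(y)) < 3:
            logger.warning("compare_cohort_fc: cohort with < 3 donors for %s; p unavailable", cytokine)
            rows.append((cytokine, float("nan"), float("nan"), direction))
            continue
        method = "exact" if len(x) + len(y) <= 20 else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append((cytokine, float(res.statistic), float(res.pvalue), direction))
    return pd.DataFrame(rows, columns=["cytokine", "statistic", "p", "direction"])


def cytokine_tss_from_manifest(manifest: pd.DataFrame, cytokines) -> dict[str, tuple[str, int]]:
    """Recover cytokine gene TSS coordinates from manifest annotations."""
    out = {}
    for cytokine in cytokines:
        sub = manifest[manifest["nearest_gene"] == cytokine]
        if len(sub) == 0:
            continue
        row = sub.iloc[0]
        out[cytokine] = (row["chrom"], int(row["pos"] - row["tss_distance"]))
    return out


def correlate_probe_cytokine(dmps: pd.DataFrame, manifest: pd.DataFrame,
                             beta: BetaMatrix, cyto: pd.DataFrame,
                             sheet: pd.DataFrame, gene_tss: dict,
                             cohort: str, window_bp: float = 1e6,
                             alpha: float = 0.05,
                             keep_all: bool = False) -> pd.DataFrame:
    """Pearson scan of activated-state beta against activated concentration.

    Candidates are DMPs within ``window_bp`` of a cytokine gene TSS on the
    same chromosome; for each (probe, cytokine) pair the activated
    samples of ``cohort`` are matched donor-wise between the beta matrix
    and the cytokine table.  Rows with p < alpha are returned unless
    ``keep_all``.  Pairs with fewer than 4 matched samples get r = NaN.
    """
    dmp_ids = dmps.loc[dmps["is_dmp"], "probe_id"]
    man = manifest.set_index("probe_id")
    sub_sheet = sheet[(sheet["cohort"] == cohort) & (sheet["condition"] == "activated")]
    sample_of_donor = dict(zip(sub_sheet["donor_id"], sub_sheet["sample_id"]))
    meta = sheet.set_index("sample_id")["donor_id"]
    act_cyto = cyto[cyto["condition"] == "activated"].copy()
    act_cyto["donor_id"] = act_cyto["sample_id"].map(meta)

    rows = []
    for cytokine, (chrom, tss) in sorted(gene_tss.items()):
        conc = act_cyto[act_cyto["cytokine"] == cytokine].set_index("donor_id")["concentration"]
        donors = [d for d in sorted(sample_of_donor) if d in conc.index]
        samples = [sample_of_donor[d] for d in donors]
        cand = [
            p for p in dmp_ids
            if man.at[p, "chrom"] == chrom and abs(man.at[p, "pos"] - tss) <= window_bp
        ]
        for probe in cand:
            if len(donors) < 4:
                rows.append((probe, cytokine, float("nan"), float("nan"), len(donors)))
                continue
            x = beta.data.loc[probe, samples].to_numpy(float)
            y = conc.loc[donors].to_numpy(float)
            r, p = sps.pearsonr(x, y)
            rows.append((probe, cytokine, float(r), float(p), len(donors)))
    out = pd.DataFrame(rows, columns=["probe_id", "cytokine", "r", "p", "n"])
    if not keep_all:
        out = out[out["p"] < alpha].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Pathway categorization and enrichment
# ---------------------------------------------------------------------------

def categorize_pathway_genes(pathway_genes, dnam_genes, expr_genes, atac_genes):
    """Assign each pathway gene its 2^3 evidence category.

    Returns (table, counts): the table has one row per gene with the three
    booleans and a category label; counts maps all 8 category labels to
    their sizes.
    """
    dnam, expr, atac = set(dnam_genes), set(expr_genes), set(atac_genes)
    rows = []
    for gene in sorted(set(pathway_genes)):
        flags = (gene in dnam, gene in expr, gene in atac)
        rows.append((gene, *flags, _category_label(*flags)))
    table = pd.DataFrame(rows, columns=["gene", "in_dnam", "in_expr", "in_atac", "category"])
    counts = {_category_label(a, b, c): 0 for a in (0, 1) for b in (0, 1) for c in (0, 1)}
    for cat in table["category"]:
        counts[cat] += 1
    return table, counts


def _category_label(in_dnam: bool, in_expr: bool, in_atac: bool) -> str:
    parts = [name for flag, name in ((in_dnam, "dnam"), (in_expr, "expr"), (in_atac, "atac")) if flag]
    if not parts:
        return "none"
    if len(parts) == 1:
        return f"{parts[0]} only"
    return "+".join(parts)


def enrichment_test(study_genes, universe_genes, gene_sets: dict,
                    probes_per_gene: dict | None = None) -> pd.DataFrame:
    """Per-set overlap p-values for the study genes against a universe.

    Default: one-sided hypergeometric upper tail.  With ``probes_per_gene``
    supplied: Wallenius noncentral hypergeometric with set odds equal to
    the ratio of mean probe counts inside vs outside the set (bias-aware
    mode: heavily probed genes are easier to hit by chance).  BH-adjusted
    across sets.
    """
    study = set(study_genes)
    universe = set(universe_genes)
    stray = study - universe
    if stray:
        raise ValueError(f"study genes missing from universe: {sorted(stray)[:10]}")
    M, N = len(universe), len(study)
    rows = []
    for name, genes in sorted(gene_sets.items()):
        in_set = set(genes) & universe
        n = len(in_set)
        k = len(in_set & study)
        if n == 0:
            rows.append((name, 0, 0, 1.0))
            continue
        odds = 1.0
        if probes_per_gene is not None:
            w_in = np.mean([probes_per_gene.get(g, 1.0) for g in sorted(in_set)])
            w_out = np.mean([probes_per_gene.get(g, 1.0) for g in sorted(universe - in_set)]) \
                if len(universe - in_set) else 1.0
            odds = float(w_in / w_out)
        if probes_per_gene is None or abs(odds - 1.0) < 1e-12:
            p = float(sps.hypergeom.sf(k - 1, M, n, N))
        else:
            p = float(sps.nchypergeom_wallenius.sf(k - 1, M, n, N, odds))
        rows.append((name, n, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p"])
    from agespec.differential import bh_adjust

    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
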