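"""End-to-end orchestration: simulate -> preprocess -> DMP x2 -> classify ->
DMR -> integrate, with a machine-readable summary and config-hash provenance.

Every stage output file carries the run's config hash in its header
comment; loading files whose hashes disagree is refused.  Identical
configuration and seed yield a byte-identical summary JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from agespec import classify, differential, integrate, preprocess, regions
from agespec import io_formats as io
from agespec import synthetic

__all__ = [
    "RunConfig",
    "config_hash",
    "run_pipeline",
    "ensure_same_run",
    "simulation_config_from_dict",
    "run_config_from_dict",
]

logger = logging.getLogger("agespec")


@dataclass(frozen=True)
class RunConfig:
    """All thresholds, flags and inputs of one pipeline run.

    Defaults equal the published thresholds of the analysis: DMP rule
    q < 0.01 and |delta beta| > 5%; "truly unresponsive" |delta beta| < 2%;
    DMRs of >= 4 probes with mean |delta beta| > 5% at region FDR < 0.01;
    1-Mb TSS windows; correlation filter p < 0.05; differential
    accessibility gate p < 0.05 and fold change > 1.5.
    """

    simulation: synthetic.SimulationConfig | None = None
    beta_path: str | None = None
    sheet_path: str | None = None
    manifest_path: str | None = None
    peaks_path: str | None = None
    cytokines_path: str | None = None
    blacklist_path: str | None = None
    alpha: float = 0.01
    resp_delta: float = 0.05
    unresp_delta: float = 0.02
    min_probes: int = 4
    maxgap: int = 1000
    window_bp: float = 1e6
    corr_alpha: float = 0.05
    atac_p: float = 0.05
    atac_fc: float = 1.5
    covariates_infant: tuple[str, ...] = ("sex",)
    covariates_adolescent: tuple[str, ...] = ("sex",)
    pair_by_donor: bool = False
    venn_mode: bool = False
    yates: bool = False
    n_pca_components: int = 5
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not (0 < self.alpha < 1 and 0 < self.corr_alpha < 1):
            raise ValueError("significance thresholds must lie in (0, 1)")
        if self.resp_delta <= self.unresp_delta:
            raise ValueError("resp_delta must exceed unresp_delta")
        if self.min_probes < 1 or self.maxgap < 1:
            raise ValueError("min_probes and maxgap must be positive")
        if self.simulation is None and (self.beta_path is None or self.sheet_path is None
                                        or self.manifest_path is None):
            raise ValueError("either a simulation config or input paths are required")
        for path in (self.beta_path, self.sheet_path, self.manifest_path,
                     self.peaks_path, self.cytokines_path, self.blacklist_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)
        return self


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _to_jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(_to_jsonable(dataclasses.asdict(config)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def ensure_same_run(*paths) -> str | None:
    """Refuse to mix stage outputs from different runs (config hashes differ)."""
    hashes = {h for h in (io.file_config_hash(p) for p in paths if p is not None)
              if h is not None}
    if len(hashes) > 1:
        raise ValueError(f"input files come from different runs: config hashes {sorted(hashes)}")
    return next(iter(hashes), None)


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        beta, sheet, manifest, truth = synthetic.simulate_cohorts(sim)
        peaks = synthetic.simulate_atac_peaks(truth, manifest, sim)
        cyto = synthetic.simulate_cytokines(sheet, beta, truth, sim)
        extras = {
            "truth": truth,
            "expr_genes": synthetic.simulate_expression_calls(truth, manifest, sim),
            "pathway": synthetic.simulate_pathway(truth, manifest, sim),
            "gene_sets": synthetic.simulate_gene_sets(truth, manifest, sim),
        }
        return beta, sheet, manifest, peaks, cyto, extras
    ensure_same_run(config.beta_path, config.sheet_path, config.manifest_path,
                    config.peaks_path, config.cytokines_path)
    beta = io.read_beta_matrix(config.beta_path)
    sheet = io.read_sample_sheet(config.sheet_path)
    manifest = io.read_manifest(config.manifest_path)
    peaks = io.read_bed_peaks(config.peaks_path) if config.peaks_path else None
    cyto = io.read_cytokine_table(config.cytokines_path) if config.cytokines_path else None
    return beta, sheet, manifest, peaks, cyto, {}


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage in dependency order and write all outputs.

    Returns the summary dictionary also written to ``summary.json``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config_hash(config)
    summary: dict = {"config_hash": h, "seed": config.seed}

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    # ----- inputs ------------------------------------------------------
    _stage("inputs")
    beta, sheet, manifest, peaks, cyto, extras = _load_inputs(config)
    summary["n_probes"] = int(len(beta.probe_ids))
    summary["n_samples"] = int(len(beta.sample_ids))

    # ----- preprocess --------------------------------------------------
    _stage("preprocess")
    blacklist = io.read_probe_list(config.blacklist_path) if config.blacklist_path else set()
    beta, filter_log = preprocess.filter_probes(beta, blacklist=blacklist)
    summary["filter"] = dataclasses.asdict(filter_log)

    inf_samples = sheet.loc[sheet["cohort"] == "infant", "sample_id"]
    adol_samples = sheet.loc[sheet["cohort"] == "adolescent", "sample_id"]
    beta_inf, beta_adol = preprocess.intersect_common_probes(
        beta.subset_samples(inf_samples), beta.subset_samples(adol_samples)
    )
    combined = io.BetaMatrix(
        pd.concat([beta_inf.data, beta_adol.data], axis=1), beta.config_hash
    )
    scaled = preprocess.scale_within_cohort(combined, sheet)
    n_comp = min(config.n_pca_components, len(combined.sample_ids))
    scores, ve = preprocess.pca(scaled, n_comp)
    with open(outdir / "pca_scores.tsv", "w") as fh:
        fh.write(io.header_comment(h) + "\n")
        scores.to_csv(fh, sep="\t")
    summary["pca_variance_explained"] = [float(v) for v in ve]

    # ----- differential (per cohort, independently) --------------------
    _stage("differential")
    stats = {}
    for cohort, covs in (("infant", config.covariates_infant),
                         ("adolescent", config.covariates_adolescent)):
        table, dmp_summary = differential.dmp_pipeline(
            combined, sheet, cohort, covariates=covs,
            pair_by_donor=config.pair_by_donor,
            alpha=config.alpha, min_delta=config.resp_delta,
        )
        stats[cohort] = table
        io.write_probe_stats(table, outdir / f"stats_{cohort}.tsv", config_hash=h)
        summary.setdefault("dmp", {})[cohort] = dmp_summary

    # ----- age classification ------------------------------------------
    _stage("classification")
    classes = classify.classify_probes(
        stats["infant"], stats["adolescent"], alpha=config.alpha,
        resp_delta=config.resp_delta, unresp_delta=config.unresp_delta,
        venn_mode=config.venn_mode,
    )
    class_summary = classify.summarize_classes(classes)
    with open(outdir / "classes.tsv", "w") as fh:
        fh.write(io.header_comment(h) + "\n")
        classes.to_csv(fh, sep="\t", index=False)
    summary["classes"] = {
        row["class"]: {"n": int(row["n"]), "n_hyper": int(row["n_hyper"]),
                       "n_hypo": int(row["n_hypo"])}
        for _, row in class_summary.iterrows()
    }

    # ----- regions ------------------------------------------------------
    _stage("regions")
    clusters = regions.cluster_probes(manifest, beta_inf.probe_ids, maxgap_bp=config.maxgap)
    dmrs = {}
    for cohort in ("infant", "adolescent"):
        dmrs[cohort] = regions.call_dmrs(
            clusters, stats[cohort], min_probes=config.min_probes,
            min_mean_delta=config.resp_delta, alpha=config.alpha,
        )
    dmrs["infant"], dmrs["adolescent"] = regions.classify_dmrs(
        dmrs["infant"], stats["adolescent"], dmrs["adolescent"], stats["infant"],
        unresp_delta=config.unresp_delta,
    )
    for cohort in ("infant", "adolescent"):
        table = dmrs[cohort]
        with open(outdir / f"dmrs_{cohort}.tsv", "w") as fh:
            fh.write(io.header_comment(h) + "\n")
            table.to_csv(fh, sep="\t", index=False)
        regions.regions_to_bed(table, outdir / f"dmrs_{cohort}.bed", config_hash=h)
        summary.setdefault("dmr", {})[cohort] = {
            "total": int(len(table)),
            "hyper": int((table["direction"] == "hyper").sum()),
            "hypo": int((table["direction"] == "hypo").sum()),
            "by_class": {c: int((table["class"] == c).sum())
                         for c in sorted(table["class"].unique())} if len(table) else {},
        }

    # ----- integration ---------------------------------------------------
    _stage("integration")
    shared_ids = classes.loc[classes["class"] == "shared", "probe_id"]
    if peaks is not None and len(peaks) and len(shared_ids):
        assignments = integrate.overlap_probes_peaks(manifest, shared_ids, peaks)
        shared_stats = stats["infant"][stats["infant"]["probe_id"].isin(set(shared_ids))]
        try:
            conc = integrate.direction_concordance(shared_stats, assignments, peaks,
                                                   yates=config.yates)
            summary["concordance"] = {
                "table": conc["table"].tolist(), "n": conc["n"],
                "chi2": conc["chi2"], "p": conc["p"], "df": 1,
            }
        except ValueError as exc:
            summary["concordance"] = {"error": str(exc)}

    if cyto is not None and len(cyto):
        fc = integrate.cytokine_log2fc(cyto, sheet)
        tests = integrate.compare_cohort_fc(fc)
        summary["cytokines"] = [
            {"cytokine": r["cytokine"], "statistic": r["statistic"],
             "p": r["p"], "direction": r["direction"]}
            for _, r in tests.iterrows()
        ]
        gene_tss = integrate.cytokine_tss_from_manifest(manifest, sorted(fc["cytokine"].unique()))
        summary["correlations"] = {}
        for cohort in ("infant", "adolescent"):
            hits = integrate.correlate_probe_cytokine(
                stats[cohort], manifest, combined, cyto, sheet, gene_tss,
                cohort, window_bp=config.window_bp, alpha=config.corr_alpha,
            )
            summary["correlations"][cohort] = [
                {"probe_id": r["probe_id"], "cytokine": r["cytokine"],
                 "r": r["r"], "p": r["p"]}
                for _, r in hits.iterrows()
            ]

    if peaks is not None and len(peaks) and extras:
        dmp_genes = _genes_of_probes(
            manifest, stats["infant"].loc[stats["infant"]["is_dmp"], "probe_id"])
        diff_peaks = peaks[(peaks["p_value"] < config.atac_p)
                           & (np.abs(np.log(peaks["fold_change"])) > np.log(config.atac_fc))]
        atac_genes = _genes_of_peaks(manifest, diff_peaks)
        pathway = extras["pathway"]
        _, counts = integrate.categorize_pathway_genes(
            pathway, dmp_genes, extras["expr_genes"], atac_genes)
        summary["pathway_counts"] = counts

        universe = sorted(manifest["nearest_gene"].dropna().unique())
        probes_per_gene = manifest["nearest_gene"].dropna().value_counts().to_dict()
        enr = integrate.enrichment_test(
            sorted(set(dmp_genes) & set(universe)), universe, extras["gene_sets"],
            probes_per_gene=probes_per_gene,
        )
        summary["enrichment"] = [
            {"set_name": r["set_name"], "overlap": int(r["overlap"]),
             "p": r["p"], "q": r["q"]}
            for _, r in enr.iterrows()
        ]

    if "truth" in extras:
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write(io.header_comment(h) + "\n")
            extras["truth"].to_csv(fh, sep="\t", index=False)

    summary_json = json.dumps(_to_jsonable(summary), sort_keys=True, indent=1)
    (outdir / "summary.json").write_text(summary_json + "\n")
    return summary


def _genes_of_probes(manifest: pd.DataFrame, probe_ids) -> set[str]:
    sub = manifest[manifest["probe_id"].isin(set(probe_ids))]
    return set(sub["nearest_gene"].dropna())


def _genes_of_peaks(manifest: pd.DataFrame, peaks: pd.DataFrame) -> set[str]:
    """Nearest gene of each peak via the probes it covers or flanks (<= 1 Mb)."""
    genes: set[str] = set()
    man = manifest.sort_values(["chrom", "pos"], kind="mergesort")
    for chrom, chrom_peaks in peaks.groupby("chrom", sort=False):
        sub = man[man["chrom"] == chrom]
        if not len(sub):
            continue
        pos = sub["pos"].to_numpy()
        mid = ((chrom_peaks["start"] + chrom_peaks["end"]) // 2).to_numpy()
        idx = np.clip(np.searchsorted(pos, mid), 0, len(pos) - 1)
        left = np.clip(idx - 1, 0, len(pos) - 1)
        pick = np.where(np.abs(pos[idx] - mid) <= np.abs(pos[left] - mid), idx, left)
        near = np.abs(pos[pick] - mid) <= 1_000_000
        genes |= set(sub.iloc[pick[near]]["nearest_gene"].dropna())
    return genes


# ---------------------------------------------------------------------------
# Config (de)serialization for the CLI
# ---------------------------------------------------------------------------

def simulation_config_from_dict(d: dict) -> synthetic.SimulationConfig:
    d = dict(d)
    if "baseline_beta_distribution" in d:
        d["baseline_beta_distribution"] = synthetic.BaselineMixture(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in d["baseline_beta_distribution"].items()}
        )
    if "covariate_spec" in d:
        d["covariate_spec"] = tuple(
            synthetic.CovariateSpec(**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in c.items()})
            for c in d["covariate_spec"]
        )
    if "cytokine_spec" in d:
        d["cytokine_spec"] = tuple(
            synthetic.CytokineSpec(**c) for c in d["cytokine_spec"]
        )
    if "atac_spec" in d:
        d["atac_spec"] = synthetic.AtacSpec(**d["atac_spec"])
    return synthetic.SimulationConfig(**d).validate()


def run_config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    if d.get("simulation") is not None:
        d["simulation"] = simulation_config_from_dict(d["simulation"])
    for key in ("covariates_infant", "covariates_adolescent"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return RunConfig(**d)
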