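"""Readers and writers for the on-disk artifacts of the pipeline.

Conventions are fixed here and nowhere else:

* probe manifest positions are 1-based (Illumina manifest convention);
* BED peak intervals are 0-based half-open; the conversion between the two
  frames happens exactly once, at the interval-overlap boundary in
  :mod:`agespec.integrate`;
* readers reject malformed input rather than coercing it (no silent
  NA-filling, no silent reordering);
* writers emit a ``#`` header comment carrying the tool version and, when
  available, the hash of the run configuration, so files from different
  runs can be told apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "BetaMatrix",
    "COHORTS",
    "CONDITIONS",
    "CGI_RELATIONS",
    "CANONICAL_CYTOKINES",
    "read_beta_matrix",
    "write_beta_matrix",
    "validate_sample_sheet",
    "read_sample_sheet",
    "write_sample_sheet",
    "unpaired_donors",
    "validate_manifest",
    "read_manifest",
    "write_manifest",
    "validate_peaks",
    "read_bed_peaks",
    "write_bed_peaks",
    "validate_cytokine_table",
    "read_cytokine_table",
    "write_cytokine_table",
    "PROBE_STATS_COLUMNS",
    "read_probe_stats",
    "write_probe_stats",
    "read_gene_sets",
    "read_gmt",
    "read_probe_list",
    "header_comment",
    "file_config_hash",
]

logger = logging.getLogger("agespec")

COHORTS = ("infant", "adolescent")
CONDITIONS = ("quiescent", "activated")
CGI_RELATIONS = ("island", "shore", "shelf", "open_sea")
CANONICAL_CYTOKINES = ("IL2", "IL6", "IL10", "IFNG", "TNF")

#: 1 Mb gene-assignment window around the TSS (GREAT-style rule).
TSS_WINDOW_BP = 1_000_000


class FormatError(ValueError):
    """A file violated the format contract (bounds, duplicates, ragged rows)."""


def header_comment(config_hash: str | None = None) -> str:
    from agespec import __version__

    tag = f"# agespec v{__version__}"
    if config_hash is not None:
        tag += f" config={config_hash}"
    return tag


def _read_header_hash(path) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "config=" in first:
        return first.split("config=", 1)[1].split()[0]
    return None


def file_config_hash(path) -> str | None:
    """Config hash recorded in a file's header comment, if any."""
    return _read_header_hash(path)


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions in [0, 1].

    ``data`` is indexed by probe id with one column per sample id.
    """

    data: pd.DataFrame
    config_hash: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise FormatError(f"duplicate probe ids: {dups[:10]}")
        if cols.duplicated().any():
            dups = sorted(cols[cols.duplicated()].unique())
            raise FormatError(f"duplicate sample ids: {dups[:10]}")
        values = self.data.to_numpy(dtype=float)
        bad = (values < 0) | (values > 1)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"beta value out of [0, 1] at probe {idx[i]!r}, sample "
                f"{cols[j]!r}: {values[i, j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[:, list(sample_ids)], self.config_hash)

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[list(probe_ids)], self.config_hash)


def read_beta_matrix(path) -> BetaMatrix:
    """Read a probes x samples TSV (first column probe_id).

    Probes carrying any missing value are dropped with a logged count; all
    other defects (duplicates, out-of-range values, ragged rows) raise
    :class:`FormatError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows carry the line number
        raise FormatError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.info("read_beta_matrix: dropped %d probes with missing values", n_missing)
        df = df.dropna(axis=0)
    return BetaMatrix(df, config_hash=_read_header_hash(path))


def write_beta_matrix(beta: BetaMatrix, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(config_hash or beta.config_hash) + "\n")
        out = beta.data.copy()
        out.index.name = "probe_id"
        out.to_csv(fh, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_REQUIRED = ("sample_id", "donor_id", "cohort", "condition")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_REQUIRED if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample sheet")
    pair = sheet[["donor_id", "condition"]].apply(tuple, axis=1)
    if pair.duplicated().any():
        raise FormatError("duplicate (donor_id, condition) in sample sheet")
    bad_cohort = set(sheet["cohort"]) - set(COHORTS)
    if bad_cohort:
        raise FormatError(f"unknown cohort labels: {sorted(bad_cohort)}")
    bad_cond = set(sheet["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise FormatError(f"unknown condition labels: {sorted(bad_cond)}")
    return sheet


def unpaired_donors(sheet: pd.DataFrame) -> list[str]:
    """Donors lacking one of the two culture conditions."""
    counts = sheet.groupby("donor_id")["condition"].nunique()
    return sorted(counts.index[counts < 2].astype(str))


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, comment="#", dtype=str)
    out = validate_sample_sheet(sheet)
    unpaired = unpaired_donors(out)
    if unpaired:
        logger.warning("sample sheet has %d unpaired donors: %s", len(unpaired), unpaired[:5])
    return out


def write_sample_sheet(sheet: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(config_hash) + "\n")
        sheet.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# ProbeManifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("probe_id", "chrom", "pos", "nearest_gene", "tss_distance", "cgi_relation")


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    if manifest["probe_id"].duplicated().any():
        dup = manifest.loc[manifest["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"duplicate probe_id in manifest: {dup!r}")
    if (manifest["pos"] < 1).any():
        raise FormatError("manifest positions must be 1-based (pos >= 1)")
    has_gene = manifest["nearest_gene"].notna()
    far = has_gene & (manifest["tss_distance"].abs() > TSS_WINDOW_BP)
    if far.any():
        raise FormatError(
            f"{int(far.sum())} probes have nearest_gene set but |tss_distance| > 1 Mb"
        )
    bad = set(manifest["cgi_relation"].dropna()) - set(CGI_RELATIONS)
    if bad:
        raise FormatError(f"unknown cgi_relation values: {sorted(bad)}")
    return manifest


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"probe_id": str, "chrom": str, "nearest_gene": str, "cgi_relation": str},
    )
    manifest["pos"] = manifest["pos"].astype(int)
    manifest["tss_distance"] = manifest["tss_distance"].astype(float)
    return validate_manifest(manifest)


def write_manifest(manifest: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(config_hash) + "\n")
        manifest.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ATACPeakSet (BED6+2: chrom start end name score=fold_change strand . p direction)
# ---------------------------------------------------------------------------

PEAK_COLUMNS = ("chrom", "start", "end", "name", "fold_change", "strand", "p_value", "direction")


def validate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    if len(peaks) == 0:
        return peaks
    if (peaks["start"] >= peaks["end"]).any():
        i = int(np.argmax((peaks["start"] >= peaks["end"]).to_numpy()))
        raise FormatError(f"peak with start >= end at row {i}: {peaks.iloc[i]['name']!r}")
    if peaks["chrom"].isna().any() or (peaks["chrom"].astype(str).str.strip() == "").any():
        raise FormatError("malformed chromosome names in peak set")
    have = peaks["direction"].notna() & peaks["fold_change"].notna()
    if have.any():
        fc = peaks.loc[have, "fold_change"].astype(float)
        direction = peaks.loc[have, "direction"]
        mism = ((direction == "gain") & (fc <= 1)) | ((direction == "loss") & (fc >= 1))
        if mism.any():
            name = peaks.loc[have].loc[mism, "name"].iloc[0]
            raise FormatError(f"peak direction inconsistent with fold change: {name!r}")
    return peaks


def read_bed_peaks(path) -> pd.DataFrame:
    """Read a BED6+2 peak file into a 0-based half-open peak table.

    With only the first 6 columns present, ``p_value``/``direction`` are
    loaded as unavailable (NaN/None).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BED columns, got {len(parts)}")
            chrom, start, end, name, score = parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4]
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            p_value = float(parts[6]) if len(parts) > 6 else np.nan
            direction = parts[7] if len(parts) > 7 else None
            rows.append(
                (chrom, start, end, name, float(score), parts[5], p_value, direction)
            )
    peaks = pd.DataFrame(rows, columns=list(PEAK_COLUMNS))
    if len(peaks) == 0:
        peaks = pd.DataFrame(columns=list(PEAK_COLUMNS))
    return validate_peaks(peaks)


def write_bed_peaks(peaks: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(config_hash) + "\n")
        for row in peaks.itertuples(index=False):
            p = "" if pd.isna(row.p_value) else f"\t{row.p_value:.6g}"
            d = "" if row.direction is None else f"\t{row.direction}"
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}"
                f"\t{row.fold_change:.6g}\t{row.strand}{p}{d}\n"
            )


# ---------------------------------------------------------------------------
# CytokineTable
# ---------------------------------------------------------------------------

CYTOKINE_COLUMNS = ("sample_id", "cytokine", "condition", "concentration")


def validate_cytokine_table(cyto: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CYTOKINE_COLUMNS if c not in cyto.columns]
    if missing:
        raise FormatError(f"cytokine table missing columns: {missing}")
    if (cyto["concentration"].astype(float) < 0).any():
        raise FormatError("negative cytokine concentration")
    pair = cyto[["sample_id", "cytokine"]].apply(tuple, axis=1)
    if pair.duplicated().any():
        raise FormatError("duplicate (sample_id, cytokine) row in cytokine table")
    unknown = set(cyto["cytokine"]) - set(CANONICAL_CYTOKINES)
    if unknown:
        logger.warning("cytokine table contains non-canonical cytokines: %s", sorted(unknown))
    return cyto


def read_cytokine_table(path) -> pd.DataFrame:
    cyto = pd.read_csv(path, comment="#", dtype={"sample_id": str, "cytokine": str, "condition": str})
    cyto["concentration"] = cyto["concentration"].astype(float)
    return validate_cytokine_table(cyto)


def write_cytokine_table(cyto: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(config_hash) + "\n")
        cyto.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# ProbeStats
# ---------------------------------------------------------------------------

PROBE_STATS_COLUMNS = (
    "probe_id", "coef_m", "sigma2", "df", "t_mod", "p", "q",
    "delta_beta", "direction", "is_dmp",
)


def read_probe_stats(path) -> pd.DataFrame:
    stats = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str, "direction": str})
    missing = [c for c in PROBE_STATS_COLUMNS if c not in stats.columns]
    if missing:
        raise FormatError(f"probe stats missing columns: {missing}")
    stats["is_dmp"] = stats["is_dmp"].astype(bool)
    return stats


def write_probe_stats(stats: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(config_hash) + "\n")
        stats.loc[:, list(PROBE_STATS_COLUMNS)].to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets and probe lists
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> dict[str, set[str]]:
    """Two-column TSV (set_name, gene) -> mapping of set name to gene set."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sets.setdefault(parts[0], set()).add(parts[1])
    return sets


def read_gmt(path) -> dict[str, set[str]]:
    """Convenience GMT parser (set name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[parts[0]] = set(parts[2:])
    return sets


def read_probe_list(path) -> set[str]:
    """One probe id per line (blacklists: cross-reactive / SNP / batch-affected)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}
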