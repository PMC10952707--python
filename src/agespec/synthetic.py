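"""EPIC-like paired two-cohort methylome simulator with planted truth.

The generator emulates the structure of a two-cohort naive CD4 T-cell
activation study: two independently assayed cohorts (by default 18 infant
and 15 adolescent donors), one quiescent and one activated sample per
donor, a cohort-level technical batch offset, and planted activation
effects that are shared, infant-specific, adolescent-specific or opposing
between the cohorts.  Accessory layers (ATAC peaks whose accessibility
direction is stochastically anticorrelated with methylation direction,
cytokine concentrations with cohort-dependent activation fold changes and
probe-coupled outputs, expression calls, pathway and gene-set files) allow
every downstream stage to be verified by parameter recovery.

Noise model: probe-wise independent Gaussian on logit(beta), plus an
optional per-(probe, donor) random intercept shared by the two conditions
of a donor, back-transformed through the logistic function.  Effects are
planted as logit-scale shifts calibrated so the noiseless beta-scale
difference equals the configured target exactly.

Seeding: a single master seed is split into named substreams (probes,
donors, atac, cytokines, expression, pathway, genesets) so adding one
component does not perturb the others.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from agespec.io_formats import (
    CANONICAL_CYTOKINES,
    PEAK_COLUMNS,
    BetaMatrix,
    validate_cytokine_table,
    validate_manifest,
    validate_peaks,
    validate_sample_sheet,
)

__all__ = [
    "ConfigurationError",
    "BaselineMixture",
    "CovariateSpec",
    "CytokineSpec",
    "AtacSpec",
    "SimulationConfig",
    "simulate_cohorts",
    "simulate_atac_peaks",
    "simulate_cytokines",
    "planted_cytokine_pairs",
    "simulate_expression_calls",
    "simulate_pathway",
    "simulate_gene_sets",
]

logger = logging.getLogger("agespec")

PLANTED_CLASSES = ("shared", "infant_specific", "adolescent_specific", "opposing")

_STREAMS = {
    "probes": 0,
    "donors": 1,
    "atac": 2,
    "cytokines": 3,
    "expression": 4,
    "pathway": 5,
    "genesets": 6,
}

_CHROMS = tuple(f"chr{i}" for i in range(1, 23))
_BASE_SPACING_BP = 5000
_GENE_GRID_BP = 200_000


class ConfigurationError(ValueError):
    """The simulation configuration violates its invariants."""


@dataclass(frozen=True)
class BaselineMixture:
    """Mixture of low / intermediate / high methylation states on the beta scale.

    Each component draws baselines from Beta(m*c, (1-m)*c); the bimodal
    low/high weighting mirrors the marginal beta-value distribution of
    Infinium arrays.
    """

    weights: tuple[float, float, float] = (0.35, 0.25, 0.40)
    means: tuple[float, float, float] = (0.10, 0.50, 0.85)
    concentration: float = 30.0


@dataclass(frozen=True)
class CovariateSpec:
    name: str
    kind: str = "categorical"  # or "numeric"
    effect_logit: float = 0.0
    levels: tuple[str, ...] = ("F", "M")


@dataclass(frozen=True)
class CytokineSpec:
    """Per-cytokine generative parameters.

    ``n_corr_infant`` / ``n_corr_adolescent`` designate how many planted
    shared probes have their activated beta linearly coupled to the
    activated concentration in that cohort, at Pearson ``corr_r`` (with k
    probes coupled to one concentration vector the per-probe correlation
    attenuates to corr_r/sqrt(k)).
    """

    name: str
    baseline: float = 50.0  # pg/mL in the quiescent state
    fc_infant: float = 4.0
    fc_adolescent: float = 4.0
    n_corr_infant: int = 0
    n_corr_adolescent: int = 0
    corr_r: float = 0.9


@dataclass(frozen=True)
class AtacSpec:
    n_peaks: int = 3000
    cover_prob: float = 0.7
    concordance_odds: float = 1.5
    frac_differential: float = 0.6


def _default_cytokines() -> tuple[CytokineSpec, ...]:
    # Adolescents respond with higher IL2 / IL10 / IFN-gamma output; IL6 and
    # TNF are age-invariant.  Four probe-cytokine couplings are planted.
    return (
        CytokineSpec("IL2", baseline=40.0, fc_infant=4.0, fc_adolescent=9.0,
                     n_corr_adolescent=1),
        CytokineSpec("IL6", baseline=120.0, fc_infant=6.0, fc_adolescent=6.0),
        CytokineSpec("IL10", baseline=25.0, fc_infant=3.0, fc_adolescent=7.0,
                     n_corr_infant=1, n_corr_adolescent=1),
        CytokineSpec("IFNG", baseline=60.0, fc_infant=5.0, fc_adolescent=12.0,
                     n_corr_adolescent=1),
        CytokineSpec("TNF", baseline=80.0, fc_infant=5.0, fc_adolescent=5.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_probes: int = 20_000
    n_donors_infant: int = 18
    n_donors_adolescent: int = 15
    frac_shared: float = 0.05
    frac_infant_specific: float = 0.02
    frac_adolescent_specific: float = 0.01
    frac_opposing: float = 0.001
    effect_delta_beta: float = 0.10
    hypo_fraction_by_class: dict = field(
        default_factory=lambda: {
            "shared": 0.74,
            "infant_specific": 0.9,
            "adolescent_specific": 0.1,
            "opposing": 0.5,
        }
    )
    baseline_beta_distribution: BaselineMixture = field(default_factory=BaselineMixture)
    noise_sd_logit: float = 0.12
    donor_sd_logit: float = 0.08  # per-(probe, donor) random intercept; 0 disables
    batch_shift_logit: float = 0.4
    n_dmr_blocks: int = 25
    dmr_block_size: int = 6
    dmr_block_span_bp: int = 3000
    covariate_spec: tuple[CovariateSpec, ...] = (
        CovariateSpec("sex", "categorical", 0.05, ("F", "M")),
    )
    cytokine_spec: tuple[CytokineSpec, ...] = field(default_factory=_default_cytokines)
    cytokine_log_noise_sd: float = 0.25
    atac_spec: AtacSpec = field(default_factory=AtacSpec)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        fracs = (
            self.frac_shared,
            self.frac_infant_specific,
            self.frac_adolescent_specific,
            self.frac_opposing,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigurationError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ConfigurationError("class fractions sum to more than 1")
        if self.dmr_block_size < 4:
            raise ConfigurationError("dmr_block_size must be >= 4")
        if not 0 <= self.effect_delta_beta < 0.5:
            raise ConfigurationError("effect_delta_beta must lie in [0, 0.5)")
        counts = self.class_counts()
        if sum(counts.values()) > self.n_probes:
            raise ConfigurationError("planted probes exceed n_probes")
        n_block_probes = self.n_dmr_blocks * self.dmr_block_size
        if n_block_probes > counts["shared"]:
            raise ConfigurationError(
                "DMR blocks require more shared probes than the shared fraction provides"
            )
        n_corr = sum(c.n_corr_infant + c.n_corr_adolescent for c in self.cytokine_spec)
        if n_block_probes + n_corr > counts["shared"]:
            raise ConfigurationError("not enough shared probes for blocks + cytokine couplings")
        for frac in self.hypo_fraction_by_class.values():
            if not 0 <= frac <= 1:
                raise ConfigurationError("hypo fractions must lie in [0, 1]")
        return self

    def class_counts(self) -> dict[str, int]:
        return {
            "shared": round(self.frac_shared * self.n_probes),
            "infant_specific": round(self.frac_infant_specific * self.n_probes),
            "adolescent_specific": round(self.frac_adolescent_specific * self.n_probes),
            "opposing": round(self.frac_opposing * self.n_probes),
        }


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],))
    )


# ---------------------------------------------------------------------------
# Genome layout: probes on slots, DMR-block runs, gene grid
# ---------------------------------------------------------------------------

def _genome_layout(config: SimulationConfig):
    """Assign each probe slot a chromosome and 1-based position.

    Slots are spaced ``_BASE_SPACING_BP`` apart except inside DMR-block
    runs, where spacing shrinks so a block spans ``dmr_block_span_bp``.
    Returns (chrom_of_slot, pos_of_slot, block_of_slot) arrays; block id is
    -1 outside blocks.
    """
    n = config.n_probes
    per_chrom = math.ceil(n / len(_CHROMS))
    chrom_idx = np.minimum(np.arange(n) // per_chrom, len(_CHROMS) - 1)

    block_of_slot = np.full(n, -1, dtype=int)
    size = config.dmr_block_size
    n_blocks = config.n_dmr_blocks
    if n_blocks > 0:
        stride = max(size + 2, n // max(n_blocks, 1))
        start = min(10, max(0, n - n_blocks * stride))
        for b in range(n_blocks):
            s = min(start + b * stride, n - size)
            # shift forward until the run sits inside one chromosome and on
            # slots not already claimed by another block
            while s + size <= n and (
                chrom_idx[s] != chrom_idx[s + size - 1]
                or (block_of_slot[s : s + size] >= 0).any()
            ):
                s += 1
            if s + size > n:
                raise ConfigurationError("cannot place DMR blocks on the genome layout")
            block_of_slot[s : s + size] = b

    intra_gap = max(1, config.dmr_block_span_bp // max(size - 1, 1))
    pos = np.empty(n, dtype=int)
    prev_chrom = -1
    cur = 0
    for i in range(n):
        if chrom_idx[i] != prev_chrom:
            cur = 10_000
            prev_chrom = chrom_idx[i]
        else:
            same_block = block_of_slot[i] >= 0 and block_of_slot[i] == block_of_slot[i - 1]
            cur += intra_gap if same_block else _BASE_SPACING_BP
        pos[i] = cur
    chroms = np.array(_CHROMS, dtype=object)[chrom_idx]
    return chroms, pos, block_of_slot


def _nearest_genes(chroms, pos, extra_genes):
    """Nearest gene per probe from a 200-kb TSS grid plus named extra genes.

    ``extra_genes`` maps gene name -> (chrom, tss).  Returns (gene, tss_distance)
    arrays; tss_distance = pos - tss (signed).
    """
    gene_names: list[str] = []
    gene_chrom: list[str] = []
    gene_tss: list[int] = []
    for chrom in _CHROMS:
        mask = chroms == chrom
        if not mask.any():
            continue
        hi = int(pos[mask].max())
        k = 0
        for tss in range(10_000, hi + _GENE_GRID_BP, _GENE_GRID_BP):
            gene_names.append(f"G_{chrom[3:]}_{k:04d}")
            gene_chrom.append(chrom)
            gene_tss.append(tss)
            k += 1
    for name, (chrom, tss) in extra_genes.items():
        gene_names.append(name)
        gene_chrom.append(chrom)
        gene_tss.append(int(tss))

    genes = pd.DataFrame({"gene": gene_names, "chrom": gene_chrom, "tss": gene_tss})
    nearest = np.empty(len(pos), dtype=object)
    dist = np.zeros(len(pos), dtype=float)
    for chrom, sub in genes.groupby("chrom", sort=False):
        sub = sub.sort_values("tss", kind="mergesort")
        tss_arr = sub["tss"].to_numpy()
        name_arr = sub["gene"].to_numpy()
        mask = chroms == chrom
        p = pos[mask]
        right = np.searchsorted(tss_arr, p)
        left = np.clip(right - 1, 0, len(tss_arr) - 1)
        right = np.clip(right, 0, len(tss_arr) - 1)
        pick = np.where(np.abs(p - tss_arr[left]) <= np.abs(p - tss_arr[right]), left, right)
        nearest[mask] = name_arr[pick]
        dist[mask] = p - tss_arr[pick]
    too_far = np.abs(dist) > 1_000_000
    nearest[too_far] = None
    dist[too_far] = np.nan
    return nearest, dist


# ---------------------------------------------------------------------------
# simulate_cohorts
# ---------------------------------------------------------------------------

def _assign_classes(config: SimulationConfig):
    """Deterministic per-probe class labels, signs and block membership.

    Probe indices 0..n_planted-1 carry the planted classes in a fixed
    order; hypo/hyper splits hit round(hypo_fraction * n_class) exactly,
    with DMR blocks constrained to carry a single sign per block.
    """
    counts = config.class_counts()
    n = config.n_probes
    true_class = np.array(["null"] * n, dtype=object)
    sign = np.zeros(n, dtype=int)
    block_id = np.full(n, -1, dtype=int)

    start = 0
    offsets = {}
    for cls in PLANTED_CLASSES:
        k = counts[cls]
        true_class[start : start + k] = cls
        offsets[cls] = (start, start + k)
        start += k

    size = config.dmr_block_size
    n_block_probes = config.n_dmr_blocks * size
    sh0, sh1 = offsets["shared"]
    for b in range(config.n_dmr_blocks):
        block_id[sh0 + b * size : sh0 + (b + 1) * size] = b

    for cls in PLANTED_CLASSES:
        lo, hi = offsets[cls]
        k = hi - lo
        if k == 0:
            continue
        n_hypo = round(config.hypo_fraction_by_class.get(cls, 0.5) * k)
        cls_sign = np.ones(k, dtype=int)
        if cls == "shared" and n_block_probes > 0:
            hypo_blocks = min(config.n_dmr_blocks, n_hypo // size)
            cls_sign[: hypo_blocks * size] = -1
            remaining = n_hypo - hypo_blocks * size
            # the remainder lands on non-block shared probes
            cls_sign[n_block_probes : n_block_probes + remaining] = -1
        else:
            cls_sign[:n_hypo] = -1
        sign[lo:hi] = cls_sign
    return true_class, sign, block_id, offsets


def simulate_cohorts(config: SimulationConfig):
    """Generate (BetaMatrix, sample sheet, probe manifest, truth table).

    One quiescent and one activated sample per donor; planted probes shift
    their mean beta by +/- ``effect_delta_beta`` in the designated
    cohort(s) via a calibrated logit-scale shift; null probes have
    identical expectations across conditions; the adolescent cohort
    carries a technical logit-scale batch offset on every probe.
    """
    config.validate()
    e = config.effect_delta_beta
    n = config.n_probes
    rng_p = _rng(config, "probes")
    rng_d = _rng(config, "donors")

    true_class, sign, block_of_probe, offsets = _assign_classes(config)

    # --- baselines -----------------------------------------------------
    mix = config.baseline_beta_distribution
    comp = rng_p.choice(3, size=n, p=np.asarray(mix.weights) / np.sum(mix.weights))
    means = np.asarray(mix.means)[comp]
    c = mix.concentration
    b0 = rng_p.beta(means * c, (1 - means) * c)
    planted = true_class != "null"
    # planted probes sit at intermediate methylation so +/- effect stays in (0,1)
    m_int = mix.means[1]
    b0[planted] = rng_p.beta(m_int * c, (1 - m_int) * c, size=int(planted.sum()))
    lo = max(0.15, e + 0.02)
    hi = min(0.85, 0.98 - e)
    b0[planted] = np.clip(b0[planted], lo, hi)
    b0 = np.clip(b0, 0.02, 0.98)

    # --- true per-cohort effects on the beta scale ---------------------
    tdb_inf = np.zeros(n)
    tdb_adol = np.zeros(n)
    signed = sign * e
    for cls, (lo_i, hi_i) in offsets.items():
        sl = slice(lo_i, hi_i)
        if cls == "shared":
            tdb_inf[sl] = signed[sl]
            tdb_adol[sl] = signed[sl]
        elif cls == "infant_specific":
            tdb_inf[sl] = signed[sl]
        elif cls == "adolescent_specific":
            tdb_adol[sl] = signed[sl]
        elif cls == "opposing":
            tdb_inf[sl] = signed[sl]
            tdb_adol[sl] = -signed[sl]
    truth_block = block_of_probe.copy()
    if e == 0:
        # nothing is planted: every probe is null and no block carries an
        # effect, but the genome layout (including tight block runs) stays
        true_class = np.array(["null"] * n, dtype=object)
        truth_block[:] = -1

    # --- genome layout and probe placement -----------------------------
    chrom_of_slot, pos_of_slot, block_of_slot = _genome_layout(config)
    slot_of_probe = _place_probes(config, block_of_probe, block_of_slot, rng_p)
    chroms = chrom_of_slot[slot_of_probe]
    pos = pos_of_slot[slot_of_probe]

    # --- cytokine-coupled probes and their gene TSSs --------------------
    corr_probe_idx, corr_meta, extra_genes = _reserve_cytokine_probes(
        config, true_class, block_of_probe, chroms, pos
    )

    nearest, tss_dist = _nearest_genes(chroms, pos, extra_genes)
    cgi = rng_p.choice(
        np.array(CGI_CHOICES, dtype=object), size=n, p=CGI_PROBS
    )
    probe_ids = np.array([f"sp{i:07d}" for i in range(n)], dtype=object)
    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chroms,
            "pos": pos,
            "nearest_gene": nearest,
            "tss_distance": tss_dist,
            "cgi_relation": cgi,
        }
    )
    manifest = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    validate_manifest(manifest)

    # --- sample sheet ---------------------------------------------------
    sheet = _sample_sheet(config, rng_d)
    validate_sample_sheet(sheet)

    # --- beta matrix -----------------------------------------------------
    beta = _beta_matrix(
        config, b0, tdb_inf, tdb_adol, sheet, probe_ids, rng_p, rng_d
    )

    cytokine_pair = np.array([None] * n, dtype=object)
    for idx, (cytokine, cohort) in zip(corr_probe_idx, corr_meta):
        cytokine_pair[idx] = f"{cytokine}:{cohort}"

    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "true_class": true_class,
            "true_delta_beta_infant": tdb_inf,
            "true_delta_beta_adolescent": tdb_adol,
            "dmr_block_id": [
                f"block{b:03d}" if b >= 0 else None for b in truth_block
            ],
            "cytokine_pair": cytokine_pair,
        }
    )
    return beta, sheet, manifest, truth


CGI_CHOICES = ("island", "shore", "shelf", "open_sea")
CGI_PROBS = (0.30, 0.25, 0.10, 0.35)


def _place_probes(config, block_of_probe, block_of_slot, rng):
    """Map probe indices to genome slots.

    Block probes occupy the reserved block runs; all other probes are
    scattered over the remaining slots by a seeded permutation, so truth
    classes are not genomically clustered.
    """
    n = config.n_probes
    slot_of_probe = np.empty(n, dtype=int)
    block_slots = np.flatnonzero(block_of_slot >= 0)
    free_slots = np.flatnonzero(block_of_slot < 0)
    block_probes = np.flatnonzero(block_of_probe >= 0)
    free_probes = np.flatnonzero(block_of_probe < 0)
    if len(block_probes):
        order_p = block_probes[np.argsort(block_of_probe[block_probes], kind="stable")]
        order_s = block_slots[np.argsort(block_of_slot[block_slots], kind="stable")]
        slot_of_probe[order_p] = order_s
    slot_of_probe[free_probes] = free_slots[rng.permutation(len(free_slots))]
    return slot_of_probe


def _reserve_cytokine_probes(config, true_class, block_of_probe, chroms, pos):
    """Pick shared non-block probes to couple to cytokines; site gene TSSs nearby.

    Probes coupled to the same cytokine must fall within the 1-Mb scan
    window of its TSS, so each cytokine claims probes on one chromosome
    near each other and its TSS is placed at their midpoint.  A zero-effect
    simulation plants no couplings (there are no DMPs to correlate).
    """
    corr_probe_idx: list[int] = []
    corr_meta: list[tuple[str, str]] = []
    extra_genes: dict[str, tuple[str, int]] = {}
    if config.effect_delta_beta == 0:
        return corr_probe_idx, corr_meta, extra_genes
    eligible = np.flatnonzero((true_class == "shared") & (block_of_probe < 0))
    by_chrom: dict[str, list[int]] = {}
    for i in eligible:
        by_chrom.setdefault(str(chroms[i]), []).append(int(i))
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda i: int(pos[i]))
    used: set[int] = set()
    for spec in config.cytokine_spec:
        total = spec.n_corr_infant + spec.n_corr_adolescent
        if total == 0:
            continue
        picked: list[int] = []
        for chrom in sorted(by_chrom):
            idxs = [i for i in by_chrom[chrom] if i not in used]
            for w in range(len(idxs) - total + 1):
                window = idxs[w : w + total]
                if pos[window[-1]] - pos[window[0]] <= 900_000:
                    picked = window
                    break
            if picked:
                break
        if not picked:
            raise ConfigurationError(
                f"not enough clustered shared probes to couple to cytokine {spec.name}"
            )
        used.update(picked)
        if total == 1:
            tss = int(pos[picked[0]]) - 1000
        else:
            tss = (int(pos[picked[0]]) + int(pos[picked[-1]])) // 2
        extra_genes[spec.name] = (str(chroms[picked[0]]), max(tss, 1))
        cohorts = ["infant"] * spec.n_corr_infant + ["adolescent"] * spec.n_corr_adolescent
        for idx, cohort in zip(picked, cohorts):
            corr_probe_idx.append(int(idx))
            corr_meta.append((spec.name, cohort))
    return corr_probe_idx, corr_meta, extra_genes


def _sample_sheet(config: SimulationConfig, rng_d) -> pd.DataFrame:
    rows = []
    donors = [(f"I{i + 1:02d}", "infant") for i in range(config.n_donors_infant)] + [
        (f"A{i + 1:02d}", "adolescent") for i in range(config.n_donors_adolescent)
    ]
    cov_values: dict[str, list] = {c.name: [] for c in config.covariate_spec}
    for j, (donor, cohort) in enumerate(donors):
        for cov in config.covariate_spec:
            if cov.kind == "categorical":
                cov_values[cov.name].append(cov.levels[j % len(cov.levels)])
            else:
                cov_values[cov.name].append(float(np.round(rng_d.normal(), 6)))
    for j, (donor, cohort) in enumerate(donors):
        for condition in ("quiescent", "activated"):
            row = {
                "sample_id": f"{donor}_{condition}",
                "donor_id": donor,
                "cohort": cohort,
                "condition": condition,
                "batch": cohort,
            }
            for cov in config.covariate_spec:
                row[cov.name] = cov_values[cov.name][j]
            rows.append(row)
    return pd.DataFrame(rows)


def _logit_shift(b0: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Logit-scale shift whose noiseless beta-scale difference equals delta."""
    target = np.clip(b0 + delta, 1e-6, 1 - 1e-6)
    return logit(target) - logit(b0)


def _beta_matrix(config, b0, tdb_inf, tdb_adol, sheet, probe_ids, rng_p, rng_d):
    n = config.n_probes
    n_samples = len(sheet)
    is_adol = (sheet["cohort"] == "adolescent").to_numpy()
    is_act = (sheet["condition"] == "activated").to_numpy()
    donors = sheet["donor_id"].to_numpy()
    donor_list = list(dict.fromkeys(donors))
    donor_col = np.array([donor_list.index(d) for d in donors])

    mu = np.tile(logit(b0)[:, None], (1, n_samples))
    mu += config.batch_shift_logit * is_adol[None, :]

    for cov in config.covariate_spec:
        if cov.effect_logit == 0:
            continue
        vals = sheet[cov.name]
        if cov.kind == "categorical":
            codes = vals.map({lv: k for k, lv in enumerate(cov.levels)}).to_numpy(float)
        else:
            codes = vals.to_numpy(float)
        mu += cov.effect_logit * codes[None, :]

    if config.donor_sd_logit > 0:
        donor_eff = rng_d.normal(0, config.donor_sd_logit, size=(n, len(donor_list)))
        mu += donor_eff[:, donor_col]

    shift_inf = _logit_shift(b0, tdb_inf)
    shift_adol = _logit_shift(b0, tdb_adol)
    act_shift = np.where(is_adol[None, :], shift_adol[:, None], shift_inf[:, None])
    mu += act_shift * is_act[None, :]

    noise = rng_p.normal(0, config.noise_sd_logit, size=(n, n_samples))
    values = expit(mu + noise)
    np.clip(values, 1e-12, 1 - 1e-12, out=values)
    data = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                        columns=sheet["sample_id"].to_numpy())
    return BetaMatrix(data)


# ---------------------------------------------------------------------------
# simulate_atac_peaks
# ---------------------------------------------------------------------------

def simulate_atac_peaks(truth: pd.DataFrame, manifest: pd.DataFrame,
                        config: SimulationConfig) -> pd.DataFrame:
    """Peaks as 0-based half-open intervals with direction and test fields.

    Each planted responsive probe is covered by a peak with probability
    ``atac_spec.cover_prob``; the peak's accessibility direction is drawn
    with the configured concordance odds relative to the probe's
    methylation direction (odds 1 = independence).  Remaining peak budget
    is spent on background peaks in inter-probe gaps.
    """
    spec = config.atac_spec
    if spec.n_peaks == 0:
        return pd.DataFrame(columns=list(PEAK_COLUMNS))
    missing = set(truth["probe_id"]) - set(manifest["probe_id"])
    if missing:
        raise ValueError(f"manifest does not cover truth probes: {sorted(missing)[:5]}")
    rng = _rng(config, "atac")
    m = manifest.set_index("probe_id")
    responsive = truth[truth["true_class"] != "null"].copy()
    meth_dir = np.where(
        responsive["true_delta_beta_infant"] != 0,
        np.sign(responsive["true_delta_beta_infant"]),
        np.sign(responsive["true_delta_beta_adolescent"]),
    )

    p_conc = spec.concordance_odds / (1.0 + spec.concordance_odds)
    rows = []
    covered = rng.random(len(responsive)) < spec.cover_prob
    for (probe, md, cov) in zip(responsive["probe_id"], meth_dir, covered):
        if not cov:
            continue
        pos = int(m.at[probe, "pos"])
        chrom = m.at[probe, "chrom"]
        left = int(rng.integers(100, 400))
        right = int(rng.integers(100, 400))
        concordant = rng.random() < p_conc
        # hypomethylation is concordant with a gain of accessibility
        direction = ("gain" if md < 0 else "loss") if concordant else ("loss" if md < 0 else "gain")
        rows.append(_peak_row(chrom, pos - 1 - left, pos + right, direction, rng, spec))
        if len(rows) >= spec.n_peaks:
            break

    n_extra = spec.n_peaks - len(rows)
    if n_extra > 0:
        # anchor background peaks only in wide inter-probe gaps so they never
        # cover a probe (in particular not the tightly spaced block probes)
        pos_all = manifest["pos"].to_numpy()
        chrom_all = manifest["chrom"].to_numpy()
        gap_next = np.full(len(manifest), np.inf)
        same_chrom = chrom_all[:-1] == chrom_all[1:]
        gap_next[:-1][same_chrom] = (pos_all[1:] - pos_all[:-1])[same_chrom]
        candidates = np.flatnonzero(gap_next >= 4500)
        take = rng.choice(candidates, size=min(n_extra, len(candidates)), replace=False)
        for i in np.sort(take):
            pos = int(manifest.iloc[i]["pos"])
            chrom = manifest.iloc[i]["chrom"]
            start = pos + 1500 + int(rng.integers(0, 500))
            width = int(rng.integers(200, 800))
            direction = "gain" if rng.random() < 0.5 else "loss"
            differential = rng.random() < 0.1
            rows.append(_peak_row(chrom, start, start + width, direction, rng, spec,
                                  force_differential=differential))

    peaks = pd.DataFrame(rows, columns=list(PEAK_COLUMNS))
    peaks = peaks.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    peaks["name"] = [f"pk{i:06d}" for i in range(len(peaks))]
    return validate_peaks(peaks)


def _peak_row(chrom, start, end, direction, rng, spec, force_differential=None):
    differential = (rng.random() < spec.frac_differential
                    if force_differential is None else force_differential)
    magnitude = 1.6 + rng.exponential(0.8) if differential else 1.0 + rng.random() * 0.45
    fc = magnitude if direction == "gain" else 1.0 / magnitude
    p = rng.uniform(1e-4, 0.04) if differential else rng.uniform(0.06, 1.0)
    return (chrom, max(int(start), 0), int(end), "", float(fc), ".", float(p), direction)


# ---------------------------------------------------------------------------
# simulate_cytokines
# ---------------------------------------------------------------------------

def planted_cytokine_pairs(truth: pd.DataFrame) -> pd.DataFrame:
    """(cytokine, cohort, probe_id) rows for the planted couplings."""
    rows = []
    sub = truth[truth["cytokine_pair"].notna()]
    for probe, tag in zip(sub["probe_id"], sub["cytokine_pair"]):
        cytokine, cohort = tag.split(":")
        rows.append((cytokine, cohort, probe))
    return pd.DataFrame(rows, columns=["cytokine", "cohort", "probe_id"])


def simulate_cytokines(sheet: pd.DataFrame, beta: BetaMatrix, truth: pd.DataFrame,
                       config: SimulationConfig) -> pd.DataFrame:
    """Per-sample cytokine concentrations (pg/mL).

    Quiescent concentrations are lognormal around the configured baseline;
    activated concentrations scale by the cohort's fold change.  For each
    planted (probe, cytokine, cohort) coupling the activated
    concentrations are linearly tied to that probe's activated beta at the
    configured Pearson correlation.
    """
    validate_sample_sheet(sheet)
    unpaired = set(sheet.groupby("donor_id")["condition"].nunique().loc[lambda s: s < 2].index)
    if unpaired:
        raise ValueError(f"simulate_cytokines requires paired donors; unpaired: {sorted(unpaired)[:5]}")
    rng = _rng(config, "cytokines")
    pairs = planted_cytokine_pairs(truth)
    sd = config.cytokine_log_noise_sd

    rows = []
    for spec in config.cytokine_spec:
        if spec.name not in CANONICAL_CYTOKINES:
            logger.warning("cytokine %r is not in the canonical panel; generating anyway", spec.name)
        for cohort in ("infant", "adolescent"):
            sub = sheet[sheet["cohort"] == cohort]
            donors = sorted(sub["donor_id"].unique())
            nd = len(donors)
            fc = spec.fc_infant if cohort == "infant" else spec.fc_adolescent
            conc_q = spec.baseline * np.exp(rng.normal(0, sd, nd))
            conc_a = spec.baseline * fc * np.exp(rng.normal(0, sd, nd))

            probes = pairs.loc[
                (pairs["cytokine"] == spec.name) & (pairs["cohort"] == cohort), "probe_id"
            ].tolist()
            if probes:
                act_samples = [
                    sub[(sub["donor_id"] == d) & (sub["condition"] == "activated")]["sample_id"].iloc[0]
                    for d in donors
                ]
                x = beta.data.loc[probes, act_samples].to_numpy(float)
                z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True, ddof=1)
                z = z.mean(axis=0) * math.sqrt(len(probes))  # unit-variance aggregate
                y = spec.corr_r * z / np.std(z, ddof=1) + math.sqrt(1 - spec.corr_r**2) * rng.normal(0, 1, nd)
                mu_a = spec.baseline * fc
                conc_a = np.maximum(mu_a * (1.0 + 0.35 * y), 0.05 * mu_a)

            for d, cq, ca in zip(donors, conc_q, conc_a):
                sid_q = sub[(sub["donor_id"] == d) & (sub["condition"] == "quiescent")]["sample_id"].iloc[0]
                sid_a = sub[(sub["donor_id"] == d) & (sub["condition"] == "activated")]["sample_id"].iloc[0]
                rows.append((sid_q, spec.name, "quiescent", float(cq)))
                rows.append((sid_a, spec.name, "activated", float(ca)))
    cyto = pd.DataFrame(rows, columns=["sample_id", "cytokine", "condition", "concentration"])
    return validate_cytokine_table(cyto)


# ---------------------------------------------------------------------------
# Expression calls, pathway, gene sets (tri-omic layers)
# ---------------------------------------------------------------------------

def _responsive_genes(truth: pd.DataFrame, manifest: pd.DataFrame) -> list[str]:
    m = manifest.set_index("probe_id")
    probes = truth.loc[truth["true_class"] != "null", "probe_id"]
    genes = m.loc[probes, "nearest_gene"].dropna().unique()
    return sorted(genes)


def simulate_expression_calls(truth: pd.DataFrame, manifest: pd.DataFrame,
                              config: SimulationConfig) -> set[str]:
    """Synthetic differentially-expressed gene calls.

    Genes near planted responsive probes are called DE with probability
    0.8; background genes with probability 0.15 (expression tracks the
    methylome imperfectly, as in real activation data).
    """
    rng = _rng(config, "expression")
    resp = set(_responsive_genes(truth, manifest))
    universe = sorted(manifest["nearest_gene"].dropna().unique())
    calls = set()
    for gene in universe:
        p = 0.8 if gene in resp else 0.15
        if rng.random() < p:
            calls.add(gene)
    return calls


def simulate_pathway(truth: pd.DataFrame, manifest: pd.DataFrame,
                     config: SimulationConfig, size: int = 74) -> set[str]:
    """A pathway gene set enriched for activation-responsive genes."""
    rng = _rng(config, "pathway")
    resp = _responsive_genes(truth, manifest)
    universe = sorted(manifest["nearest_gene"].dropna().unique())
    other = [g for g in universe if g not in set(resp)]
    n_resp = min(len(resp), int(round(size * 0.6)))
    picked = list(rng.choice(resp, size=n_resp, replace=False)) if n_resp else []
    n_other = min(size - n_resp, len(other))
    picked += list(rng.choice(other, size=n_other, replace=False))
    return set(str(g) for g in picked)


def simulate_gene_sets(truth: pd.DataFrame, manifest: pd.DataFrame,
                       config: SimulationConfig, n_sets: int = 5,
                       set_size: int = 50) -> dict[str, set[str]]:
    """Gene-set collection with one set enriched in responsive genes."""
    rng = _rng(config, "genesets")
    universe = sorted(manifest["nearest_gene"].dropna().unique())
    resp = _responsive_genes(truth, manifest)
    sets: dict[str, set[str]] = {}
    n_resp = min(len(resp), int(round(set_size * 0.6)))
    enriched = list(rng.choice(resp, size=n_resp, replace=False)) if n_resp else []
    pool = [g for g in universe if g not in set(enriched)]
    enriched += list(rng.choice(pool, size=set_size - n_resp, replace=False))
    sets["activation_response"] = set(str(g) for g in enriched)
    for k in range(1, n_sets):
        sets[f"random_set_{k}"] = set(
            str(g) for g in rng.choice(universe, size=min(set_size, len(universe)), replace=False)
        )
    return sets
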