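import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from agespec import integrate as ig
from agespec.io_formats import PEAK_COLUMNS, BetaMatrix
from conftest import paired_sheet


def _peaks(rows):
    """rows: (chrom, start, end) or full tuples."""
    full = []
    for i, r in enumerate(rows):
        if len(r) == 3:
            full.append((*r, f"pk{i}", 2.0, ".", 0.01, "gain"))
        else:
            full.append(r)
    return pd.DataFrame(full, columns=list(PEAK_COLUMNS))


def _manifest(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "nearest_gene": None,
            "tss_distance": np.nan,
            "cgi_relation": "open_sea",
        }
    )


class TestOverlap:
    def test_half_open_boundary_semantics(self):
        peaks = _peaks([("chr1", 100, 200)])
        man = _manifest([200, 201])
        out = ig.overlap_probes_peaks(man, ["p0", "p1"], peaks)
        # 1-based 200 is covered by [100,200); 201 is not
        assert list(out["probe_id"]) == ["p0"]

    def test_multi_overlap_resolved_to_nearest_midpoint(self):
        peaks = _peaks([("chr1", 0, 1000), ("chr1", 140, 160)])
        man = _manifest([150])
        out = ig.overlap_probes_peaks(man, ["p0"], peaks)
        assert out["peak_name"].iloc[0] == "pk1"

    def test_chrom_naming_mismatch_is_explicit_error(self):
        peaks = _peaks([("1", 100, 200)])
        man = _manifest([150])
        with pytest.raises(ValueError, match="chr1.*'1'|naming mismatch"):
            ig.overlap_probes_peaks(man, ["p0"], peaks)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_brute_force(self, seed):
        """Tree-based assignment equals the all-pairs oracle on random
        instances (1,000 probes x 100 peaks over 3 chromosomes)."""
        rng = np.random.default_rng(seed)
        chroms = [f"chr{c}" for c in rng.integers(1, 4, size=1000)]
        pos = rng.integers(1, 100_000, size=1000)
        man = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(1000)], "chrom": chroms, "pos": pos,
             "nearest_gene": None, "tss_distance": np.nan, "cgi_relation": "open_sea"}
        )
        starts = rng.integers(0, 100_000, size=100)
        widths = rng.integers(1, 3000, size=100)
        peaks = _peaks([
            (f"chr{int(c)}", int(s), int(s + w))
            for c, s, w in zip(rng.integers(1, 4, size=100), starts, widths)
        ])
        out = ig.overlap_probes_peaks(man, man["probe_id"], peaks)
        got = dict(zip(out["probe_id"], out["peak_index"]))

        expected = {}
        for _, pr in man.iterrows():
            best, best_key = None, None
            for j, pk in peaks.iterrows():
                if pk["chrom"] != pr["chrom"]:
                    continue
                if pk["start"] <= pr["pos"] - 1 < pk["end"]:
                    key = (abs((pk["start"] + pk["end"]) / 2 - (pr["pos"] - 1)), pk["start"])
                    if best_key is None or key < best_key:
                        best, best_key = j, key
            if best is not None:
                expected[pr["probe_id"]] = best
        assert got == expected


class TestChi2:
    def test_closed_form_value(self):
        chi2, p = ig.chi2_2x2([[30, 10], [10, 30]])
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(float(sps.chi2.sf(20.0, 1)))

    def test_identical_row_proportions_give_zero(self):
        chi2, _ = ig.chi2_2x2([[20, 20], [10, 10]])
        assert chi2 == pytest.approx(0.0)

    def test_zero_marginal_is_error(self):
        with pytest.raises(ValueError, match="marginal"):
            ig.chi2_2x2([[0, 0], [10, 30]])

    def test_matches_scipy_without_correction(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(1, 50, size=(2, 2))
            chi2, p = ig.chi2_2x2(t)
            ref = sps.chi2_contingency(t, correction=False)
            assert chi2 == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_yates_correction_flag(self):
        t = [[30, 10], [10, 30]]
        chi2_y, _ = ig.chi2_2x2(t, yates=True)
        ref = sps.chi2_contingency(np.array(t), correction=True)
        assert chi2_y == pytest.approx(ref.statistic)


class TestCytokineFC:
    def _cyto(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "cytokine", "condition", "concentration"])

    def test_log2_arithmetic_and_floor(self):
        sheet = paired_sheet(n_infant=2, n_adolescent=0)
        cyto = self._cyto([
            ("I01_quiescent", "IL2", "quiescent", 100.0),
            ("I01_activated", "IL2", "activated", 400.0),
            ("I02_quiescent", "IL2", "quiescent", 0.0),
            ("I02_activated", "IL2", "activated", 8.0),
        ])
        fc = ig.cytokine_log2fc(cyto, sheet, floor=1.0)
        by_donor = fc.set_index("donor_id")["log2fc"]
        assert by_donor["I01"] == pytest.approx(2.0)
        assert by_donor["I02"] == pytest.approx(3.0)

    def test_no_change_gives_zero(self):
        sheet = paired_sheet(n_infant=1, n_adolescent=0)
        cyto = self._cyto([
            ("I01_quiescent", "IL2", "quiescent", 50.0),
            ("I01_activated", "IL2", "activated", 50.0),
        ])
        assert ig.cytokine_log2fc(cyto, sheet)["log2fc"].iloc[0] == pytest.approx(0.0)

    def test_scale_invariance(self):
        sheet = paired_sheet()
        rng = np.random.default_rng(0)
        rows = []
        for _, s in sheet.iterrows():
            rows.append((s["sample_id"], "IL6", s["condition"], float(rng.uniform(10, 100))))
        cyto = self._cyto(rows)
        scaled = cyto.assign(concentration=cyto["concentration"] * 10)
        fc1 = ig.cytokine_log2fc(cyto, sheet)
        fc2 = ig.cytokine_log2fc(scaled, sheet)
        np.testing.assert_allclose(fc1["log2fc"], fc2["log2fc"], atol=1e-12)

    def test_negative_concentration_rejected(self):
        sheet = paired_sheet(n_infant=1, n_adolescent=0)
        cyto = self._cyto([("I01_quiescent", "IL2", "quiescent", -1.0),
                           ("I01_activated", "IL2", "activated", 5.0)])
        with pytest.raises(ValueError, match="negative"):
            ig.cytokine_log2fc(cyto, sheet)


class TestCompareCohortFC:
    def _fc(self, infant, adolescent, cytokine="IL2"):
        rows = [(f"I{i}", "infant", cytokine, v) for i, v in enumerate(infant)]
        rows += [(f"A{i}", "adolescent", cytokine, v) for i, v in enumerate(adolescent)]
        return pd.DataFrame(rows, columns=["donor_id", "cohort", "cytokine", "log2fc"])

    def test_exact_two_sided_p(self):
        out = ig.compare_cohort_fc(self._fc([1, 2, 3], [4, 5, 6]))
        assert out["p"].iloc[0] == pytest.approx(0.1)
        assert out["direction"].iloc[0] == "adolescent"

    def test_identical_samples_p_one(self):
        out = ig.compare_cohort_fc(self._fc([1, 2, 3], [1, 2, 3]))
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_small_cohort_gives_nan_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="agespec"):
            out = ig.compare_cohort_fc(self._fc([1, 2, 3], [4, 5]))
        assert math.isnan(out["p"].iloc[0])

    def test_planted_age_difference_detected_for_right_cytokines(self):
        """Adolescent > infant for IL2/IL10/IFNG only, across seeds."""
        from agespec.synthetic import simulate_cohorts, simulate_cytokines
        from conftest import small_config

        sig = {c: 0 for c in ("IL2", "IL6", "IL10", "IFNG", "TNF")}
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = small_config(n_probes=2000, n_dmr_blocks=4, seed=seed)
            beta, sheet, manifest, truth = simulate_cohorts(cfg)
            cyto = simulate_cytokines(sheet, beta, truth, cfg)
            tests = ig.compare_cohort_fc(ig.cytokine_log2fc(cyto, sheet))
            for _, row in tests.iterrows():
                if row["p"] < 0.05 and row["direction"] == "adolescent":
                    sig[row["cytokine"]] += 1
        for c in ("IL2", "IL10", "IFNG"):
            assert sig[c] >= int(0.9 * n_seeds), c
        for c in ("IL6", "TNF"):
            assert sig[c] <= int(0.25 * n_seeds), c


class TestCorrelationScan:
    def test_pearson_hand_values(self):
        r, _ = sps.pearsonr([1, 2, 3], [2, 1, 3])
        assert r == pytest.approx(0.5)

    def _setup(self, tss_offset):
        sheet = paired_sheet(n_infant=6, n_adolescent=0)
        act = sheet[sheet["condition"] == "activated"]
        rng = np.random.default_rng(0)
        x = np.linspace(0.2, 0.7, len(act))
        data = pd.DataFrame([x], index=["p0"], columns=act["sample_id"].tolist())
        beta = BetaMatrix(data)
        man = _manifest([1_000_000])
        dmps = pd.DataFrame({"probe_id": ["p0"], "is_dmp": [True]})
        cyto = pd.DataFrame(
            [(s, "IL2", "activated", 10 + 5 * v) for s, v in zip(act["sample_id"], x)],
            columns=["sample_id", "cytokine", "condition", "concentration"],
        )
        gene_tss = {"IL2": ("chr1", 1_000_000 + tss_offset)}
        return dmps, man, beta, cyto, sheet, gene_tss

    def test_perfectly_linear_pair_r_one(self):
        dmps, man, beta, cyto, sheet, gene_tss = self._setup(1000)
        out = ig.correlate_probe_cytokine(dmps, man, beta, cyto, sheet, gene_tss, "infant")
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_probe_outside_window_excluded(self):
        dmps, man, beta, cyto, sheet, gene_tss = self._setup(1_200_000)
        out = ig.correlate_probe_cytokine(dmps, man, beta, cyto, sheet, gene_tss, "infant",
                                          keep_all=True)
        assert len(out) == 0

    def test_too_few_samples_reported_unavailable(self):
        dmps, man, beta, cyto, sheet, gene_tss = self._setup(1000)
        cyto = cyto.iloc[:3]
        out = ig.correlate_probe_cytokine(dmps, man, beta, cyto, sheet, gene_tss, "infant",
                                          keep_all=True)
        assert math.isnan(out["r"].iloc[0])


class TestPathwayCategories:
    def test_set_logic(self):
        table, counts = ig.categorize_pathway_genes(
            {"A", "B", "C"}, {"A"}, {"A", "B"}, {"A"})
        by_gene = table.set_index("gene")["category"]
        assert by_gene["A"] == "dnam+expr+atac"
        assert by_gene["B"] == "expr only"
        assert by_gene["C"] == "none"
        assert counts["dnam+expr+atac"] == 1 and counts["none"] == 1
        assert len(counts) == 8

    def test_empty_evidence_all_none(self):
        _, counts = ig.categorize_pathway_genes({"A", "B"}, set(), set(), set())
        assert counts["none"] == 2

    def test_full_evidence_all_triple(self):
        genes = {"A", "B"}
        _, counts = ig.categorize_pathway_genes(genes, genes, genes, genes)
        assert counts["dnam+expr+atac"] == 2


class TestEnrichment:
    def test_hypergeometric_by_hand(self):
        universe = [f"g{i}" for i in range(10)]
        sets_ = {"s": set(universe[:4])}
        out = ig.enrichment_test(universe[:5], universe, sets_)
        # P(overlap >= 4) = C(4,4) C(6,1) / C(10,5) = 6/252
        assert out["p"].iloc[0] == pytest.approx(6 / 252)

    def test_study_equals_universe_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        out = ig.enrichment_test(universe, universe, {"s": set(universe[:3])})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_stray_study_gene_rejected(self):
        with pytest.raises(ValueError, match="missing from universe"):
            ig.enrichment_test(["zz"], ["g1"], {"s": {"g1"}})

    def test_equal_weights_wallenius_equals_hypergeometric(self):
        universe = [f"g{i}" for i in range(30)]
        sets_ = {"s": set(universe[:10])}
        study = universe[5:15]
        plain = ig.enrichment_test(study, universe, sets_)
        weighted = ig.enrichment_test(study, universe, sets_,
                                      probes_per_gene={g: 3.0 for g in universe})
        assert weighted["p"].iloc[0] == pytest.approx(plain["p"].iloc[0], abs=1e-6)

    def test_probe_bias_shifts_p_upward(self):
        """If the set's genes carry more probes, the same overlap is less
        surprising under the bias-aware null."""
        universe = [f"g{i}" for i in range(40)]
        sets_ = {"s": set(universe[:10])}
        study = universe[:10]
        weights = {g: (5.0 if g in sets_["s"] else 1.0) for g in universe}
        plain = ig.enrichment_test(study, universe, sets_)
        biased = ig.enrichment_test(study, universe, sets_, probes_per_gene=weights)
        assert biased["p"].iloc[0] > plain["p"].iloc[0]
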