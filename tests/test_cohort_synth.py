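import json

import numpy as np
import pandas as pd
import pytest

import concordmap as cm
from concordmap import omics_io, pipeline
from concordmap.cohort_synth import PATTERNS, spearman_to_pearson
from oracles import brute_spearman


def _cfg(**kw):
    base = dict(n_genes=400, n_events=20, n_pattern_genes=5,
                n_per_group={"normal": 6, "inflammation": 6, "tumor": 12})
    base.update(kw)
    return cm.SynthConfig(**base)


class TestConfigValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            _cfg(psi_effect=1.5)
        with pytest.raises(ValueError):
            _cfg(censor_rate=1.0)
        with pytest.raises(ValueError):
            _cfg(target_rho={"normal": 2.0, "inflammation": 0.2, "tumor": 0.3})
        with pytest.raises(ValueError):
            _cfg(n_genes=10)

    def test_infeasible_perfect_coupling_with_noise(self):
        with pytest.raises(ValueError, match="attainable"):
            _cfg(target_rho={"normal": 1.0, "inflammation": 0.2, "tumor": 0.3},
                 rho_noise_sd=0.05)

    def test_copula_inversion(self):
        assert spearman_to_pearson(1.0) == pytest.approx(1.0)
        assert spearman_to_pearson(0.0) == 0.0
        # round-trip through the forward Spearman formula
        r = spearman_to_pearson(0.36)
        assert 6 / np.pi * np.arcsin(r / 2) == pytest.approx(0.36, abs=1e-12)


class TestSimulate:
    def test_deterministic(self):
        a = cm.simulate_cohort(_cfg(seed=5))
        b = cm.simulate_cohort(_cfg(seed=5))
        pd.testing.assert_frame_equal(a[0].protein.values, b[0].protein.values)
        pd.testing.assert_frame_equal(a[1].inc, b[1].inc)
        assert a[2].to_json() == b[2].to_json()

    def test_seed_changes_output(self):
        a = cm.simulate_cohort(_cfg(seed=5))
        b = cm.simulate_cohort(_cfg(seed=6))
        assert not a[0].protein.values.equals(b[0].protein.values)

    def test_perfect_coupling_gives_rho_one(self):
        cfg = _cfg(target_rho={"normal": 1.0, "inflammation": 1.0, "tumor": 1.0},
                   rho_noise_sd=0.0, pattern_effect=0.0, marker_effect=0.0,
                   mki67_coupling=0.0, missing_rate=0.0,
                   # keep log2(FPKM+1) away from its floor: ties at exactly 0
                   # would make "perfect" rank coupling undefined
                   mrna_baseline_mean=8.0, mrna_baseline_sd=1.0)
        cohort, _, _ = cm.simulate_cohort(cfg)
        for s in list(cohort.samples)[:6]:
            rho = brute_spearman(list(cohort.protein.values[s]),
                                 list(cohort.mrna.values[s]))
            assert rho == pytest.approx(1.0, abs=1e-12)

    def test_realized_rho_converges_to_target(self):
        # many genes, no per-sample noise: realized rho within 0.03 of target
        cfg = cm.SynthConfig(seed=2, n_genes=5000, n_events=10, n_pattern_genes=5,
                             rho_noise_sd=0.0, pattern_effect=0.0,
                             missing_rate=0.0, mki67_coupling=0.0,
                             n_per_group={"normal": 4, "inflammation": 4, "tumor": 8})
        cohort, _, truth = cm.simulate_cohort(cfg)
        arm = cohort.meta.arm
        for s in cohort.samples:
            rho = pd.Series(cohort.protein.values[s]).corr(
                pd.Series(cohort.mrna.values[s]), method="spearman")
            assert rho == pytest.approx(cfg.target_rho[arm[s]], abs=0.03)

    def test_median_rho_difference_recovered_independently(self):
        # direct Spearman on the emitted matrices, independent rank routine
        cfg = cm.SynthConfig(seed=1, n_genes=3000, n_events=10,
                             target_rho={"normal": 0.21, "inflammation": 0.21,
                                         "tumor": 0.36},
                             n_per_group={"normal": 10, "inflammation": 10,
                                          "tumor": 20})
        cohort, _, _ = cm.simulate_cohort(cfg)
        arm = cohort.meta.arm
        rhos = {}
        for s in cohort.samples:
            x = cohort.protein.values[s]
            y = cohort.mrna.values[s]
            keep = x.notna() & y.notna()
            rhos[s] = pd.Series(x[keep]).corr(pd.Series(y[keep]), method="spearman")
        rhos = pd.Series(rhos)
        diff = rhos[arm == "tumor"].median() - rhos[arm != "tumor"].median()
        assert 0.15 - 0.07 <= diff <= 0.15 + 0.07

    def test_missingness_rate_and_layer(self):
        cohort, _, _ = cm.simulate_cohort(_cfg(seed=3, missing_rate=0.2))
        assert cohort.protein.values.isna().mean().mean() == pytest.approx(0.2, abs=0.02)
        assert not cohort.mrna.values.isna().any().any()

    def test_censor_fraction_matches_rate(self):
        cfg = cm.SynthConfig(seed=4, n_genes=300, n_events=10, n_pattern_genes=3,
                             hazard_rho=0.0, event_hazard_beta=0.0,
                             censor_rate=0.3,
                             n_per_group={"normal": 2, "inflammation": 2,
                                          "tumor": 250})
        cohort, _, _ = cm.simulate_cohort(cfg)
        ep = cohort.meta.endpoint("OS")
        assert 1.0 - ep["event"].mean() == pytest.approx(0.3, abs=0.05)

    def test_ground_truth_items_exist_in_outputs(self):
        cohort, table, truth = cm.simulate_cohort(_cfg(seed=8))
        genes = set(cohort.genes)
        assert set(truth.pattern_genes) <= genes
        assert truth.marker_gene in genes
        assert set(truth.sf_genes) <= genes
        assert set(truth.aberrant_events) <= set(table.inc.index)
        assert set(truth.pattern_genes.values()) <= set(PATTERNS)
        assert set(truth.hazard_events) <= set(truth.aberrant_events)

    def test_marker_shift_planted(self):
        cohort, _, truth = cm.simulate_cohort(_cfg(seed=9, missing_rate=0.0))
        arm = cohort.meta.arm
        row = cohort.protein.values.loc[truth.marker_gene]
        delta = row[arm == "tumor"].mean() - row[arm != "tumor"].mean()
        assert delta == pytest.approx(1.5, abs=0.35)

    def test_null_generator_calls_almost_no_events(self):
        # with all effects off, the AASE caller at nominal thresholds is quiet
        from concordmap import splicing_landscape
        n_called = n_total = 0
        for seed in range(25):
            cfg = cm.SynthConfig(seed=seed, n_genes=120, n_pattern_genes=1,
                                 n_events=8, aberrant_frac=0.0,
                                 pattern_effect=0.0, sf_coupling=0.0,
                                 n_per_group={"normal": 5, "inflammation": 5,
                                              "tumor": 10})
            _, table, _ = cm.simulate_cohort(cfg)
            calls = splicing_landscape.call_aase(table)
            n_called += int(calls["passes"].sum())
            n_total += len(calls)
        assert n_called / n_total <= 0.01


class TestWriteCohort:
    def test_round_trip_matrices(self, tmp_path):
        cohort, table, truth = cm.simulate_cohort(_cfg(seed=11))
        cm.write_cohort(cohort, table, truth, tmp_path)
        back, back_table, back_truth = pipeline.load_cohort_dir(tmp_path,
                                                                prepare=False)
        # pairing sorts genes/samples; compare on the shared ordering
        pd.testing.assert_frame_equal(
            back.protein.values,
            cohort.protein.values.loc[back.genes, back.samples],
            atol=1e-9, rtol=0)
        pd.testing.assert_frame_equal(
            back.mrna.values,
            cohort.mrna.values.loc[back.genes, back.samples],
            atol=1e-9, rtol=0)
        assert back_truth.marker_gene == truth.marker_gene

    def test_rmats_dialect_round_trip(self, tmp_path):
        cohort, table, truth = cm.simulate_cohort(_cfg(seed=12))
        files = cm.write_cohort(cohort, table, truth, tmp_path)
        ev, inc = omics_io.read_rmats_table(files["SE"], "SE")
        # IncLevelDifference column equals the recomputed tumor-control delta
        tumor_cols = [c for c in inc.columns if c.startswith("g1_")]
        control_cols = [c for c in inc.columns if c.startswith("g2_")]
        recomputed = inc[tumor_cols].mean(axis=1) - inc[control_cols].mean(axis=1)
        assert np.allclose(ev["inc_level_difference"], recomputed, atol=1e-6)

    def test_inclevel_order_matches_samples(self, tmp_path):
        cohort, table, truth = cm.simulate_cohort(_cfg(seed=13))
        files = cm.write_cohort(cohort, table, truth, tmp_path)
        tumor = [s for s in table.samples if table.groups[s] == "tumor"]
        with open(files["RI"]) as fh:
            header = fh.readline().split("\t")
            first = fh.readline().split("\t")
        vals = [float(v) for v in first[header.index("IncLevel1")].split(",")]
        key = f"RI:{first[0]}"
        assert vals == pytest.approx(list(table.inc.loc[key, tumor]), abs=1e-6)

    def test_empty_event_table_gives_header_only_file(self, tmp_path):
        cohort, table, truth = cm.simulate_cohort(_cfg(seed=14))
        empty = table.inc.iloc[0:0]
        tbl = cm.SpliceEventTable(events=table.events.iloc[0:0],
                                  inc=empty, groups=table.groups)
        files = cm.write_cohort(cohort, tbl, truth, tmp_path)
        lines = files["SE"].read_text().strip().split("\n")
        assert len(lines) == 1 and lines[0].startswith("ID\t")

    def test_ground_truth_json_round_trip(self, tmp_path):
        _, _, truth = cm.simulate_cohort(_cfg(seed=15))
        text = truth.to_json()
        assert cm.GroundTruth.from_json(text).to_json() == text
        json.loads(text)  # valid JSON
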