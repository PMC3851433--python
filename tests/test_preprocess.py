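"""Preprocessing: threshold/log2, LOWESS dye-bias removal, centering, filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from troutarray.design import GroupDesign
from troutarray.preprocess import (ExpressionMatrix, ScanFormatError,
                                   assemble_matrix, baseline_center,
                                   filter_entities, lowess_normalize,
                                   preprocess_scans, read_scan, threshold_and_log)
from troutarray.simulate import ArrayScan, SimulationConfig, simulate_scans, \
    simulate_truth


def make_scan(ch1, ch2, flags=None, sample_id="s1", group="Wa") -> ArrayScan:
    n = len(ch1)
    return ArrayScan(sample_id, group, pd.DataFrame({
        "probe_id": [f"P{i:04d}" for i in range(n)],
        "gene_name": [f"g{i:04d}" for i in range(n)],
        "ch1": ch1, "ch2": ch2,
        "flag": flags if flags is not None else ["G"] * n,
    }))


class TestThresholdAndLog:
    @pytest.mark.parametrize(
        "ch1,ch2,m,a",
        [
            (0.5, 0.5, 0.0, 0.0),   # both floored to 1.0
            (2.0, 8.0, 2.0, 2.0),   # log2 arithmetic by hand
            (1.0, 1.0, 0.0, 0.0),
        ],
    )
    def test_examples(self, ch1, ch2, m, a):
        rec = threshold_and_log(make_scan([ch1], [ch2])).table
        assert rec["M"].iloc[0] == pytest.approx(m)
        assert rec["A"].iloc[0] == pytest.approx(a)


class TestLowess:
    def test_constant_bias_removed(self, rng):
        a = rng.uniform(4, 14, size=2000)
        m = np.full(2000, 0.5)
        scan = make_scan(np.exp2(a - m / 2), np.exp2(a + m / 2))
        rec = lowess_normalize(threshold_and_log(scan))
        assert abs(np.median(rec.table["M"])) < 0.01

    def test_near_noop_on_unbiased_data(self, rng):
        a = rng.uniform(4, 14, size=5000)
        m = rng.normal(0, 0.2, size=5000)
        scan = make_scan(np.exp2(a - m / 2), np.exp2(a + m / 2))
        before = threshold_and_log(scan)
        after = lowess_normalize(before)
        shift = np.abs(after.table["M"] - before.table["M"])
        assert shift.max() < 0.1  # well under the 0.2 noise sd

    def test_monotone_bias_attenuated(self, rng):
        a = rng.uniform(4, 14, size=5000)
        bias = 0.5 / (1 + np.exp((a - 8) / 1.5))
        m = bias + rng.normal(0, 0.1, size=5000)
        scan = make_scan(np.exp2(a - m / 2), np.exp2(a + m / 2))
        before = threshold_and_log(scan)
        after = lowess_normalize(before)
        r0 = np.corrcoef(before.table["M"], before.table["A"])[0, 1]
        r1 = np.corrcoef(after.table["M"], after.table["A"])[0, 1]
        assert abs(r1) < abs(r0) / 5

    def test_flagged_spots_corrected_but_ignored_in_fit(self, rng):
        a = rng.uniform(4, 14, size=1000)
        m = rng.normal(0, 0.05, size=1000)
        flags = ["B" if i < 100 else "G" for i in range(1000)]
        m[:100] += 10.0  # wild flagged spots must not bend the fit
        scan = make_scan(np.exp2(a - m / 2), np.exp2(a + m / 2), flags=flags)
        rec = lowess_normalize(threshold_and_log(scan))
        good = rec.table[rec.table["flag"] == "G"]
        assert np.abs(good["M"]).median() < 0.05
        bad = rec.table[rec.table["flag"] == "B"]
        assert np.all(bad["M"] > 5)  # still corrected, not dropped

    def test_too_few_good_spots(self):
        scan = make_scan([100.0] * 5, [100.0] * 5)
        with pytest.raises(ValueError, match="insufficient spots"):
            lowess_normalize(threshold_and_log(scan))


class TestAssembleAndCenter:
    def _records(self, n_probes=3, n_per_group=2):
        design = GroupDesign.balanced(n_per_group)
        recs = []
        for i, s in enumerate(design.samples):
            scan = make_scan([2.0] * n_probes, [2.0 ** (i + 2)] * n_probes,
                             sample_id=s, group=design.group_of[s])
            recs.append(threshold_and_log(scan))
        return recs, design

    def test_shapes_and_values_preserved(self):
        recs, design = self._records()
        m = assemble_matrix(recs, design)
        assert m.data.shape == (3, 8)
        np.testing.assert_allclose(m.data.iloc[0].to_numpy(),
                                   [i + 1 for i in range(8)])

    def test_extra_probe_rejected(self):
        recs, design = self._records()
        extra = recs[1].table.iloc[[0]].assign(probe_id="P9999")
        recs[1].table = pd.concat([recs[1].table, extra], ignore_index=True)
        with pytest.raises(ValueError, match="mismatch"):
            assemble_matrix(recs, design)

    @pytest.mark.parametrize(
        "row,expected",
        [
            ([1, 2, 3, 0, 0, 0, 0, 0], None),            # computed below
            ([1, 2, 3, 4, 1, 2, 3, 4], None),
        ],
    )
    def test_baseline_center_row_medians_zero(self, row, expected):
        recs, design = self._records(n_probes=1)
        m = assemble_matrix(recs, design)
        m.data.iloc[0] = row
        centered = baseline_center(m)
        assert centered.data.iloc[0].median() == pytest.approx(0.0, abs=1e-12)

    def test_even_count_median_convention(self):
        # median of [1,2,3,4] is 2.5 (mean of middle pair)
        recs, design = self._records(n_probes=1, n_per_group=1)
        m = assemble_matrix(recs, design)
        m.data.iloc[0] = [1.0, 2.0, 3.0, 4.0]
        centered = baseline_center(m)
        np.testing.assert_allclose(centered.data.iloc[0], [-1.5, -0.5, 0.5, 1.5])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=8, max_size=8))
    def test_idempotence(self, row):
        recs, design = self._records(n_probes=1)
        m = assemble_matrix(recs, design)
        m.data.iloc[0] = row
        once = baseline_center(m)
        twice = baseline_center(once)
        np.testing.assert_allclose(twice.data.to_numpy(), once.data.to_numpy(),
                                   atol=1e-12)


class TestFilter:
    def _scan_set(self, intensity_by_probe, design, flags=None):
        scans = []
        for s in design.samples:
            n = len(intensity_by_probe)
            scans.append(make_scan([500.0] * n, list(intensity_by_probe),
                                   flags=flags, sample_id=s,
                                   group=design.group_of[s]))
        return scans

    def test_low_intensity_removed_high_retained(self):
        design = GroupDesign.balanced(2)
        scans = self._scan_set([250.0, 10_000.0], design)
        recs = [threshold_and_log(s) for s in scans]
        matrix = assemble_matrix(recs, design)
        filtered, report = filter_entities(matrix, scans, cutoff=300)
        assert report.n_total == 2 and report.n_present == 1
        assert list(filtered.data.index) == ["P0001"]

    def test_group_specific_expression_protected(self):
        # above cutoff in all D fish only -> retained
        design = GroupDesign.balanced(2)
        scans = []
        for s in design.samples:
            val = 5000.0 if design.group_of[s] == "D" else 50.0
            scans.append(make_scan([500.0], [val], sample_id=s,
                                   group=design.group_of[s]))
        recs = [threshold_and_log(s) for s in scans]
        filtered, report = filter_entities(assemble_matrix(recs, design), scans)
        assert report.n_present == 1

    def test_bad_flags_drop_entity(self):
        design = GroupDesign.balanced(2)
        scans = self._scan_set([10_000.0], design, flags=["B"])
        recs = [threshold_and_log(s) for s in scans]
        _, report = filter_entities(assemble_matrix(recs, design), scans)
        assert report.n_present == 0

    def test_cutoff_must_be_positive(self):
        design = GroupDesign.balanced(2)
        scans = self._scan_set([400.0], design)
        recs = [threshold_and_log(s) for s in scans]
        with pytest.raises(ValueError, match="cutoff"):
            filter_entities(assemble_matrix(recs, design), scans, cutoff=0)

    def test_present_fraction_tracks_truth(self):
        # ~40% of genes unexpressed -> n_present/n_total near the expressed rate
        cfg = SimulationConfig(n_genes=1500, n_per_group=3, expressed_fraction=0.6,
                               replicate_probe_fraction=0.0, flagged_fraction=0.0,
                               fraction_affected=0.0, stage_effect_fraction=0.0,
                               seed=3)
        scans = simulate_scans(simulate_truth(cfg), cfg)
        design = GroupDesign.balanced(cfg.n_per_group)
        _, report = preprocess_scans(scans, design)
        se = np.sqrt(0.6 * 0.4 / cfg.n_genes)
        assert abs(report.n_present / report.n_total - 0.6) < 4 * se


class TestScanParsing:
    def test_missing_column(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("probe_id\tgene_name\tch1\tflag\nP1\tg1\t5\tG\n")
        with pytest.raises(ScanFormatError, match="ch2"):
            read_scan(p)

    def test_non_numeric_intensity_reports_line(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("probe_id\tgene_name\tch1\tch2\tflag\n"
                     "P1\tg1\t5\t6\tG\nP2\tg2\tfoo\t6\tG\n")
        with pytest.raises(ScanFormatError, match="line.*3"):
            read_scan(p)

    def test_header_only(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("probe_id\tgene_name\tch1\tch2\tflag\n")
        with pytest.raises(ScanFormatError, match="no probes"):
            read_scan(p)


class TestPipelineProperties:
    def test_sample_order_invariance(self):
        cfg = SimulationConfig(n_genes=200, n_per_group=3, expressed_fraction=1.0,
                               replicate_probe_fraction=0.0, seed=21)
        scans = simulate_scans(simulate_truth(cfg), cfg)
        design = GroupDesign.balanced(cfg.n_per_group)
        m1, _ = preprocess_scans(scans, design)
        m2, _ = preprocess_scans(list(reversed(scans)), design)
        pd.testing.assert_frame_equal(m1.data, m2.data)

    def test_matrix_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_genes=100, n_per_group=2, expressed_fraction=1.0,
                               replicate_probe_fraction=0.0, seed=2)
        scans = simulate_scans(simulate_truth(cfg), cfg)
        design = GroupDesign.balanced(cfg.n_per_group)
        matrix, _ = preprocess_scans(scans, design)
        matrix.write(tmp_path / "m.tsv")
        back = ExpressionMatrix.read(tmp_path / "m.tsv", design)
        np.testing.assert_allclose(back.data.to_numpy(), matrix.data.to_numpy(),
                                   atol=1e-6)
        assert back.provenance == matrix.provenance

    def test_unbiased_pipeline_recovers_group_differences(self):
        # normalization neutrality: true D-vs-Ws offsets recovered within 3 SE.
        # LOWESS assumes most genes unchanged, so keep the affected fraction
        # realistic (10%) -- a heavily perturbed transcriptome would bias any
        # intensity-dependent normalization.
        cfg = SimulationConfig(n_genes=1000, n_per_group=6, expressed_fraction=1.0,
                               replicate_probe_fraction=0.0, dye_bias_amplitude=0.0,
                               background_mean=0.0, flagged_fraction=0.0,
                               fraction_affected=0.1, biological_cv=0.1, seed=17)
        truth = simulate_truth(cfg)
        scans = simulate_scans(truth, cfg)
        design = GroupDesign.balanced(cfg.n_per_group)
        matrix, _ = preprocess_scans(scans, design)
        mu = {t.gene_id: t.group_mean("D") - t.group_mean("Ws") for t in truth}
        d = matrix.group_columns("D").mean(axis=1)
        ws = matrix.group_columns("Ws").mean(axis=1)
        sd_fish = np.log2(1 + cfg.biological_cv)
        se = np.sqrt(2 * (sd_fish ** 2 + (0.5 * sd_fish) ** 2) / cfg.n_per_group)
        errors = [(d[e] - ws[e]) - mu[matrix.gene_names[e]]
                  for e in matrix.entities]
        assert np.mean(np.abs(errors) < 3 * se) > 0.95
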