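"""Threshold calibration, the expected-precision grid and redundancy
elimination."""

import numpy as np
import pytest

import safrag as sf
from safrag.filtering import (
    MJS_BIN_WIDTH,
    N_MJS_BINS,
    _mjs_bin,
    calibrate_precision_grid,
    expected_precision,
)


def rule_for(sizes, cutoff=1.0, k=2.0):
    # mu - k*sigma == cutoff for every size
    return sf.TPRule(mu={s: cutoff + k * 0.5 for s in sizes}, sigma={s: 0.5 for s in sizes}, k=k)


def make_candidate(qstart, size, ep, mjs=0.1, bank_id="b", bank_start=0, weight=3):
    coords = np.zeros((size, 3))
    hit = sf.Hit(qstart, size, bank_id, bank_start, size, mjs, coords)
    return sf.Candidate(hit=hit, weight=weight, expected_precision=ep)


class TestThresholdCalibration:
    def test_all_tp_threshold_is_max_observed_on_grid(self):
        rule = rule_for([9])
        pairs = [(9, m, 0.2) for m in (0.05, 0.11, 0.2501)] * 20
        th = sf.calibrate_mjs_thresholds(pairs, rule, min_pairs=10)
        assert th[9] == pytest.approx(0.251)  # rounded up to the 0.001 grid

    def test_precision_boundary_at_constructed_cliff(self):
        """95% precision holds only below MJS 0.15: threshold lands there."""
        rule = rule_for([12])
        pairs = [(12, 0.008 * i, 0.2) for i in range(18)]  # 18 TPs below 0.15
        pairs += [(12, 0.15 + 0.001 * i, 5.0) for i in range(1, 40)]  # FPs above
        # one extra FP keeps the prefix precision under 0.95 beyond 0.150
        th = sf.calibrate_mjs_thresholds(pairs, rule, min_pairs=10)
        assert th[12] == pytest.approx(0.150)

    def test_reevaluated_precision_meets_target(self):
        """Self-consistency: precision among pairs at or below the returned
        threshold is >= 0.95."""
        rng = np.random.default_rng(0)
        rule = rule_for([10])
        pairs = []
        for _ in range(2000):
            m = rng.random()
            # low mjs mostly accurate, high mjs mostly not
            crmsd = 0.3 if rng.random() > m else 3.0
            pairs.append((10, m, crmsd))
        th = sf.calibrate_mjs_thresholds(pairs, rule, min_pairs=10)
        sel = [(m, c) for _, m, c in pairs if m <= th[10]]
        prec = np.mean([c < rule.cutoff(10) for _, c in sel])
        assert prec >= 0.95

    def test_unsupported_size_borrows_nearest_neighbor(self):
        rule = rule_for([8, 9, 20])
        pairs = [(8, 0.1, 0.2)] * 100 + [(9, 0.2, 0.2)] * 100 + [(20, 0.5, 5.0)] * 100
        th = sf.calibrate_mjs_thresholds(pairs, rule, min_pairs=50)
        assert th[20] == th[9]  # size 20 has no TPs; nearest calibrated size

    def test_no_calibratable_size_raises(self):
        rule = rule_for([7])
        pairs = [(7, 0.3, 9.0)] * 100  # all FP
        with pytest.raises(ValueError):
            sf.calibrate_mjs_thresholds(pairs, rule, min_pairs=10)


class TestPrecisionGrid:
    def test_all_tp_cells_are_one(self):
        clusters = [(9, 0.1 + 0.01 * i, 1 + i % 4, True) for i in range(40)]
        grids = sf.calibrate_precision_grid(clusters, min_support=1)
        g = grids[9]
        defined = np.isfinite(g.precision)
        assert defined.any()
        assert np.all(g.precision[defined] == 1.0)

    def test_single_cluster_support_semantics(self):
        clusters = [(7, 0.10, 5, True)]
        g1 = sf.calibrate_precision_grid(clusters, min_support=1)[7]
        assert expected_precision(g1, 0.10, 5, sf.FilterConfig()) == 1.0
        g10 = sf.calibrate_precision_grid(clusters, min_support=10)[7]
        cfg = sf.FilterConfig()
        assert expected_precision(g10, 0.10, 5, cfg) == pytest.approx(cfg.fallback)

    def test_raw_grid_matches_bruteforce_and_envelope_is_monotone(self):
        rng = np.random.default_rng(1)
        clusters = [
            (11, float(rng.random()), int(rng.integers(1, 8)), bool(rng.random() < 0.6))
            for _ in range(300)
        ]
        g = sf.calibrate_precision_grid(clusters, min_support=5)[11]
        # brute-force recomputation of the raw cumulative precision per cell
        for b in range(0, N_MJS_BINS, 97):
            for w in range(1, g.w_max + 1):
                sel = [tp for _, m, cw, tp in clusters if _mjs_bin(m) <= b and cw >= w]
                if len(sel) >= 5:
                    assert g.raw_precision[b, w - 1] == pytest.approx(np.mean(sel))
                else:
                    assert np.isnan(g.raw_precision[b, w - 1])
        # envelope: non-increasing in mjs, non-decreasing in W, never above raw
        P = g.precision
        with np.errstate(invalid="ignore"):
            dx = np.diff(P, axis=0)
            dy = np.diff(P, axis=1)
        assert np.all(dx[np.isfinite(dx)] <= 1e-12)
        assert np.all(dy[np.isfinite(dy)] >= -1e-12)
        both = np.isfinite(P) & np.isfinite(g.raw_precision)
        assert np.all(P[both] <= g.raw_precision[both] + 1e-12)

    def test_half_open_bin_convention(self):
        clusters = [(6, 0.100, 3, True)] * 12
        g = sf.calibrate_precision_grid(clusters, min_support=10)[6]
        cfg = sf.FilterConfig()
        # 0.100 falls in bin [0.100, 0.101): defined there, undefined just below
        assert expected_precision(g, 0.1004, 3, cfg) == 1.0
        assert expected_precision(g, 0.0999, 3, cfg) == pytest.approx(cfg.fallback)

    def test_weight_above_calibrated_range_clips(self):
        clusters = [(8, 0.05, 4, True)] * 15
        g = sf.calibrate_precision_grid(clusters, min_support=10)[8]
        cfg = sf.FilterConfig()
        assert expected_precision(g, 0.05, 400, cfg) == 1.0

    def test_mjs_out_of_range_rejected(self):
        clusters = [(8, 0.05, 4, True)] * 15
        g = sf.calibrate_precision_grid(clusters, min_support=10)[8]
        with pytest.raises(ValueError):
            expected_precision(g, 1.2, 4, sf.FilterConfig())


class TestRedundancyEliminate:
    def test_high_confidence_all_kept(self):
        cands = [make_candidate(i * 5, 8, 0.995, bank_id=f"b{i}") for i in range(4)]
        kept = sf.redundancy_eliminate(cands, query_len=40, cfg=sf.FilterConfig())
        assert len(kept) == 4
        assert all(c.kept for c in cands)

    def test_low_confidence_all_dropped(self):
        cands = [make_candidate(i * 5, 8, 0.5, bank_id=f"b{i}") for i in range(4)]
        kept = sf.redundancy_eliminate(cands, query_len=40, cfg=sf.FilterConfig())
        assert kept == []
        assert not any(c.kept for c in cands)

    def test_midband_greedy_keeps_best_of_identical_spans(self):
        a = make_candidate(0, 8, 0.90, bank_id="x")
        b = make_candidate(0, 8, 0.85, bank_id="y")
        kept = sf.redundancy_eliminate([a, b], query_len=20, cfg=sf.FilterConfig())
        assert kept == [a]

    def test_midband_fills_uncovered_regions_only(self):
        sure = make_candidate(0, 10, 0.999, bank_id="x")
        covered_mid = make_candidate(2, 6, 0.90, bank_id="y")
        uncovered_mid = make_candidate(12, 6, 0.85, bank_id="z")
        kept = sf.redundancy_eliminate(
            [sure, covered_mid, uncovered_mid], query_len=20, cfg=sf.FilterConfig()
        )
        assert sure in kept and uncovered_mid in kept and covered_mid not in kept

    def test_nested_same_protein_hit_dropped(self):
        outer = make_candidate(0, 12, 0.995, bank_id="p", bank_start=10)
        inner = make_candidate(2, 6, 0.995, bank_id="p", bank_start=12)
        other = make_candidate(2, 6, 0.995, bank_id="q", bank_start=12)
        kept = sf.redundancy_eliminate([outer, inner, other], query_len=20, cfg=sf.FilterConfig())
        assert outer in kept and other in kept and inner not in kept

    def test_output_subset_with_min_expected_precision(self):
        rng = np.random.default_rng(3)
        cands = [
            make_candidate(
                int(rng.integers(0, 30)), int(rng.integers(6, 12)),
                float(rng.random()), bank_id=f"b{i % 5}", bank_start=int(rng.integers(0, 20)),
            )
            for i in range(50)
        ]
        cfg = sf.FilterConfig()
        kept = sf.redundancy_eliminate(cands, query_len=45, cfg=cfg)
        assert set(id(c) for c in kept) <= set(id(c) for c in cands)
        assert all(c.expected_precision >= cfg.lower_precision for c in kept)
        # no nested same-protein pair survives
        for a in kept:
            for b in kept:
                if a is not b:
                    from safrag.filtering import _nested

                    assert not _nested(a, b)

    def test_missing_expected_precision_rejected(self):
        c = make_candidate(0, 8, None)
        with pytest.raises(ValueError):
            sf.redundancy_eliminate([c], query_len=20, cfg=sf.FilterConfig())

    def test_filter_config_validation_and_preset(self):
        with pytest.raises(ValueError):
            sf.FilterConfig(upper_precision=0.5, lower_precision=0.8)
        from safrag.filtering import redundant_bank_config

        preset = redundant_bank_config()
        assert preset.upper_precision == 0.995 and preset.lower_precision == 0.65
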