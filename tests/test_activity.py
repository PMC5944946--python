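import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ribophase.activity import (
    classify_quadrant,
    phase_timeline,
    ratio_series,
    rma_fit,
    signed_ratio,
    top_abundant_otus,
    unsign_ratio,
)
from ribophase.io_tables import OtuTable
from ribophase.preprocess import RelAbundanceTable
from ribophase.synthetic_data import rma_points

positive = st.floats(min_value=1e-8, max_value=1.0, allow_nan=False)


class TestSignedRatio:
    def test_forty_fold_dna_excess(self):
        assert signed_ratio(0.020, 0.0005) == pytest.approx(-40.0)

    def test_equality_maps_to_plus_one(self):
        assert signed_ratio(0.003, 0.003) == 1.0

    def test_three_fold_rna_excess(self):
        assert signed_ratio(0.001, 0.003) == pytest.approx(3.0)

    def test_zero_on_either_side_excluded(self):
        assert signed_ratio(0.0, 0.01) is None
        assert signed_ratio(0.01, 0.0) is None

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            signed_ratio(-0.1, 0.1)

    @given(positive, positive)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetry_and_reconstruction(self, a, b):
        v = signed_ratio(a, b)
        w = signed_ratio(b, a)
        assert abs(v) >= 1.0
        if abs(v) > 1.0:
            assert w == pytest.approx(-v, rel=1e-9)
        else:
            assert w == 1.0
        # raw ratio recoverable exactly
        assert unsign_ratio(v) == pytest.approx(b / a, rel=1e-12)


class TestRmaFit:
    def test_identity_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = rma_fit(x, x, n_boot=50, seed=0)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_points(self):
        fit = rma_fit([0, 1, 2], [1, 3, 5], n_boot=50, seed=0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_slope_is_geometric_mean_of_ols_slopes(self, rng):
        x = rng.normal(0, 1, 200)
        y = 0.8 * x + rng.normal(0, 0.4, 200)
        fit = rma_fit(x, y, n_boot=50, seed=1)
        b_yx = np.polyfit(x, y, 1)[0]
        b_xy = np.polyfit(y, x, 1)[0]
        assert abs(fit.slope) == pytest.approx(math.sqrt(abs(b_yx / b_xy)), rel=1e-9)

    def test_recovers_planted_slope_within_bootstrap_error(self):
        x, y = rma_points(0.9, intercept=0.13, n=300, seed=5)
        fit = rma_fit(x, y, n_boot=1000, seed=5)
        assert abs(fit.slope - 0.9) <= 3 * fit.se_slope

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            rma_fit([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            rma_fit([0.0, 1.0], [0.0, 1.0])


class TestClassifyQuadrant:
    @pytest.mark.parametrize(
        "dna,rna,expected",
        [
            (0.00005, 0.00005, "rare-low"),
            (0.00005, 0.005, "rare-active"),
            (0.005, 0.005, "abundant-active"),
            (0.005, 0.00005, "abundant-low"),
            (0.0005, 0.0005, "transition"),
            (0.0005, 0.005, "transition"),
            (0.00005, 0.0005, "transition"),
        ],
    )
    def test_quadrant_geometry(self, dna, rna, expected):
        assert classify_quadrant(dna, rna) == expected

    def test_scale_consistency(self, rng):
        # thresholds act on relative abundances, so scaling every count in
        # a sample by a constant leaves the classification unchanged
        for _ in range(50):
            counts = rng.integers(1, 10000, size=8).astype(float)
            scaled = 37.0 * counts
            rel = counts / counts.sum()
            rel_scaled = scaled / scaled.sum()
            assert classify_quadrant(rel[0], rel[1]) == classify_quadrant(
                rel_scaled[0], rel_scaled[1]
            )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_quadrant(-0.1, 0.1)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_quadrant(0.1, 0.1, rare_thresh=0.01, abundant_thresh=0.001)


def _timeline(dna, rna, step_days=7):
    dates = pd.date_range("2013-02-01", periods=len(dna), freq=f"{step_days}D")
    return phase_timeline("OTU27", dates, dna, rna)


class TestPhaseTimeline:
    def test_constant_rare_series_quiet(self):
        tl = _timeline([5e-5] * 6, [5e-5] * 6)
        assert tl.bloom_intervals == []
        assert len(tl.warnings) == 0

    def test_warning_two_dates_before_bloom(self):
        # rRNA crosses the abundant threshold two sampling dates before rDNA
        dna = [5e-5, 5e-5, 5e-5, 5e-5, 5e-3, 5e-3, 5e-5]
        rna = [5e-5, 5e-5, 5e-3, 5e-3, 5e-3, 5e-3, 5e-5]
        tl = _timeline(dna, rna)
        assert tl.bloom_intervals == [(4, 5)]
        assert tl.warnings["lead_intervals"].tolist() == [2, 1]
        assert tl.warnings["lead_days"].tolist() == [14, 7]

    def test_senescence_flagged_after_bloom(self):
        dna = [5e-5, 5e-3, 5e-3, 5e-3, 5e-5]
        rna = [5e-5, 5e-3, 5e-3, 5e-5, 5e-5]
        tl = _timeline(dna, rna)
        assert tl.bloom_intervals == [(1, 2)]
        assert len(tl.senescence_dates) == 1

    def test_needs_two_dates(self):
        with pytest.raises(ValueError):
            _timeline([1e-3], [1e-3])


class TestRatioSeries:
    def _tables(self):
        d = pd.DataFrame(
            [[0.8, 0.2, 0.0]], index=pd.Index(["D1"]), columns=["OTU1", "OTU2", "OTU3"]
        )
        r = pd.DataFrame(
            [[0.4, 0.0, 0.6]], index=pd.Index(["R1"]), columns=["OTU1", "OTU2", "OTU3"]
        )
        mk = lambda v: RelAbundanceTable(v)
        return mk(d), mk(r)

    def test_single_molecule_occurrences_excluded(self):
        d, r = self._tables()
        s = ratio_series(d, r, [(pd.Timestamp("2013-02-26"), "D1", "R1")])
        by = s.set_index("otu_id")
        assert not by.loc["OTU1", "excluded"]
        assert by.loc["OTU2", "excluded"] and math.isnan(by.loc["OTU2", "signed_ratio"])
        assert by.loc["OTU3", "excluded"]
        assert by.loc["OTU1", "signed_ratio"] == pytest.approx(-2.0)


class TestTopAbundantOtus:
    def _table(self):
        counts = pd.DataFrame(
            [[50, 10, 10, 5, 0], [40, 10, 9, 5, 1]],
            index=pd.Index(["S1", "S2"]),
            columns=["OTU1", "OTU2", "OTU3", "OTU4", "OTU5"],
        )
        return OtuTable(counts)

    def test_top_k_by_total(self):
        ids, share = top_abundant_otus(self._table(), k=2)
        assert ids == ["OTU1", "OTU2"]
        assert share == pytest.approx(110 / 140)

    def test_tie_breaks_by_otu_id(self):
        counts = pd.DataFrame(
            [[5, 5, 1]], index=pd.Index(["S1"]), columns=["OTUb", "OTUa", "OTUc"]
        )
        ids, _ = top_abundant_otus(OtuTable(counts), k=2)
        assert ids == ["OTUa", "OTUb"]

    def test_total_fraction_floor(self):
        ids, _ = top_abundant_otus(self._table(), k=None, min_total_frac=0.05)
        assert ids == ["OTU1", "OTU2", "OTU3", "OTU4"]
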