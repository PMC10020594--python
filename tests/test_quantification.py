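"""GC-MS normalisation, quantification, classification and derived metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trichoterp.quantification import (
    ParentalReference,
    PeakRecord,
    ResponseFactor,
    SampleMeta,
    bin_levels,
    classify_high_low,
    fold_change,
    format_fold,
    normalize_peak,
    normalize_table,
    parental_reference,
    percent_reduction,
    quantify,
    quantify_table,
    round_half_away,
    sum_by_localization,
)


@pytest.fixture
def leaf_meta():
    return SampleMeta(
        sample_id="s1",
        basis="fresh_weight",
        fresh_weight_mg=50.0,
        extraction_volume_ul=1000.0,
        injection_volume_ul=2.0,
        dilution=1.0,
    )


class TestNormalize:
    def test_zero_peak_is_zero(self, leaf_meta):
        rec = PeakRecord("s1", "7-epizingiberene", 0.0, 1e5)
        assert normalize_peak(rec, leaf_meta) == 0.0

    def test_three_record_spreadsheet_oracle(self):
        """Hand-computed (peak/IS)*dilution*(ext/inj)/denominator values."""
        meta = {
            "s1": SampleMeta("s1", "fresh_weight", 1000.0, 2.0, 1.0, 40.0),
            "s2": SampleMeta("s2", "fresh_weight", 1000.0, 1.0, 2.0, 25.0),
            "s3": SampleMeta("s3", "glands", 300.0, 1.0, 1.0, n_glands=150),
        }
        records = [
            PeakRecord("s1", "x", 2.0e5, 1.0e5),  # 2*1*(500)/40 = 25
            PeakRecord("s2", "x", 5.0e4, 2.0e5),  # 0.25*2*1000/25 = 20
            PeakRecord("s3", "x", 3.0e5, 1.0e5),  # 3*1*300/150 = 6
        ]
        expected = [25.0, 20.0, 6.0]
        for rec, want in zip(records, expected):
            assert normalize_peak(rec, meta[rec.sample_id]) == pytest.approx(want)

    @given(st.floats(1, 1e6), st.floats(0.1, 10))
    def test_linearity(self, area, scale):
        meta = SampleMeta("s", "fresh_weight", 1000.0, 2.0, 1.0, 50.0)
        base = normalize_peak(PeakRecord("s", "x", area, 1e5), meta)
        scaled = normalize_peak(PeakRecord("s", "x", area * scale, 1e5), meta)
        halved = normalize_peak(PeakRecord("s", "x", area, 1e5 * scale), meta)
        assert scaled == pytest.approx(base * scale, rel=1e-12)
        assert halved == pytest.approx(base / scale, rel=1e-12)

    def test_mismatched_sample_rejected(self, leaf_meta):
        with pytest.raises(ValueError, match="does not match"):
            normalize_peak(PeakRecord("other", "x", 1.0, 1.0), leaf_meta)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            PeakRecord("s", "x", 1.0, 0.0)  # IS area must be positive
        with pytest.raises(ValueError):
            SampleMeta("s", "fresh_weight", 1000.0, 2.0, 1.0)  # missing mass
        with pytest.raises(ValueError):
            SampleMeta("s", "leafs", 1000.0, 2.0, 1.0, 50.0)

    def test_table_matches_scalar_path(self):
        peaks = pd.DataFrame(
            {
                "sample_id": ["s1", "s1", "s2"],
                "compound": ["a", "b", "a"],
                "peak_area": [2.0e5, 1.0e4, 9.0e4],
                "is_area": [1.0e5, 1.0e5, 3.0e5],
            }
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "basis": ["fresh_weight", "glands"],
                "fresh_weight_mg": [40.0, np.nan],
                "n_glands": [np.nan, 150],
                "extraction_volume_ul": [1000.0, 300.0],
                "injection_volume_ul": [2.0, 1.0],
                "dilution": [1.0, 1.0],
            }
        )
        out = normalize_table(peaks, meta)
        sm = {
            "s1": SampleMeta("s1", "fresh_weight", 1000.0, 2.0, 1.0, 40.0),
            "s2": SampleMeta("s2", "glands", 300.0, 1.0, 1.0, n_glands=150),
        }
        for row, rec in zip(out.itertuples(), peaks.itertuples()):
            want = normalize_peak(
                PeakRecord(rec.sample_id, rec.compound, rec.peak_area, rec.is_area),
                sm[rec.sample_id],
            )
            assert row.normalized_area == pytest.approx(want)

    def test_missing_metadata_rejected(self):
        peaks = pd.DataFrame(
            {"sample_id": ["sX"], "compound": ["a"], "peak_area": [1.0], "is_area": [1.0]}
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["s1"],
                "basis": ["fresh_weight"],
                "fresh_weight_mg": [40.0],
                "extraction_volume_ul": [1000.0],
                "injection_volume_ul": [2.0],
                "dilution": [1.0],
            }
        )
        with pytest.raises(ValueError, match="sX"):
            normalize_table(peaks, meta)


class TestQuantify:
    def test_unit_slope_is_identity(self):
        rf = ResponseFactor("x", "beta-caryophyllene", 1.0)
        assert quantify(3.7, rf) == 3.7

    def test_missing_rf_flagged_not_dropped(self):
        normalized = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "compound": ["7-epizingiberene", "mystery"],
                "basis": ["glands", "glands"],
                "normalized_area": [2.0, 5.0],
            }
        )
        rfs = {"7-epizingiberene": ResponseFactor("7-epizingiberene", "bcar", 0.5)}
        out = quantify_table(normalized, rfs)
        assert len(out) == 2
        q = out.set_index("compound")
        assert q.loc["7-epizingiberene", "quant_status"] == "quantified"
        assert q.loc["7-epizingiberene", "quantity"] == pytest.approx(1.0)
        assert q.loc["mystery", "quant_status"] == "semi-quantitative"
        assert q.loc["mystery", "quantity"] == pytest.approx(5.0)

    def test_csv_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(20)],
                "compound": ["7-epizingiberene"] * 20,
                "quantity": rng.lognormal(1, 1, 20),
            }
        )
        from trichoterp.quantification import read_quantified_csv, write_quantified_csv

        path = tmp_path / "q.csv"
        write_quantified_csv(table, path)
        back = read_quantified_csv(path)
        assert (back["quantity"] == table["quantity"]).all()


class TestParentalReference:
    def test_constant_values(self):
        ref = parental_reference([5.0, 5.0, 5.0])
        assert ref.sd == 0 and ref.ci_low == ref.ci_high == ref.mean == 5.0

    def test_hand_computed_n4(self):
        ref = parental_reference([1.0, 2.0, 3.0, 4.0])
        assert ref.mean == pytest.approx(2.5)
        assert ref.sd == pytest.approx(1.29099, abs=1e-5)
        half = 1.96 * ref.sd / 2
        assert ref.ci_low == pytest.approx(2.5 - half)
        assert half == pytest.approx(1.2652, abs=1e-4)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            parental_reference([1.0])


class TestClassify:
    def test_mean_is_high_and_zero_is_low(self):
        ref = parental_reference([60.0, 70.0, 80.0, 70.0])
        assert classify_high_low(ref.mean, ref) == "high"
        assert classify_high_low(0.0, ref) == "low"

    @given(st.floats(0, 200), st.floats(0, 200))
    def test_monotone_in_value(self, a, b):
        ref = ParentalReference(70.0, 10.0, 4, 60.2, 79.8)
        lo, hi = sorted([a, b])
        order = {"low": 0, "high": 1}
        assert (
            order[classify_high_low(lo, ref)] <= order[classify_high_low(hi, ref)]
        )

    def test_recovers_true_high_fraction_on_synthetic_population(self, rng):
        """~3% true-high population: recovered count within binomial bounds."""
        from trichoterp.synthetic import SimulationConfig, simulate_population

        cfg = SimulationConfig(model="a-b-C-D", n_plants=392, seed=11)  # f≈0.035
        pop = simulate_population(cfg)
        ref = parental_reference(
            rng.lognormal(np.log(70) - 0.043, 0.294, cfg.parental_n)
        )
        calls = pop["terpene_ng_per_mg"].map(lambda v: classify_high_low(v, ref))
        f = 9 / 256
        sd = math.sqrt(392 * f * (1 - f))
        assert abs((calls == "high").sum() - 392 * f) < 1.96 * sd + 1


class TestBinLevels:
    def test_all_zeros_single_bin(self):
        hist = bin_levels([0.0, 0.0, 0.0], parental_sd=2.0)
        assert hist["count"].tolist() == [3]

    def test_bin_placement(self):
        hist = bin_levels([0.5, 1.5], parental_sd=1.0)
        assert hist.set_index("bin")["count"].to_dict() == {0: 0, 1: 1, 2: 1}

    def test_exact_multiple_is_right_closed(self):
        hist = bin_levels([1.0], parental_sd=1.0)
        assert hist.set_index("bin")["count"][1] == 1

    @given(st.lists(st.floats(0, 50), min_size=1, max_size=200))
    def test_matches_loop_oracle_and_conserves_counts(self, values):
        sd = 1.7
        hist = bin_levels(values, sd)
        assert hist["count"].sum() == len(values)
        oracle = {}
        for v in values:
            b = 0 if v == 0 else math.ceil(v / sd)
            oracle[b] = oracle.get(b, 0) + 1
        got = hist.set_index("bin")["count"]
        for b, c in oracle.items():
            assert got[b] == c

    def test_detection_limit_feeds_zero_bin(self):
        hist = bin_levels([0.01, 5.0], parental_sd=1.0, detection_limit=0.1)
        assert hist.set_index("bin")["count"][0] == 1

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            bin_levels([-1.0], 1.0)


class TestDerivedMetrics:
    @pytest.mark.parametrize(
        "control, treated, pct",
        [(12.3, 0.21, 98), (25.0, 1.2, 95), (5.2, 0.065, 99), (0.13, 0.083, 36)],
    )
    def test_percent_reductions(self, control, treated, pct):
        assert round_half_away(percent_reduction(control, treated)) == pct

    def test_half_away_rounding(self):
        # 0.16 -> 0.060 is a 62.5% reduction, reported as 63
        assert round_half_away(percent_reduction(0.16, 0.060)) == 63

    @pytest.mark.parametrize(
        "a, b, display", [(17.7, 0.51, "~35"), (0.9, 0.51, "~1.8")]
    )
    def test_fold_change_display(self, a, b, display):
        assert format_fold(fold_change(a, b)) == display

    def test_identity_cases(self):
        assert fold_change(3.3, 3.3) == 1.0
        assert percent_reduction(3.3, 3.3) == 0.0
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)

    @given(st.floats(0.01, 1e3), st.floats(0.0, 1e3))
    def test_percent_and_fold_consistency(self, control, treated):
        if treated <= 0:
            return
        pct = percent_reduction(control, treated)
        fc = fold_change(control, treated)
        assert pct == pytest.approx(100 * (1 - 1 / fc), rel=1e-9, abs=1e-9)


class TestLocalization:
    def test_single_plastidial_compound(self):
        table = pd.DataFrame(
            {"sample_id": ["s1"], "compound": ["7-epizingiberene"], "quantity": [4.2]}
        )
        totals, unmapped = sum_by_localization(table)
        assert unmapped == []
        assert totals.loc[0, "plastidial"] == pytest.approx(4.2)
        assert totals.loc[0, "cytosolic"] == 0.0

    def test_unmapped_reported_not_summed(self):
        table = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "compound": ["beta-caryophyllene", "unknownene"],
                "quantity": [1.0, 99.0],
            }
        )
        totals, unmapped = sum_by_localization(table)
        assert unmapped == ["unknownene"]
        assert totals.loc[0, "cytosolic"] == pytest.approx(1.0)
        assert totals.loc[0, "plastidial"] == 0.0

    def test_row_order_invariance(self, rng):
        compounds = ["7-epizingiberene", "beta-caryophyllene", "alpha-humulene"]
        table = pd.DataFrame(
            {
                "sample_id": rng.choice(["s1", "s2"], 30),
                "compound": rng.choice(compounds, 30),
                "quantity": rng.lognormal(0, 1, 30),
            }
        )
        a, _ = sum_by_localization(table)
        b, _ = sum_by_localization(table.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(
            a.sort_values("sample_id").reset_index(drop=True),
            b.sort_values("sample_id").reset_index(drop=True),
        )
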