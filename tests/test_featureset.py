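"""Window placement and the 36-feature extraction contracts."""

import numpy as np
import pandas as pd
import pytest

from edascreen import decomp, featureset, sigproc, synthcohort
from edascreen.featureset import (
    BASE_FEATURES,
    DERIVED_PAIRS,
    FEATURE_COLUMNS,
    PRIMARY_SETS,
    WindowPolicy,
    assemble_feature_table,
    compute_derived,
    compute_primary,
    read_feature_table,
    select_window,
    write_feature_table,
)


class TestSelectWindow:
    @pytest.mark.parametrize(
        "bounds, placement, expected",
        [
            ((0.0, 300.0), "last", (1200, 2400)),    # REST: final 150 s
            ((300.0, 600.0), "first", (2400, 3600)),  # MAT: first 150 s
        ],
    )
    def test_150s_window_at_8hz(self, bounds, placement, expected):
        assert select_window(bounds, placement, 150.0, 8.0) == expected

    def test_window_equal_to_phase_is_whole_phase(self):
        assert select_window((60.0, 120.0), "first", 60.0, 8.0) == (480, 960)
        assert select_window((60.0, 120.0), "last", 60.0, 8.0) == (480, 960)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            select_window((0.0, 100.0), "last", 150.0, 8.0)

    def test_default_policy_placements(self):
        policy = WindowPolicy()
        assert policy.placement["MAT"] == "first"
        for phase in ("REST", "REC1", "RLX", "REC2"):
            assert policy.placement[phase] == "last"


class TestComputePrimary:
    def test_constant_tonic_no_phasic(self):
        out = compute_primary(np.full(100, 2.0), np.zeros(100), (0, 100), 8.0)
        assert out == {"MSCL": 2.0, "SDSCL": 0.0, "SKSCL": 0.0, "NSSCR": 0.0}

    def test_three_sample_hand_arithmetic(self):
        out = compute_primary(np.array([1.0, 2.0, 3.0]), np.zeros(3), (0, 3), 1.0)
        assert out["MSCL"] == pytest.approx(2.0)
        assert out["SDSCL"] == pytest.approx(1.0)  # sample SD, n-1

    def test_skewness_fisher_pearson_g1(self):
        # {1,1,1,5}: g1 = (sum (x-m)^3/n) / (sum (x-m)^2/n)^1.5 = 1.1547
        out = compute_primary(np.array([1.0, 1.0, 1.0, 5.0]), np.zeros(4), (0, 4), 1.0)
        assert out["SKSCL"] == pytest.approx(1.1547, abs=1e-4)

    def test_nsscr_counts_only_peaks_inside_window(self):
        rate = 8.0
        kernel = decomp.biexponential_kernel(0.7, 2.0, rate)
        phasic = np.zeros(2400)
        for onset in (30.0, 60.0, 250.0):  # third peak outside [0, 100)s
            i = int(onset * rate)
            phasic[i : i + len(kernel)] += 0.4 * kernel[: 2400 - i]
        out = compute_primary(np.ones(2400), phasic, (0, 800), rate)
        assert out["NSSCR"] == 2

    def test_window_outside_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            compute_primary(np.ones(10), np.zeros(10), (5, 20), 1.0)


class TestComputeDerived:
    @staticmethod
    def _primary(values: dict[str, float]) -> dict[str, dict[str, float]]:
        return {
            phase: {f: values.get(phase, 0.0) for f in BASE_FEATURES}
            for phase in PRIMARY_SETS.values()
        }

    def test_documented_subtractions(self):
        prim = self._primary({"REST": 2.0, "MAT": 3.0, "REC1": 5.0, "RLX": 1.0,
                              "REC2": 4.0})
        d = compute_derived(prim)
        assert d["D1_dMSCL"] == 3.0 - 2.0   # MAT - REST
        assert d["D2_dMSCL"] == 5.0 - 2.0   # REC1 - REST
        assert d["D3_dMSCL"] == 5.0 - 1.0   # REC1 - RLX
        assert d["D4_dMSCL"] == 5.0 - 4.0   # REC1 - REC2

    def test_identical_phases_give_zeros(self):
        d = compute_derived(self._primary({}))
        assert len(d) == 16
        assert all(v == 0.0 for v in d.values())

    def test_antisymmetric_in_phase_swap(self):
        vals = {"REST": 1.0, "MAT": 4.0, "REC1": 2.5, "RLX": 0.5, "REC2": 3.5}
        d = compute_derived(self._primary(vals))
        for dset, (minuend, subtrahend) in DERIVED_PAIRS.items():
            swapped = dict(vals)
            swapped[minuend], swapped[subtrahend] = vals[subtrahend], vals[minuend]
            d_swapped = compute_derived(self._primary(swapped))
            for f in BASE_FEATURES:
                assert d_swapped[f"{dset}_d{f}"] == -d[f"{dset}_d{f}"]


class TestFeatureTable:
    def test_column_structure(self):
        assert len(FEATURE_COLUMNS) == 36
        primary = [c for c in FEATURE_COLUMNS if c.startswith("P")]
        derived = [c for c in FEATURE_COLUMNS if c.startswith("D")]
        assert len(primary) == 20 and len(derived) == 16

    def test_single_subject_table(self, decomposed_small, small_policy):
        _, _, pre, result = decomposed_small
        table = assemble_feature_table([(pre, result)], small_policy)
        assert table.shape == (1, 38)
        assert list(table.columns[:2]) == ["subject_id", "group"]
        assert list(table.columns[2:]) == list(FEATURE_COLUMNS)
        assert not table.isna().any().any()

    def test_conductance_shift_moves_only_mscl(self, decomposed_small, small_policy):
        from dataclasses import replace

        _, _, pre, result = decomposed_small
        shifted = replace(result, tonic=result.tonic + 1.5)
        base = assemble_feature_table([(pre, result)], small_policy).iloc[0]
        up = assemble_feature_table([(pre, shifted)], small_policy).iloc[0]
        for pset in PRIMARY_SETS:
            assert up[f"{pset}_MSCL"] == pytest.approx(base[f"{pset}_MSCL"] + 1.5)
            for f in ("SDSCL", "SKSCL", "NSSCR"):
                assert up[f"{pset}_{f}"] == pytest.approx(base[f"{pset}_{f}"], abs=1e-9)
        # level shifts cancel in every difference feature
        for dset in DERIVED_PAIRS:
            assert up[f"{dset}_dMSCL"] == pytest.approx(base[f"{dset}_dMSCL"], abs=1e-9)

    def test_analysis_rate_invariance(self, small_protocol, noiseless_fx, small_policy):
        rec, _ = synthcohort.synthesize_recording(small_protocol, noiseless_fx, seed=8)
        rows = {}
        for rate in (4.0, 8.0):
            pre = sigproc.preprocess(rec, sigproc.FilterSpec(target_rate_hz=rate))
            res = decomp.decompose(pre.samples, rate)
            rows[rate] = featureset.subject_features(pre, res, small_policy)
        for pset in PRIMARY_SETS:
            for f in ("MSCL", "SDSCL"):
                col = f"{pset}_{f}"
                assert rows[4.0][col] == pytest.approx(rows[8.0][col], rel=0.02,
                                                       abs=1e-3)
            assert rows[4.0][f"{pset}_NSSCR"] == rows[8.0][f"{pset}_NSSCR"]

    def test_csv_round_trip_with_checksum(self, tmp_path):
        table = pd.DataFrame(
            np.zeros((2, 36)), columns=FEATURE_COLUMNS
        )
        table.insert(0, "group", ["control", "case"])
        table.insert(0, "subject_id", ["a", "b"])
        path = tmp_path / "features.csv"
        write_feature_table(table, path)
        back = read_feature_table(path)
        pd.testing.assert_frame_equal(back, table)

    def test_checksum_mismatch_detected(self, tmp_path):
        table = pd.DataFrame(np.zeros((1, 36)), columns=FEATURE_COLUMNS)
        table.insert(0, "group", ["case"])
        table.insert(0, "subject_id", ["a"])
        path = tmp_path / "features.csv"
        write_feature_table(table, path)
        text = path.read_text().replace("P1_MSCL", "P1_XSCL")
        path.write_text(text)
        with pytest.raises(ValueError, match="checksum"):
            read_feature_table(path)
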