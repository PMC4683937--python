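import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grace_melt import (
    MeltRun,
    SimSampleSpec,
    call_by_peaks,
    call_by_windows,
    interpret,
    normalized_peak_ratio,
    ratio_to_copies,
    simulate_curve,
)
from grace_melt.calling import (
    FLAG_ABSENT_TARGET,
    FLAG_AMBIGUOUS,
    FLAG_IMPROBABLE_REFERENCE,
)
from grace_melt.errors import GraceMeltError, RunQCError
from grace_melt.signal import Peak, PeakSet

from conftest import ALL_COPY_PAIRS, make_run


def peakset(sid, clcn7, hba1, hba2):
    absent = {g for g, h in (("HBA1", hba1), ("HBA2", hba2)) if h == 0}
    return PeakSet(
        sid,
        {
            "CLCN7": Peak(79.4, clcn7),
            "HBA1": Peak(82.2, hba1),
            "HBA2": Peak(85.2, hba2),
        },
        frozenset(absent),
    )


class TestNormalizedPeakRatio:
    def test_self_ratio_is_exactly_one(self):
        ctrl = peakset("wt", 2.3, 2.1, 2.2)
        assert normalized_peak_ratio(ctrl, ctrl, "HBA1") == 1.0
        assert normalized_peak_ratio(ctrl, ctrl, "HBA2") == 1.0

    def test_half_copies_half_ratio(self):
        ctrl = peakset("wt", 2.0, 2.0, 2.0)
        unk = peakset("s", 2.0, 1.0, 2.0)
        assert normalized_peak_ratio(ctrl, unk, "HBA1") == pytest.approx(0.5)

    def test_absent_target_returns_zero(self):
        ctrl = peakset("wt", 2.0, 2.0, 2.0)
        unk = peakset("s", 2.0, 2.0, 0.0)
        assert normalized_peak_ratio(ctrl, unk, "HBA2") == 0.0

    def test_zero_reference_is_an_error(self):
        ctrl = peakset("wt", 2.0, 2.0, 2.0)
        bad = PeakSet("s", {"CLCN7": Peak(79.4, 0.0), "HBA1": Peak(82.2, 1.0), "HBA2": Peak(85.2, 1.0)})
        with pytest.raises(GraceMeltError, match="reference"):
            normalized_peak_ratio(ctrl, bad, "HBA1")

    def test_scale_invariance(self):
        ctrl = peakset("wt", 2.3, 2.1, 2.2)
        unk = peakset("s", 1.9, 1.0, 2.8)
        scaled = peakset("s", 1.9 * 5, 1.0 * 5, 2.8 * 5)
        for gene in ("HBA1", "HBA2"):
            assert normalized_peak_ratio(ctrl, scaled, gene) == pytest.approx(
                normalized_peak_ratio(ctrl, unk, gene)
            )


class TestRatioToCopies:
    @pytest.mark.parametrize(
        "ratio, control, expected",
        [
            (1.0, 2, (2, False)),
            (1.5, 2, (3, False)),   # duplication pattern: ratio 3:2
            (0.5, 2, (1, False)),
            (0.0, 2, (0, False)),
            (0.68, 2, (1, True)),   # candidate 1.36: distance 0.36 > 0.35
        ],
    )
    def test_snap_and_tolerance(self, ratio, control, expected):
        assert ratio_to_copies(ratio, control) == expected

    @given(st.integers(0, 3), st.floats(-0.3, 0.3))
    def test_round_trip_within_tolerance(self, copies, jitter):
        ratio = (copies + jitter) / 2
        got, ambiguous = ratio_to_copies(max(ratio, 0.0), 2)
        if abs(jitter) <= 0.25:  # clearly inside the snap band
            assert got == copies and not ambiguous

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ratio_to_copies(-0.1, 2)
        with pytest.raises(ValueError):
            ratio_to_copies(1.0, 0)


class TestInterpret:
    @pytest.mark.parametrize(
        "pair, needle",
        [
            ((2, 2), "normal"),
            ((2, 1), "α+"),
            ((2, 0), "-α/-α"),
            ((1, 1), "α0"),
            ((1, 0), "Hb H"),
            ((2, 3), "duplication"),
            ((0, 0), "four-gene"),
            ((3, 3), "atypical"),
        ],
    )
    def test_copy_pair_labels(self, pair, needle):
        gi = interpret(pair)
        assert needle in gi.label
        assert gi.copy_pair == pair
        assert gi.caveats  # footnote caveats always attached


class TestCallers:
    @pytest.mark.parametrize("caller", [call_by_peaks, call_by_windows])
    def test_noiseless_calls_match_truth(self, panel, noiseless_run, caller):
        run, pairs = noiseless_run
        calls = {c.sample_id: c for c in caller(run, panel)}
        for sid, pair in pairs.items():
            assert calls[sid].copy_pair == pair
            assert not calls[sid].is_flagged

    def test_methods_identical_on_noiseless_genotypes(self, panel, noiseless_run):
        run, _ = noiseless_run
        by_peaks = {c.sample_id: c.copy_pair for c in call_by_peaks(run, panel)}
        by_windows = {c.sample_id: c.copy_pair for c in call_by_windows(run, panel)}
        assert by_peaks == by_windows

    def test_wildtype_only_run_calls_2_2(self, panel):
        run, _ = make_run(panel, [(2, 2), (2, 2), (2, 2)])
        for call in call_by_peaks(run, panel):
            assert call.copy_pair == (2, 2) and not call.flags

    @pytest.mark.parametrize("caller", [call_by_peaks, call_by_windows])
    def test_scale_invariance_of_calls(self, panel, caller):
        run, pairs = make_run(panel, ALL_COPY_PAIRS, scales=[3.0, 0.4, 1.0, 2.2, 0.7, 1.3])
        calls = {c.sample_id: c for c in caller(run, panel)}
        for sid, pair in pairs.items():
            assert calls[sid].copy_pair == pair

    def test_stage2_ratio_monotone_in_hba2_copies(self, panel):
        run, pairs = make_run(panel, [(2, 0), (2, 1), (2, 2), (2, 3)])
        calls = {c.sample_id: c for c in call_by_windows(run, panel)}
        ratios = [calls[f"S{i}"].stage2_ratio for i in range(4)]
        assert ratios == sorted(ratios)
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_window_sequential_resolution_algebra(self, panel):
        # control (2,2), unknown (2,1): stage-2 odds ratio (1/2)/(2/2) = 0.5 -> HBA2 = 1
        run, _ = make_run(panel, [(2, 1)])
        call = next(c for c in call_by_windows(run, panel))
        assert call.stage2_ratio == pytest.approx(0.5, abs=0.05)
        assert call.copy_pair == (2, 1)

    def test_absent_target_short_circuits_to_zero(self, panel):
        run, _ = make_run(panel, [(2, 0), (1, 0)])
        for caller in (call_by_peaks, call_by_windows):
            calls = {c.sample_id: c for c in caller(run, panel)}
            assert calls["S0"].hba2_copies == 0
            assert FLAG_ABSENT_TARGET in calls["S0"].flags
            assert calls["S1"].copy_pair == (1, 0)

    def test_improbable_reference_flag(self, panel):
        # a CLCN7 anomaly (one reference copy) doubles both target ratios:
        # HBA1 reads as ~4 copies, an improbable state
        rng = np.random.default_rng(0)
        curves = {
            "WT": simulate_curve(SimSampleSpec("WT", {"HBA1": 2, "HBA2": 2}), panel),
            "S0": simulate_curve(
                SimSampleSpec("S0", {"CLCN7": 1, "HBA1": 2, "HBA2": 2}), panel
            ),
        }
        run = MeltRun("r", curves, "WT")
        call = next(c for c in call_by_peaks(run, panel))
        assert FLAG_IMPROBABLE_REFERENCE in call.flags

    def test_run_without_usable_control_fails(self, panel):
        # control whose curve carries no reference melt -> run-level error
        curves = {
            "WT": simulate_curve(SimSampleSpec("WT", {"CLCN7": 0, "HBA1": 2, "HBA2": 2}), panel),
            "S0": simulate_curve(SimSampleSpec("S0", {"HBA1": 2, "HBA2": 2}), panel),
        }
        run = MeltRun("r", curves, "WT")
        with pytest.raises(GraceMeltError):
            call_by_peaks(run, panel)
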