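"""Relative areas, control baseline, normalization and (M, D) measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imprintscan import (
    DenominatorMode,
    Role,
    SamplePair,
    SampleSpec,
    build_baseline,
    measure_loci,
    mosaic_lom,
    normalize,
    relative_areas,
    simulate_sample_pair,
)
from imprintscan.errors import BaselineError, DegenerateDataError
from imprintscan.quantify import (
    FLAG_LOW_CONTROL_N,
    FLAG_MISSING_PEAK,
    RelativeProfile,
)
from imprintscan.panel_io import Condition

ALL = DenominatorMode.ALL_PEAKS
REF = DenominatorMode.REFERENCE_ONLY


def _pair(areas, sample_id="s", role=Role.PATIENT, missing=frozenset()):
    return SamplePair(sample_id=sample_id, digested=dict(areas),
                      undigested=dict(areas), role=role, missing=missing)


class TestRelativeAreas:
    def test_all_peaks_divides_by_total(self, mini_panel):
        dig, undig = relative_areas(
            _pair({"dmr": 200.0, "ref1": 500.0, "ref2": 300.0}),
            mini_panel, ALL)
        for profile in (dig, undig):
            assert profile.rel == {"dmr": 0.2, "ref1": 0.5, "ref2": 0.3}
            assert sum(profile.rel.values()) == pytest.approx(1.0, abs=1e-9)

    def test_reference_only_divides_by_reference_sum(self, mini_panel):
        dig, _ = relative_areas(
            _pair({"dmr": 200.0, "ref1": 500.0, "ref2": 300.0}),
            mini_panel, REF)
        assert dig.rel == {"dmr": 0.25, "ref1": 0.625, "ref2": 0.375}
        ref_mean = (dig.rel["ref1"] + dig.rel["ref2"]) / 2
        assert ref_mean == pytest.approx(0.5, abs=1e-9)  # 1 / n_references

    @pytest.mark.parametrize("mode", [ALL, REF])
    def test_global_rescaling_is_invisible(self, mini_panel, mode):
        base = {"dmr": 200.0, "ref1": 500.0, "ref2": 300.0}
        scaled = {k: 10.0 * v for k, v in base.items()}
        a, _ = relative_areas(_pair(base), mini_panel, mode)
        b, _ = relative_areas(_pair(scaled), mini_panel, mode)
        assert a.rel == pytest.approx(b.rel)

    def test_zero_denominator_is_degenerate(self, mini_panel):
        with pytest.raises(DegenerateDataError, match="reference"):
            relative_areas(_pair({"dmr": 5.0, "ref1": 0.0, "ref2": 0.0}),
                           mini_panel, REF)


class TestBaseline:
    def test_identical_controls_give_zero_cv(self, mini_panel):
        controls = [_pair({"dmr": 2.0, "ref1": 5.0, "ref2": 3.0}, f"c{i}")
                    for i in range(5)]
        base = build_baseline(controls, mini_panel, ALL)
        assert base.means[Condition.DIGESTED]["dmr"] == pytest.approx(0.2)
        assert all(cv == pytest.approx(0.0)
                   for per in base.cv.values() for cv in per.values())

    def test_mean_and_cv_match_hand_computation(self, mini_panel):
        # relative dmr areas 0.2 and 0.3 -> mean 0.25, CV = 0.05/0.25 = 0.2
        controls = [_pair({"dmr": 2.0, "ref1": 5.0, "ref2": 3.0}, "c1"),
                    _pair({"dmr": 3.0, "ref1": 4.0, "ref2": 3.0}, "c2")]
        base = build_baseline(controls, mini_panel, ALL,
                              min_controls=2)
        assert base.means[Condition.DIGESTED]["dmr"] == pytest.approx(0.25)
        assert base.cv[Condition.DIGESTED]["dmr"] == pytest.approx(0.2)

    def test_too_few_controls_raise_unless_overridden(self, mini_panel):
        controls = [_pair({"dmr": 2.0, "ref1": 5.0, "ref2": 3.0}, f"c{i}")
                    for i in range(3)]
        with pytest.raises(BaselineError, match="control"):
            build_baseline(controls, mini_panel, ALL)
        base = build_baseline(controls, mini_panel, ALL, allow_low_n=True)
        assert base.low_n

    def test_zero_mean_amplicon_cannot_normalize(self, mini_panel):
        controls = [_pair({"dmr": 0.0, "ref1": 5.0, "ref2": 3.0}, f"c{i}")
                    for i in range(5)]
        with pytest.raises(BaselineError, match="dmr"):
            build_baseline(controls, mini_panel, REF)


class TestNormalize:
    def test_self_normalization_is_exactly_one(self, mini_panel):
        controls = [_pair({"dmr": 2.0, "ref1": 5.0, "ref2": 3.0}, f"c{i}")
                    for i in range(5)]
        base = build_baseline(controls, mini_panel, REF)
        profile = RelativeProfile("x", Condition.DIGESTED,
                                  dict(base.means[Condition.DIGESTED]), REF)
        assert all(v == 1.0 for v in normalize(profile, base).values())

    def test_ratio_against_baseline_mean(self, mini_panel):
        # control dmr relative area 2.5/10 = 0.25; sample rel 0.05 -> 0.2
        controls = [_pair({"dmr": 2.5, "ref1": 4.5, "ref2": 3.0}, f"c{i}")
                    for i in range(5)]
        base = build_baseline(controls, mini_panel, ALL)
        profile = RelativeProfile("x", Condition.DIGESTED, {"dmr": 0.05,
                                  "ref1": 0.5, "ref2": 0.3}, ALL)
        normalized = normalize(profile, base)
        assert normalized["dmr"] == pytest.approx(0.2)

    def test_amplicon_absent_from_baseline_is_an_error(self, mini_panel):
        controls = [_pair({"dmr": 2.0, "ref1": 5.0, "ref2": 3.0}, f"c{i}")
                    for i in range(5)]
        base = build_baseline(controls, mini_panel, ALL)
        profile = RelativeProfile("x", Condition.DIGESTED, {"other": 0.1}, ALL)
        with pytest.raises(BaselineError, match="other"):
            normalize(profile, base)


class TestMeasureLoci:
    @pytest.mark.parametrize("locus,c,expected_loss", [
        ("KCNQ1OT1", 0.8, 80.0),
        ("SNRPN", 0.4, 40.0),
    ])
    def test_mosaic_lom_recovers_published_percentages(
            self, panel, noise_free_baseline, locus, c, expected_loss):
        amplicon = panel.amplicon_for_locus(locus)
        spec = SampleSpec(sample_id="p",
                          epigenotypes={locus: mosaic_lom(amplicon, c)})
        pair, _ = simulate_sample_pair(spec, panel)
        by_locus = {m.locus: m for m in
                    measure_loci(pair, noise_free_baseline, panel)}
        assert by_locus[locus].M == pytest.approx(1 - c, abs=1e-12)
        assert by_locus[locus].D == pytest.approx(1.0, abs=1e-12)
        assert by_locus[locus].percent_loss == pytest.approx(expected_loss,
                                                             abs=1e-9)
        assert by_locus[locus].percent_gain == 0.0

    def test_control_identical_sample_sits_at_unity(self, panel,
                                                    noise_free_baseline):
        pair, _ = simulate_sample_pair(SampleSpec(sample_id="n"), panel)
        for m in measure_loci(pair, noise_free_baseline, panel):
            assert m.M == pytest.approx(1.0, abs=1e-12)
            assert m.D == pytest.approx(1.0, abs=1e-12)
            assert m.percent_loss == m.percent_gain == 0.0
            assert m.M_per_copy * m.D == pytest.approx(m.M, abs=1e-9)

    def test_missing_peak_flag_carried(self, panel, noise_free_baseline):
        from imprintscan import EpigenotypeSpec
        spec = SampleSpec(sample_id="p", epigenotypes={
            "MEG3": EpigenotypeSpec("MEG3", cn_maternal=2, cn_paternal=0,
                                    meth_maternal=0.0, meth_paternal=1.0)})
        pair, _ = simulate_sample_pair(spec, panel)
        meas = {m.locus: m for m in measure_loci(pair, noise_free_baseline,
                                                 panel)}
        assert meas["MEG3"].M == 0.0
        assert FLAG_MISSING_PEAK in meas["MEG3"].flags

    def test_low_control_n_flag_propagates(self, panel):
        controls = [simulate_sample_pair(
            SampleSpec(sample_id=f"c{i}", role=Role.CONTROL), panel)[0]
            for i in range(3)]
        base = build_baseline(controls, panel, allow_low_n=True)
        pair, _ = simulate_sample_pair(SampleSpec(sample_id="p"), panel)
        assert all(FLAG_LOW_CONTROL_N in m.flags
                   for m in measure_loci(pair, base, panel))

    @settings(max_examples=25, derandomize=True)
    @given(loading=st.floats(min_value=0.01, max_value=100.0,
                             allow_nan=False))
    def test_loading_factor_invariance(self, panel, noise_free_baseline,
                                       loading):
        amplicon = panel.amplicon_for_locus("KCNQ1OT1")
        ref_spec = SampleSpec(sample_id="p", epigenotypes={
            "KCNQ1OT1": mosaic_lom(amplicon, 0.8)})
        scaled_spec = SampleSpec(sample_id="p", epigenotypes={
            "KCNQ1OT1": mosaic_lom(amplicon, 0.8)}, loading_factor=loading)
        m_ref = measure_loci(simulate_sample_pair(ref_spec, panel)[0],
                             noise_free_baseline, panel)
        m_scaled = measure_loci(simulate_sample_pair(scaled_spec, panel)[0],
                                noise_free_baseline, panel)
        for a, b in zip(m_ref, m_scaled):
            assert b.M == pytest.approx(a.M, rel=1e-12)
            assert b.D == pytest.approx(a.D, rel=1e-12)

    def test_all_peaks_mode_inflates_m_under_lom(self, panel):
        """The shrinking ALL_PEAKS denominator biases M upward under LOM."""
        amplicon = panel.amplicon_for_locus("KCNQ1OT1")
        spec = SampleSpec(sample_id="p", epigenotypes={
            "KCNQ1OT1": mosaic_lom(amplicon, 0.8)})
        pair, _ = simulate_sample_pair(spec, panel)
        controls = [simulate_sample_pair(
            SampleSpec(sample_id=f"c{i}", role=Role.CONTROL), panel)[0]
            for i in range(5)]
        m = {}
        for mode in (ALL, REF):
            base = build_baseline(controls, panel, mode)
            meas = {x.locus: x for x in measure_loci(pair, base, panel)}
            m[mode] = meas["KCNQ1OT1"].M
        assert m[ALL] >= m[REF]
        assert m[REF] == pytest.approx(0.2, abs=1e-12)

    def test_normal_cohort_false_positive_rate_below_5_percent(self, panel):
        """sigma = 0.05 noise keeps normal samples inside 0.8-1.2 almost always."""
        rng = np.random.default_rng(2015)
        controls = [simulate_sample_pair(
            SampleSpec(sample_id=f"c{i}", role=Role.CONTROL,
                       noise_sigma=0.05), panel, rng=rng)[0]
            for i in range(20)]
        base = build_baseline(controls, panel)
        n_outside = 0
        n = 500
        for i in range(n):
            pair, _ = simulate_sample_pair(
                SampleSpec(sample_id=f"s{i}", noise_sigma=0.05), panel,
                rng=rng)
            meas = measure_loci(pair, base, panel)
            if any(not (0.8 <= m.M <= 1.2) or not (0.8 <= m.D <= 1.2)
                   for m in meas):
                n_outside += 1
        assert n_outside / n < 0.05
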