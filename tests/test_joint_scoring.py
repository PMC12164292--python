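import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from digitclock.clock_sim import ClockParams, RenderConfig, make_schedule, render_profile
from digitclock.core_phenotype import DigitID
from digitclock.joint_scoring import (
    CyclicalClass,
    DomainConfig,
    ExpressionDomain,
    MonotonicityWarning,
    OnOffSeries,
    build_joint_table,
    classify_cyclical,
    detect_domains,
    score_joints,
)


def bump(x, center, od=0.8, sigma=0.012):
    return od * np.exp(-0.5 * ((x - center) / sigma) ** 2)


class TestDetectDomains:
    def test_flat_zero_profile_empty(self):
        assert detect_domains(np.zeros(500)) == []

    def test_all_runs_too_short_empty(self):
        # above-threshold excursions exist but none is long enough to count
        prof = np.zeros(500)
        prof[50:53] = 1.0
        prof[200:204] = 0.9
        assert detect_domains(prof) == []

    def test_planted_joints_plus_tip(self, params5, noiseless_cfg):
        prof, truth = render_profile(make_schedule(params5), params5, 33.0, noiseless_cfg)
        domains = detect_domains(prof.samples)
        assert sum(d.is_tip for d in domains) == (1 if truth.tip_on else 0)
        assert sum(not d.is_tip for d in domains) == truth.most_recent_joint

    def test_short_run_discarded(self):
        x = np.linspace(0, 1, 500)
        prof = bump(x, 0.5)
        prof[100:104] = 1.0  # 0.8% of length: below the 2% minimum
        domains = detect_domains(prof)
        assert len(domains) == 1
        assert domains[0].center == pytest.approx(0.5, abs=0.01)

    def test_tip_flagging_respects_margin(self):
        x = np.linspace(0, 1, 500)
        near = detect_domains(bump(x, 0.02, sigma=0.008))
        far = detect_domains(bump(x, 0.3))
        assert near[0].is_tip
        assert not far[0].is_tip

    def test_domains_ordered_distal_to_proximal(self):
        x = np.linspace(0, 1, 500)
        prof = bump(x, 0.7) + bump(x, 0.3) + bump(x, 0.5)
        centers = [d.center for d in detect_domains(prof)]
        assert centers == sorted(centers)


class TestScoreJoints:
    def dom(self, start, end, tip=False):
        return ExpressionDomain(start=start, end=end, peak_od=1.0, is_tip=tip)

    def test_no_domains(self):
        assert score_joints([]) == (0, 0)

    def test_one_joint_plus_tip(self):
        # oracle: manual gap count - one gap between tip domain and joint
        domains = [self.dom(0.0, 0.05, tip=True), self.dom(0.4, 0.5)]
        assert score_joints(domains) == (1, 1)

    def test_five_joints_late_stage(self):
        starts = np.linspace(0.1, 0.8, 5)
        domains = [self.dom(s, s + 0.05) for s in starts]
        joints, elements = score_joints(domains)
        assert joints == 5

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            score_joints([self.dom(0.1, 0.3), self.dom(0.2, 0.4)])

    @given(
        n=st.integers(0, 6),
        tip=st.booleans(),
        gap_to_tip=st.booleans(),
    )
    def test_elements_bounded_by_joints(self, n, tip, gap_to_tip):
        domains = []
        pos = 0.0
        if tip:
            domains.append(self.dom(0.0, 0.04, tip=True))
            pos = 0.04
        if not gap_to_tip and n:
            # first joint flush against the previous domain
            domains.append(self.dom(pos, pos + 0.05))
            pos += 0.05
            n -= 1
        for _ in range(n):
            pos += 0.05
            domains.append(self.dom(pos, pos + 0.05))
            pos += 0.05
        joints, elements = score_joints(domains)
        assert elements <= joints + 1


class TestBuildJointTable:
    def test_single_stage_row(self):
        scores = [(30.0, DigitID("hindlimb", i), 1) for i in range(1, 6)]
        table, qc = build_joint_table(scores)
        assert table.shape == (1, 5)
        assert (table.loc[30.0] == 1).all()
        assert qc == []

    def test_duplicate_rejected(self):
        scores = [(30.0, DigitID("hindlimb", 1), 1), (30.0, DigitID("hindlimb", 1), 2)]
        with pytest.raises(ValueError, match="duplicate"):
            build_joint_table(scores)

    def test_monotonicity_violation_warned_not_dropped(self):
        scores = [
            (30.0, DigitID("hindlimb", 1), 2),
            (31.0, DigitID("hindlimb", 1), 1),
        ]
        with pytest.warns(MonotonicityWarning):
            table, qc = build_joint_table(scores)
        assert len(qc) == 1
        assert table.loc[31.0, "I"] == 1

    def test_simulated_ancestor_hindlimb_series(self, noiseless_cfg):
        counts = [2, 3, 4, 5, 4]
        scores = []
        for stage in [29.0, 30.0, 31.0, 32.0, 33.0, 34.0, 35.0, 36.0]:
            for idx, p in enumerate(counts, start=1):
                params = ClockParams(DigitID("hindlimb", idx), p)
                prof, _ = render_profile(make_schedule(params), params, stage, noiseless_cfg)
                joints, _ = score_joints(detect_domains(prof.samples))
                scores.append((stage, params.digit, joints))
        table, qc = build_joint_table(scores)
        assert list(table.loc[36.0]) == counts  # final row equals P per digit
        assert list(table.loc[29.0]) == [1, 1, 1, 1, 1]  # only the first joint
        assert qc == []


def classify_oracle(states):
    """Brute-force string run-length encoding oracle."""
    text = "".join("1" if s else "0" for s in states)
    runs = [r for r in text.split("0") if r]
    if len(runs) >= 2:
        return "cyclical", len(runs)
    if not runs:
        return "silent", 0
    if "0" not in text:
        return "constitutive", 1
    if text.endswith("1"):
        return "monotone_on", 1
    return "monotone_off", 1


class TestClassifyCyclical:
    def series(self, states):
        stages = tuple(30.0 + 0.5 * i for i in range(len(states)))
        return OnOffSeries("g", DigitID("hindlimb", 2), stages, tuple(states))

    def test_published_style_series_is_cyclical(self):
        states = [True, False, True, True, False, True, True, False]
        call = classify_cyclical(self.series(states))
        assert call.category is CyclicalClass.CYCLICAL
        assert call.n_on_runs == 3

    def test_constitutive(self):
        call = classify_cyclical(self.series([True] * 5))
        assert call.category is CyclicalClass.CONSTITUTIVE

    def test_monotone_off(self):
        call = classify_cyclical(self.series([True, True, False, False, False]))
        assert call.category is CyclicalClass.MONOTONE_OFF
        assert call.n_on_runs == 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            classify_cyclical(self.series([True, False]))

    def test_exhaustive_length_8_matches_oracle(self):
        for states in itertools.product([False, True], repeat=8):
            call = classify_cyclical(self.series(list(states)))
            want_cat, want_runs = classify_oracle(states)
            assert call.category.value == want_cat, states
            assert call.n_on_runs == want_runs, states


class TestRoundTripInvariant:
    def test_noiseless_recovery_all_counts(self):
        for p in range(1, 7):
            params = ClockParams(DigitID("forelimb", 3), p, claw=p <= 5)
            prof, _ = render_profile(
                make_schedule(params), params, 36.0, RenderConfig(profile_length_px=500)
            )
            joints, _ = score_joints(detect_domains(prof.samples))
            assert joints == p

    def test_noisy_recovery_rate(self):
        hits = 0
        for seed in range(100):
            p = 1 + seed % 6
            params = ClockParams(DigitID("forelimb", 3), p, claw=p <= 5)
            cfg = RenderConfig(profile_length_px=500, noise_sd=0.1, seed=seed)
            prof, _ = render_profile(make_schedule(params), params, 36.0, cfg)
            joints, _ = score_joints(detect_domains(prof.samples))
            hits += joints == p
        assert hits >= 90
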