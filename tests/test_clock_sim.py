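import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from digitclock.clock_sim import (
    ClockParams,
    LayoutError,
    RenderConfig,
    UndefinedPhaseError,
    make_schedule,
    phase_at,
    render_autopod_image,
    render_profile,
    simulate_calls,
    simulate_tpm,
)
from digitclock.core_phenotype import DigitID
from digitclock.joint_scoring import detect_domains
from digitclock.phase_correlation import normalize_length
from digitclock.stain_profile import extract_profile
from digitclock.transition_claw import Location


def params_for(p, index=3, claw=True, **kw):
    return ClockParams(digit=DigitID("forelimb", index), phalanx_count=p, claw=claw, **kw)


class TestMakeSchedule:
    def test_single_phalanx(self):
        assert make_schedule(params_for(1)).formation_stages == (29.0,)

    def test_five_phalanges_linear(self):
        # closed form: 29 + k*7/4
        assert make_schedule(params_for(5)).formation_stages == (29.0, 30.75, 32.5, 34.25, 36.0)

    def test_interval_scales_with_count(self):
        s2 = make_schedule(params_for(2)).formation_stages
        s5 = make_schedule(params_for(5)).formation_stages
        assert s2[1] - s2[0] == pytest.approx(7.0)
        assert s5[1] - s5[0] == pytest.approx(1.75)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            params_for(0)

    def test_clawless_base_count_extends_past_offset(self):
        sched = make_schedule(params_for(6, claw=False), base_count=5)
        assert sched.formation_stages == (29.0, 30.75, 32.5, 34.25, 36.0, 37.75)

    def test_clawed_cannot_extend(self):
        with pytest.raises(ValueError):
            make_schedule(params_for(6), base_count=5)


class TestPhaseAt:
    def test_zero_at_onset(self):
        assert phase_at(params_for(4), 29.0).phi == 0.0

    def test_zero_exactly_at_each_joint_stage(self):
        for p in range(1, 7):
            params = params_for(p, claw=p <= 5)
            for stage in make_schedule(params).formation_stages:
                assert phase_at(params, stage).phi == pytest.approx(0.0, abs=1e-9), (p, stage)

    def test_p5_midwindow(self):
        assert phase_at(params_for(5), 32.5).phi == pytest.approx(0.0, abs=1e-12)

    @given(
        p=st.integers(2, 6),
        step=st.integers(0, 18),
        ia=st.integers(1, 5),
        ib=st.integers(1, 5),
    )
    def test_equal_counts_share_phase(self, p, step, ia, ib):
        stage = 29.0 + 0.5 * step
        pa = phase_at(params_for(p, index=ia, claw=False), stage).phi
        pb = phase_at(params_for(p, index=ib, claw=False), stage).phi
        assert pa == pytest.approx(pb, abs=1e-12)

    def test_before_window_undefined(self):
        with pytest.raises(UndefinedPhaseError):
            phase_at(params_for(3), 28.0)

    def test_clawed_frozen_after_offset(self):
        assert phase_at(params_for(3), 37.5).phi == 0.0


class TestRenderProfile:
    def test_single_joint_plus_gated_tip(self, noiseless_cfg):
        params = params_for(3)
        prof, truth = render_profile(make_schedule(params), params, 29.5, noiseless_cfg)
        assert truth.most_recent_joint == 1
        assert len(truth.joint_centers) == 1
        domains = detect_domains(prof.samples)
        assert sum(not d.is_tip for d in domains) == 1

    def test_seeded_determinism(self):
        params = params_for(4)
        cfg = RenderConfig(noise_sd=0.2, seed=42)
        a, _ = render_profile(make_schedule(params), params, 33.0, cfg)
        b, _ = render_profile(make_schedule(params), params, 33.0, cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_five_joints_detectable_at_offset(self, noiseless_cfg):
        params = params_for(5)
        prof, truth = render_profile(make_schedule(params), params, 36.0, noiseless_cfg)
        assert truth.most_recent_joint == 5
        domains = detect_domains(prof.samples)
        assert sum(not d.is_tip for d in domains) == 5

    def test_length_drawn_from_range(self):
        params = params_for(3)
        cfg = RenderConfig(seed=5)
        prof, _ = render_profile(make_schedule(params), params, 33.0, cfg)
        assert 184 <= prof.n_raw <= 1195

    def test_isomorphic_digits_correlate_perfectly(self, noiseless_cfg):
        for stage in [29.0, 31.5, 34.0, 36.0]:
            pa, pb = params_for(3, index=2), params_for(3, index=5)
            a, _ = render_profile(make_schedule(pa), pa, stage, noiseless_cfg)
            b, _ = render_profile(make_schedule(pb), pb, stage, noiseless_cfg)
            r = np.corrcoef(
                normalize_length(a).samples, normalize_length(b).samples
            )[0, 1]
            assert r == pytest.approx(1.0, abs=1e-12), stage


@pytest.fixture(scope="module")
def autopod():
    params = [params_for(p, index=i) for i, p in zip(range(1, 6), [2, 3, 4, 5, 3])]
    cfg = RenderConfig(profile_length_px=300, seed=11)
    return render_autopod_image(params, 34.0, cfg), cfg


class TestRenderAutopodImage:
    def test_no_stain_equals_background(self):
        params = [params_for(3)]
        cfg = RenderConfig(profile_length_px=200, joint_od=0.0, tip_od=0.0, seed=0)
        render = render_autopod_image(params, 33.0, cfg)
        bg = np.asarray(cfg.background_rgb)
        assert np.allclose(render.image, bg[None, None, :])

    def test_round_trip_recovers_planted_centers(self, autopod):
        render, cfg = autopod
        for idx, truth in render.truths.items():
            prof = extract_profile(render.image, render.polylines[idx], cfg.stain_model())
            domains = detect_domains(normalize_length(prof).samples)
            found = sorted(d.center for d in domains if not d.is_tip)
            assert len(found) == len(truth.joint_centers)
            for got, want in zip(found, sorted(truth.joint_centers)):
                assert got == pytest.approx(want, abs=0.01)  # within 1% of length

    def test_beer_lambert_linearity(self):
        # doubling the deposited OD doubles -log10(pixel/background)
        params = [params_for(3)]
        images = {}
        for od in (0.4, 0.8):
            cfg = RenderConfig(profile_length_px=200, joint_od=od, tip_od=0.0, seed=0)
            images[od] = render_autopod_image(params, 36.0, cfg)
        bg = np.asarray(RenderConfig().background_rgb)
        log_lo = -np.log10(images[0.4].image / bg[None, None, :])
        log_hi = -np.log10(images[0.8].image / bg[None, None, :])
        assert np.allclose(log_hi, 2 * log_lo, atol=1e-9)

    def test_overlapping_rays_rejected(self):
        params = [params_for(3, index=i) for i in range(1, 6)]
        cfg = RenderConfig(profile_length_px=200, fan_deg=8.0, seed=0)
        with pytest.raises(LayoutError):
            render_autopod_image(params, 34.0, cfg)

    def test_polylines_are_distal_first(self, autopod):
        render, cfg = autopod
        palm_y = render.image.shape[0] - 1
        for line in render.polylines.values():
            # distal (tip) point must be farther from the palm edge row
            assert abs(line[0, 1] - palm_y) > abs(line[1, 1] - palm_y)


class TestSimulateCalls:
    STAGES = [30 + 0.5 * i for i in range(16)]

    def test_clawed_transitions_at_36(self):
        calls = simulate_calls([params_for(3)], self.STAGES, seed=0)
        pfr_on = [c.stage for c in calls if c.gene == "Sox9" and c.state]
        assert max(pfr_on) == 35.5
        claw_tip = [
            c.stage for c in calls if c.gene == "Bambi" and c.state and c.location is Location.TIP_PFR
        ]
        assert min(claw_tip) == 36.0

    def test_clawless_persistent_keeps_pfr_on(self):
        calls = simulate_calls([params_for(6, claw=False)], self.STAGES, seed=0)
        sox = {c.stage: c.state for c in calls if c.gene == "Sox9"}
        assert sox[37.0] and sox[37.5]
        assert not any(
            c.location is Location.TIP_PFR for c in calls if c.gene in {"Bambi", "Msx1", "Msx2"}
        )

    def test_reduced_shuts_down_early(self):
        calls = simulate_calls(
            [params_for(2, claw=False, reduced=True, offset_stage=34.0)], self.STAGES, seed=0
        )
        sox_on = [c.stage for c in calls if c.gene == "Sox9" and c.state]
        assert max(sox_on) == 33.5

    def test_determinism(self):
        a = simulate_calls([params_for(3)], self.STAGES, seed=9, mislabel_rate=0.1)
        b = simulate_calls([params_for(3)], self.STAGES, seed=9, mislabel_rate=0.1)
        assert a == b

    def test_mislabeling_flips_calls(self):
        clean = simulate_calls([params_for(3)], self.STAGES, seed=9)
        noisy = simulate_calls([params_for(3)], self.STAGES, seed=9, mislabel_rate=0.2)
        flipped = sum(c.state != n.state for c, n in zip(clean, noisy))
        assert 0 < flipped < len(clean)

    def test_stage_bounds(self):
        with pytest.raises(ValueError):
            simulate_calls([params_for(3)], [27.0, 30.0, 31.0], seed=0)


class TestSimulateTpm:
    def test_shape_and_labels(self):
        matrix, truth = simulate_tpm(n_genes=50, n_planted=3, seed=0)
        assert matrix.shape == (50, 12)
        assert list(matrix.columns)[:3] == ["digitI_rep1", "digitI_rep2", "digitI_rep3"]
        assert truth.planted.sum() == 3

    def test_determinism(self):
        a, _ = simulate_tpm(n_genes=30, n_planted=2, seed=4)
        b, _ = simulate_tpm(n_genes=30, n_planted=2, seed=4)
        assert a.equals(b)

    def test_null_matrix_has_no_structure(self):
        matrix, truth = simulate_tpm(n_genes=400, n_planted=0, cv=0.05, seed=1)
        assert not truth.planted.any()
        group_means = np.column_stack(
            [matrix.filter(like=f"digit{g}_").mean(axis=1) for g in ("I", "II", "III", "IV")]
        )
        rel_spread = (group_means.max(axis=1) - group_means.min(axis=1)) / group_means.mean(axis=1)
        assert np.median(rel_spread) < 0.2

    def test_planted_effect_size(self):
        matrix, truth = simulate_tpm(
            n_genes=200, n_planted=1, effect_tpm=100.0, cv=0.02, seed=2, planted_base_mean=10.0
        )
        gene = truth[truth.planted].index[0]
        group = truth.loc[gene, "group"]
        target = matrix.loc[gene].filter(like=f"digit{group}_").mean()
        others = matrix.loc[gene].drop(matrix.filter(like=f"digit{group}_").columns).mean()
        assert target - others == pytest.approx(100.0, rel=0.15)
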