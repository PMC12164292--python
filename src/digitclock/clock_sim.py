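"""Ground-truthed synthetic data for the digit-clock pipeline.

Model: every digit owns an autonomous clock confined to a shared stage
window (default 29-36).  A digit destined to form P phalanges lays down P
joints at linearly spaced stages across that window, so its cycle frequency
scales with P; digits with equal P are therefore in identical phase at
every stage.  The generator renders the resulting stain patterns as 1-D
intensity profiles and whole-mount-like RGB images (with the traced
polylines and planted ground truth returned alongside), and emits marker
on/off call tables and TPM matrices with planted effects, so every
downstream analysis stage can be validated without external data.

Geometry of a rendered profile (distal -> proximal, normalized [0, 1]):
a tip growth-zone (PFR) domain near 0 whose amplitude is gated on/off by
the clock phase, then one Gaussian stain domain per formed joint, the most
recently formed joint nearest the tip.  Joints keep their arclength from
the digit base while the tip grows out, which is what makes equal-P digits
correlate perfectly after length normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_phenotype import ClockWindow, DigitID, as_stage
from .stain_profile import (
    DEFAULT_BACKGROUND_RGB,
    DEFAULT_STAIN_UNIT,
    IntensityProfile,
    ProfileMeta,
    StainModel,
)
from .transition_claw import ExpressionCall, Location, MarkerPanel

__all__ = [
    "ClockParams",
    "JointSchedule",
    "PhaseState",
    "RenderConfig",
    "ProfileTruth",
    "AutopodRender",
    "LayoutError",
    "UndefinedPhaseError",
    "make_schedule",
    "phase_at",
    "render_profile",
    "render_autopod_image",
    "simulate_calls",
    "simulate_tpm",
    "simulate_limb_profiles",
]


class UndefinedPhaseError(ValueError):
    """Phase is undefined before the clock window opens."""


class LayoutError(ValueError):
    """Digit rays overlap in a rendered autopod image."""


@dataclass(frozen=True)
class ClockParams:
    """Clock settings of one digit.

    ``claw`` digits stop cycling at the window offset; clawless digits
    either keep the growth zone active indefinitely (``reduced=False``,
    allowing hyperphalangy) or shut it down early at ``offset_stage``
    (``reduced=True``).
    """

    digit: DigitID
    phalanx_count: int
    window: ClockWindow = field(default_factory=ClockWindow)
    claw: bool = True
    reduced: bool = False
    offset_stage: Optional[float] = None

    def __post_init__(self) -> None:
        if int(self.phalanx_count) < 1:
            raise ValueError(f"{self.digit}: phalanx_count must be >= 1 for a present digit")
        object.__setattr__(self, "phalanx_count", int(self.phalanx_count))
        if self.claw and self.reduced:
            raise ValueError("reduced digits are clawless by definition")
        if self.offset_stage is not None:
            object.__setattr__(self, "offset_stage", as_stage(self.offset_stage))

    @property
    def kind(self) -> str:
        if self.claw:
            return "clawed"
        return "reduced" if self.reduced else "clawless_persistent"


@dataclass(frozen=True)
class JointSchedule:
    """Joint formation stages, numbered 1..K proximal to distal."""

    digit: DigitID
    formation_stages: tuple[float, ...]

    def __post_init__(self) -> None:
        st = tuple(float(s) for s in self.formation_stages)
        if not st or any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("formation stages must be non-empty and strictly increasing")
        object.__setattr__(self, "formation_stages", st)

    @property
    def n_joints(self) -> int:
        return len(self.formation_stages)

    def joints_formed(self, stage: float) -> int:
        return int(sum(s <= stage + 1e-9 for s in self.formation_stages))


@dataclass(frozen=True)
class PhaseState:
    digit: DigitID
    stage: float
    phi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"phase must lie in [0, 1), got {self.phi}")


@dataclass(frozen=True)
class RenderConfig:
    """Rendering knobs for profiles and autopod images.

    ``profile_length_px=None`` draws each profile length uniformly from
    ``length_range`` (the span of raw line lengths the analysis is expected
    to cope with).  OD amplitudes, Gaussian widths, the tip duty fraction
    and the stain/background colors are all configurable; geometry fields
    control the image fan layout.
    """

    profile_length_px: Optional[int] = None
    length_range: tuple[int, int] = (184, 1195)
    noise_sd: float = 0.0
    background_rgb: tuple[float, float, float] = DEFAULT_BACKGROUND_RGB
    stain_rgb: Optional[tuple[float, float, float]] = None
    seed: int = 0
    joint_od: float = 0.8
    tip_od: float = 1.0
    joint_sigma: float = 0.012
    tip_sigma: float = 0.008
    tip_center: float = 0.02
    joint_offset: float = 0.12
    proximal_margin: float = 0.05
    duty: float = 0.5
    # image layout
    palm_radius_px: float = 60.0
    fan_deg: float = 100.0
    base_halfwidth_px: float = 6.0
    tip_halfwidth_frac: float = 0.4
    image_pad_px: int = 12

    def __post_init__(self) -> None:
        if self.profile_length_px is not None and self.profile_length_px < 32:
            raise ValueError("profile_length_px must be >= 32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.duty <= 1:
            raise ValueError("duty must lie in (0, 1]")

    def stain_unit(self) -> np.ndarray:
        """Absorbance unit vector used for Beer-Lambert deposition."""
        if self.stain_rgb is None:
            return DEFAULT_STAIN_UNIT.copy()
        bg = np.asarray(self.background_rgb, dtype=float)
        stain = np.asarray(self.stain_rgb, dtype=float)
        vec = -np.log10(np.clip(stain, 1e-6, None) / bg)
        norm = np.linalg.norm(vec)
        if norm <= 0:
            raise ValueError("stain_rgb must differ from background_rgb")
        return vec / norm

    def stain_model(self) -> StainModel:
        """The matching extraction model for images rendered with this config."""
        return StainModel(stain_rgb_unit=self.stain_unit(), background_rgb=self.background_rgb)


@dataclass(frozen=True)
class ProfileTruth:
    """Planted ground truth accompanying a rendered profile."""

    digit: DigitID
    stage: float
    joint_centers: tuple[float, ...]  # normalized distal->proximal positions
    most_recent_joint: int
    tip_on: bool
    tip_center: float


@dataclass
class AutopodRender:
    """A rendered autopod: image, per-digit traces and planted truth."""

    image: np.ndarray
    od: np.ndarray
    polylines: dict[int, np.ndarray]
    truths: dict[int, ProfileTruth]
    profiles: dict[int, IntensityProfile]


def make_schedule(params: ClockParams, base_count: Optional[int] = None) -> JointSchedule:
    """Joint formation stages for one digit.

    The K = P joints (the metapodial-phalangeal joint plus P-1
    interphalangeal ones) are spaced linearly across the window:
    ``s_on + (k-1) * span / (P-1)``, a single joint at onset when P = 1.
    For clawless digits *base_count* may pin the inter-joint interval to an
    ancestral count, in which case extra joints simply continue at that
    spacing past the window offset (a delayed transition).
    """
    w = params.window
    p = params.phalanx_count
    ref = p if base_count is None else int(base_count)
    if ref < 1:
        raise ValueError("base_count must be >= 1")
    if base_count is not None and params.claw and p > ref:
        raise ValueError("clawed digits cannot extend joints past the window offset")
    if ref == 1:
        step = w.span  # degenerate; only used when p > ref on clawless digits
    else:
        step = w.span / (ref - 1)
    stages = tuple(w.s_on + k * step for k in range(p)) if p > 1 else (w.s_on,)
    return JointSchedule(digit=params.digit, formation_stages=stages)


def _progress(params: ClockParams, stage: float) -> float:
    """Continuous joint-formation progress: joint k forms at progress k-1."""
    w = params.window
    if stage < w.s_on - 1e-9:
        raise UndefinedPhaseError(
            f"{params.digit}: phase undefined before window onset "
            f"(stage {stage} < {w.s_on})"
        )
    rate = max(params.phalanx_count - 1, 0) / w.span
    prog = (stage - w.s_on) * rate
    if params.claw:
        prog = min(prog, float(params.phalanx_count - 1))
    elif params.reduced:
        off = params.offset_stage if params.offset_stage is not None else w.s_off - 2.0
        prog = min(prog, (off - w.s_on) * rate)
    return prog


def phase_at(params: ClockParams, stage: float) -> PhaseState:
    """Fractional progress through the current expression cycle.

    phi = frac((stage - s_on) * (P-1) / span); clawed digits freeze at
    phi = 0 once the window closes.  Digits with equal P share phi at every
    stage by construction.
    """
    prog = _progress(params, stage)
    phi = prog - math.floor(prog)
    if phi > 1.0 - 1e-9:  # float fuzz exactly at a joint-formation stage
        phi = 0.0
    if params.claw and prog >= params.phalanx_count - 1 - 1e-12:
        phi = 0.0
    return PhaseState(digit=params.digit, stage=float(stage), phi=phi)


def _domain_positions(params: ClockParams, schedule: JointSchedule, stage: float, cfg: RenderConfig):
    """Normalized distal->proximal centers of the formed joints (1..m)."""
    m = schedule.joints_formed(stage)
    span_u = 1.0 - cfg.joint_offset - cfg.proximal_margin
    t_len = 1.0 + _progress(params, stage)  # tip arclength in phalanx units
    centers = [cfg.joint_offset + span_u * (t_len - k) / t_len for k in range(1, m + 1)]
    return m, centers


def render_profile(
    schedule: JointSchedule,
    params: ClockParams,
    stage: float,
    cfg: Optional[RenderConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[IntensityProfile, ProfileTruth]:
    """Render one digit's stain profile at *stage* with planted truth.

    Deterministic given the config seed (or a caller-supplied generator).
    """
    cfg = cfg or RenderConfig()
    if stage < params.window.s_on - 1e-9:
        raise UndefinedPhaseError(f"cannot render before window onset at {params.window.s_on}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.profile_length_px
    if n is None:
        n = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
    x = np.linspace(0.0, 1.0, n)

    m, centers = _domain_positions(params, schedule, stage, cfg)
    od = np.zeros(n)
    for c in centers:
        od += cfg.joint_od * np.exp(-0.5 * ((x - c) / cfg.joint_sigma) ** 2)
    phi = phase_at(params, stage).phi
    tip_on = phi < cfg.duty - 1e-12 or math.isclose(cfg.duty, 1.0)
    if tip_on:
        od += cfg.tip_od * np.exp(-0.5 * ((x - cfg.tip_center) / cfg.tip_sigma) ** 2)
    if cfg.noise_sd > 0:
        od += rng.normal(0.0, cfg.noise_sd, size=n)
    od = np.clip(od, 0.0, None)

    profile = IntensityProfile(
        samples=od,
        meta=ProfileMeta(specimen="", stage=as_stage(stage), digit=params.digit),
    )
    truth = ProfileTruth(
        digit=params.digit,
        stage=float(stage),
        joint_centers=tuple(centers),
        most_recent_joint=m,
        tip_on=tip_on,
        tip_center=cfg.tip_center,
    )
    return profile, truth


def render_autopod_image(
    per_digit_params: Sequence[ClockParams],
    stage: float,
    cfg: Optional[RenderConfig] = None,
) -> AutopodRender:
    """Render an autopod as an RGB image with per-digit polylines and truth.

    Digits are straight tapering rays fanning upward from a palm point;
    stain is deposited by Beer-Lambert mixing, so pixel = background *
    10**(-OD * stain_unit) per channel.  Raises :class:`LayoutError` when
    two rays overlap (e.g. too many digits in too narrow a fan).
    """
    cfg = cfg or RenderConfig()
    if not 1 <= len(per_digit_params) <= 5:
        raise ValueError("an autopod has 1-5 digits")
    rng = np.random.default_rng(cfg.seed)

    profiles: dict[int, IntensityProfile] = {}
    truths: dict[int, ProfileTruth] = {}
    lengths: dict[int, float] = {}
    for params in per_digit_params:
        schedule = make_schedule(params)
        prof, truth = render_profile(schedule, params, stage, cfg, rng=rng)
        idx = params.digit.index
        profiles[idx] = prof
        truths[idx] = truth
        lengths[idx] = float(prof.n_raw - 1)  # arclength giving n_raw samples

    d = len(per_digit_params)
    fan = math.radians(cfg.fan_deg)
    angles = (
        [math.pi / 2]
        if d == 1
        else [math.pi / 2 + fan / 2 - i * fan / (d - 1) for i in range(d)]
    )
    order = sorted(profiles)  # digit index, anterior to posterior

    max_len = max(lengths.values())
    pad = cfg.image_pad_px + cfg.base_halfwidth_px
    reach = cfg.palm_radius_px + max_len + pad
    half_w = int(math.ceil(reach * max(abs(math.cos(a)) for a in angles) + pad)) + 1
    height = int(math.ceil(reach + pad)) + 1
    width = 2 * half_w + 1
    cx, cy = float(half_w), float(height - 1)  # palm point at bottom center

    yy, xx = np.mgrid[0:height, 0:width]
    od_map = np.zeros((height, width))
    claimed = np.zeros((height, width), dtype=np.int16)
    polylines: dict[int, np.ndarray] = {}

    for idx, angle in zip(order, angles):
        length = lengths[idx]
        dx, dy = math.cos(angle), -math.sin(angle)  # image y grows downward
        bx, by = cx + cfg.palm_radius_px * dx, cy + cfg.palm_radius_px * dy
        tx, ty = bx + length * dx, by + length * dy
        polylines[idx] = np.array([[tx, ty], [bx, by]])  # distal end first

        t = (xx - bx) * dx + (yy - by) * dy
        dist = np.abs(-(xx - bx) * dy + (yy - by) * dx)
        taper = cfg.base_halfwidth_px * (
            1.0 - (1.0 - cfg.tip_halfwidth_frac) * np.clip(t / length, 0.0, 1.0)
        )
        mask = (t >= 0) & (t <= length) & (dist <= taper)
        u = (length - t) / length  # distal fraction along the profile
        prof = profiles[idx].samples
        grid = np.linspace(0.0, 1.0, prof.size)
        od_map[mask] += np.interp(u[mask], grid, prof)
        claimed[mask] += 1

    if int(claimed.max(initial=0)) > 1:
        raise LayoutError(
            f"digit rays overlap ({int((claimed > 1).sum())} px); widen fan_deg or palm_radius_px"
        )

    bg = np.asarray(cfg.background_rgb, dtype=float)
    unit = cfg.stain_unit()
    image = bg[None, None, :] * np.power(10.0, -od_map[:, :, None] * unit[None, None, :])
    return AutopodRender(image=image, od=od_map, polylines=polylines, truths=truths, profiles=profiles)


def simulate_calls(
    per_digit_params: Sequence[ClockParams],
    stages: Sequence[float],
    species: str = "sim",
    panel: Optional[MarkerPanel] = None,
    seed: int = 0,
    mislabel_rate: float = 0.0,
) -> list[ExpressionCall]:
    """Marker on/off call tables following the transition model.

    PFR markers are on at the tip until the digit's transition (window
    offset for clawed digits, ``offset_stage`` for reduced ones, never for
    clawless-persistent ones).  Claw markers run around the limb periphery
    while the early ridge persists (through stage 31), then vanish, and
    tip-restrict from the window offset in clawed digits only.
    ``mislabel_rate`` flips each call independently.
    """
    panel = panel or MarkerPanel()
    rng = np.random.default_rng(seed)
    stages = [as_stage(s) for s in stages]
    if any(not 28.0 <= s <= 38.0 for s in stages):
        raise ValueError("stages must lie within 28-38")
    aer_last = 31.0  # periphery expression of claw markers ends with the ridge

    calls: list[ExpressionCall] = []
    for params in per_digit_params:
        if params.claw:
            pfr_until = params.window.s_off
        elif params.reduced:
            pfr_until = (
                params.offset_stage if params.offset_stage is not None else params.window.s_off - 2.0
            )
        else:
            pfr_until = math.inf
        for stage in stages:
            for gene in sorted(panel.pfr_markers):
                on = stage < pfr_until - 1e-9
                calls.append(
                    ExpressionCall(
                        gene=gene,
                        species=species,
                        digit=params.digit,
                        stage=stage,
                        location=Location.TIP_PFR if on else Location.ABSENT,
                        state=on,
                    )
                )
            for gene in sorted(panel.claw_markers):
                if stage <= aer_last + 1e-9:
                    loc, on = Location.PERIPHERY_AER, True
                elif params.claw and stage >= params.window.s_off - 1e-9:
                    loc, on = Location.TIP_PFR, True
                else:
                    loc, on = Location.ABSENT, False
                calls.append(
                    ExpressionCall(
                        gene=gene,
                        species=species,
                        digit=params.digit,
                        stage=stage,
                        location=loc,
                        state=on,
                    )
                )

    if mislabel_rate > 0:
        flipped: list[ExpressionCall] = []
        for c in calls:
            if rng.random() < mislabel_rate:
                state = not c.state
                loc = Location.TIP_PFR if state else Location.ABSENT
                c = ExpressionCall(c.gene, c.species, c.digit, c.stage, loc, state)
            flipped.append(c)
        calls = flipped
    return calls


def simulate_tpm(
    n_genes: int = 2000,
    n_planted: int = 0,
    effect_tpm: float = 100.0,
    cv: float = 0.1,
    seed: int = 0,
    n_groups: int = 4,
    n_reps: int = 3,
    base_mean_range: tuple[float, float] = (5.0, 200.0),
    planted_base_mean: Optional[float] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A genes x (digit group, replicate) TPM matrix with planted effects.

    Background genes share one mean across groups (log-uniform over
    ``base_mean_range``) with log-normal replicate noise of coefficient of
    variation *cv*.  Each planted gene has its mean raised by *effect_tpm*
    in exactly one group; ``planted_base_mean`` pins the planted genes'
    background level (high backgrounds dilute the fold change, so power
    studies should set it).  Returns ``(matrix, truth)``; *matrix* columns
    are labeled ``digitI_rep1`` ... and *truth* has one row per gene with
    ``planted`` and ``group`` columns.
    """
    if n_planted > n_genes:
        raise ValueError("cannot plant more genes than exist")
    rng = np.random.default_rng(seed)
    from .core_phenotype import roman as _roman

    groups = [_roman(i + 1) for i in range(n_groups)]
    base = np.exp(rng.uniform(np.log(base_mean_range[0]), np.log(base_mean_range[1]), n_genes))
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    if planted_base_mean is not None:
        base[planted_idx] = planted_base_mean
    means = np.repeat(base[:, None], n_groups, axis=1)
    planted_group = rng.integers(0, n_groups, size=n_planted)
    means[planted_idx, planted_group] += effect_tpm

    sigma = math.sqrt(math.log(1.0 + cv**2))
    cols, data = [], []
    for g in range(n_groups):
        for r in range(n_reps):
            cols.append(f"digit{groups[g]}_rep{r + 1}")
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_genes)
            data.append(means[:, g] * noise)
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    matrix = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    matrix.index.name = "gene"

    truth = pd.DataFrame({"planted": False, "group": ""}, index=genes)
    truth.loc[[genes[i] for i in planted_idx], "planted"] = True
    truth.loc[[genes[i] for i in planted_idx], "group"] = [groups[g] for g in planted_group]
    return matrix, truth


def simulate_limb_profiles(
    counts: Sequence[int],
    limb: str = "forelimb",
    n_specimens: int = 18,
    window: Optional[ClockWindow] = None,
    cfg: Optional[RenderConfig] = None,
    seed: int = 0,
) -> list[dict[int, IntensityProfile]]:
    """A developmental series of specimens, each a dict digit -> profile.

    Specimen stages are spread evenly across the clock window (replicates
    wrap around, mirroring a staged whole-mount series).  ``counts[i]`` is
    the phalanx count of digit i+1; zero counts mark absent digits.
    """
    window = window or ClockWindow()
    cfg = cfg or RenderConfig()
    rng = np.random.default_rng(seed)
    stage_grid = [
        as_stage(round((window.s_on + i * window.span / 7) / 0.5) * 0.5) for i in range(8)
    ]
    specimens: list[dict[int, IntensityProfile]] = []
    for s in range(n_specimens):
        stage = stage_grid[s % len(stage_grid)]
        spec: dict[int, IntensityProfile] = {}
        for i, p in enumerate(counts, start=1):
            if p < 1:
                continue
            params = ClockParams(digit=DigitID(limb, i), phalanx_count=p, window=window)
            prof, _ = render_profile(make_schedule(params), params, stage, cfg, rng=rng)
            prof.meta = ProfileMeta(specimen=f"spec{s + 1:02d}", stage=stage, digit=params.digit)
            spec[i] = prof
        specimens.append(spec)
    return specimens
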