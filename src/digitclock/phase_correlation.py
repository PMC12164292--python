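"""Length normalization and phase-correlation analysis of digit profiles.

Digits of one autopod differ in raw length, so each profile is linearly
resampled onto a fixed number of points of normalized arclength before
within-autopod pairwise Pearson correlation.  Per-specimen correlation
matrices are then averaged, pairwise-complete, across a specimen series,
and the resulting ranking is checked against the isomorphic-digit
hypothesis: digits destined for equal phalanx counts should be in
identical clock phase and hence correlate most strongly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_phenotype import Limb, PhenotypeRecord, as_limb, records_for, roman
from .stain_profile import IntensityProfile, ProfileMeta

__all__ = [
    "DEFAULT_N_POINTS",
    "NormalizedProfile",
    "CorrelationSummary",
    "IsomorphyReport",
    "ZeroVarianceWarning",
    "normalize_length",
    "pairwise_correlation",
    "aggregate",
    "rank_isomorphic",
    "summary_to_long",
]

#: Default resample length; sits inside the observed raw range (184-1195).
DEFAULT_N_POINTS = 500


class ZeroVarianceWarning(UserWarning):
    """A profile with zero variance was excluded from correlation."""


@dataclass
class NormalizedProfile:
    """A profile resampled to fixed length on normalized arclength [0, 1]."""

    samples: np.ndarray
    meta: ProfileMeta = field(default_factory=ProfileMeta)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or not np.all(np.isfinite(s)):
            raise ValueError("normalized profile must be a finite 1-D array")
        self.samples = s

    @property
    def n_points(self) -> int:
        return int(self.samples.size)


def normalize_length(profile: IntensityProfile, n_points: int = DEFAULT_N_POINTS) -> NormalizedProfile:
    """Linearly interpolate a profile onto *n_points* equally spaced
    positions of normalized arclength; endpoints are preserved."""
    if n_points < 8:
        raise ValueError(f"n_points must be >= 8, got {n_points}")
    src = np.linspace(0.0, 1.0, profile.n_raw)
    dst = np.linspace(0.0, 1.0, int(n_points))
    return NormalizedProfile(samples=np.interp(dst, src, profile.samples), meta=profile.meta)


def _label(profile: NormalizedProfile, fallback: int) -> int:
    if profile.meta.digit is not None:
        return profile.meta.digit.index
    return fallback


def pairwise_correlation(profiles: Sequence[NormalizedProfile]) -> pd.DataFrame:
    """Pearson correlation matrix of one autopod's normalized profiles.

    Returned as a DataFrame indexed by digit index, symmetric with unit
    diagonal.  Zero-variance profiles cannot be correlated; they are
    excluded (NaN row/column) with a :class:`ZeroVarianceWarning` rather
    than silently reported as zero.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    n = {p.n_points for p in profiles}
    if len(n) != 1:
        raise ValueError(f"profiles must share a common length, got {sorted(n)}")
    labels = [_label(p, i + 1) for i, p in enumerate(profiles)]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate digit labels in one autopod: {labels}")

    mat = pd.DataFrame(np.eye(len(profiles)), index=labels, columns=labels)
    degenerate = [lab for lab, p in zip(labels, profiles) if np.ptp(p.samples) == 0]
    for lab in degenerate:
        warnings.warn(
            f"digit {roman(lab)} profile has zero variance; excluded from correlation",
            ZeroVarianceWarning,
            stacklevel=2,
        )
        mat.loc[lab, :] = np.nan
        mat.loc[:, lab] = np.nan
    for (la, pa), (lb, pb) in combinations(zip(labels, profiles), 2):
        if la in degenerate or lb in degenerate:
            continue
        r = float(np.corrcoef(pa.samples, pb.samples)[0, 1])
        mat.loc[la, lb] = mat.loc[lb, la] = r
    return mat


@dataclass
class CorrelationSummary:
    """Mean pairwise correlations over a specimen series."""

    mean_r: pd.DataFrame
    n: pd.DataFrame
    per_specimen: list[pd.DataFrame]
    limb: Optional[Limb] = None

    def pair_mean(self, a: int, b: int) -> float:
        return float(self.mean_r.loc[a, b])


def aggregate(
    matrices: Sequence[pd.DataFrame], limb: "Limb | str | None" = None
) -> CorrelationSummary:
    """Average per-specimen correlation matrices, pairwise-complete.

    Pairs missing in some specimens use the specimens that observed them;
    the per-pair specimen count is recorded.  A pair observed by no
    specimen has n = 0 and an undefined (NaN) mean.
    """
    if not matrices:
        raise ValueError("need at least one specimen matrix")
    labels = sorted({lab for m in matrices for lab in m.index})
    aligned = [m.reindex(index=labels, columns=labels) for m in matrices]
    stack = np.stack([m.to_numpy(dtype=float) for m in aligned])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
        mean = np.nanmean(stack, axis=0)
    count = np.sum(~np.isnan(stack), axis=0)
    mean[count == 0] = np.nan
    return CorrelationSummary(
        mean_r=pd.DataFrame(mean, index=labels, columns=labels),
        n=pd.DataFrame(count, index=labels, columns=labels),
        per_specimen=list(matrices),
        limb=None if limb is None else as_limb(limb),
    )


@dataclass
class IsomorphyReport:
    """Digit pairs ranked by mean correlation, with isomorphy flags."""

    ranking: pd.DataFrame  # columns: digit_a, digit_b, mean_r, n, isomorphic
    top_pairs: list[tuple[int, int]]
    top_is_isomorphic: bool


def rank_isomorphic(
    summary: CorrelationSummary,
    species: str,
    limb: "Limb | str",
    records: "Sequence[PhenotypeRecord] | None" = None,
) -> IsomorphyReport:
    """Rank digit pairs by mean r and flag whether the leaders are
    isomorphic (equal phalanx count per the phenotype table).

    Ties at the top (within 1e-12) are all reported as co-leaders; the flag
    is true when any co-leader is an isomorphic pair.
    """
    recs = {r.digit.index: r for r in records_for(species, limb, records) if r.present}
    rows = []
    labels = list(summary.mean_r.index)
    for a, b in combinations(labels, 2):
        r = summary.pair_mean(a, b)
        iso = (
            a in recs
            and b in recs
            and (recs[a].phalanx_min, recs[a].phalanx_max)
            == (recs[b].phalanx_min, recs[b].phalanx_max)
        )
        rows.append(
            {
                "digit_a": a,
                "digit_b": b,
                "mean_r": r,
                "n": int(summary.n.loc[a, b]),
                "isomorphic": iso,
            }
        )
    ranking = (
        pd.DataFrame(rows)
        .sort_values(["mean_r", "digit_a", "digit_b"], ascending=[False, True, True])
        .reset_index(drop=True)
    )
    defined = ranking.dropna(subset=["mean_r"])
    if defined.empty:
        return IsomorphyReport(ranking=ranking, top_pairs=[], top_is_isomorphic=False)
    best = defined["mean_r"].iloc[0]
    leaders = defined[defined["mean_r"] >= best - 1e-12]
    top_pairs = [(int(r.digit_a), int(r.digit_b)) for r in leaders.itertuples()]
    return IsomorphyReport(
        ranking=ranking,
        top_pairs=top_pairs,
        top_is_isomorphic=bool(leaders["isomorphic"].any()),
    )


def summary_to_long(summary: CorrelationSummary, limb: "Limb | str | None" = None) -> pd.DataFrame:
    """Long-format (limb, digit_a, digit_b, mean_r, n) table."""
    limb_val = as_limb(limb).value if limb is not None else (
        summary.limb.value if summary.limb is not None else ""
    )
    rows = [
        {
            "limb": limb_val,
            "digit_a": roman(a),
            "digit_b": roman(b),
            "mean_r": summary.pair_mean(a, b),
            "n": int(summary.n.loc[a, b]),
        }
        for a, b in combinations(summary.mean_r.index, 2)
    ]
    return pd.DataFrame(rows)
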