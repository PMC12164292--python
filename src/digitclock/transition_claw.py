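"""Phalanx-claw transition calling from marker on/off expression tables.

Each digit is classified from a table of per-(gene, stage) on/off calls:
``clawed`` digits shut down their tip growth-zone markers at a transition
stage at which at least one claw marker becomes tip-restricted;
``clawless_persistent`` digits keep the growth-zone markers on past the
normal offset and never tip-restrict a claw marker; ``reduced`` digits shut
the growth zone down early without ever starting claw development.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .core_phenotype import DigitID, PhenotypeRecord, as_stage

__all__ = [
    "Location",
    "ExpressionCall",
    "MarkerPanel",
    "TransitionClass",
    "TransitionConfig",
    "TransitionCall",
    "SynchronyResult",
    "InsufficientDataError",
    "call_transition",
    "limb_synchrony",
    "hyperphalangy_flag",
    "read_calls_csv",
    "write_calls_csv",
    "write_transition_report",
]

DEFAULT_PFR_MARKERS = frozenset(
    {"Sox9", "Gdf5", "Wnt9a", "Ackr3", "Hes1", "Hes4", "Id4", "Bmpr1b"}
)
DEFAULT_CLAW_MARKERS = frozenset({"Bambi", "Msx1", "Msx2"})


class InsufficientDataError(ValueError):
    """Raised when a digit's call table cannot support a transition call."""


class Location(str, enum.Enum):
    """Where in the digit an expression call was scored."""

    TIP_PFR = "tip_PFR"
    JOINTS = "joints"
    PERIPHERY_AER = "periphery_AER"
    ABSENT = "absent"


@dataclass(frozen=True)
class ExpressionCall:
    """One on/off expression observation for a (gene, digit, stage)."""

    gene: str
    species: str
    digit: DigitID
    stage: float
    location: Location
    state: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage", as_stage(self.stage))
        object.__setattr__(self, "location", Location(self.location))
        if not self.state and self.location is not Location.ABSENT:
            raise ValueError("an 'off' call must have location=absent")


@dataclass(frozen=True)
class MarkerPanel:
    """Disjoint growth-zone (PFR) and claw marker gene sets."""

    pfr_markers: frozenset = DEFAULT_PFR_MARKERS
    claw_markers: frozenset = DEFAULT_CLAW_MARKERS

    def __post_init__(self) -> None:
        pfr = frozenset(self.pfr_markers)
        claw = frozenset(self.claw_markers)
        if not pfr or not claw:
            raise ValueError("marker sets must be non-empty")
        if pfr & claw:
            raise ValueError(f"marker sets must be disjoint, overlap: {sorted(pfr & claw)}")
        object.__setattr__(self, "pfr_markers", pfr)
        object.__setattr__(self, "claw_markers", claw)


class TransitionClass(str, enum.Enum):
    CLAWED = "clawed"
    CLAWLESS_PERSISTENT = "clawless_persistent"
    REDUCED = "reduced"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class TransitionConfig:
    """Tunable thresholds of the transition-calling rule.

    ``majority_frac``: fraction of observed PFR markers that must be off at
    the tip to count a stage as post-transition.  ``persist_margin``: how
    far beyond the normal offset PFR expression must persist before a digit
    is called clawless-persistent.  ``reduced_lead``: how early (in stages
    before the offset) the PFR must shut down, without claw markers, to be
    called reduced.  ``claw_tol``: how much later than the PFR shutdown a
    claw marker may first tip-restrict and still support a clawed call.
    On dense call tables (>= ``claw_min_calls`` claw-marker observations)
    tip-restriction is treated as real only when more than
    ``claw_noise_frac`` of the claw calls are tip-on, which keeps isolated
    mislabeled calls from faking claw development; sparse tables take every
    tip call at face value.
    """

    s_off: float = 36.0
    majority_frac: float = 0.5
    persist_margin: float = 1.0
    reduced_lead: float = 2.0
    claw_tol: float = 0.5
    claw_noise_frac: float = 0.12
    claw_min_calls: int = 10


@dataclass
class TransitionCall:
    digit: DigitID
    category: TransitionClass
    transition_stage: Optional[float] = None
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category is TransitionClass.CLAWED and self.transition_stage is None:
            raise ValueError("clawed calls must carry a transition stage")


@dataclass(frozen=True)
class SynchronyResult:
    applicable: bool
    synchronous: Optional[bool]
    spread: Optional[float]
    n_clawed: int


def _tip_on(call: ExpressionCall) -> bool:
    return call.state and call.location is Location.TIP_PFR


def call_transition(
    calls: Sequence[ExpressionCall],
    panel: Optional[MarkerPanel] = None,
    cfg: Optional[TransitionConfig] = None,
) -> TransitionCall:
    """Classify one digit from its marker call table.

    Requires calls spanning >= 3 stages with at least one PFR marker and
    one claw marker observed.
    """
    panel = panel or MarkerPanel()
    cfg = cfg or TransitionConfig()
    if not calls:
        raise InsufficientDataError("no calls supplied")
    digits = {c.digit for c in calls}
    if len(digits) != 1:
        raise ValueError(f"calls must concern a single digit, got {sorted(map(str, digits))}")
    digit = digits.pop()

    pfr_calls = [c for c in calls if c.gene in panel.pfr_markers]
    claw_calls = [c for c in calls if c.gene in panel.claw_markers]
    stages = sorted({c.stage for c in calls})
    if len(stages) < 3 or not pfr_calls or not claw_calls:
        raise InsufficientDataError(
            f"{digit}: need >= 3 stages with both PFR and claw markers observed "
            f"(got {len(stages)} stages, {len(pfr_calls)} PFR calls, {len(claw_calls)} claw calls)"
        )

    def majority_off(stage: float) -> Optional[bool]:
        obs = [c for c in pfr_calls if c.stage == stage]
        if not obs:
            return None
        off = sum(not _tip_on(c) for c in obs)
        return off / len(obs) > cfg.majority_frac

    tip_calls = [c for c in claw_calls if _tip_on(c)]
    if (
        len(claw_calls) >= cfg.claw_min_calls
        and len(tip_calls) / len(claw_calls) <= cfg.claw_noise_frac
    ):
        claw_tip_stages: list[float] = []  # sporadic tip calls on a dense table: noise
    else:
        claw_tip_stages = sorted({c.stage for c in tip_calls})

    evidence: dict = {}
    for gene in sorted({c.gene for c in calls}):
        gene_calls = sorted((c for c in calls if c.gene == gene), key=lambda c: c.stage)
        first_off = next((c.stage for c in gene_calls if not c.state), None)
        first_tip = next((c.stage for c in gene_calls if _tip_on(c)), None)
        evidence[gene] = {"first_off": first_off, "first_tip_on": first_tip}

    # clawed: earliest stage where the PFR majority is off at the tip and a
    # claw marker is tip-restricted there or within claw_tol after.
    for s in stages:
        if majority_off(s) and any(s <= cs <= s + cfg.claw_tol + 1e-9 for cs in claw_tip_stages):
            return TransitionCall(digit, TransitionClass.CLAWED, s, evidence)

    if not claw_tip_stages:
        persists = any(
            s >= cfg.s_off + cfg.persist_margin - 1e-9 and majority_off(s) is False
            for s in stages
        )
        if persists:
            return TransitionCall(digit, TransitionClass.CLAWLESS_PERSISTENT, None, evidence)
        # reduced: PFR majority-off from some early stage onward.
        off_from = None
        for s in reversed(stages):
            mo = majority_off(s)
            if mo is None:
                continue
            if not mo:
                break
            off_from = s
        if off_from is not None and off_from <= cfg.s_off - cfg.reduced_lead + 1e-9:
            return TransitionCall(digit, TransitionClass.REDUCED, None, evidence)
    return TransitionCall(digit, TransitionClass.INDETERMINATE, None, evidence)


def limb_synchrony(transitions: Iterable[TransitionCall], tol: float = 0.5) -> SynchronyResult:
    """Whether the clawed digits of one limb transition within *tol* stages.

    Invariant under digit ordering; with fewer than two clawed digits the
    question does not apply and ``synchronous`` is None.
    """
    stages = [
        t.transition_stage
        for t in transitions
        if t.category is TransitionClass.CLAWED and t.transition_stage is not None
    ]
    if len(stages) < 2:
        return SynchronyResult(False, None, None, len(stages))
    spread = max(stages) - min(stages)
    return SynchronyResult(True, spread <= tol + 1e-9, spread, len(stages))


def hyperphalangy_flag(
    transition: TransitionCall,
    record: PhenotypeRecord,
    ancestral: PhenotypeRecord,
) -> bool:
    """True when a clawless-persistent digit exceeds its ancestral count."""
    if record.digit.index != ancestral.digit.index or record.digit.limb != ancestral.digit.limb:
        raise KeyError(
            f"ancestral record {ancestral.digit} is not homologous to {record.digit}"
        )
    if transition.category is not TransitionClass.CLAWLESS_PERSISTENT:
        return False
    return record.phalanx_max > ancestral.phalanx_max


# -- plain-text I/O ---------------------------------------------------------

_CALL_COLUMNS = ["gene", "species", "limb", "digit", "stage", "location", "state"]


def write_calls_csv(path: "str | Path", calls: Iterable[ExpressionCall]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CALL_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    c.gene,
                    c.species,
                    c.digit.limb.value,
                    c.digit.index,
                    c.stage,
                    c.location.value,
                    int(c.state),
                ]
            )


def read_calls_csv(path: "str | Path") -> list[ExpressionCall]:
    calls: list[ExpressionCall] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            calls.append(
                ExpressionCall(
                    gene=row["gene"],
                    species=row["species"],
                    digit=DigitID(row["limb"], int(row["digit"])),
                    stage=float(row["stage"]),
                    location=Location(row["location"]),
                    state=bool(int(row["state"])),
                )
            )
    return calls


def write_transition_report(
    path: "str | Path", species: str, transitions: Iterable[TransitionCall]
) -> None:
    """Transition report CSV with a JSON evidence column."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "limb", "digit", "class", "transition_stage", "evidence"])
        for t in transitions:
            writer.writerow(
                [
                    species,
                    t.digit.limb.value,
                    t.digit.index,
                    t.category.value,
                    "" if t.transition_stage is None else t.transition_stage,
                    json.dumps(t.evidence, sort_keys=True),
                ]
            )
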