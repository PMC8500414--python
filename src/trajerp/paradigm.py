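"""Rotating-trajectory stimulus paradigm: session generation and validation.

The display is a 12-slot circular array (slots 0-11, clockwise from the
12 o'clock position) holding two shapes -- a cued shape that a central
arrow points at, and a non-cued shape -- which rotate together in five
500 ms steps, clockwise or anticlockwise.  The fifth step ends with one
shape on the vertical midline (slot 0 or 6) and the other strictly
lateral (slot 3, right visual field, or slot 9, left visual field).
Conditions are named after the lateralised endpoint shape and whether
its final position follows the implied trajectory:

* ``predictable_cued`` / ``predictable_noncued`` -- both shapes advance
  one slot per step throughout.
* ``unpredictable_cued`` / ``unpredictable_noncued`` -- the lateralised
  shape "moves back": at step 5 it repeats its step-4 slot while the
  trajectory implied one further rotation step; the other shape
  continues predictably.

The arrow always points at the cued shape's trajectory-implied slot, so
only in ``unpredictable_cued`` sequences does it point (at step 5) at an
expected-but-unoccupied position.

A fraction of sequences carry a red fixation dot on one step; these are
a vigilance check and are discarded before any ERP analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

N_SLOTS = 12
DEG_PER_SLOT = 360 // N_SLOTS

CONDITIONS = (
    "predictable_cued",
    "unpredictable_cued",
    "predictable_noncued",
    "unpredictable_noncued",
)
ROTATIONS = ("clockwise", "anticlockwise")
VISUAL_FIELDS = ("left", "right")
SHAPES = ("circle", "square")

#: default strictly-lateral endpoint slot per visual field (3 o'clock / 9 o'clock)
LATERAL_SLOT = {"right": 3, "left": 9}
#: midline slots host the non-lateralised shape at step 5
MIDLINE_SLOTS = (0, 6)

#: stimulus geometry carried as metadata only; nothing is rendered
GEOMETRY_PX = {
    "shape_size": 225,
    "arrow_length": 50,
    "arrow_max_width": 24,
    "red_dot_diameter": 12,
    "screen": (1920, 1080),
}

#: final-step offset of the non-cued shape relative to the cued shape
_NONCUED_FINAL_OFFSET = 3


class ConfigurationError(ValueError):
    """Raised when session-design parameters violate a balance constraint."""


@dataclass(frozen=True)
class TrialFrame:
    """One 500 ms step of a five-step sequence."""

    step_index: int          # 1..5
    cued_position: int       # 0..11
    noncued_position: int    # 0..11
    arrow_angle_deg: int     # multiple of 30; the slot the arrow points at x30
    red_dot: bool = False

    def __post_init__(self) -> None:
        if self.cued_position == self.noncued_position:
            raise ValueError("cued and non-cued shapes cannot share a slot")


@dataclass
class SequenceSpec:
    """Design description of one five-step sequence."""

    condition: str
    rotation: str
    endpoint_vf: str
    start_position: int
    cued_shape: str
    red_dot_step: int = 0    # 0 = no red dot, else 1..5
    frames: list[TrialFrame] = field(default_factory=list)

    @property
    def is_red_dot(self) -> bool:
        return self.red_dot_step > 0

    @property
    def lateral_shape(self) -> str:
        """Which shape role ('cued'/'noncued') ends laterally."""
        return "cued" if self.condition.endswith("_cued") else "noncued"

    @property
    def is_predictable(self) -> bool:
        return self.condition.startswith("predictable")

    def to_record(self) -> dict:
        rec = asdict(self)
        rec["frames"] = [asdict(f) for f in self.frames]
        return rec


def _direction(rotation: str) -> int:
    if rotation == "clockwise":
        return 1
    if rotation == "anticlockwise":
        return -1
    raise ValueError(f"unknown rotation {rotation!r}")


def slot_side(slot: int) -> str:
    """Classify a slot as 'left', 'right' or 'midline' of the vertical axis."""
    slot %= N_SLOTS
    if slot in MIDLINE_SLOTS:
        return "midline"
    return "right" if slot < 6 else "left"


def render_sequence(spec: SequenceSpec) -> list[TrialFrame]:
    """Expand a :class:`SequenceSpec` into its five :class:`TrialFrame` steps.

    The cued shape starts at ``spec.start_position``; the non-cued shape is
    placed so that its final slot sits three slots clockwise of the cued
    shape's final slot.  In unpredictable sequences the condition-designated
    lateral shape repeats its step-4 slot at step 5.
    """
    d = _direction(spec.rotation)
    start = spec.start_position % N_SLOTS
    violator = None if spec.is_predictable else spec.lateral_shape

    # cued-shape trajectory
    cued = [(start + i * d) % N_SLOTS for i in range(5)]
    if violator == "cued":
        cued[4] = cued[3]

    # non-cued shape: anchored by its final slot, advancing every step unless
    # it is the violator, in which case it stalls at step 5
    noncued_final = (cued[4] + _NONCUED_FINAL_OFFSET) % N_SLOTS
    if violator == "noncued":
        # advances steps 1-4, then stalls: step 5 repeats the step-4 slot
        noncued = [(noncued_final - (3 - i) * d) % N_SLOTS for i in range(4)]
        noncued.append(noncued_final)
    else:
        noncued = [(noncued_final - (5 - (i + 1)) * d) % N_SLOTS for i in range(5)]

    # arrow points at the cued shape's trajectory-implied slot
    arrow = list(cued)
    if violator == "cued":
        arrow[4] = (cued[3] + d) % N_SLOTS

    frames = [
        TrialFrame(
            step_index=i + 1,
            cued_position=cued[i],
            noncued_position=noncued[i],
            arrow_angle_deg=arrow[i] * DEG_PER_SLOT,
            red_dot=(spec.red_dot_step == i + 1),
        )
        for i in range(5)
    ]
    spec.frames = frames
    return frames


def _start_for_endpoint(condition: str, rotation: str, endpoint_vf: str) -> int:
    """Cued-shape start slot making the lateral shape end at its strict slot."""
    d = _direction(rotation)
    lateral_slot = LATERAL_SLOT[endpoint_vf]
    if condition.endswith("_cued"):
        cued_final = lateral_slot
    else:
        cued_final = (lateral_slot - _NONCUED_FINAL_OFFSET) % N_SLOTS
    # cued shape advances 4 steps unless it is itself the violator (3 steps)
    n_steps = 3 if condition == "unpredictable_cued" else 4
    return (cued_final - n_steps * d) % N_SLOTS


@dataclass
class SessionPlan:
    """A full experimental session: an ordered list of rendered sequences."""

    sequences: list[SequenceSpec]
    counts: dict
    seed: int

    def __len__(self) -> int:
        return len(self.sequences)

    def analysis_sequences(self) -> list[SequenceSpec]:
        """Sequences entering the ERP analysis (red-dot sequences dropped)."""
        return [s for s in self.sequences if not s.is_red_dot]

    def to_json(self, path=None) -> str | None:
        payload = {
            "seed": self.seed,
            "counts": self.counts,
            "sequences": [s.to_record() for s in self.sequences],
        }
        text = json.dumps(payload, indent=1)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_json(cls, path) -> "SessionPlan":
        with open(path) as fh:
            payload = json.load(fh)
        seqs = []
        for rec in payload["sequences"]:
            frames = [TrialFrame(**f) for f in rec.pop("frames")]
            seqs.append(SequenceSpec(**rec, frames=frames))
        return cls(sequences=seqs, counts=payload["counts"], seed=payload["seed"])


def generate_session(
    per_condition: int = 108,
    red_dot_total: int = 48,
    seed: int = 0,
) -> SessionPlan:
    """Generate a balanced, seeded session plan.

    Each condition receives ``per_condition`` analysis sequences split
    exactly evenly over rotation (2) x endpoint visual field (2), with the
    cued shape alternating circle/square as evenly as divisibility allows.
    ``red_dot_total`` additional vigilance sequences are distributed evenly
    over the four conditions with the dot on a uniformly random step.
    Presentation order is a seeded random permutation; the same seed is
    bit-reproducible.
    """
    if per_condition % 4 != 0:
        raise ConfigurationError(
            f"per-condition count {per_condition} not divisible by 4 "
            "(rotation x endpoint visual field balance)"
        )
    if red_dot_total % 4 != 0:
        raise ConfigurationError(
            f"red-dot count {red_dot_total} not divisible by 4 "
            "(even distribution across conditions)"
        )
    rng = np.random.default_rng(seed)
    sequences: list[SequenceSpec] = []
    per_cell = per_condition // 4
    shape_cycle = 0
    for condition in CONDITIONS:
        for rotation in ROTATIONS:
            for vf in VISUAL_FIELDS:
                start = _start_for_endpoint(condition, rotation, vf)
                for _ in range(per_cell):
                    spec = SequenceSpec(
                        condition=condition,
                        rotation=rotation,
                        endpoint_vf=vf,
                        start_position=start,
                        cued_shape=SHAPES[shape_cycle % 2],
                    )
                    render_sequence(spec)
                    sequences.append(spec)
                    shape_cycle += 1
    per_cond_dots = red_dot_total // 4
    for condition in CONDITIONS:
        for k in range(per_cond_dots):
            rotation = ROTATIONS[k % 2]
            vf = VISUAL_FIELDS[(k // 2) % 2]
            spec = SequenceSpec(
                condition=condition,
                rotation=rotation,
                endpoint_vf=vf,
                start_position=_start_for_endpoint(condition, rotation, vf),
                cued_shape=SHAPES[k % 2],
                red_dot_step=int(rng.integers(1, 6)),
            )
            render_sequence(spec)
            sequences.append(spec)
    order = rng.permutation(len(sequences))
    sequences = [sequences[i] for i in order]
    counts = {
        "total": len(sequences),
        "per_condition": per_condition,
        "red_dot": red_dot_total,
    }
    return SessionPlan(sequences=sequences, counts=counts, seed=seed)


@dataclass
class BalanceReport:
    """Contingency counts and imbalance flags for a session plan."""

    table: pd.DataFrame
    flags: list[str]

    @property
    def balanced(self) -> bool:
        return not self.flags


def validate_balance(plan: SessionPlan) -> BalanceReport:
    """Tabulate rotation x visual-field x cued-shape counts per condition.

    Analysis sequences must fill every rotation x visual-field cell of a
    condition equally; cued-shape counts within a cell may differ by at most
    one (the divisibility-forced minimum).  Any larger discrepancy is
    flagged.  An empty plan yields an empty report.
    """
    rows = [
        {
            "condition": s.condition,
            "rotation": s.rotation,
            "endpoint_vf": s.endpoint_vf,
            "cued_shape": s.cued_shape,
        }
        for s in plan.analysis_sequences()
    ]
    if not rows:
        return BalanceReport(table=pd.DataFrame(), flags=[])
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["condition", "rotation", "endpoint_vf", "cued_shape"])
        .size()
        .rename("count")
        .reset_index()
    )
    flags: list[str] = []
    for cond, sub in df.groupby("condition"):
        cell = sub.groupby(["rotation", "endpoint_vf"]).size()
        cell = cell.reindex(
            pd.MultiIndex.from_product([ROTATIONS, VISUAL_FIELDS]), fill_value=0
        )
        if cell.nunique() > 1:
            flags.append(
                f"{cond}: rotation x visual-field cells unbalanced "
                f"({cell.min()}..{cell.max()})"
            )
        shape = sub.groupby("cued_shape").size()
        shape = shape.reindex(SHAPES, fill_value=0)
        if abs(int(shape.iloc[0]) - int(shape.iloc[1])) > 1:
            flags.append(
                f"{cond}: cued-shape counts unbalanced "
                f"(circle={shape['circle']}, square={shape['square']})"
            )
    return BalanceReport(table=table, flags=flags)
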