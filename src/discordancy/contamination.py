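"""Single-observation slippage contamination and event classification.

A contaminated sample of size n has n - 1 observations from N(0, 1) and
one *contaminant* from a slipped normal: N(delta, 1) under slippage of
central tendency (location), or N(0, epsilon^2) under slippage of
dispersion (scale, standard deviation |epsilon|).  A negative epsilon
produces the same contaminant distribution as +|epsilon| (the slipped
normal is symmetric); only the extreme the slippage points at differs,
which is why +/- parameter values can be pooled.

A contaminated replication is a **C event** when the contaminant is the
observation the test application evaluates — the array's outlier, i.e.
the extreme farther from the sample mean — and a **C-bar event** when
that evaluated extreme is a legitimate observation.  The classification
is a property of the sample, shared by all tests applied to it, and
tracks the contaminant's index through the ordering; it never compares
floating point values for equality.

Base observations and contaminants come from two independently seeded
generator streams per experiment (see :func:`experiment_streams`),
mirroring a simulation design where each experiment consumes its own
pair of random-number streams.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .stats import TailMode, order_sample

__all__ = [
    "ContaminationKind",
    "ContaminationSpec",
    "SimulatedSample",
    "EventType",
    "experiment_streams",
    "draw_samples",
    "draw_sample",
    "classify_events",
    "classify_event",
]


class ContaminationKind(str, enum.Enum):
    NONE = "none"
    LOCATION = "location"
    SCALE = "scale"


class EventType(str, enum.Enum):
    C = "C"          # contaminant at the tested extreme
    C_BAR = "C_bar"  # contaminant at an inner position
    ABSENT = "absent"  # uncontaminated replication


@dataclass(frozen=True)
class ContaminationSpec:
    """The slippage model of one simulation cell.

    ``delta`` is the location shift (used when kind is location);
    ``epsilon`` the scale factor (|epsilon| > 1 when kind is scale,
    +/-1 when uncontaminated).
    """

    kind: ContaminationKind = ContaminationKind.NONE
    delta: float = 0.0
    epsilon: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "kind", ContaminationKind(self.kind))
        if self.kind is ContaminationKind.LOCATION:
            if self.delta == 0.0:
                raise ValueError("location slippage requires delta != 0")
            if self.epsilon != 1.0:
                raise ValueError("location slippage fixes epsilon at 1")
        elif self.kind is ContaminationKind.SCALE:
            if abs(self.epsilon) <= 1.0:
                raise ValueError(
                    f"scale slippage requires |epsilon| > 1, got {self.epsilon}"
                )
            if self.delta != 0.0:
                raise ValueError("scale slippage fixes delta at 0")
        else:
            if self.delta != 0.0 or abs(self.epsilon) != 1.0:
                raise ValueError(
                    "uncontaminated spec requires delta = 0 and epsilon = +/-1"
                )

    @classmethod
    def none(cls) -> "ContaminationSpec":
        return cls(ContaminationKind.NONE)

    @classmethod
    def location(cls, delta: float) -> "ContaminationSpec":
        return cls(ContaminationKind.LOCATION, delta=float(delta))

    @classmethod
    def scale(cls, epsilon: float) -> "ContaminationSpec":
        return cls(ContaminationKind.SCALE, epsilon=float(epsilon))

    @classmethod
    def from_parameter(cls, kind, value: float) -> "ContaminationSpec":
        """Build a spec from a raw grid parameter.

        delta = 0 and epsilon = +/-1 denote the uncontaminated model, so
        grids can mix contaminated and null cells in one parameter column.
        """
        kind = ContaminationKind(kind)
        value = float(value)
        if kind is ContaminationKind.LOCATION and value != 0.0:
            return cls.location(value)
        if kind is ContaminationKind.SCALE and abs(value) != 1.0:
            return cls.scale(value)
        return cls.none()

    @property
    def contaminated(self) -> bool:
        return self.kind is not ContaminationKind.NONE

    @property
    def parameter(self) -> float:
        if self.kind is ContaminationKind.LOCATION:
            return self.delta
        if self.kind is ContaminationKind.SCALE:
            return self.epsilon
        return 0.0

    @property
    def forced_tail(self) -> TailMode:
        """Tail the test application is forced to; two-sided when clean."""
        if self.kind is ContaminationKind.LOCATION:
            return TailMode.UPPER if self.delta > 0 else TailMode.LOWER
        if self.kind is ContaminationKind.SCALE:
            return TailMode.UPPER if self.epsilon > 1 else TailMode.LOWER
        return TailMode.TWO_SIDED

    def contaminant_params(self) -> tuple[float, float]:
        """(mean, standard deviation) of the contaminant's distribution."""
        if self.kind is ContaminationKind.LOCATION:
            return self.delta, 1.0
        if self.kind is ContaminationKind.SCALE:
            return 0.0, abs(self.epsilon)
        return 0.0, 1.0


@dataclass(frozen=True)
class SimulatedSample:
    """One replication: the data plus the contaminant's original index."""

    values: np.ndarray
    spec: ContaminationSpec
    contaminant_index: int | None = None

    def __post_init__(self):
        if self.spec.contaminated != (self.contaminant_index is not None):
            raise ValueError("contaminant_index present iff the spec is contaminated")
        if self.contaminant_index is not None and not (
            0 <= self.contaminant_index < self.values.size
        ):
            raise ValueError("contaminant_index out of range")


def experiment_streams(
    base_seed: int, experiment_id: int = 0
) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """Independent (base-observations, contaminant, position) generators.

    Seeded by SeedSequence mixing of (base_seed, experiment_id, role
    code), so every experiment draws from its own streams and the whole
    design is reproducible from one integer.  Keeping the insertion
    positions on their own stream makes chunked and unchunked generation
    consume the value streams identically.
    """

    def _stream(role: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(base_seed), int(experiment_id), role])
        )

    return _stream(0), _stream(1), _stream(2)


def draw_samples(
    m: int,
    n: int,
    spec: ContaminationSpec,
    rng_base: np.random.Generator,
    rng_contaminant: np.random.Generator,
    rng_position: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw m replications of size n as an (m, n) block.

    Every replication takes n - 1 values from the base stream and one
    from the contaminant stream (a clean N(0, 1) draw when the spec is
    uncontaminated), inserted at a position chosen uniformly at random
    from the position stream.  Returns the block and the contaminant's
    column indices (None for an uncontaminated spec).
    """
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    if m < 1:
        raise ValueError(f"m must be positive, got {m}")
    base = rng_base.standard_normal((m, n - 1))
    mean, sd = spec.contaminant_params()
    extra = mean + sd * rng_contaminant.standard_normal(m)
    pos = rng_position.integers(0, n, size=m)

    # Scatter the extra observation into column `pos`, shifting base
    # columns right of it by one.
    cols = np.arange(n)[None, :]
    src = cols - (cols > pos[:, None])
    out = np.take_along_axis(
        np.concatenate([base, base[:, -1:]], axis=1), src, axis=1
    )
    out[np.arange(m), pos] = extra
    if not spec.contaminated:
        return out, None
    return out, pos


def draw_sample(
    n: int,
    spec: ContaminationSpec,
    rng_base: np.random.Generator,
    rng_contaminant: np.random.Generator,
    rng_position: np.random.Generator,
) -> SimulatedSample:
    """Draw a single replication (scalar convenience over draw_samples)."""
    block, pos = draw_samples(1, n, spec, rng_base, rng_contaminant, rng_position)
    idx = None if pos is None else int(pos[0])
    return SimulatedSample(values=block[0], spec=spec, contaminant_index=idx)


def classify_events(
    block: np.ndarray,
    contaminant_index: np.ndarray | None,
    tested_side,
) -> np.ndarray:
    """Vectorized C / C-bar classification of an (m, n) block.

    ``tested_side`` is either a boolean array (True where the
    application tests the highest observation — the per-replication side
    a two-sided application points at) or a fixed
    :class:`~discordancy.stats.TailMode` for single-side classification.
    Returns a boolean array, True where the contaminant is the tested
    observation (C event).  Raises for an uncontaminated block, whose
    replications are 'absent' events.
    """
    if contaminant_index is None:
        raise ValueError("uncontaminated block has no C / C-bar classification")
    if isinstance(tested_side, TailMode):
        if tested_side is TailMode.UPPER:
            tested = np.argmax(block, axis=1)
        elif tested_side is TailMode.LOWER:
            tested = np.argmin(block, axis=1)
        else:
            raise ValueError("classification needs a resolved side, not two_sided")
    else:
        side = np.asarray(tested_side, dtype=bool)
        tested = np.where(side, np.argmax(block, axis=1), np.argmin(block, axis=1))
    return tested == contaminant_index


def classify_event(sample: SimulatedSample, tested_rank=None) -> EventType:
    """Classify one replication given which extreme the test evaluated.

    ``tested_rank`` is a :class:`~discordancy.stats.TestedRank` (or its
    string value); when omitted, the extreme the sample's slippage points
    at is used.  The comparison goes through the rank of the tracked
    contaminant index, stable under ties.
    """
    from .stats import TestedRank

    if not sample.spec.contaminated:
        return EventType.ABSENT
    if tested_rank is None:
        tested_rank = (
            TestedRank.HIGHEST
            if sample.spec.forced_tail is TailMode.UPPER
            else TestedRank.LOWEST
        )
    ordered = order_sample(sample.values)
    rank = ordered.order_map[sample.contaminant_index]
    target = sample.values.size - 1 if TestedRank(tested_rank) is TestedRank.HIGHEST else 0
    return EventType.C if rank == target else EventType.C_BAR
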