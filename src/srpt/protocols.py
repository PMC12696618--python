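"""Stimulus protocol (event-log) construction.

A protocol is an ordered list of grating presentations for one recording
session.  Five designs are supported:

``ABCD`` / ``DCBA``
    200 trials of a four-element sequence; the four gratings abut in time
    and each sequence is followed by a 1.5 s gray screen.
``AXXX`` / ``NXXX``
    200 trials of a pseudorandom sequence whose first element is fixed
    (A at 45 deg, or a novel lead N) and whose remaining three elements are
    drawn without replacement from the other orientations.
``SINGLE``
    200 trials of a single oriented grating followed by 1.5 s of gray.
``PHASE_REVERSAL``
    400 phase reversals of one grating at 2 Hz with no intervening gray,
    the classical stimulus used to drive SRP in V1.

All trial-based sessions are split into four blocks of 50 trials separated
by a 30 s gray screen (4 x 100 for phase reversals).  Times are in
milliseconds from session start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StimulusEvent",
    "SessionProtocol",
    "make_protocol",
    "PROTOCOL_KINDS",
    "DEFAULT_ORIENTATIONS",
]

PROTOCOL_KINDS = ("ABCD", "DCBA", "AXXX", "NXXX", "SINGLE", "PHASE_REVERSAL")

#: canonical grating orientations (degrees) per stimulus role
DEFAULT_ORIENTATIONS: dict[str, float] = {
    "A": 45.0,
    "B": 105.0,
    "C": 15.0,
    "D": 75.0,
    "E": 135.0,
    "N": 165.0,
    "REVERSAL": 45.0,
}

GRAY_MS = 1500.0
INTERBLOCK_GAP_MS = 30_000.0
N_TRIALS_DEFAULT = 200
BLOCK_SIZE_DEFAULT = 50
REVERSAL_PERIOD_MS = 500.0  # 2 Hz phase reversal
TRIAL_DURATIONS_MS = (150.0, 300.0, 1500.0)

#: three pseudorandom follow-up elements are drawn from this pool
PSEUDORANDOM_POOL = ("B", "C", "D", "E")


@dataclass(frozen=True)
class StimulusEvent:
    """One grating presentation (or one phase reversal)."""

    onset: float          # ms from session start
    duration: float       # ms
    orientation: float    # degrees in [0, 180)
    role: str             # A, B, C, D, E, N, X-pool element, or REVERSAL
    seq_position: int     # 1..4 within a sequence, 1 for single stimuli
    trial: int            # 1-based trial (sequence) index
    block: int            # 1..4


@dataclass
class SessionProtocol:
    """Ordered stimulus events for one session/day with block structure."""

    kind: str
    day: int
    events: list[StimulusEvent]
    n_trials: int
    block_size: int
    stimulus_duration: float
    orientation_map: dict[str, float]
    gray_ms: float = GRAY_MS
    interblock_gap_ms: float = INTERBLOCK_GAP_MS

    @property
    def n_blocks(self) -> int:
        return self.n_trials // self.block_size

    @property
    def duration_ms(self) -> float:
        """Session span: last event offset plus one trailing gray period."""
        last = self.events[-1]
        return last.onset + last.duration + self.gray_ms

    @property
    def lead_role(self) -> str:
        return self.events[0].role

    def select(
        self,
        role: str | None = None,
        seq_position: int | None = None,
        orientation: float | None = None,
        block: int | None = None,
    ) -> list[StimulusEvent]:
        """Events filtered by role / sequence position / orientation / block."""
        out = []
        for ev in self.events:
            if role is not None and ev.role != role:
                continue
            if seq_position is not None and ev.seq_position != seq_position:
                continue
            if orientation is not None and ev.orientation != orientation:
                continue
            if block is not None and ev.block != block:
                continue
            out.append(ev)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day,
                "kind": self.kind,
                "trial": [e.trial for e in self.events],
                "block": [e.block for e in self.events],
                "seq_position": [e.seq_position for e in self.events],
                "role": [e.role for e in self.events],
                "orientation_deg": [e.orientation for e in self.events],
                "onset_ms": [e.onset for e in self.events],
                "duration_ms": [e.duration for e in self.events],
            }
        )

    def validate(self) -> None:
        """Raise ``ValueError`` if the event list violates its invariants."""
        onsets = np.array([e.onset for e in self.events])
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        for prev, nxt in zip(self.events, self.events[1:]):
            if nxt.seq_position > 1:  # same sequence: elements abut
                if abs(nxt.onset - (prev.onset + prev.duration)) > 1e-9:
                    raise ValueError("within-sequence elements must abut")


def _sequence_roles(kind: str, lead_role: str | None, rng: np.random.Generator | None):
    if kind == "ABCD":
        return ["A", "B", "C", "D"]
    if kind == "DCBA":
        return ["D", "C", "B", "A"]
    if kind in ("AXXX", "NXXX"):
        lead = lead_role or ("A" if kind == "AXXX" else "N")
        tail = [r for r in PSEUDORANDOM_POOL if r != lead]
        picks = rng.permutation(len(tail))[:3]
        return [lead] + [tail[i] for i in picks]
    if kind == "SINGLE":
        return [lead_role or "A"]
    raise ValueError(f"unknown kind {kind!r}")


def make_protocol(
    kind: str,
    day: int = 1,
    stimulus_duration: float = 300.0,
    orientation_map: dict[str, float] | None = None,
    seed: int | None = None,
    n_trials: int = N_TRIALS_DEFAULT,
    block_size: int = BLOCK_SIZE_DEFAULT,
    gray_ms: float = GRAY_MS,
    interblock_gap_ms: float = INTERBLOCK_GAP_MS,
    lead_role: str | None = None,
) -> SessionProtocol:
    """Build the full event log for one session.

    Parameters
    ----------
    kind
        One of :data:`PROTOCOL_KINDS`.
    day
        Training day (1..4); recorded on the protocol, does not alter timing.
    stimulus_duration
        Per-element grating duration in ms; must be one of 150, 300 or
        1500 for trial-based kinds (ignored for ``PHASE_REVERSAL``, whose
        period is fixed at 500 ms).
    orientation_map
        Role-to-degrees overrides merged onto :data:`DEFAULT_ORIENTATIONS`
        (e.g. ``{"N": 135.0}`` for a novel single-orientation session).
    seed
        Required for ``AXXX``/``NXXX`` (pseudorandom tails); unused otherwise.
    lead_role
        First element of every sequence; defaults to A (N for ``NXXX``).
    """
    if kind not in PROTOCOL_KINDS:
        raise ValueError(f"unknown protocol kind {kind!r}")
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    orientations = dict(DEFAULT_ORIENTATIONS)
    if orientation_map:
        orientations.update(orientation_map)

    rng = None
    if kind in ("AXXX", "NXXX"):
        if seed is None:
            raise ValueError(f"{kind} protocols require a seed")
        rng = np.random.default_rng(seed)

    events: list[StimulusEvent] = []
    if kind == "PHASE_REVERSAL":
        n_trials, block_size = 400, 100
        duration = REVERSAL_PERIOD_MS
        t = gray_ms
        for i in range(n_trials):
            if i > 0:
                t += duration
                if i % block_size == 0:
                    t += interblock_gap_ms
            events.append(
                StimulusEvent(
                    onset=t,
                    duration=duration,
                    orientation=orientations[lead_role or "REVERSAL"],
                    role="REVERSAL",
                    seq_position=1,
                    trial=i + 1,
                    block=i // block_size + 1,
                )
            )
    else:
        if stimulus_duration <= 0:
            raise ValueError("stimulus_duration must be positive")
        if stimulus_duration not in TRIAL_DURATIONS_MS:
            raise ValueError(
                f"stimulus_duration must be one of {TRIAL_DURATIONS_MS}"
            )
        if n_trials % block_size:
            raise ValueError("n_trials must divide evenly into blocks")
        t = gray_ms
        for i in range(n_trials):
            if i > 0:
                t += gray_ms if i % block_size else interblock_gap_ms
            roles = _sequence_roles(kind, lead_role, rng)
            for pos, role in enumerate(roles, start=1):
                events.append(
                    StimulusEvent(
                        onset=t,
                        duration=stimulus_duration,
                        orientation=orientations[role],
                        role=role,
                        seq_position=pos,
                        trial=i + 1,
                        block=i // block_size + 1,
                    )
                )
                t += stimulus_duration

    proto = SessionProtocol(
        kind=kind,
        day=day,
        events=events,
        n_trials=n_trials,
        block_size=block_size,
        stimulus_duration=(
            REVERSAL_PERIOD_MS if kind == "PHASE_REVERSAL" else stimulus_duration
        ),
        orientation_map=orientations,
        gray_ms=gray_ms,
        interblock_gap_ms=interblock_gap_ms,
    )
    proto.validate()
    return proto
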