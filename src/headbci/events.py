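"""Rotation events: the unit of ground truth and of detector output."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

LEFT = "left"
RIGHT = "right"


@dataclass(frozen=True)
class RotationEvent:
    """One head rotation: onset/offset in seconds, direction, center provenance.

    ``from_center`` is True when the head faced straight ahead at onset, i.e.
    the rotation is a scored center-outward movement. Only those are used for
    training and onset-locked analyses; return (side-to-center) movements are
    detected but excluded.
    """

    onset: float
    direction: str
    offset: float
    from_center: bool = True

    def __post_init__(self) -> None:
        if self.direction not in (LEFT, RIGHT):
            raise ValueError(f"direction must be 'left' or 'right', got {self.direction!r}")
        if not self.offset > self.onset:
            raise ValueError(f"offset ({self.offset}) must exceed onset ({self.onset})")


def events_to_frame(events: Sequence[RotationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [e.onset for e in events],
            "direction": [e.direction for e in events],
            "offset_s": [e.offset for e in events],
            "from_center": [e.from_center for e in events],
        }
    )


def write_events_tsv(events: Sequence[RotationEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[RotationEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        RotationEvent(
            onset=float(r.onset_s),
            direction=str(r.direction),
            offset=float(r.offset_s),
            from_center=bool(r.from_center),
        )
        for r in df.itertuples()
    ]


def scored(events: Iterable[RotationEvent]) -> list[RotationEvent]:
    """The center-outward subset, in time order."""
    return [e for e in events if e.from_center]
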