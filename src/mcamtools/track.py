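"""Frame-to-frame track linking by optimal gated assignment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detect import Detection

__all__ = ["Track", "link_detections"]

_GATE_COST = 1e6


@dataclass
class Track:
    """A time-linked sequence of detections for one individual.

    ``embedding`` is an optional running-mean identity vector; ``state`` is
    ``active`` while the track is being extended, ``closed`` once the gap
    limit is exceeded.
    """

    track_id: int
    detections: list[Detection] = field(default_factory=list)
    embedding: np.ndarray | None = None
    state: str = "active"
    gap: int = 0

    def add(self, det: Detection) -> None:
        if self.detections and det.frame_index <= self.detections[-1].frame_index:
            raise ValueError("detections must have strictly increasing frame indices")
        self.detections.append(det)
        self.gap = 0

    @property
    def last_center(self) -> tuple[float, float]:
        return self.detections[-1].center


def link_detections(
    tracks: list[Track],
    detections_t: list[Detection],
    max_displacement_px: float = 80.0,
    max_gap: int = 2,
) -> list[Track]:
    """Extend tracks with one frame of detections.

    Active tracks and new detections are matched by the assignment minimizing
    total centroid distance, subject to a per-pair gate of
    ``max_displacement_px`` (solved optimally on the gated cost matrix).
    Unmatched detections start new tracks; unmatched active tracks accumulate
    a gap and close after ``max_gap`` missed frames.  Returns the updated
    track list (mutated in place and returned).
    """
    active = [tr for tr in tracks if tr.state == "active"]
    matched_tracks: set[int] = set()
    matched_dets: set[int] = set()
    if active and detections_t:
        cost = np.full((len(active), len(detections_t)), _GATE_COST)
        for i, tr in enumerate(active):
            tx, ty = tr.last_center
            for j, det in enumerate(detections_t):
                dx, dy = det.center
                d = float(np.hypot(dx - tx, dy - ty))
                if d <= max_displacement_px:
                    cost[i, j] = d
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] < _GATE_COST:
                active[i].add(detections_t[j])
                matched_tracks.add(i)
                matched_dets.add(j)
    for i, tr in enumerate(active):
        if i not in matched_tracks:
            tr.gap += 1
            if tr.gap > max_gap:
                tr.state = "closed"
    next_id = max((tr.track_id for tr in tracks), default=-1) + 1
    for j, det in enumerate(detections_t):
        if j not in matched_dets:
            tr = Track(track_id=next_id)
            tr.add(det)
            tracks.append(tr)
            next_id += 1
    return tracks
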