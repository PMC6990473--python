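"""Discrete-event scheduler.

A priority queue of events ordered by (scheduled time, event id); ties break
on the id, i.e. creation order, so every worker pops the same sequence.
Fixed-interval events (walks, loggers) compute their n-th firing time as
``n * interval`` by multiplication rather than repeated addition, which keeps
the times bit-identical across workers and free of accumulated rounding.

Rescheduling an event bumps a version counter; stale heap entries are skipped
on pop (lazy deletion).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

__all__ = ["EventRecord", "Scheduler"]


@dataclass
class EventRecord:
    """One scheduler entry: a walk group, the unimolecular reaction event, or a logger."""

    event_id: int
    kind: str  # "walk" | "unimolecular_reaction" | "numbers_logger" | "coordinates_logger"
    interval: float | None  # fixed interval; None for the variable reaction event
    payload: object = None  # species-id tuple for walks, LoggerSpec for loggers
    n_fired: int = 0
    next_time: float = 0.0


class Scheduler:
    def __init__(self):
        self._heap: list[tuple[float, int, int]] = []
        self._version: dict[int, int] = {}
        self.t = 0.0

    def schedule(self, event_id: int, t: float) -> None:
        v = self._version.get(event_id, 0) + 1
        self._version[event_id] = v
        heapq.heappush(self._heap, (t, event_id, v))

    def peek(self):
        """(t, event_id) of the earliest live entry, or None."""
        while self._heap:
            t, eid, v = self._heap[0]
            if self._version.get(eid) == v and not math.isinf(t):
                return t, eid
            heapq.heappop(self._heap)
        return None

    def pop(self):
        nxt = self.peek()
        if nxt is None:
            return None
        heapq.heappop(self._heap)
        self.t = nxt[0]
        return nxt

    def pop_due(self, t_end: float):
        """Pop the earliest live entry with t <= t_end, in one heap pass."""
        heap = self._heap
        version = self._version
        while heap:
            t, eid, v = heap[0]
            if version.get(eid) == v and not math.isinf(t):
                if t > t_end:
                    return None
                heapq.heappop(heap)
                self.t = t
                return t, eid
            heapq.heappop(heap)
        return None

    def __len__(self) -> int:
        return sum(
            1
            for t, eid, v in self._heap
            if self._version.get(eid) == v and not math.isinf(t)
        )
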