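"""Bulk-transfer capacity model: archive push vs. storage write.

Bulk retrieval stages studies through an intermediate archive that pushes
to research storage.  When the push rate exceeds the storage write rate,
the archive's in-memory buffer fills and the service crashes; the
remediation is to slow the push and/or enlarge the buffer.  This module
captures that failure mode with a study-granular producer–consumer model
in two interchangeable forms:

* a closed-form fluid approximation (:func:`simulate_transfer`), in which
  the buffer grows linearly at ``push − write`` while the producer runs
  and overflow occurs at ``capacity / (push − write)``;
* a discrete-event oracle (:func:`simulate_transfer_discrete`) that moves
  one study at a time and agrees with the fluid model to within one study.

Retrieval windows restricted to part of the day (e.g. nights only, to
protect clinical PACS load) are modeled as a duty-cycle multiplier on
wall-clock time.  Modeling is per-study, not per-byte: study-size
variation is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = ["TransferScenario", "TransferOutcome", "simulate_transfer", "simulate_transfer_discrete"]


@dataclass(frozen=True)
class TransferScenario:
    """A bulk-transfer configuration.

    Parameters
    ----------
    push_rate, write_rate :
        Producer and consumer throughput, studies per hour of active time.
    buffer_capacity :
        Studies the intermediate buffer can hold before the service fails.
    total_volume :
        Studies to move end to end.
    nightly_window_hours :
        If set, transfers run only this many hours per day; reported times
        are wall-clock hours under that duty cycle.
    """

    push_rate: float
    write_rate: float
    buffer_capacity: float
    total_volume: int
    nightly_window_hours: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.push_rate, self.write_rate, self.buffer_capacity) < 0:
            raise ValueError("rates and capacity must be non-negative")
        if self.total_volume <= 0:
            raise ValueError("total_volume must be positive")
        if self.nightly_window_hours is not None and not 0 < self.nightly_window_hours <= 24:
            raise ValueError("nightly_window_hours must be in (0, 24]")


@dataclass(frozen=True)
class TransferOutcome:
    """Result of a transfer run.

    Exactly one of ``time_to_overflow`` / ``completion_time`` is present,
    except for non-terminating scenarios (e.g. zero write rate with a
    buffer large enough never to overflow), where both are absent and
    ``non_terminating`` is set.
    """

    overflowed: bool
    time_to_overflow: Optional[float] = None
    completion_time: Optional[float] = None
    peak_buffer: float = 0.0
    non_terminating: bool = False


def _duty_cycle(scenario: TransferScenario) -> float:
    if scenario.nightly_window_hours is None:
        return 1.0
    return scenario.nightly_window_hours / 24.0


def simulate_transfer(scenario: TransferScenario) -> TransferOutcome:
    """Closed-form fluid solution of the producer–consumer buffer.

    While the producer runs (for ``volume / push`` active hours) the buffer
    grows at ``push − write``; overflow happens when the buffer would
    exceed capacity.  If production ends first, the residual buffer drains
    at the write rate and completion is at ``volume / write`` active hours
    (``volume / push`` when the writer keeps up).  Active time is converted
    to wall-clock time by the duty-cycle factor.
    """
    push, write = scenario.push_rate, scenario.write_rate
    cap, vol = scenario.buffer_capacity, scenario.total_volume
    duty = _duty_cycle(scenario)

    if push == 0:
        return TransferOutcome(overflowed=False, non_terminating=True)

    t_prod = vol / push
    if push > write:
        peak = (push - write) * t_prod
        if peak > cap:
            return TransferOutcome(
                overflowed=True,
                time_to_overflow=(cap / (push - write)) / duty,
                peak_buffer=cap,
            )
        if write == 0:
            return TransferOutcome(overflowed=False, peak_buffer=peak, non_terminating=True)
        return TransferOutcome(overflowed=False, completion_time=(vol / write) / duty, peak_buffer=peak)

    # writer keeps up: buffer stays at the single in-flight study
    return TransferOutcome(
        overflowed=False, completion_time=t_prod / duty, peak_buffer=min(1.0, cap)
    )


def simulate_transfer_discrete(
    scenario: TransferScenario, max_events: int = 5_000_000
) -> TransferOutcome:
    """Study-granular discrete-event oracle for :func:`simulate_transfer`.

    Studies arrive one at a time at intervals ``1/push``; the writer
    removes one study every ``1/write`` hours while any are buffered.
    Overflow is declared when the buffer count exceeds capacity.  Supports
    duty-cycle-free scenarios only (the fluid model handles windows by a
    time rescale that would be identical here).
    """
    if scenario.nightly_window_hours is not None:
        raise ValueError("discrete oracle models full-time transfer only")
    push, write = scenario.push_rate, scenario.write_rate
    cap, vol = scenario.buffer_capacity, scenario.total_volume

    if push == 0:
        return TransferOutcome(overflowed=False, non_terminating=True)

    t = 0.0
    buffer = 0
    pushed = 0
    written = 0
    peak = 0
    next_push = 1.0 / push
    next_write = math.inf
    for _ in range(max_events):
        if written >= vol:
            return TransferOutcome(overflowed=False, completion_time=t, peak_buffer=peak)
        if pushed >= vol and write == 0:
            return TransferOutcome(overflowed=False, peak_buffer=peak, non_terminating=True)
        if next_push <= next_write:
            t = next_push
            pushed += 1
            buffer += 1
            peak = max(peak, buffer)
            if buffer > cap:
                return TransferOutcome(overflowed=True, time_to_overflow=t, peak_buffer=cap)
            next_push = t + 1.0 / push if pushed < vol else math.inf
            if next_write is math.inf and write > 0:
                next_write = t + 1.0 / write
        else:
            t = next_write
            if buffer > 0:
                buffer -= 1
                written += 1
            next_write = t + 1.0 / write if (buffer > 0 or pushed < vol) else math.inf
            if buffer == 0 and pushed >= vol:
                # nothing left to write
                if written >= vol:
                    return TransferOutcome(overflowed=False, completion_time=t, peak_buffer=peak)
    raise RuntimeError("event budget exhausted; scenario too large for the oracle")
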