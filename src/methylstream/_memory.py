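"""Instrumentation for the package's dense-block memory contract.

Every operation that materializes a dense numeric block from the on-disk
store funnels through :func:`track`, which records the block size and —
when a cap is armed — refuses blocks that exceed it.  Tests and the
acceptance checks use :func:`monitor` to assert that no public operation
ever holds a dense block larger than the configured ``max_block_elements``.
"""

from __future__ import annotations

import threading
from contextlib import contextmanager

__all__ = ["MemoryCapError", "track", "monitor", "peak_elements"]


class MemoryCapError(MemoryError):
    """A dense block larger than the armed element cap was requested."""


class _Monitor(threading.local):
    def __init__(self) -> None:
        self.peak = 0
        self.cap: int | None = None
        self.active = False


_state = _Monitor()


def track(n_elements: int) -> None:
    """Register the materialization of a dense block of ``n_elements``."""
    if n_elements > _state.peak:
        _state.peak = n_elements
    if _state.active and _state.cap is not None and n_elements > _state.cap:
        raise MemoryCapError(
            f"dense block of {n_elements} elements exceeds the armed cap "
            f"of {_state.cap} elements"
        )


def peak_elements() -> int:
    """Largest dense block registered since the monitor was last reset."""
    return _state.peak


@contextmanager
def monitor(cap: int | None = None):
    """Context manager that resets the peak counter and optionally arms a cap.

    Yields an object whose ``peak`` attribute holds the largest block (in
    elements) materialized inside the context.
    """

    class _Result:
        peak = 0

    prev_peak, prev_cap, prev_active = _state.peak, _state.cap, _state.active
    _state.peak, _state.cap, _state.active = 0, cap, True
    result = _Result()
    try:
        yield result
    finally:
        result.peak = _state.peak
        _state.peak = max(prev_peak, _state.peak)
        _state.cap, _state.active = prev_cap, prev_active
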