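"""Small shared helpers: clock-time formatting and circular arithmetic."""

from __future__ import annotations

import numpy as np

HOURS_PER_DAY = 24.0


def hours_to_clock(hours: float) -> str:
    """Format decimal hours since midnight as ``HH:MM``, rounded to the minute.

    Values wrap modulo 24 h, so 23.9999 rounds to ``"00:00"``. NaN maps to the
    empty string (used for undefined acrophases).
    """
    if hours is None or not np.isfinite(hours):
        return ""
    minutes = int(round(float(hours) * 60.0)) % (24 * 60)
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def circular_distance(a, b, period: float = HOURS_PER_DAY):
    """Shortest distance between clock times ``a`` and ``b`` on a circle."""
    d = np.mod(np.asarray(a, dtype=float) - b, period)
    return np.minimum(d, period - d)


def in_circular_window(t, start: float, end: float, period: float = HOURS_PER_DAY):
    """Membership of clock time(s) ``t`` in the half-open window [start, end).

    Windows with ``start > end`` wrap past midnight (e.g. 21.5–1.0).
    """
    t = np.mod(np.asarray(t, dtype=float), period)
    start = start % period
    end = end % period
    if start <= end:
        return (t >= start) & (t < end)
    return (t >= start) | (t < end)
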