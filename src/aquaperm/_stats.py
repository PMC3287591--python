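"""Shared aggregation helper (re-exported by :mod:`aquaperm.reporting`)."""

from __future__ import annotations

import math

__all__ = ["summarize"]


def summarize(values) -> tuple[float, float | None]:
    """Arithmetic mean and sample (n-1) standard deviation.

    This is the "Mean +/- SD" convention used for aggregating per-monomer
    results; with fewer than two values the SD is reported as ``None``
    (missing), never as zero.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("summarize requires at least one value")
    mean = sum(vals) / len(vals)
    if len(vals) < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    return mean, math.sqrt(var)
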