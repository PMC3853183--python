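"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, digits: int = 2) -> float:
    """Round half away from zero at ``digits`` decimals.

    Python's built-in ``round`` uses banker's rounding; report tables use the
    conventional half-away rule (2.005 -> 2.01, -2.005 -> -2.01). A tiny
    epsilon guards against representation error just below the .5 boundary.
    """
    if not math.isfinite(x):
        return x
    scale = 10.0**digits
    scaled = x * scale
    eps = math.copysign(1e-9, scaled)
    return math.floor(abs(scaled) + 0.5 + abs(eps)) / scale * math.copysign(1.0, x)


def format_pvalue(p: float, floor: float = 1e-4) -> str:
    """Render a p-value the way correlation tables print it.

    Values below ``floor`` are shown as ``<0.0001``; the numeric value is
    always stored at full precision elsewhere.
    """
    if p < floor:
        return f"<{floor:.4f}".rstrip("0").rstrip(".") if floor != 1e-4 else "<0.0001"
    return f"{p:.4f}"
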