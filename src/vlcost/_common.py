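"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for reported counts).

    Python's built-in ``round`` is banker's rounding; reported patient and
    test counts follow the usual half-up convention instead.
    """
    scale = 10.0 ** ndigits
    value = math.floor(abs(x) * scale + 0.5) / scale
    value = math.copysign(value, x)
    return value if ndigits > 0 else float(int(value))


def iround(x: float) -> int:
    """Round half away from zero to an int."""
    return int(round_half_away(x))
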