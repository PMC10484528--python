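"""Integer rounding primitives shared by the mapping and the emulator.

Every place the toolkit turns a real ratio into a hardware integer uses
truncation toward zero; this is the rounding mode that reproduces the
fixed-point chip's printed behaviour (e.g. a bias mantissa of 587 from
1175/2, and a decay parameter of 184 from 4096/22.2).
"""

from __future__ import annotations

import math

__all__ = ["trunc_toward_zero", "int_trunc_div"]

#: Relative slack used to recognise a float that is an integer up to IEEE
#: round-off before truncating.  Without it, quantities that are integers by
#: construction (e.g. a bias current calibrated to map to exactly 1175) could
#: truncate to the neighbour below after a division/multiplication round trip.
_SNAP_RTOL = 1e-9


def trunc_toward_zero(x: float) -> int:
    """Truncate ``x`` toward zero, snapping to an integer within round-off.

    Raises
    ------
    ValueError
        If ``x`` is NaN or infinite.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot truncate non-finite value {x!r}")
    nearest = round(x)
    if abs(x - nearest) <= _SNAP_RTOL * max(1.0, abs(x)):
        return int(nearest)
    return math.trunc(x)


def int_trunc_div(a: int, b: int) -> int:
    """Exact integer division truncated toward zero (unlike ``//`` which floors)."""
    if b <= 0:
        raise ValueError("divisor must be a positive integer")
    q = abs(a) // b
    return -q if a < 0 else q
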