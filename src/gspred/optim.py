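"""Small numerical helpers shared across modules."""

from __future__ import annotations

import math
from typing import Callable, Tuple

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def golden_section(
    f: Callable[[float], float], lo: float, hi: float, tol: float = 1e-8
) -> Tuple[float, float]:
    """Minimise a unimodal scalar function on [lo, hi].

    Returns (argmin, min).  A coarse bracketing scan precedes the golden
    search so a flat or multi-basin profile settles into its best basin.
    """
    grid = [lo + (hi - lo) * i / 32.0 for i in range(33)]
    vals = [f(x) for x in grid]
    k = min(range(len(grid)), key=lambda i: vals[i])
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]

    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    x = (a + b) / 2.0
    return x, f(x)


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed derived from string-able parts via CRC32."""
    import zlib

    s = "|".join(str(p) for p in parts)
    return zlib.crc32(s.encode()) & 0x7FFFFFFF
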