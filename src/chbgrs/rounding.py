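"""Decimal display conventions used by report tables and the risk-score model.

Two distinct two-decimal conventions coexist in this package:

* odds ratios and confidence-interval bounds are *truncated* toward zero
  (1.6577 -> 1.65), which is the convention that makes recomputed allele-test
  statistics agree digit-for-digit with the published candidate-gene tables;
* per-genotype risk scores are *rounded half away from zero* (0.245 -> 0.25),
  matching the published score tables.

Both go through a short fixed-point string first so that binary-float noise
(e.g. 1.72 stored as 1.71999...97) cannot flip the last digit.
"""

from __future__ import annotations

import math
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

__all__ = ["round2", "trunc2"]

# beyond this magnitude two-decimal display is meaningless; pass through
_HUGE = 1e12


def _dec(x: float) -> Decimal:
    return Decimal(f"{float(x):.9f}")


def round2(x: float) -> float:
    """Round to 2 decimals, ties away from zero (0.245 -> 0.25, -0.245 -> -0.25)."""
    if not math.isfinite(x) or abs(x) > _HUGE:
        return float(x)
    return float(_dec(x).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def trunc2(x: float) -> float:
    """Truncate to 2 decimals toward zero (1.6577 -> 1.65, -1.6577 -> -1.65)."""
    if not math.isfinite(x) or abs(x) > _HUGE:
        return float(x)
    return float(_dec(x).quantize(Decimal("0.01"), rounding=ROUND_DOWN))
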