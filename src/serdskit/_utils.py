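"""Small shared helpers: report rounding and per-stage seed derivation."""

from __future__ import annotations

import zlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention;
    Python's round() is banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def derive_seed(global_seed: int, stage: str) -> int:
    """Named, reproducible child seed for a pipeline stage (< 2**31)."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))
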