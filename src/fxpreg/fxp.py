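"""Fixed-point (Q-format) number system emulating hardware MAC arithmetic.

A value is stored as a two's-complement integer payload ``raw`` of ``M``
total bits, ``I`` of them (including the sign) above the binary point and
``F = M - I`` below; the real value is ``raw * 2**-F``.  The representable
range is ``[-2**(I-1), 2**(I-1) - 2**-F]`` with resolution ``2**-F``.

Multiply-accumulate chains follow DSP behavior: products are accumulated
*exactly* in a widened register and requantized once per output element.
Exactness is guaranteed for arbitrary word lengths by splitting one operand
into 16-bit halves so partial sums stay within int64, with the final combine
done in arbitrary-precision integers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FxpFormat",
    "FxpValue",
    "quantize",
    "quantize_array",
    "dequantize_array",
    "fxp_mac",
    "requantize",
    "requantize_array",
    "exact_matmul_raw",
    "accumulator_bits",
]

ROUND_NEAREST_EVEN = "nearest-even"
ROUND_TRUNCATE = "truncate"
OVERFLOW_SATURATE = "saturate"
OVERFLOW_WRAP = "wrap"


@dataclass(frozen=True)
class FxpFormat:
    """Word spec: M = I + F bits, I includes the sign bit."""

    total_bits: int
    integer_bits: int
    rounding: str = ROUND_NEAREST_EVEN
    overflow: str = OVERFLOW_SATURATE

    def __post_init__(self) -> None:
        if self.total_bits < 2 or not (1 <= self.integer_bits <= self.total_bits):
            raise ValueError("need total_bits >= 2 and 1 <= I <= M")
        if self.rounding not in (ROUND_NEAREST_EVEN, ROUND_TRUNCATE):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")
        if self.overflow not in (OVERFLOW_SATURATE, OVERFLOW_WRAP):
            raise ValueError(f"unknown overflow mode {self.overflow!r}")

    @property
    def frac_bits(self) -> int:
        return self.total_bits - self.integer_bits

    @property
    def resolution(self) -> float:
        return 2.0 ** -self.frac_bits

    @property
    def raw_min(self) -> int:
        return -(1 << (self.total_bits - 1))

    @property
    def raw_max(self) -> int:
        return (1 << (self.total_bits - 1)) - 1

    @property
    def min_value(self) -> float:
        return self.raw_min * self.resolution

    @property
    def max_value(self) -> float:
        return self.raw_max * self.resolution

    def spec_string(self) -> str:
        return f"Q{self.integer_bits}.{self.frac_bits}"

    @staticmethod
    def from_string(s: str, **kw) -> "FxpFormat":
        """Parse a 'QI.F' spec string, e.g. 'Q4.16' for a 20-bit word."""
        m = re.fullmatch(r"[Qq](\d+)\.(\d+)", s.strip())
        if not m:
            raise ValueError(f"not a QI.F format string: {s!r}")
        i, f = int(m.group(1)), int(m.group(2))
        return FxpFormat(total_bits=i + f, integer_bits=i, **kw)


@dataclass(frozen=True)
class FxpValue:
    """A quantized scalar: integer payload plus its format."""

    raw: int
    fmt: FxpFormat

    def __post_init__(self) -> None:
        if not (self.fmt.raw_min <= self.raw <= self.fmt.raw_max):
            raise ValueError("raw payload outside the format's word range")

    @property
    def value(self) -> float:
        return self.raw * self.fmt.resolution


def _round_raw(scaled: np.ndarray, rounding: str) -> np.ndarray:
    """Round real numbers already scaled by 2**F to integer codes."""
    if rounding == ROUND_NEAREST_EVEN:
        return np.rint(scaled)
    return np.floor(scaled)  # truncation = drop fraction bits = floor


def _apply_overflow(raw, fmt: FxpFormat):
    if fmt.overflow == OVERFLOW_SATURATE:
        return np.clip(raw, fmt.raw_min, fmt.raw_max)
    span = 1 << fmt.total_bits
    return (raw - fmt.raw_min) % span + fmt.raw_min


def quantize_array(x, fmt: FxpFormat) -> np.ndarray:
    """Quantize floats to int64 raw codes under the format's modes."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot quantize non-finite values")
    scaled = x * (2.0 ** fmt.frac_bits)
    raw = _round_raw(scaled, fmt.rounding)
    raw = _apply_overflow(raw, fmt)
    return raw.astype(np.int64)


def dequantize_array(raw, fmt: FxpFormat) -> np.ndarray:
    return np.asarray(raw, dtype=float) * fmt.resolution


def quantize(x: float, fmt: FxpFormat) -> FxpValue:
    """Nearest representable value (or truncation), saturating or wrapping."""
    return FxpValue(int(quantize_array(np.float64(x), fmt)), fmt)


def accumulator_bits(fmt: FxpFormat, n_terms: int) -> int:
    """Width guaranteeing exact accumulation of ``n_terms`` full products."""
    return 2 * fmt.total_bits + int(np.ceil(np.log2(max(n_terms, 2))))


def fxp_mac(acc: int, a: FxpValue, b: FxpValue) -> int:
    """One exact multiply-accumulate step on the wide accumulator.

    ``acc`` carries fraction scale ``a.fmt.frac_bits + b.fmt.frac_bits``;
    Python integers make the accumulation exact at any width.
    """
    if a.fmt.frac_bits != b.fmt.frac_bits or a.fmt.total_bits != b.fmt.total_bits:
        raise ValueError("mac operands must share a format")
    return int(acc) + int(a.raw) * int(b.raw)


def requantize(acc: int, in_fmt, out_fmt: FxpFormat) -> FxpValue:
    """Store-back after a MAC chain: product scale 2**-2F -> output scale.

    ``in_fmt`` is the operand format (accumulator fraction bits = 2F) or,
    when an int is given, the accumulator's fraction-bit count directly.
    """
    acc_frac = 2 * in_fmt.frac_bits if isinstance(in_fmt, FxpFormat) else int(in_fmt)
    arr = np.empty(1, dtype=object)
    arr[0] = int(acc)
    raw = requantize_array(arr, acc_frac, out_fmt)
    return FxpValue(int(raw[0]), out_fmt)


def requantize_array(acc, acc_frac_bits: int, fmt: FxpFormat) -> np.ndarray:
    """Shift exact accumulators to the output scale, round, and saturate/wrap.

    ``acc`` is an object ndarray of exact Python ints at fraction scale
    ``acc_frac_bits``; the result is int64 raw codes in ``fmt``.
    """
    acc = np.asarray(acc, dtype=object)
    shift = acc_frac_bits - fmt.frac_bits
    if shift < 0:
        raw = acc << (-shift)
    elif shift == 0:
        raw = acc
    else:
        q0 = acc >> shift  # floor shift, exact for negatives
        if fmt.rounding == ROUND_TRUNCATE:
            raw = q0
        else:
            r = acc - (q0 << shift)
            half = 1 << (shift - 1)
            inc = (r > half) | ((r == half) & ((q0 & 1) == 1))
            raw = q0 + inc
    raw = _apply_overflow(raw, fmt)
    out = np.empty(raw.shape, dtype=np.int64)
    out[...] = raw
    return out


def exact_matmul_raw(a_raw: np.ndarray, b_raw: np.ndarray) -> np.ndarray:
    """Exact integer matmul of raw codes, any word length up to 32 bits.

    Splits ``b`` into 16-bit halves so both partial int64 matmuls are
    provably overflow-free for the layer sizes used here, then recombines in
    arbitrary precision.  Result is an object ndarray of exact Python ints
    at fraction scale F_a + F_b.
    """
    a = np.asarray(a_raw, dtype=np.int64)
    b = np.asarray(b_raw, dtype=np.int64)
    k = a.shape[-1]
    # Partial-sum bounds: |a| < 2^31, |b_hi| <= 2^15, |b_lo| < 2^16.
    if int(np.abs(a).max(initial=0)) * (1 << 16) * k >= (1 << 62):
        raise OverflowError("accumulator width exceeded")  # unreachable for
        # the network's layer sizes (k <= 784, |raw| < 2**31)
    b_hi = b >> 16
    b_lo = b & 0xFFFF
    s_hi = a @ b_hi
    s_lo = a @ b_lo
    return s_hi.astype(object) * 65536 + s_lo.astype(object)
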