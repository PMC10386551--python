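"""Bit-accurate fixed-point forward pass and the bit-width sweep study.

The quantized pipeline mirrors the float network operation for operation:
inputs are quantized on entry; every convolution / fully connected output
element is an exact wide-accumulator MAC over raw integer codes followed by a
single requantization; ReLU and max pooling act directly on raw codes (both
are exact in fixed point); the three head outputs are emitted sequentially.

Word lengths follow the hardware study presets (32, 28, 20, 18, 16 total
bits).  The integer/fraction split is calibrated per tensor class — input,
each weight/bias tensor, each layer's activations, outputs — as the smallest
integer width covering the float dynamic range observed on a calibration
batch, shared across all word lengths so that a sweep varies only the
fraction resolution 2**-F.

Error metrics in the sweep compare quantized predictions against the *float
model's* predictions (the software-reference convention), not against ground
truth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from . import fxp
from .fxp import FxpFormat, exact_matmul_raw, quantize_array, requantize_array
from .model import NetworkWeights, _im2col, forward_batch, maxpool_2x2

__all__ = [
    "SWEEP_PRESETS",
    "QuantizedModel",
    "quantize_model",
    "forward_fxp",
    "forward_fxp_batch",
    "mac_counts",
    "conv_mac_count",
    "bitwidth_sweep",
    "SweepReport",
]

#: The bit-width study configurations, float reference first.
SWEEP_PRESETS = ("fp32", "fxp32", "fxp28", "fxp20", "fxp18", "fxp16")

HEADS = ("rot", "dx", "dy")

# Tensor classes that get an individually calibrated integer width.
_CLASSES = (
    "input",
    "conv1_w",
    "conv1_b",
    "act1",
    "conv2_w",
    "conv2_b",
    "act2",
    "head_w",
    "output",
)


@dataclass
class QuantizedModel:
    """Weights as raw integer codes plus the per-class formats."""

    total_bits: int
    formats: dict  # class name -> FxpFormat
    raw: dict  # tensor name -> int64 ndarray
    calibration: dict  # class name -> {"max_abs": float, "integer_bits": int}

    def fmt(self, cls: str) -> FxpFormat:
        return self.formats[cls]

    def dequantized_weights(self) -> NetworkWeights:
        """The quantized weights mapped back to floats (grid values)."""
        g = {
            "conv1_w": "conv1_w",
            "conv1_b": "conv1_b",
            "conv2_w": "conv2_w",
            "conv2_b": "conv2_b",
            "head_rot_w": "head_w",
            "head_dx_w": "head_w",
            "head_dy_w": "head_w",
        }
        return NetworkWeights(
            **{
                name: fxp.dequantize_array(self.raw[name], self.fmt(cls))
                for name, cls in g.items()
            }
        )


def _integer_bits_for(max_abs: float) -> int:
    """Smallest signed integer width whose range covers ``[-m, m]``."""
    if max_abs <= 0:
        return 1
    return max(1, int(np.floor(np.log2(max_abs))) + 2)


def quantize_model(
    w: NetworkWeights,
    fmt,
    calib: np.ndarray,
    rounding: str = fxp.ROUND_NEAREST_EVEN,
    overflow: str = fxp.OVERFLOW_SATURATE,
) -> QuantizedModel:
    """Quantize weights and calibrate activation formats.

    ``fmt`` is a total bit width (int), a preset string like ``"fxp20"``, or
    a ``"QI.F"`` string forcing one split for every class.  ``calib`` is a
    non-empty batch of (B,32,32,3) normalized inputs whose float activations
    define each class's dynamic range.
    """
    forced_I = None
    if isinstance(fmt, str):
        s = fmt.lower().strip()
        if s.startswith("fxp"):
            total_bits = int(s[3:])
        else:
            f = FxpFormat.from_string(fmt)
            total_bits, forced_I = f.total_bits, f.integer_bits
    elif isinstance(fmt, FxpFormat):
        total_bits, forced_I = fmt.total_bits, fmt.integer_bits
    else:
        total_bits = int(fmt)
    calib = np.asarray(calib, dtype=float)
    if calib.ndim != 4 or calib.shape[0] < 1:
        raise ValueError("calibration batch must be non-empty (B,32,32,3)")

    # Float activations on the calibration batch define the dynamic ranges.
    cache: dict = {}
    forward_batch(w, calib, cache=cache)
    max_abs = {
        "input": float(np.abs(calib).max()),
        "conv1_w": float(np.abs(w.conv1_w).max()),
        "conv1_b": float(np.abs(w.conv1_b).max()),
        "act1": float(np.abs(cache["a1"]).max()),
        "conv2_w": float(np.abs(w.conv2_w).max()),
        "conv2_b": float(np.abs(w.conv2_b).max()),
        "act2": float(np.abs(cache["a2"]).max()),
        "head_w": float(np.abs(w.heads()).max()),
        "output": float(np.abs(cache["y"]).max()),
    }

    formats, calibration = {}, {}
    for cls in _CLASSES:
        ibits = forced_I if forced_I is not None else _integer_bits_for(max_abs[cls])
        if ibits >= total_bits:
            raise ValueError(
                f"dynamic range of {cls} (|x| <= {max_abs[cls]:.3g}) needs "
                f"{ibits} integer bits, infeasible for a {total_bits}-bit word"
            )
        formats[cls] = FxpFormat(total_bits, ibits, rounding, overflow)
        calibration[cls] = {"max_abs": max_abs[cls], "integer_bits": ibits}

    raw = {
        "conv1_w": quantize_array(w.conv1_w, formats["conv1_w"]),
        "conv1_b": quantize_array(w.conv1_b, formats["conv1_b"]),
        "conv2_w": quantize_array(w.conv2_w, formats["conv2_w"]),
        "conv2_b": quantize_array(w.conv2_b, formats["conv2_b"]),
        "head_rot_w": quantize_array(w.head_rot_w, formats["head_w"]),
        "head_dx_w": quantize_array(w.head_dx_w, formats["head_w"]),
        "head_dy_w": quantize_array(w.head_dy_w, formats["head_w"]),
    }
    return QuantizedModel(total_bits, formats, raw, calibration)


def _conv_fxp(
    x_raw: np.ndarray,
    x_fmt: FxpFormat,
    w_raw: np.ndarray,
    w_fmt: FxpFormat,
    b_raw: np.ndarray,
    b_fmt: FxpFormat,
    out_fmt: FxpFormat,
) -> np.ndarray:
    """One quantized conv layer: exact MACs + bias, one requantize, on raw codes."""
    k = w_raw.shape[0]
    n_in, n_out = w_raw.shape[2], w_raw.shape[3]
    cols = _im2col(x_raw, k)
    b, oh, ow = cols.shape[:3]
    acc_frac = x_fmt.frac_bits + w_fmt.frac_bits
    acc = exact_matmul_raw(
        cols.reshape(-1, k * k * n_in), w_raw.reshape(k * k * n_in, n_out)
    )
    bias_shift = acc_frac - b_fmt.frac_bits
    if bias_shift < 0:
        raise ValueError("bias format finer than the accumulator scale")
    acc = acc + (b_raw.astype(object) << bias_shift)
    out_raw = requantize_array(acc, acc_frac, out_fmt)
    return out_raw.reshape(b, oh, ow, n_out)


def forward_fxp_batch(qm: QuantizedModel, x: np.ndarray) -> np.ndarray:
    """Quantized inference on a (B,32,32,3) batch -> (B,3) dequantized floats."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 4 or x.shape[1:] != (32, 32, 3):
        raise ValueError("input batch must have shape (B, 32, 32, 3)")
    f = qm.fmt
    xq = quantize_array(x, f("input"))

    a1 = _conv_fxp(
        xq, f("input"), qm.raw["conv1_w"], f("conv1_w"),
        qm.raw["conv1_b"], f("conv1_b"), f("act1"),
    )
    p1 = maxpool_2x2(np.maximum(a1, 0))  # ReLU and max are exact on raw codes

    a2 = _conv_fxp(
        p1, f("act1"), qm.raw["conv2_w"], f("conv2_w"),
        qm.raw["conv2_b"], f("conv2_b"), f("act2"),
    )
    p2 = maxpool_2x2(np.maximum(a2, 0))
    flat = p2.reshape(x.shape[0], 784)

    acc_frac = f("act2").frac_bits + f("head_w").frac_bits
    outs = []
    for name in ("head_rot_w", "head_dx_w", "head_dy_w"):  # sequential heads
        acc = exact_matmul_raw(flat, qm.raw[name][:, None])
        raw = requantize_array(acc, acc_frac, f("output"))
        outs.append(fxp.dequantize_array(raw[:, 0], f("output")))
    return np.stack(outs, axis=1)


def forward_fxp(qm: QuantizedModel, x: np.ndarray):
    """Quantized inference on one image; returns a float-valued Prediction."""
    from .model import Prediction

    x = np.asarray(x, dtype=float)
    if x.shape != (32, 32, 3):
        raise ValueError("input must have shape (32, 32, 3)")
    y = forward_fxp_batch(qm, x[None])[0]
    return Prediction(*map(float, y))


def conv_mac_count(k: int, n_in: int, n_out: int) -> int:
    """Parallel multiplications per output pixel: k*k*N*M."""
    return k * k * n_in * n_out


def mac_counts() -> dict:
    """Per-layer parallel multiplication counts of the architecture."""
    return {
        "conv1": conv_mac_count(2, 3, 8),
        "conv2": conv_mac_count(2, 8, 16),
        "fc_per_output": 784,
    }


# ---------------------------------------------------------------------------
# Bit-width sweep (the float-vs-quantized comparison study)
# ---------------------------------------------------------------------------


@dataclass
class SweepReport:
    """Per-format regression metrics of quantized vs float predictions."""

    rows: list = field(default_factory=list)  # dicts: format/head/metrics
    predictions: dict = field(default_factory=dict)  # format -> (B,3) array
    calibration: dict = field(default_factory=dict)  # format -> calib record

    def metric(self, fmt_name: str, head: str, metric: str) -> float:
        for r in self.rows:
            if r["format"] == fmt_name and r["head"] == head:
                return r[metric]
        raise KeyError((fmt_name, head, metric))

    def to_json(self) -> str:
        return json.dumps(
            {"rows": self.rows, "calibration": self.calibration}, indent=1
        )

    def write(self, json_path=None, csv_path=None) -> None:
        if json_path is not None:
            with open(json_path, "w") as fh:
                fh.write(self.to_json())
        if csv_path is not None:
            cols = [
                "format", "head", "mae", "mse", "rmse", "r2",
                "resolution", "q_split",
            ]
            with open(csv_path, "w", newline="") as fh:
                wtr = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
                wtr.writeheader()
                wtr.writerows(self.rows)

    def prediction_table(self) -> list:
        """Per-image predictions for every format (plot-ready layout)."""
        table = []
        fmts = list(self.predictions)
        n = len(next(iter(self.predictions.values())))
        for i in range(n):
            row = {"index": i}
            for f in fmts:
                for j, h in enumerate(HEADS):
                    row[f"{h}_{f}"] = float(self.predictions[f][i, j])
            table.append(row)
        return table


def bitwidth_sweep(
    w: NetworkWeights,
    testset,
    formats=SWEEP_PRESETS,
    calib: np.ndarray | None = None,
) -> SweepReport:
    """Run float and quantized inference over ``testset`` for each format.

    ``testset`` is a list of ImagePair (>= 1); metrics treat the float
    predictions as the reference.  The calibration batch defaults to the test
    inputs themselves.
    """
    from .metrics import regression_metrics
    from .phantom import concat_pair

    formats = list(formats)
    if not formats:
        raise ValueError("format list must be non-empty")
    x = np.stack([concat_pair(p.fixed, p.moving) for p in testset])
    if calib is None:
        calib = x
    ref = forward_batch(w, x)

    report = SweepReport()
    for name in formats:
        if name == "fp32":
            pred = ref.copy()
            report.calibration[name] = None
            resolution = 0.0
            split = "float"
        else:
            qm = quantize_model(w, name, calib)
            pred = forward_fxp_batch(qm, x)
            report.calibration[name] = qm.calibration
            resolution = qm.fmt("output").resolution
            split = qm.fmt("output").spec_string()
        report.predictions[name] = pred
        for j, head in enumerate(HEADS):
            mae, mse, rmse, r2 = regression_metrics(ref[:, j], pred[:, j])
            report.rows.append(
                {
                    "format": name,
                    "head": head,
                    "mae": mae,
                    "mse": mse,
                    "rmse": rmse,
                    "r2": r2,
                    "resolution": resolution,
                    "q_split": split,
                }
            )
    return report
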