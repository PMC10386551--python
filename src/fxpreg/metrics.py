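"""Regression and image-similarity metrics, and the warp-and-compare study.

Regression metrics are the standard closed forms:

    MSE  = mean((y - yhat)^2)         MAE  = mean(|y - yhat|)
    RMSE = sqrt(MSE)                  R^2  = 1 - SS_res / SS_tot

PSNR is ``10 log10(MAX^2 / MSE)`` in dB (MAX = 1 for the package's
normalized floats; 255 available for 8-bit comparisons).  SSIM uses the
standard parameterization: 11x11 Gaussian window with sigma 1.5, exponents
alpha = beta = gamma = 1, stabilizers C1 = (0.01 MAX)^2, C2 = (0.03 MAX)^2,
delegated to scikit-image.  Multi-channel images are compared on their
channel mean (channels are replicas here).
"""

from __future__ import annotations

import math

import numpy as np
from skimage.metrics import structural_similarity

from .model import NetworkWeights, forward_float
from .phantom import ImagePair
from .qinference import QuantizedModel, forward_fxp
from .rigid import RigidParams, image_center, params_to_matrix, warp_image

__all__ = [
    "regression_metrics",
    "psnr",
    "ssim",
    "warp_compare",
]


def regression_metrics(y, yhat) -> tuple[float, float, float, float]:
    """Return (MAE, MSE, RMSE, R^2) of predictions against reference values."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("inputs must be equal-length non-empty vectors")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ZeroDivisionError("R^2 undefined: reference has zero variance")
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return mae, mse, rmse, r2


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    return img.mean(axis=2) if img.ndim == 3 else img


def psnr(a: np.ndarray, b: np.ndarray, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give ``inf``."""
    a, b = _to_gray(a), _to_gray(b)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(max_value**2 / mse)


def ssim(a: np.ndarray, b: np.ndarray, max_value: float = 1.0) -> float:
    """Mean structural similarity over 11x11 Gaussian windows (sigma 1.5)."""
    a, b = _to_gray(a), _to_gray(b)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if min(a.shape) < 11:
        raise ValueError("images smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            a,
            b,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=max_value,
        )
    )


def warp_compare(
    w: NetworkWeights, qm: QuantizedModel, pair: ImagePair
) -> dict:
    """Warp the moving image with the float and the quantized prediction.

    Denormalizes both predictions, applies each resulting rigid transform to
    the moving image (I_WS from the float model, I_WH from the fixed-point
    model), and reports SSIM, PSNR and the absolute difference map between
    the two warped images.
    """
    from .phantom import concat_pair

    x = concat_pair(pair.fixed, pair.moving)
    center = image_center(pair.moving)

    def warp_with(pred) -> np.ndarray:
        p = RigidParams.from_normalized(pred.as_array())
        return warp_image(pair.moving, params_to_matrix(p, center))

    i_ws = warp_with(forward_float(w, x))
    i_wh = warp_with(forward_fxp(qm, x))
    return {
        "i_ws": i_ws,
        "i_wh": i_wh,
        "ssim": ssim(i_ws, i_wh),
        "psnr": psnr(i_ws, i_wh),
        "diff": np.abs(i_ws - i_wh),
    }
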