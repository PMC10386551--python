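"""Independent naive-loop reference implementations used as test oracles.

These are deliberately written as plain nested loops over the mathematical
definitions, sharing no code path with the package's vectorized versions.
"""

import math

import numpy as np


def naive_conv2d(x, kernels, biases):
    """Six-nested-loop valid cross-correlation (stride 1)."""
    h, w, n_in = x.shape
    k = kernels.shape[0]
    n_out = kernels.shape[3]
    oh, ow = h - k + 1, w - k + 1
    out = np.zeros((oh, ow, n_out))
    for m in range(n_out):
        for r in range(oh):
            for c in range(ow):
                acc = biases[m]
                for n in range(n_in):
                    for i in range(k):
                        for j in range(k):
                            acc += x[r + i, c + j, n] * kernels[i, j, n, m]
                out[r, c, m] = acc
    return out


def naive_maxpool(x):
    """Loop-based 2x2/stride-2 max pooling, trailing odd row/col dropped."""
    h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    out = np.zeros((h2, w2, c))
    for ch in range(c):
        for r in range(h2):
            for cc in range(w2):
                out[r, cc, ch] = max(
                    x[2 * r, 2 * cc, ch],
                    x[2 * r, 2 * cc + 1, ch],
                    x[2 * r + 1, 2 * cc, ch],
                    x[2 * r + 1, 2 * cc + 1, ch],
                )
    return out


def naive_forward(weights, x):
    """Reference forward pass built only from the naive layers above."""
    a = naive_conv2d(x, weights.conv1_w, weights.conv1_b)
    a = np.maximum(a, 0)
    a = naive_maxpool(a)
    a = naive_conv2d(a, weights.conv2_w, weights.conv2_b)
    a = np.maximum(a, 0)
    a = naive_maxpool(a)
    flat = a.reshape(-1)
    return np.array(
        [
            float(sum(flat[i] * weights.head_rot_w[i] for i in range(784))),
            float(sum(flat[i] * weights.head_dx_w[i] for i in range(784))),
            float(sum(flat[i] * weights.head_dy_w[i] for i in range(784))),
        ]
    )


def naive_regression_metrics(y, yhat):
    """Loop-based MAE/MSE/RMSE/R^2."""
    n = len(y)
    mae = sum(abs(a - b) for a, b in zip(y, yhat)) / n
    mse = sum((a - b) ** 2 for a, b in zip(y, yhat)) / n
    ybar = sum(y) / n
    ss_tot = sum((a - ybar) ** 2 for a in y)
    r2 = 1.0 - sum((a - b) ** 2 for a, b in zip(y, yhat)) / ss_tot
    return mae, mse, math.sqrt(mse), r2
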