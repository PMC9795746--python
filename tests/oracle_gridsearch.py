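"""Independent log-grid-search oracle for saturation-curve least squares.

Used to cross-check the package's nonlinear fits: exhaustive evaluation of
the sum-of-squares objective on a log-spaced (scale, half-saturation) grid,
followed by Nelder-Mead refinement from the grid optimum.  Deliberately a
different optimization route from the fit under test.
"""

import numpy as np
from scipy.optimize import minimize


def gridsearch_ss(x, y, n_grid=400):
    """Best objective value for y ~ scale * x / (half + x) by grid + refine."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scale0 = max(y.max(), 1e-300)
    half0 = np.median(x)
    scales = scale0 * np.logspace(-3, 3, n_grid)
    halves = half0 * np.logspace(-3, 3, n_grid)
    pred = scales[:, None, None] * x[None, None, :] / (halves[None, :, None] + x[None, None, :])
    ss = ((pred - y[None, None, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(ss), ss.shape)

    def objective(logp):
        s, h = np.exp(logp)
        return float(((s * x / (h + x) - y) ** 2).sum())

    res = minimize(
        objective,
        x0=np.log([scales[i], halves[j]]),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
    )
    return min(float(ss[i, j]), float(res.fun))
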