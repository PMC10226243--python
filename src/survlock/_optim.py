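"""Deterministic quasi-Newton maximization with a simplex polish.

L-BFGS-B with finite-difference gradients occasionally terminates with an
abnormal line search when it is already at the optimum to near machine
precision; a short Nelder-Mead polish from the incumbent both certifies
and sharpens the solution without introducing randomness.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

BAD = 1e12


def minimize_multistart(fun, starts):
    """Minimize ``fun`` from each start; polish the best; return (x, f, ok)."""
    best = None
    for x0 in starts:
        res = optimize.minimize(
            fun, x0, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    polish = optimize.minimize(
        fun, best.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000, "maxfev": 4000},
    )
    if polish.fun <= best.fun:
        x, f = polish.x, polish.fun
        ok = bool((best.success or polish.success) and f < BAD / 2)
    else:
        x, f = best.x, best.fun
        ok = bool(best.success and f < BAD / 2)
    return np.asarray(x, dtype=float), float(f), ok
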