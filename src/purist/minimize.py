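"""Nonlinear conjugate-gradient minimizer with Wolfe-Powell line search.

Polak-Ribiere conjugate directions with a line search built from
quadratic and cubic polynomial interpolations/extrapolations, accepting a
step only when the Wolfe-Powell conditions (sufficient decrease and a
curvature test on the directional derivative) hold.

Trial points may fall outside the objective's domain and come back with
infinite or NaN values and derivatives.  All line-search comparisons
therefore use NaN-tolerant operators that report ``False`` whenever an
operand is not-a-number, so an out-of-domain trial simply fails the
acceptance tests and the search contracts toward the last good point
instead of aborting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LineSearchOptions",
    "MinimizeResult",
    "minimize",
    "nan_safe_less",
    "nan_safe_greater",
]


def nan_safe_less(a: float, b: float) -> bool:
    """Strict ``a < b`` that is ``False`` whenever either operand is NaN."""
    if math.isnan(a) or math.isnan(b):
        return False
    return a < b


def nan_safe_greater(a: float, b: float) -> bool:
    """Strict ``a > b`` that is ``False`` whenever either operand is NaN."""
    if math.isnan(a) or math.isnan(b):
        return False
    return a > b


@dataclass
class LineSearchOptions:
    """Tunable constants of the line search.

    ``suff_decrease`` and ``curvature`` are the Wolfe-Powell constants;
    ``interp_limit`` keeps interpolated points away from the bracket
    boundaries; ``extrapolate`` caps extrapolation at that multiple of the
    current step; ``max_evals_per_search`` bounds the cost of a single
    line search; ``slope_ratio`` caps the step growth between searches.
    """

    suff_decrease: float = 0.1
    curvature: float = 0.05
    interp_limit: float = 0.1
    extrapolate: float = 3.0
    max_evals_per_search: int = 20
    slope_ratio: float = 100.0


@dataclass
class MinimizeResult:
    x_opt: np.ndarray
    f_history: np.ndarray  # accepted function values, non-increasing
    n_evals: int


def minimize(objective, x0, length: int, options: LineSearchOptions | None = None
             ) -> MinimizeResult:
    """Minimize ``objective(x) -> (value, gradient)`` from ``x0``.

    ``length`` is the budget: positive counts line searches, negative
    counts function/gradient evaluations.  The routine returns the best
    point found when the budget is exhausted or when two consecutive line
    searches fail.  Accepted function values are non-increasing.
    """
    if length == 0:
        raise ValueError("budget must be nonzero")
    o = options or LineSearchOptions()
    x = np.array(x0, dtype=float)
    if x.size == 0:
        return MinimizeResult(x, np.empty(0), 0)
    i = 0
    f1, df1 = objective(x)
    f1 = float(f1)
    df1 = np.asarray(df1, dtype=float).copy()
    n_evals = 1
    if not (np.isfinite(f1) and np.all(np.isfinite(df1))):
        raise FloatingPointError("objective is non-finite at the starting point")
    f_history = [f1]
    if length < 0:
        i += 1

    # trial points may carry inf/NaN values and gradients by design
    old_err = np.seterr(over="ignore", invalid="ignore", divide="ignore")
    try:
        return _descend(objective, x, f1, df1, f_history, n_evals, i, length, o)
    finally:
        np.seterr(**old_err)


def _descend(objective, x, f1, df1, f_history, n_evals, i, length, o):
    RHO, SIG = o.suff_decrease, o.curvature
    INT, EXT = o.interp_limit, o.extrapolate
    MAX, RATIO = o.max_evals_per_search, o.slope_ratio
    ls_failed = False
    s = -df1
    d1 = float(-(s @ s))
    z1 = 1.0 / (1.0 - d1)
    while i < abs(length):
        if length > 0:
            i += 1
        x_prev, f_prev, df_prev = x.copy(), f1, df1.copy()
        x = x + z1 * s
        f2, df2 = objective(x)
        f2 = float(f2)
        df2 = np.asarray(df2, dtype=float)
        n_evals += 1
        if length < 0:
            i += 1
        d2 = float(df2 @ s)
        f3, d3, z3 = f1, d1, -z1
        M = MAX if length > 0 else min(MAX, -length - i)
        success = False
        limit = -1.0

        while True:
            # contract while the Wolfe-Powell tests fail or the trial is
            # outside the domain (non-finite value)
            while (
                nan_safe_greater(f2, f1 + z1 * RHO * d1)
                or nan_safe_greater(d2, -SIG * d1)
                or not math.isfinite(f2)
            ) and M > 0:
                limit = z1
                if nan_safe_greater(f2, f1):
                    # quadratic fit through (0, f3, d3) and (z3, f2)
                    denom = d3 * z3 + f2 - f3
                    z2 = z3 - (0.5 * d3 * z3 * z3) / denom if denom != 0 else math.nan
                else:
                    # cubic fit
                    A = 6.0 * (f2 - f3) / z3 + 3.0 * (d2 + d3)
                    Bq = 3.0 * (f3 - f2) - z3 * (d3 + 2.0 * d2)
                    disc = Bq * Bq - A * d2 * z3 * z3
                    if disc >= 0 and A != 0:
                        z2 = (math.sqrt(disc) - Bq) / A
                    else:
                        z2 = math.nan
                if not math.isfinite(z2):
                    z2 = z3 / 2.0  # bisect on numerical trouble
                z2 = max(min(z2, INT * z3), (1.0 - INT) * z3)
                z1 += z2
                x = x + z2 * s
                f2, df2 = objective(x)
                f2 = float(f2)
                df2 = np.asarray(df2, dtype=float)
                M -= 1
                n_evals += 1
                if length < 0:
                    i += 1
                d2 = float(df2 @ s)
                z3 = z3 - z2

            if (
                nan_safe_greater(f2, f1 + z1 * RHO * d1)
                or nan_safe_greater(d2, -SIG * d1)
                or not math.isfinite(f2)
            ):
                break  # line search failed
            if nan_safe_greater(d2, SIG * d1) and math.isfinite(f2):
                success = True
                break
            if M == 0:
                break
            # cubic extrapolation
            A = 6.0 * (f2 - f3) / z3 + 3.0 * (d2 + d3)
            Bq = 3.0 * (f3 - f2) - z3 * (d3 + 2.0 * d2)
            disc = Bq * Bq - A * d2 * z3 * z3
            if disc >= 0 and (Bq + math.sqrt(disc)) != 0:
                z2 = -d2 * z3 * z3 / (Bq + math.sqrt(disc))
            else:
                z2 = math.nan
            if not math.isfinite(z2) or z2 < 0:
                z2 = z1 * (EXT - 1.0) if limit < -0.5 else (limit - z1) / 2.0
            elif limit > -0.5 and z2 + z1 > limit:
                z2 = (limit - z1) / 2.0
            elif limit < -0.5 and z2 + z1 > z1 * EXT:
                z2 = z1 * (EXT - 1.0)
            elif z2 < -z3 * INT:
                z2 = -z3 * INT
            elif limit > -0.5 and z2 < (limit - z1) * (1.0 - INT):
                z2 = (limit - z1) * (1.0 - INT)
            f3, d3, z3 = f2, d2, -z2
            z1 += z2
            x = x + z2 * s
            f2, df2 = objective(x)
            f2 = float(f2)
            df2 = np.asarray(df2, dtype=float)
            M -= 1
            n_evals += 1
            if length < 0:
                i += 1
            d2 = float(df2 @ s)

        if success:
            f1 = f2
            f_history.append(f1)
            # Polak-Ribiere direction update
            beta = float((df2 @ df2 - df1 @ df2) / (df1 @ df1))
            s = beta * s - df2
            df1 = df2.copy()
            d2 = float(df1 @ s)
            if d2 > 0:  # conjugacy lost: restart with steepest descent
                s = -df1
                d2 = float(-(s @ s))
            z1 = z1 * min(RATIO, d1 / (d2 - np.finfo(float).tiny))
            d1 = d2
            ls_failed = False
        else:
            # restore the best point and retry with steepest descent
            x, f1, df1 = x_prev, f_prev, df_prev
            if ls_failed or i > abs(length):
                break
            s = -df1
            d1 = float(-(s @ s))
            z1 = 1.0 / (1.0 - d1)
            ls_failed = True

    return MinimizeResult(x, np.asarray(f_history), n_evals)
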