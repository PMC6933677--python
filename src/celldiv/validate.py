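"""Cross-validation battery: analytic, FSP, and stochastic routes against each other.

Each check returns a measured discrepancy and a pass/fail against a fixed
threshold; the battery is the package's internal consistency contract
(closed form vs FSP, quadrature recursion vs FSP, SSA vs FSP moments,
added-size noise, adder regression, translation periodicity, and the
division-count variance plateau).
"""

from __future__ import annotations

import numpy as np

from .core import InitialSizeSpec, ModelParams
from .master_equation import (
    DEFAULT_ODE_TOL,
    default_time_grid,
    fsp_auto_truncate,
    fsp_propagate,
    moments_n,
    p0_closed_form,
    p_i_recursive,
    periodicity_residual,
)
from .simulate import SimulationConfig, simulate_ensemble
from .size_stats import size_moments

__all__ = ["run_validation", "adder_regression"]


def _check(name, value, passed, threshold, note=""):
    return {
        "name": name,
        "value": float(value),
        "threshold": threshold,
        "passed": bool(passed),
        "note": note,
    }


def adder_regression(params: ModelParams, n_cycles: int, seed: int, spread=(1.0, 2.0)):
    """OLS of division size on birth size over independent cycles.

    Birth sizes are drawn uniform on ``spread``*s0; under the linear rate the
    conditional mean is E[s_d|s_b] = s_b + mu/k, so the slope is 1 and the
    intercept the mean added size, independent of the birth-size spread.
    Returns (slope, intercept).
    """
    rng = np.random.default_rng(seed)
    s_b = rng.uniform(spread[0] * params.s0, spread[1] * params.s0, size=n_cycles)
    E = rng.exponential(size=n_cycles)
    lm = params.lam * params.mu
    T = np.log1p(lm * E / (params.k * s_b**params.lam)) / lm
    s_d = s_b * np.exp(params.mu * T)
    slope, intercept = np.polyfit(s_b, s_d, 1)
    return float(slope), float(intercept)


def run_validation(
    params: ModelParams | None = None,
    seed: int = 0,
    n_cells: int = 10_000,
    n_cycles: int = 50_000,
    ode_tol: tuple = DEFAULT_ODE_TOL,
) -> dict:
    """Run the full battery; returns a report dict with per-check results."""
    params = params or ModelParams()
    tau = params.tau
    checks = []

    # 1. FSP vs closed-form P0 on [0, 7 tau]
    grid7 = default_time_grid(params, 7)
    N7 = fsp_auto_truncate(params, grid7[-1], 1e-10, ode_tol=ode_tol)
    dist7 = fsp_propagate(params, N7, grid7, ode_tol=ode_tol)
    diff0 = float(np.max(np.abs(dist7.clamped()[0] - p0_closed_form(grid7, params))))
    checks.append(_check("fsp_vs_closed_form_p0", diff0, diff0 <= 1e-6, 1e-6))

    # 2. quadrature recursion vs FSP, i <= 5, theta in {0.5, 1, 2}
    worst = 0.0
    for scale in (0.5, 1.0, 2.0):
        p_th = ModelParams(mu=params.mu, k=scale * params.mu / params.s0, s0=params.s0)
        g = default_time_grid(p_th, 7)
        d = fsp_propagate(p_th, max(fsp_auto_truncate(p_th, g[-1], 1e-10), 6), g, ode_tol=ode_tol)
        for i in range(6):
            r = p_i_recursive(i, g, p_th, quad_tol=1e-9)
            worst = max(worst, float(np.max(np.abs(r - d.clamped()[i]))))
    checks.append(_check("recursion_vs_fsp", worst, worst <= 1e-5, 1e-5))

    # 3. SSA vs FSP: moments of n and s inside empirical 95% CIs
    config = SimulationConfig(n_cells=n_cells, t_final=grid7[-1], seed=seed, record_grid=grid7)
    summary = simulate_ensemble(config, params)
    mn = moments_n(dist7)
    ms = size_moments(dist7, params)
    eps = 1e-12
    coverages = {
        "mean_n": np.mean(np.abs(mn.mean - summary.mean_n) <= summary.ci_n + eps),
        "var_n": np.mean(np.abs(mn.var - summary.var_n) <= summary.ci_var_n + eps),
        "mean_s": np.mean(np.abs(ms.mean - summary.mean_s) <= summary.ci_s + eps),
        "var_s": np.mean(np.abs(ms.var - summary.var_s) <= summary.ci_var_s + eps),
    }
    cov = min(coverages.values())
    note = "min over " + ", ".join(f"{k}={v:.3f}" for k, v in coverages.items())
    checks.append(_check("ssa_fsp_ci_coverage", cov, cov >= 0.90, 0.90, note))

    # 4. added-size noise CV^2 = 1 (exponential added size); pool early
    # generations only — they complete well before the horizon, so the pool
    # avoids the length bias of censoring in-progress cycles
    cyc = summary.cycles
    gen_cap = max(int(grid7[-1] / tau) - 2, 1)
    deltas = cyc.loc[cyc["generation"] < gen_cap, "added_size"].to_numpy()
    extra = max(n_cycles - deltas.size, 0)
    if extra:
        rng = np.random.default_rng(seed + 1)
        s_b = np.full(extra, params.s0)
        E = rng.exponential(size=extra)
        lm = params.lam * params.mu
        T = np.log1p(lm * E / (params.k * s_b**params.lam)) / lm
        deltas = np.concatenate([deltas, s_b * np.expm1(params.mu * T)])
    cv2 = float(deltas.var(ddof=1) / deltas.mean() ** 2)
    checks.append(_check("added_size_cv2", cv2, 0.95 <= cv2 <= 1.05, [0.95, 1.05], f"{deltas.size} cycles"))

    # 5. adder regression: slope 1, intercept mean added size
    slope, intercept = adder_regression(params, n_cycles, seed + 2)
    db = params.delta_bar
    checks.append(_check("adder_slope", slope, abs(slope - 1.0) <= 0.05, [0.95, 1.05]))
    checks.append(
        _check("adder_intercept_over_delta_bar", intercept / db, abs(intercept / db - 1.0) <= 0.05, [0.95, 1.05])
    )

    # 6. asymptotic translation periodicity
    grid12 = default_time_grid(params, 12)
    N12 = fsp_auto_truncate(params, grid12[-1], 1e-10, ode_tol=ode_tol)
    dist12 = fsp_propagate(params, N12, grid12, ode_tol=ode_tol)
    res = [periodicity_residual(dist12, i) for i in range(2, 9)]
    monotone = all(res[j + 1] <= res[j] for j in range(1, len(res) - 1))  # i >= 3
    checks.append(_check("periodicity_residual_i8", res[-1], res[-1] < 1e-3 and monotone, 1e-3, "monotone from i=3"))

    # 7. division-count variance plateau
    grid10 = default_time_grid(params, 10)
    N10 = fsp_auto_truncate(params, grid10[-1], 1e-8, ode_tol=ode_tol)
    m10 = moments_n(fsp_propagate(params, N10, grid10, ode_tol=ode_tol))
    v_final = float(m10.var[-1])
    checks.append(_check("var_n_plateau", v_final, abs(v_final - 0.75) <= 0.05, [0.70, 0.80], "t = 10 tau"))

    return {
        "params": params.to_dict(),
        "seed": seed,
        "n_cells": n_cells,
        "n_cycles": n_cycles,
        "ode_tol": list(ode_tol),
        "checks": checks,
        "passed": all(c["passed"] for c in checks),
    }
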