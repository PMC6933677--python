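"""Time-dependent cell-size distribution of a fixed (mother-machine) population.

When every cell starts at the same size s0, the size at time t is determined
by the number of divisions: s = s0*e^{mu t}/2^i with probability P_i(t).  The
size density is therefore a mixture of weighted Dirac deltas,

    rho(s|t) = sum_i delta(s - s0 e^{mu t}/2^i) P_i(t),

whose moments follow directly from the atom weights.  As s0 varies the atoms
sweep out an enveloping curve; a distribution of initial sizes convolves the
atom sets of its components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InitialSizeSpec, ModelParams
from .master_equation import (
    DivisionCountDistribution,
    MomentSeries,
    default_time_grid,
    fsp_auto_truncate,
    fsp_propagate,
)

__all__ = [
    "SizeAtomSet",
    "size_atoms",
    "size_moments",
    "envelope_atoms",
    "initial_size_mixture",
]

#: atoms lighter than this are dropped from written outputs (kept in memory
#: so conservation checks remain exact)
OUTPUT_WEIGHT_FLOOR = 1e-12


@dataclass
class SizeAtomSet:
    """Weighted Dirac atoms representing rho(s|t) at one time.

    ``atoms`` has columns (source_s0, i, size, size_over_s0, weight); sizes
    within one source halve exactly between consecutive i.  Total weight plus
    ``leak`` (FSP truncation mass) is 1.
    """

    t: float
    atoms: pd.DataFrame
    leak: float

    def total_weight(self) -> float:
        return float(self.atoms["weight"].sum())

    def mean(self) -> float:
        return float((self.atoms["size"] * self.atoms["weight"]).sum())

    def var(self) -> float:
        m = self.mean()
        return float(((self.atoms["size"] - m) ** 2 * self.atoms["weight"]).sum())

    def merged(self, rtol: float = 1e-9) -> "SizeAtomSet":
        """Combine atoms whose sizes coincide to relative tolerance rtol.

        Distinct initial sizes can place atoms at identical positions (e.g.
        2*s0 after i divisions coincides with s0 after i-1); merging exposes
        the combined mass at each site.
        """
        df = self.atoms.sort_values("size", ascending=False, ignore_index=True)
        sizes = df["size"].to_numpy()
        group = np.zeros(len(df), dtype=int)
        g = 0
        for j in range(1, len(df)):
            if sizes[j - 1] - sizes[j] > rtol * sizes[j - 1]:
                g += 1
            group[j] = g
        out = (
            df.assign(_g=group)
            .groupby("_g", as_index=False)
            .agg(
                source_s0=("source_s0", "first"),
                i=("i", "min"),
                size=("size", "first"),
                size_over_s0=("size_over_s0", "first"),
                weight=("weight", "sum"),
            )
            .drop(columns=[], errors="ignore")
        )
        return SizeAtomSet(self.t, out, self.leak)

    def output_frame(self, weight_floor: float = OUTPUT_WEIGHT_FLOOR) -> pd.DataFrame:
        """Table for writing, with sub-floor atoms dropped (file hygiene)."""
        df = self.atoms[self.atoms["weight"] >= weight_floor].copy()
        df.insert(0, "t", self.t)
        return df.reset_index(drop=True)


def _atoms_frame(dist: DivisionCountDistribution, j: int, params: ModelParams, scale: float = 1.0) -> pd.DataFrame:
    i = np.arange(dist.N + 1)
    sizes = params.s0 * np.exp(params.mu * dist.t_grid[j]) / 2.0**i
    weights = dist.clamped()[:, j] * scale
    return pd.DataFrame(
        {
            "source_s0": params.s0,
            "i": i,
            "size": sizes,
            "size_over_s0": sizes / params.s0,
            "weight": weights,
        }
    )


def size_atoms(dist: DivisionCountDistribution, t: float, params: ModelParams) -> SizeAtomSet:
    """Atom set (s0 e^{mu t}/2^i, P_i(t)) at a grid time t."""
    j = dist.time_index(t)
    return SizeAtomSet(float(dist.t_grid[j]), _atoms_frame(dist, j, params), float(max(dist.leak[j], 0.0)))


def size_moments(dist: DivisionCountDistribution, params: ModelParams) -> MomentSeries:
    """Mean and variance of the size over the whole time grid.

    <s(t)> = sum_i (s0 e^{mu t}/2^i) P_i(t);
    var s(t) = sum_i (s0 e^{mu t}/2^i - <s>)^2 P_i(t).
    Times with material truncation leak are flagged.
    """
    i = np.arange(dist.N + 1)
    P = dist.clamped()
    sizes = params.s0 * np.exp(params.mu * dist.t_grid)[None, :] / 2.0 ** i[:, None]
    mean = (sizes * P).sum(axis=0)
    var = ((sizes - mean) ** 2 * P).sum(axis=0)
    flag = dist.leak > 10.0 * max(dist.ode_tol[0], 1e-15)
    return MomentSeries(dist.t_grid, mean, var, label="s", leak_flag=flag)


def _dist_for_s0(params: ModelParams, s0: float, t: float, leak_bound: float, n_grid: int = 257) -> DivisionCountDistribution:
    p = params.with_s0(s0)
    N = fsp_auto_truncate(p, t, leak_bound) if t > 0 else 1
    grid = np.linspace(0.0, t, n_grid) if t > 0 else np.array([0.0])
    return fsp_propagate(p, N, grid)


def envelope_atoms(
    s0_values,
    t: float,
    params_base: ModelParams,
    leak_bound: float = 1e-10,
    weights=None,
) -> SizeAtomSet:
    """Union of atom sets for several initial sizes at a common time.

    Each s0 gets its own division-count distribution (k fixed); the tagged
    union traces the enveloping curve the deltas draw as s0 varies.  Sources
    are weighted equally by default so total mass stays 1; a single s0
    reduces exactly to :func:`size_atoms`.
    """
    s0_values = np.atleast_1d(np.asarray(s0_values, float))
    if np.any(s0_values <= 0):
        raise ValueError("all initial sizes must be positive")
    if weights is None:
        weights = np.full(s0_values.size, 1.0 / s0_values.size)
    else:
        weights = np.asarray(weights, float)
        if weights.shape != s0_values.shape or not math.isclose(weights.sum(), 1.0):
            raise ValueError("weights must match s0_values and sum to 1")
    frames = []
    leak = 0.0
    for s0, w in zip(s0_values, weights):
        dist = _dist_for_s0(params_base, s0, t, leak_bound)
        j = dist.time_index(t)
        frames.append(_atoms_frame(dist, j, params_base.with_s0(s0), scale=w))
        leak += w * float(max(dist.leak[j], 0.0))
    return SizeAtomSet(t, pd.concat(frames, ignore_index=True), leak)


def initial_size_mixture(
    spec: InitialSizeSpec,
    n_nodes: int,
    t: float,
    params_base: ModelParams,
    leak_bound: float = 1e-10,
    merge_rtol: float = 1e-9,
) -> SizeAtomSet:
    """Size distribution under a distribution of initial sizes.

    The initial-size law is discretised into equal-probability quantile nodes
    (deterministic, so tests are exact); each node contributes its own atom
    set weighted by its probability, and coinciding atoms are merged.
    Converges weakly to the true convolution as n_nodes grows; a point mass
    reduces to :func:`size_atoms` for any n_nodes.
    """
    nodes, probs = spec.quantile_nodes(n_nodes)
    combined = envelope_atoms(nodes, t, params_base, leak_bound=leak_bound, weights=probs)
    return combined.merged(rtol=merge_rtol)
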