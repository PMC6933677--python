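"""Model parameters and the exact single-cycle division-time law.

The continuous-rate model describes a rod-shaped cell growing exponentially,
ds/dt = mu*s, that divides symmetrically with an instantaneous division rate
(splitting rate function) h = k*s^lam.  For lam = 1 the added size per cycle,
Delta = s_d - s_b, is exponential with mean mu/k independently of the birth
size — the adder division strategy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

LN2 = math.log(2.0)

__all__ = [
    "LN2",
    "ModelParams",
    "LineageRecord",
    "InitialSizeSpec",
    "doubling_time",
    "mean_added_size",
    "sample_interdivision_time",
]


def doubling_time(mu: float) -> float:
    """Individual cell-size doubling time tau = ln2/mu.

    Parameters
    ----------
    mu : float
        Exponential growth rate (1/time), strictly positive.
    """
    if not mu > 0:
        raise ValueError(f"growth rate mu must be positive, got {mu}")
    return LN2 / mu


def mean_added_size(mu: float, k: float) -> float:
    """Mean size added per division cycle, Delta_bar = mu/k (lam = 1)."""
    if not mu > 0:
        raise ValueError(f"growth rate mu must be positive, got {mu}")
    if not k > 0:
        raise ValueError(f"rate constant k must be positive, got {k}")
    return mu / k


@dataclass(frozen=True)
class ModelParams:
    """Growth and division parameters.

    Attributes
    ----------
    mu : float
        Exponential growth rate (1/time).
    k : float
        Splitting-rate constant; the division hazard is h = k*s^lam
        (units 1/(size^lam * time)).
    s0 : float
        Initial (birth) size at t = 0.
    lam : float
        Rate exponent; lam = 1 (default) gives the linear rate h = k*s
        and hence the adder strategy.

    Derived quantities: ``tau`` = ln2/mu, ``delta_bar`` = mu/k (meaningful
    at lam = 1), and the dimensionless ``theta`` = k*s0/mu governing the
    counting-process dynamics together with mu*t.
    """

    mu: float = LN2
    k: float = LN2
    s0: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu", "k", "s0", "lam"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be a positive finite number, got {value!r}")

    @property
    def tau(self) -> float:
        return doubling_time(self.mu)

    @property
    def delta_bar(self) -> float:
        return mean_added_size(self.mu, self.k)

    @property
    def theta(self) -> float:
        return self.k * self.s0 / self.mu

    def with_s0(self, s0: float) -> "ModelParams":
        return replace(self, s0=s0)

    # flat JSON config, {"mu":..,"k":..,"s0":..,"lambda":..}
    def to_dict(self) -> dict:
        return {"mu": self.mu, "k": self.k, "s0": self.s0, "lambda": self.lam}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {"mu", "k", "s0", "lambda", "lam"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        lam = d.get("lambda", d.get("lam", 1.0))
        return cls(mu=d["mu"], k=d["k"], s0=d["s0"], lam=lam)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class LineageRecord:
    """One completed division cycle of a single cell.

    Invariants: ``division_size = birth_size * exp(mu * interdivision_time)``,
    ``added_size = division_size - birth_size > 0``, and the daughter is born
    at ``division_size / 2`` (symmetric division, no partitioning error).
    """

    birth_size: float
    division_size: float
    added_size: float
    interdivision_time: float
    birth_time: float
    generation: int


def sample_interdivision_time(
    birth_size: float, params: ModelParams, unit_exponential_draw: float
) -> float:
    """Exact interdivision time by inverse-transform of the cumulative hazard.

    Within one cycle the size is s(t) = s_b*exp(mu*t), so the hazard
    h(t) = k*s_b^lam*exp(lam*mu*t) accumulates to
    H(T) = (k*s_b^lam/(lam*mu)) * (exp(lam*mu*T) - 1).  Setting H(T) equal to
    the supplied unit-mean exponential draw E and inverting gives

        T = (1/(lam*mu)) * log(1 + lam*mu*E / (k*s_b^lam)).

    For lam = 1 the implied added size Delta = s_b*(exp(mu*T)-1) = (mu/k)*E
    is exponential with mean mu/k, independent of the birth size (adder).

    The caller supplies the draw so that all randomness lives with the
    simulator's RNG streams.
    """
    if not birth_size > 0:
        raise ValueError(f"birth_size must be positive, got {birth_size}")
    E = unit_exponential_draw
    if E < 0:
        raise ValueError(f"unit_exponential_draw must be nonnegative, got {E}")
    lm = params.lam * params.mu
    return math.log1p(lm * E / (params.k * birth_size**params.lam)) / lm


@dataclass(frozen=True)
class InitialSizeSpec:
    """Distribution of birth sizes at t = 0.

    kind:
      - "fixed": point mass at ``s0``
      - "uniform": uniform on [``a``, ``b``]
      - "lognormal": log s0 ~ Normal(``meanlog``, ``sdlog``)
      - "atoms": explicit sizes with probabilities
    """

    kind: str = "fixed"
    s0: float = 1.0
    a: float = 1.0
    b: float = 2.0
    meanlog: float = 0.0
    sdlog: float = 0.1
    sizes: tuple = field(default=())
    probs: tuple = field(default=())

    _KINDS = ("fixed", "uniform", "lognormal", "atoms")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unsupported initial-size kind {self.kind!r}; expected one of {self._KINDS}")
        if self.kind == "fixed" and not self.s0 > 0:
            raise ValueError("fixed initial size must be positive")
        if self.kind == "uniform" and not (0 < self.a <= self.b):
            raise ValueError("uniform bounds must satisfy 0 < a <= b")
        if self.kind == "lognormal" and not self.sdlog >= 0:
            raise ValueError("sdlog must be nonnegative")
        if self.kind == "atoms":
            sizes = np.asarray(self.sizes, dtype=float)
            probs = np.asarray(self.probs, dtype=float)
            if sizes.size == 0 or sizes.size != probs.size:
                raise ValueError("atoms need matching nonempty sizes and probs")
            if np.any(sizes <= 0) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
                raise ValueError("atom sizes must be positive and probs sum to 1")

    @classmethod
    def fixed(cls, s0: float) -> "InitialSizeSpec":
        return cls(kind="fixed", s0=s0)

    @classmethod
    def uniform(cls, a: float, b: float) -> "InitialSizeSpec":
        return cls(kind="uniform", a=a, b=b)

    @classmethod
    def lognormal(cls, meanlog: float, sdlog: float) -> "InitialSizeSpec":
        return cls(kind="lognormal", meanlog=meanlog, sdlog=sdlog)

    @classmethod
    def atoms(cls, sizes, probs) -> "InitialSizeSpec":
        return cls(kind="atoms", sizes=tuple(sizes), probs=tuple(probs))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.s0)
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size=n)
        if self.kind == "lognormal":
            return np.exp(rng.normal(self.meanlog, self.sdlog, size=n))
        return rng.choice(np.asarray(self.sizes, float), size=n, p=np.asarray(self.probs, float))

    def quantile_nodes(self, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic equal-probability discretisation into n_nodes.

        Continuous kinds use midpoint quantiles ((j+1/2)/n); "fixed" and
        "atoms" return their exact support regardless of n_nodes.
        """
        if n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.kind == "fixed":
            return np.array([self.s0]), np.array([1.0])
        if self.kind == "atoms":
            return np.asarray(self.sizes, float), np.asarray(self.probs, float)
        q = (np.arange(n_nodes) + 0.5) / n_nodes
        if self.kind == "uniform":
            nodes = self.a + (self.b - self.a) * q
        else:
            from scipy.stats import norm

            nodes = np.exp(norm.ppf(q) * self.sdlog + self.meanlog)
        return nodes, np.full(n_nodes, 1.0 / n_nodes)

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "fixed":
            d["s0"] = self.s0
        elif self.kind == "uniform":
            d.update(a=self.a, b=self.b)
        elif self.kind == "lognormal":
            d.update(meanlog=self.meanlog, sdlog=self.sdlog)
        else:
            d.update(sizes=list(self.sizes), probs=list(self.probs))
        return d
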