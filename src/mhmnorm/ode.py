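"""Random gene networks and linear ODE trajectory simulation.

A gene network is a binary adjacency matrix with real interaction weights:
entry ``(i, j)`` is nonzero when gene ``j`` regulates gene ``i``, and the
expression vector evolves as the linear system ``dx/dt = W x``.  Trajectories
are integrated with an adaptive high-order solver and sampled on a regular
grid, which is the data the network-inference benchmark consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InstabilityError, ValidationError

__all__ = [
    "GeneNetwork",
    "TrajectorySample",
    "random_network",
    "simulate_ode",
    "sample_stable_system",
]

logger = logging.getLogger(__name__)

#: trajectories with any |x| beyond this are treated as numerically unstable
OVERFLOW_GUARD = 1e12


@dataclass(frozen=True)
class GeneNetwork:
    """Binary adjacency plus real interaction weights of a gene network.

    ``weights[i, j]`` is the regulatory strength of gene ``j`` on gene ``i``
    and is nonzero exactly where ``adjacency[i, j] == 1``.
    """

    adjacency: np.ndarray  # (n, n) of {0, 1}
    weights: np.ndarray  # (n, n) real

    def __post_init__(self) -> None:
        adjacency = np.asarray(self.adjacency, dtype=np.int8)
        weights = np.asarray(self.weights, dtype=np.float64)
        if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
            raise ValidationError("adjacency must be a square matrix")
        if adjacency.shape[0] < 2:
            raise ValidationError("network needs at least 2 nodes")
        if weights.shape != adjacency.shape:
            raise ValidationError("weights and adjacency shapes differ")
        if not np.all(np.isin(adjacency, (0, 1))):
            raise ValidationError("adjacency entries must be 0 or 1")
        if not np.all((weights != 0) == (adjacency == 1)):
            raise ValidationError("weights must be nonzero exactly on adjacency edges")
        object.__setattr__(self, "adjacency", adjacency.copy())
        object.__setattr__(self, "weights", weights.copy())

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())


@dataclass(frozen=True)
class TrajectorySample:
    """Regularly sampled states of one trajectory: ``states[k] = x(times[k])``."""

    times: np.ndarray  # (K,), strictly increasing, constant spacing
    states: np.ndarray  # (K, n)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        states = np.asarray(self.states, dtype=np.float64)
        if times.ndim != 1 or times.size < 2:
            raise ValidationError("need at least 2 sampling times")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValidationError("sampling times must be strictly increasing")
        if np.any(np.abs(steps - steps[0]) > 1e-12 * max(abs(times[-1]), 1.0)):
            raise ValidationError("sampling times must be regularly spaced")
        if states.ndim != 2 or states.shape[0] != times.size:
            raise ValidationError("states must be (K, n) matching times")
        if not np.all(np.isfinite(states)):
            raise ValidationError("states contain non-finite values")
        object.__setattr__(self, "times", times.copy())
        object.__setattr__(self, "states", states.copy())

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]


def random_network(
    n_nodes: int,
    n_edges: int,
    weight_range: tuple[float, float] = (-1.0, 1.0),
    seed: int | np.random.Generator = 0,
) -> GeneNetwork:
    """Place ``n_edges`` edges uniformly at random with Uniform weights.

    Edge positions are drawn without replacement among all ``n_nodes**2``
    ordered pairs (self-loops allowed, as in a linear decay/self-regulation
    term); weights are Uniform(weight_range) with exact zeros redrawn so the
    weight/adjacency correspondence holds.
    """
    if n_nodes < 2:
        raise ValidationError("network needs at least 2 nodes")
    if not 0 <= n_edges <= n_nodes * n_nodes:
        raise ValidationError(
            f"n_edges must lie in [0, {n_nodes * n_nodes}], got {n_edges}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    adjacency = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    flat = rng.choice(n_nodes * n_nodes, size=n_edges, replace=False)
    adjacency.flat[flat] = 1
    weights = np.zeros((n_nodes, n_nodes))
    draws = rng.uniform(*weight_range, size=n_edges)
    while np.any(draws == 0.0):  # measure-zero, but keep the contract exact
        zero = draws == 0.0
        draws[zero] = rng.uniform(*weight_range, size=int(zero.sum()))
    weights.flat[flat] = draws
    return GeneNetwork(adjacency, weights)


def simulate_ode(
    net: GeneNetwork,
    x0: np.ndarray,
    t_end: float,
    n_samples: int,
) -> TrajectorySample:
    """Integrate ``dx/dt = W x`` and sample it on a regular grid.

    Uses an adaptive 8th-order Runge-Kutta integrator (rtol 1e-10, atol
    1e-12, so sampled states are reliable to ~1e-8 relative) evaluated at
    ``n_samples`` equispaced times including ``t = 0`` (where the state is
    exactly ``x0``).  Raises :class:`InstabilityError` if the sampled
    trajectory exceeds the overflow guard of ``1e12`` in magnitude.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    if x0.shape != (net.n_nodes,):
        raise ValidationError(f"x0 must have shape ({net.n_nodes},)")
    if not np.all(np.isfinite(x0)):
        raise ValidationError("x0 contains non-finite values")
    if n_samples < 2:
        raise ValidationError("n_samples must be at least 2")
    if not t_end > 0:
        raise ValidationError("t_end must be positive")

    times = np.linspace(0.0, t_end, n_samples)
    weights = net.weights
    sol = solve_ivp(
        lambda _t, x: weights @ x,
        (0.0, t_end),
        x0,
        t_eval=times,
        method="DOP853",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise InstabilityError(
            f"ODE integration failed near t={sol.t[-1] if sol.t.size else 0.0:.4g}: "
            f"{sol.message}",
            time=float(sol.t[-1]) if sol.t.size else None,
        )
    states = sol.y.T
    over = np.abs(states) > OVERFLOW_GUARD
    if np.any(over):
        k = int(np.argmax(over.any(axis=1)))
        raise InstabilityError(
            f"trajectory magnitude exceeded {OVERFLOW_GUARD:g} at t={times[k]:.4g}",
            time=float(times[k]),
        )
    states[0] = x0  # the initial condition is known exactly
    return TrajectorySample(times, states)


def sample_stable_system(
    n_nodes: int,
    n_edges: int,
    seed: int,
    *,
    t_end: float = 3.0,
    n_samples: int = 16,
    weight_range: tuple[float, float] = (-1.0, 1.0),
    x0_range: tuple[float, float] = (1.0, 10.0),
    amplitude_cap: float = 1e3,
    max_attempts: int = 50,
) -> tuple[GeneNetwork, TrajectorySample]:
    """Draw a random network + initial state whose trajectory stays bounded.

    Weights are not constrained to a stable spectrum, so some draws blow up;
    those are rejected and redrawn (fresh seed-derived draw) until the sampled
    trajectory stays within ``amplitude_cap * max|x0|``, up to ``max_attempts``
    attempts.  Rejection keeps trajectories in a reasonable range without
    biasing toward any particular spectrum.
    """
    rng = np.random.default_rng(seed)
    for attempt in range(max_attempts):
        net = random_network(n_nodes, n_edges, weight_range, seed=rng)
        x0 = rng.uniform(*x0_range, size=n_nodes)
        try:
            sample = simulate_ode(net, x0, t_end, n_samples)
        except InstabilityError:
            logger.warning(
                "unstable network (attempt %d of %d), resampling", attempt + 1, max_attempts
            )
            continue
        if np.max(np.abs(sample.states)) <= amplitude_cap * np.max(np.abs(x0)):
            if attempt:
                logger.info("accepted network after %d resamples", attempt)
            return net, sample
        logger.warning(
            "trajectory amplitude above cap (attempt %d of %d), resampling",
            attempt + 1,
            max_attempts,
        )
    raise InstabilityError(
        f"no stable network found in {max_attempts} attempts "
        f"(n_nodes={n_nodes}, n_edges={n_edges}, t_end={t_end})"
    )
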