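"""Finite-state Markov environments: generators, stationary laws, embedded chains.

The environment is a stationary continuous-time Markov chain ``Z`` on a finite
label set.  Its generator ``Lambda`` is stored in *column-source* orientation:
``Lambda[z', z]`` is the rate of jumping from ``z`` to ``z'`` (for ``z' != z``)
and each column sums to zero, so the stationary distribution satisfies
``Lambda @ pi = 0``.  Most textbooks use the transposed (row-source)
convention; :func:`explicit_environment` accepts either and normalizes.

Countable environments (birth-death, Markov-modulated birth-death) are
truncated to ``{0, ..., z_max}`` with a controlled stationary tail mass.  The
truncation is reflecting: the birth transition out of ``z_max`` is dropped, so
the truncated matrix is again a proper generator, and the stationary law is
re-solved on the truncated state space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats


class EnvironmentError_(ValueError):
    """Raised for invalid environment specifications."""


@dataclass
class MarkovEnvironment:
    """A finite, irreducible CTMC environment.

    Parameters
    ----------
    states
        Ordered list of state labels (ints or tuples of ints).  The order
        fixes the block indexing used everywhere downstream.
    Lambda
        Generator in column-source orientation (``Lambda @ pi = 0``).
    pi
        Stationary distribution over ``states``.
    truncation_tail_mass
        Upper bound on the stationary mass discarded by truncation
        (0 for intrinsically finite environments).
    """

    states: list
    Lambda: np.ndarray
    pi: np.ndarray
    truncation_tail_mass: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        n = len(self.states)
        if self.Lambda.shape != (n, n):
            raise EnvironmentError_(
                f"generator shape {self.Lambda.shape} does not match "
                f"{n} states"
            )
        _validate_generator(self.Lambda)
        self._index = {s: i for i, s in enumerate(self.states)}

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def exit_rates(self) -> np.ndarray:
        """Total exit rate per state, ``Lambda0(z) = -Lambda[z, z]``."""
        return -np.diag(self.Lambda)

    def index(self, z) -> int:
        try:
            return self._index[z]
        except KeyError:
            raise EnvironmentError_(f"unknown environment state {z!r}") from None

    def state_array(self) -> np.ndarray:
        """States as an array; tuple labels become rows."""
        return np.asarray(self.states)

    def component(self, k: int | None = None) -> np.ndarray:
        """Scalar values of component ``k`` of the (possibly tuple) labels."""
        arr = self.state_array()
        if arr.ndim == 1:
            return arr.astype(float)
        if k is None:
            raise EnvironmentError_(
                "product environment: specify which component to extract"
            )
        return arr[:, k].astype(float)

    def mean(self, component: int | None = None) -> float:
        """Stationary mean of a (component of the) environment label."""
        return float(self.pi @ self.component(component))


@dataclass
class EmbeddedChain:
    """Jump chain of the environment: kernel ``K`` (column-stochastic,
    zero diagonal) and the unnormalized stationary vector ``pi ∘ Lambda0``."""

    K: np.ndarray
    pi_tilde: np.ndarray


def _validate_generator(Lam: np.ndarray, atol: float = 1e-12) -> None:
    off = Lam - np.diag(np.diag(Lam))
    if np.any(off < -atol):
        raise EnvironmentError_("generator has negative off-diagonal entries")
    colsums = Lam.sum(axis=0)
    scale = max(1.0, float(np.abs(Lam).max()))
    if np.any(np.abs(colsums) > 1e-9 * scale):
        raise EnvironmentError_(
            f"generator columns do not sum to zero (max |sum| = "
            f"{np.abs(colsums).max():.3e})"
        )


def _check_irreducible(Lam: np.ndarray, states: Sequence) -> None:
    n = Lam.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    src, dst = np.nonzero((Lam - np.diag(np.diag(Lam))).T > 0)
    g.add_edges_from(zip(src, dst))
    comps = list(nx.strongly_connected_components(g))
    if len(comps) > 1:
        labels = [sorted(states[i] for i in c) for c in comps]
        raise EnvironmentError_(
            f"environment is reducible: {len(comps)} communicating classes "
            f"{labels}"
        )


def stationary_distribution(Lambda: np.ndarray, states: Sequence | None = None) -> np.ndarray:
    """Unique probability vector ``pi`` with ``Lambda @ pi = 0``.

    Solved from the dense null space of the generator; tiny negative
    round-off (< 1e-14) is clipped before renormalization.  Raises if the
    chain is reducible, naming the disconnected classes.
    """
    Lam = np.asarray(Lambda, dtype=float)
    _validate_generator(Lam)
    n = Lam.shape[0]
    if states is None:
        states = list(range(n))
    _check_irreducible(Lam, states)
    # Replace one balance equation by the normalization constraint.
    M = np.vstack([Lam, np.ones(n)])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    pi, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    pi[np.abs(pi) < 1e-14] = np.clip(pi[np.abs(pi) < 1e-14], 0.0, None)
    if np.any(pi < 0):
        raise EnvironmentError_("stationary solve produced negative mass")
    pi = pi / pi.sum()
    resid = np.abs(Lam @ pi).max()
    if resid > 1e-10 * max(1.0, np.abs(Lam).max()):
        raise EnvironmentError_(f"stationary residual too large: {resid:.3e}")
    return pi


def embedded_chain(env: MarkovEnvironment) -> EmbeddedChain:
    """Jump-chain kernel ``K(z', z) = Lambda(z', z) / Lambda0(z)`` and the
    unnormalized stationary vector ``pi_tilde = pi ∘ Lambda0``.

    Requires every state to have a positive exit rate (no absorbing states).
    The stationarity identity ``K @ pi_tilde = pi_tilde`` is verified on
    construction.
    """
    lam0 = env.exit_rates
    if np.any(lam0 <= 0):
        bad = [env.states[i] for i in np.nonzero(lam0 <= 0)[0]]
        raise EnvironmentError_(f"absorbing environment states: {bad}")
    K = env.Lambda / lam0[np.newaxis, :]
    np.fill_diagonal(K, 0.0)
    pi_tilde = env.pi * lam0
    resid = np.abs(K @ pi_tilde - pi_tilde).max()
    if resid > 1e-10 * max(1.0, pi_tilde.max()):
        raise EnvironmentError_(
            f"embedded-chain stationarity violated (residual {resid:.3e})"
        )
    return EmbeddedChain(K=K, pi_tilde=pi_tilde)


def explicit_environment(
    states: Sequence,
    generator,
    orientation: str = "column",
) -> MarkovEnvironment:
    """Environment from an explicit generator.

    ``orientation="column"`` means ``generator[z', z]`` is the z→z' rate
    (the convention used internally); ``"row"`` accepts the transposed
    textbook convention.
    """
    Lam = np.asarray(generator, dtype=float)
    if orientation == "row":
        Lam = Lam.T
    elif orientation != "column":
        raise EnvironmentError_(f"unknown orientation {orientation!r}")
    states = [tuple(s) if isinstance(s, (list, np.ndarray)) else s for s in states]
    pi = stationary_distribution(Lam, states)
    return MarkovEnvironment(states=list(states), Lambda=Lam, pi=pi,
                             meta={"type": "explicit"})


def telegraph(rate_on: float, rate_off: float) -> MarkovEnvironment:
    """Two-state switch with states ``[0, 1]``.

    ``rate_on`` is the 0→1 switching rate, ``rate_off`` the 1→0 rate, so the
    stationary law is ``(rate_off, rate_on) / (rate_on + rate_off)``.
    """
    if rate_on <= 0 or rate_off <= 0:
        raise EnvironmentError_("telegraph rates must be positive")
    Lam = np.array([[-rate_on, rate_off], [rate_on, -rate_off]])
    pi = np.array([rate_off, rate_on]) / (rate_on + rate_off)
    return MarkovEnvironment(
        states=[0, 1], Lambda=Lam, pi=pi,
        meta={"type": "telegraph", "rate_on": rate_on, "rate_off": rate_off},
    )


def poisson_truncation_level(mean: float, tail_mass: float) -> int:
    """Smallest ``z_max`` with Poisson upper tail ``P[Z > z_max] < tail_mass``."""
    if tail_mass <= 0:
        raise EnvironmentError_("tail_mass must be positive")
    z = int(stats.poisson.isf(tail_mass, mean)) if tail_mass < 1 else 0
    while stats.poisson.sf(z, mean) >= tail_mass:
        z += 1
    while z > 0 and stats.poisson.sf(z - 1, mean) < tail_mass:
        z -= 1
    return z


def birth_death(
    birth: float,
    death: float,
    tail_mass: float = 1e-12,
    z_max: int | None = None,
) -> MarkovEnvironment:
    """Immigration-death environment: birth at constant rate ``birth``,
    death at rate ``death * z`` (stationary law Poisson(birth/death)),
    truncated reflectingly at ``z_max``.

    ``z_max`` defaults to the smallest level whose Poisson upper tail is
    below ``tail_mass``.
    """
    if birth <= 0 or death <= 0:
        raise EnvironmentError_("birth and death rates must be positive")
    mean = birth / death
    if z_max is None:
        z_max = max(1, poisson_truncation_level(mean, tail_mass))
        recorded_tail = float(stats.poisson.sf(z_max, mean))
    else:
        recorded_tail = float(stats.poisson.sf(z_max, mean))
    n = z_max + 1
    Lam = np.zeros((n, n))
    for z in range(n):
        if z < z_max:
            Lam[z + 1, z] += birth
        if z > 0:
            Lam[z - 1, z] += death * z
    np.fill_diagonal(Lam, 0.0)
    np.fill_diagonal(Lam, -Lam.sum(axis=0))
    states = list(range(n))
    pi = stationary_distribution(Lam, states)
    return MarkovEnvironment(
        states=states, Lambda=Lam, pi=pi, truncation_tail_mass=recorded_tail,
        meta={"type": "birth_death", "birth": birth, "death": death,
              "z_max": z_max},
    )


def modulated_birth_death(
    birth: float,
    death: float,
    switch_on: float,
    switch_off: float,
    tail_mass: float = 1e-12,
    z_max: int | None = None,
) -> MarkovEnvironment:
    """Birth-death component whose birth rate is gated by a telegraph switch.

    States are tuples ``(z, s)`` in lexicographic order, ``s in {0, 1}``.
    Transitions: birth ``(z, s) -> (z+1, s)`` at rate ``birth * s``, death at
    rate ``death * z``, and switch flips at rates ``switch_on`` /
    ``switch_off``.  The joint chain is Markov even though the birth-death
    component alone is not.

    The truncation level is bounded via the Poisson law of the always-on
    chain (birth rate ``birth``), which stochastically dominates the gated
    one, so the recorded tail mass is a conservative bound.
    """
    if min(birth, death, switch_on, switch_off) <= 0:
        raise EnvironmentError_("all rates must be positive")
    if z_max is None:
        z_max = max(1, poisson_truncation_level(birth / death, tail_mass))
    recorded_tail = float(stats.poisson.sf(z_max, birth / death))
    states = [(z, s) for z in range(z_max + 1) for s in (0, 1)]
    n = len(states)
    idx = {st: i for i, st in enumerate(states)}
    Lam = np.zeros((n, n))
    for (z, s), j in idx.items():
        if z < z_max and s == 1:
            Lam[idx[(z + 1, s)], j] += birth
        if z > 0:
            Lam[idx[(z - 1, s)], j] += death * z
        if s == 0:
            Lam[idx[(z, 1)], j] += switch_on
        else:
            Lam[idx[(z, 0)], j] += switch_off
    np.fill_diagonal(Lam, -Lam.sum(axis=0) + np.diag(Lam))
    pi = stationary_distribution(Lam, states)
    return MarkovEnvironment(
        states=states, Lambda=Lam, pi=pi, truncation_tail_mass=recorded_tail,
        meta={"type": "modulated_birth_death", "birth": birth, "death": death,
              "switch_on": switch_on, "switch_off": switch_off,
              "z_max": z_max},
    )


def product_environment(*components: MarkovEnvironment) -> MarkovEnvironment:
    """Independent product of environments.

    States are tuples in lexicographic order (first component outermost,
    tuple components flattened); the generator is the Kronecker sum of the
    component generators and the stationary law the outer product.
    """
    if len(components) < 2:
        raise EnvironmentError_("product needs at least two components")
    env = components[0]
    for other in components[1:]:
        na, nb = env.n_states, other.n_states
        Lam = np.kron(env.Lambda, np.eye(nb)) + np.kron(np.eye(na), other.Lambda)
        pi = np.kron(env.pi, other.pi)
        states = []
        for a in env.states:
            ta = a if isinstance(a, tuple) else (a,)
            for b in other.states:
                tb = b if isinstance(b, tuple) else (b,)
                states.append(ta + tb)
        tail = env.truncation_tail_mass + other.truncation_tail_mass
        env = MarkovEnvironment(states=states, Lambda=Lam, pi=pi,
                                truncation_tail_mass=tail,
                                meta={"type": "product"})
    return env


def correlation_time(env_kind: str, **rates: float) -> float:
    """Autocorrelation decay time of a standard environment.

    ``telegraph``: ``1 / (rate_on + rate_off)``; ``birth_death``:
    ``1 / death`` (the relaxation time of the immigration-death chain).
    """
    if env_kind == "telegraph":
        return 1.0 / (rates["rate_on"] + rates["rate_off"])
    if env_kind == "birth_death":
        return 1.0 / rates["death"]
    raise EnvironmentError_(f"unknown environment kind {env_kind!r}")
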