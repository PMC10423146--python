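"""Monte-Carlo oracles for modulated linear CRNs.

Two complementary simulators:

* :func:`ssa_trajectory` — the exact stochastic simulation algorithm
  (direct method) on the joint (subsystem, environment) jump chain.  Works
  for arbitrary propensities, including non-linear ones supplied through a
  :class:`JointModel`.
* :func:`hybrid_conditional_mean` — simulates only the environment jumps
  and propagates the conditional subsystem mean through each sojourn with
  the exact affine interval update, using an augmented matrix exponential
  so that singular per-state rate matrices (e.g. a switched-off
  degradation channel) need no special-casing.  For linear subsystems this
  estimator targets the same stationary mean as the SSA with a much
  smaller variance at equal horizon.

Time averages are reported with batch-means standard errors.  All
randomness flows through an explicit integer seed; there is no global RNG
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .crn_model import ModulatedCRN, rate_matrices_at
from .environment import MarkovEnvironment

MAX_EVENTS_DEFAULT = 10**8


class SimulationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Piecewise-constant jump path (SSA) or piecewise-smooth conditional
    mean path sampled at environment jumps (hybrid).

    ``times[k]`` is the k-th event time; ``X[k]`` and ``z_index[k]`` are the
    subsystem state (or conditional mean) and environment state index valid
    on ``[times[k], times[k+1])``.
    """

    times: np.ndarray
    X: np.ndarray
    z_index: np.ndarray
    t_end: float
    env: MarkovEnvironment
    kind: str
    clamped_events: int = 0
    n_events: int = 0

    @property
    def clamp_fraction(self) -> float:
        return self.clamped_events / max(self.n_events, 1)


@dataclass
class StationaryEstimate:
    mean: np.ndarray
    standard_error: np.ndarray
    burn_in: float
    horizon: float
    n_batches: int
    method: dict = field(default_factory=dict)


@dataclass
class JointModel:
    """Joint jump model with user-supplied subsystem propensities.

    ``propensities(x, z_label)`` returns the length-M propensity vector;
    ``change_vectors`` is (d x M).  Environment jumps are taken from the
    generator of ``env``.  Used for non-linear (e.g. Hill-type) kinetics
    that are outside the exact-solver class but still simulable.
    """

    propensities: object
    change_vectors: np.ndarray
    env: MarkovEnvironment
    species_names: list


def _env_transition_tables(env: MarkovEnvironment):
    """Per-state arrays of (target index, rate) for environment jumps."""
    targets, rates = [], []
    for j in range(env.n_states):
        col = env.Lambda[:, j].copy()
        col[j] = 0.0
        nz = np.nonzero(col > 0)[0]
        targets.append(nz)
        rates.append(col[nz])
    return targets, rates


class _Buffer:
    def __init__(self, d: int, cap: int = 4096):
        self.t = np.empty(cap)
        self.x = np.empty((cap, d))
        self.z = np.empty(cap, dtype=np.int64)
        self.n = 0

    def push(self, t, x, z):
        if self.n == len(self.t):
            self.t = np.concatenate([self.t, np.empty_like(self.t)])
            self.x = np.concatenate([self.x, np.empty_like(self.x)])
            self.z = np.concatenate([self.z, np.empty_like(self.z)])
        self.t[self.n] = t
        self.x[self.n] = x
        self.z[self.n] = z
        self.n += 1

    def arrays(self):
        return self.t[:self.n].copy(), self.x[:self.n].copy(), self.z[:self.n].copy()


def ssa_trajectory(
    model: ModulatedCRN | JointModel,
    t_end: float,
    seed: int,
    x0=None,
    z0=None,
    max_events: int = MAX_EVENTS_DEFAULT,
) -> Trajectory:
    """Exact direct-method SSA of the joint (X, Z) chain.

    Negative propensity evaluations (possible for linearized repression)
    are clamped to zero and tallied in ``Trajectory.clamped_events``; a NaN
    propensity raises.  Identical seeds give identical jump sequences.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(seed)
    if isinstance(model, ModulatedCRN):
        env = model.environment
        d = model.n_species
        M = model.subsystem.n_reactions
        Gs = np.stack([model.rates.Gamma(z) for z in env.states])
        gs = np.stack([model.rates.gamma(z) for z in env.states])
        N = model.subsystem.N.astype(float)
        prop_fn = None
    else:
        env = model.env
        N = np.asarray(model.change_vectors, dtype=float)
        d, M = N.shape
        prop_fn = model.propensities
        Gs = gs = None
    etargets, erates = _env_transition_tables(env)
    lam0 = env.exit_rates

    if x0 is None:
        x = np.zeros(d)
    else:
        x = np.asarray(x0, dtype=float).copy()
    zi = env.index(z0) if z0 is not None else int(rng.choice(env.n_states, p=env.pi))

    buf = _Buffer(d)
    t = 0.0
    buf.push(t, x, zi)
    clamped = 0
    n_events = 0
    while True:
        if prop_fn is None:
            props = Gs[zi] @ x + gs[zi]
        else:
            props = np.asarray(prop_fn(x, env.states[zi]), dtype=float)
        if np.any(np.isnan(props)):
            raise SimulationError(f"NaN propensity at state x={x}, "
                                  f"z={env.states[zi]}")
        if np.any(props < 0):
            clamped += int(np.sum(props < 0))
            props = np.clip(props, 0.0, None)
        a_sub = props.sum()
        a0 = a_sub + lam0[zi]
        if a0 <= 0:
            break
        t += rng.exponential(1.0 / a0)
        if t >= t_end:
            break
        n_events += 1
        if n_events > max_events:
            raise SimulationError(
                f"event budget exceeded ({max_events} events before "
                f"t={t:.3g} of {t_end:.3g}); rates may be exploding"
            )
        u = rng.random() * a0
        if u < a_sub:
            j = int(np.searchsorted(np.cumsum(props), u, side="right"))
            x = x + N[:, j]
        else:
            v = u - a_sub
            j = int(np.searchsorted(np.cumsum(erates[zi]), v, side="right"))
            j = min(j, len(etargets[zi]) - 1)
            zi = int(etargets[zi][j])
        buf.push(t, x, zi)
    times, X, Z = buf.arrays()
    return Trajectory(times=times, X=X, z_index=Z, t_end=t_end, env=env,
                      kind="ssa", clamped_events=clamped, n_events=n_events)


# ---------------------------------------------------------------------------
# Interval propagation for the conditional-mean (hybrid) path


def _affine_step_scalar(a: float, b: float, y0: float, dt: float):
    """Exact update of dy/dt = b - a*y over dt: returns (y(dt), int_0^dt y)."""
    if a == 0.0:
        return y0 + b * dt, y0 * dt + 0.5 * b * dt * dt
    e = np.exp(-a * dt)
    yinf = b / a
    y1 = yinf + (y0 - yinf) * e
    integral = yinf * dt + (y0 - yinf) * (1.0 - e) / a
    return y1, integral


def _affine_step_matrix(A: np.ndarray, b: np.ndarray, y0: np.ndarray,
                        dt: float):
    """Exact affine update via the augmented matrix exponential.

    Propagates v = [y; s; 1] with dy/dt = -A y + b, ds/dt = y, which is
    well-defined for singular A (zero eigenvalues included).
    """
    d = len(b)
    M = np.zeros((2 * d + 1, 2 * d + 1))
    M[:d, :d] = -A
    M[:d, -1] = b
    M[d:2 * d, :d] = np.eye(d)
    P = expm(M * dt)
    y1 = P[:d, :d] @ y0 + P[:d, -1]
    integral = P[d:2 * d, :d] @ y0 + P[d:2 * d, -1]
    return y1, integral


def hybrid_conditional_mean(
    crn: ModulatedCRN,
    t_end: float,
    seed: int,
    y0=None,
    burn_in: float | None = None,
    n_batches: int = 50,
) -> tuple[Trajectory, StationaryEstimate]:
    """Conditional-mean path estimator of the stationary mean.

    Simulates the environment jump chain only; across each sojourn the
    conditional mean Y obeys dY/dt = b(z) - A(z) Y and is propagated by the
    exact affine update, scalar closed form for d = 1 and augmented matrix
    exponential otherwise.  Returns the Y-path sampled at jump times and
    the batch-means time-average estimate.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    env = crn.environment
    d = crn.n_species
    rng = np.random.default_rng(seed)
    etargets, erates = _env_transition_tables(env)
    lam0 = env.exit_rates
    Amats, bvecs = [], []
    for z in env.states:
        A, b = rate_matrices_at(crn, z)
        Amats.append(A)
        bvecs.append(b)
    scalar = d == 1

    zi = int(rng.choice(env.n_states, p=env.pi))
    y = np.zeros(d) if y0 is None else np.asarray(y0, dtype=float).copy()
    if burn_in is None:
        burn_in = 0.2 * t_end

    buf = _Buffer(d)
    t = 0.0
    buf.push(t, y, zi)
    # per-interval integral records for averaging and share estimation
    seg_t0, seg_int, seg_z = [], [], []
    while t < t_end:
        rate = lam0[zi]
        dt = rng.exponential(1.0 / rate) if rate > 0 else t_end - t
        dt = min(dt, t_end - t)
        if scalar:
            y1, integral = _affine_step_scalar(
                Amats[zi][0, 0], bvecs[zi][0], y[0], dt)
            y1 = np.array([y1])
            integral = np.array([integral])
        else:
            y1, integral = _affine_step_matrix(Amats[zi], bvecs[zi], y, dt)
        seg_t0.append(t)
        seg_int.append(integral)
        seg_z.append(zi)
        t += dt
        y = y1
        if t < t_end and rate > 0:
            probs = np.cumsum(erates[zi])
            j = int(np.searchsorted(probs, rng.random() * probs[-1],
                                    side="right"))
            zi = int(etargets[zi][min(j, len(etargets[zi]) - 1)])
            buf.push(t, y, zi)
    times, Y, Z = buf.arrays()
    traj = Trajectory(times=times, X=Y, z_index=Z, t_end=t_end, env=env,
                      kind="hybrid", n_events=len(times) - 1)
    traj.segment_t0 = np.asarray(seg_t0)
    traj.segment_integrals = np.asarray(seg_int)
    traj.segment_z = np.asarray(seg_z, dtype=np.int64)

    keep = traj.segment_t0 >= burn_in
    span = t_end - burn_in
    edges = burn_in + span * np.arange(n_batches + 1) / n_batches
    batch_idx = np.clip(np.searchsorted(edges, traj.segment_t0[keep],
                                        side="right") - 1, 0, n_batches - 1)
    sums = np.zeros((n_batches, d))
    np.add.at(sums, batch_idx, traj.segment_integrals[keep])
    batch_means = sums / (span / n_batches)
    mean = batch_means.mean(axis=0)
    se = batch_means.std(axis=0, ddof=1) / np.sqrt(n_batches)
    est = StationaryEstimate(
        mean=mean, standard_error=se, burn_in=burn_in, horizon=t_end,
        n_batches=n_batches,
        method={"estimator": "hybrid-conditional-mean", "seed": seed},
    )
    return traj, est


# ---------------------------------------------------------------------------
# Time averages and share estimation from trajectories


def _cumulative_integral(traj: Trajectory):
    """Cumulative time integral of X along a piecewise-constant path."""
    t = np.append(traj.times, traj.t_end)
    dt = np.diff(t)
    contrib = traj.X * dt[:, np.newaxis]
    cum = np.vstack([np.zeros((1, traj.X.shape[1])), np.cumsum(contrib, axis=0)])
    return t, cum  # cum[k] = integral over [t[0], t[k]]


def _integral_between(t, cum, a: float, b: float):
    """Integral of the piecewise-constant path over [a, b]."""
    def at(s):
        k = np.searchsorted(t, s, side="right") - 1
        k = min(max(k, 0), len(t) - 2)
        return cum[k] + (s - t[k]) * (cum[k + 1] - cum[k]) / (t[k + 1] - t[k])
    return at(b) - at(a)


def time_average(traj: Trajectory, burn_in: float | None = None,
                 n_batches: int = 50) -> StationaryEstimate:
    """Batch-means time average of a piecewise-constant trajectory.

    The default burn-in discards the first 20% of the horizon; the standard
    error is the spread of ``n_batches`` equal-length batch averages.
    """
    if burn_in is None:
        burn_in = 0.2 * traj.t_end
    if burn_in >= traj.t_end:
        raise ValueError("burn-in must be shorter than the horizon")
    t, cum = _cumulative_integral(traj)
    edges = np.linspace(burn_in, traj.t_end, n_batches + 1)
    vals = np.array([_integral_between(t, cum, a, b) / (b - a)
                     for a, b in zip(edges[:-1], edges[1:])])
    mean = vals.mean(axis=0)
    se = vals.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return StationaryEstimate(
        mean=mean, standard_error=se, burn_in=burn_in, horizon=traj.t_end,
        n_batches=n_batches, method={"estimator": f"{traj.kind}-time-average"},
    )


def _sojourn_table(traj: Trajectory, burn_in: float):
    """Environment sojourns [start, end) with labels, after burn-in."""
    zi = traj.z_index
    change = np.nonzero(np.diff(zi) != 0)[0] + 1
    starts = np.concatenate([[0], change])
    t_start = traj.times[starts]
    t_next = np.append(t_start[1:], traj.t_end)
    labels = zi[starts]
    keep = t_next > burn_in
    t_start = np.clip(t_start[keep], burn_in, None)
    return t_start, t_next[keep], labels[keep]


def estimate_shares(traj: Trajectory, species: int = 0,
                    burn_in: float | None = None,
                    min_jumps: int = 1000,
                    n_batches: int = 50):
    """Empirical environmental shares from a trajectory.

    For each environment state the share is the fraction of the total
    post-burn-in time integral of species ``i`` accumulated during
    sojourns labeled with that state; shares sum to one exactly.  Standard
    errors use the delta method on batch means of the (numerator,
    denominator) pair.

    Returns ``(shares, se)`` as dicts keyed by state label.
    """
    if burn_in is None:
        burn_in = 0.2 * traj.t_end
    n_jumps = int(np.sum(np.diff(traj.z_index) != 0))
    if n_jumps < min_jumps:
        raise SimulationError(
            f"only {n_jumps} environment jumps (< {min_jumps}); extend the "
            "horizon for share estimation"
        )
    t, cum = _cumulative_integral(traj)
    s_start, s_end, s_label = _sojourn_table(traj, burn_in)
    cumx = cum[:, species]

    def cum_at(s):
        k = np.clip(np.searchsorted(t, s, side="right") - 1, 0, len(t) - 2)
        return cumx[k] + (s - t[k]) * (cumx[k + 1] - cumx[k]) / (t[k + 1] - t[k])

    seg_int = cum_at(s_end) - cum_at(s_start)
    total = seg_int.sum()
    if total <= 0:
        raise SimulationError("total species integral is zero; no shares")
    nz = traj.env.n_states
    num = np.zeros(nz)
    np.add.at(num, s_label, seg_int)
    shares = {traj.env.states[k]: float(num[k] / total) for k in range(nz)}

    # delta-method SE from batch means of (numerator_z, denominator)
    edges = np.linspace(burn_in, traj.t_end, n_batches + 1)
    bidx = np.clip(np.searchsorted(edges, s_start, side="right") - 1,
                   0, n_batches - 1)
    num_b = np.zeros((n_batches, nz))
    np.add.at(num_b, (bidx, s_label), seg_int)
    den_b = num_b.sum(axis=1)
    se = {}
    nb = float(n_batches)
    mden = den_b.mean()
    for k in range(nz):
        mnum = num_b[:, k].mean()
        if mden == 0:
            se[traj.env.states[k]] = float("nan")
            continue
        cov = np.cov(num_b[:, k], den_b, ddof=1)
        var = (cov[0, 0] / mden**2
               - 2 * mnum * cov[0, 1] / mden**3
               + mnum**2 * cov[1, 1] / mden**4) / nb
        se[traj.env.states[k]] = float(np.sqrt(max(var, 0.0)))
    return shares, se


def interval_endpoint_average(traj: Trajectory, z, species: int = 0,
                              burn_in: float | None = None):
    """Average of X at the *ends* of sojourns labeled ``z`` and the
    time-average of X *during* those sojourns.

    Both estimate the same conditional end-of-sojourn mean: by the waiting
    time paradox a uniformly random time point inside a sojourn behaves
    like a sojourn endpoint.  Returns ``(endpoint_mean, endpoint_se,
    occupation_mean, occupation_se)``.
    """
    if burn_in is None:
        burn_in = 0.2 * traj.t_end
    zi_target = traj.env.index(z)
    t, cum = _cumulative_integral(traj)
    s_start, s_end, s_label = _sojourn_table(traj, burn_in)
    sel = (s_label == zi_target) & (s_end < traj.t_end)
    if sel.sum() < 20:
        raise SimulationError(f"too few sojourns in state {z!r}")
    ends = s_end[sel]
    # value just before the environment jump that ends the sojourn
    end_vals = np.array([
        traj.X[max(np.searchsorted(traj.times, e, side="left") - 1, 0), species]
        for e in ends
    ])
    cumx = cum[:, species]

    def cum_at(s):
        j = np.clip(np.searchsorted(t, s, side="right") - 1, 0, len(t) - 2)
        return cumx[j] + (s - t[j]) * (cumx[j + 1] - cumx[j]) / (t[j + 1] - t[j])

    occ_ints = cum_at(s_end[sel]) - cum_at(s_start[sel])
    occ_times = s_end[sel] - s_start[sel]
    # batch the sojourns into consecutive groups for a ratio-estimator SE
    n_groups = min(20, sel.sum() // 2)
    edges = np.linspace(0, len(occ_ints), n_groups + 1).astype(int)
    g_int = np.add.reduceat(occ_ints, edges[:-1])
    g_time = np.add.reduceat(occ_times, edges[:-1])
    g_ratio = g_int / g_time
    return (float(end_vals.mean()),
            float(end_vals.std(ddof=1) / np.sqrt(len(end_vals))),
            float(occ_ints.sum() / occ_times.sum()),
            float(g_ratio.std(ddof=1) / np.sqrt(n_groups)))


# ---------------------------------------------------------------------------
# Division-dilution lineage simulator


def division_dilution_sim(
    birth_rate: float,
    division_law: str,
    mean_division_time: float,
    n_cycles: int,
    seed: int,
    n_stages: int = 1,
    n_batches: int = 50,
) -> StationaryEstimate:
    """Lineage time-average of a birth process with binomial halving at
    division.

    ``division_law`` is ``"deterministic"`` (all cycles of length
    ``mean_division_time``) or ``"erlang"`` (Erlang with ``n_stages``
    stages and the given mean).  Between divisions, birth events occur as
    a Poisson process of rate ``birth_rate``; at each division the copy
    number is thinned Binomial(n, 1/2).  The first 10% of cycles are
    discarded as burn-in.
    """
    if n_cycles < 10**3:
        raise ValueError("n_cycles must be at least 1000")
    if division_law not in ("deterministic", "erlang"):
        raise ValueError(f"unknown division law {division_law!r}")
    if n_stages < 1 or mean_division_time <= 0 or birth_rate <= 0:
        raise ValueError("invalid division-law parameters")
    rng = np.random.default_rng(seed)
    if division_law == "deterministic":
        taus = np.full(n_cycles, mean_division_time)
    else:
        taus = rng.gamma(shape=n_stages,
                         scale=mean_division_time / n_stages,
                         size=n_cycles)
    x = 0
    burn = n_cycles // 10
    integrals = np.empty(n_cycles - burn)
    times = np.empty(n_cycles - burn)
    for i, tau in enumerate(taus):
        n_births = rng.poisson(birth_rate * tau)
        # integral of X over the cycle: X0*tau + sum of (tau - birth time)
        if n_births:
            birth_times = rng.uniform(0.0, tau, size=n_births)
            integral = x * tau + np.sum(tau - birth_times)
        else:
            integral = x * tau
        if i >= burn:
            integrals[i - burn] = integral
            times[i - burn] = tau
        x = rng.binomial(x + n_births, 0.5)
    edges = np.linspace(0, len(integrals), n_batches + 1).astype(int)
    b_int = np.add.reduceat(integrals, edges[:-1])
    b_time = np.add.reduceat(times, edges[:-1])
    ratios = b_int / b_time
    mean = float(integrals.sum() / times.sum())
    se = float(ratios.std(ddof=1) / np.sqrt(n_batches))
    return StationaryEstimate(
        mean=np.array([mean]), standard_error=np.array([se]),
        burn_in=float(burn), horizon=float(n_cycles), n_batches=n_batches,
        method={"estimator": "division-dilution-lineage", "seed": seed,
                "division_law": division_law, "n_stages": n_stages},
    )
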