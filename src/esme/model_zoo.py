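"""Case-study model constructors.

All constructors are parametrized by biophysically meaningful quantities
(target quasi-steady-state means, environment means, relative correlation
times) and convert them internally to rate constants:

* ``make_e1`` — birth-death subsystem whose death channel is gated by a
  two-state telegraph switch (death rate ``c6 * z``, ``z in {0, 1}``).
* ``make_e2`` — the death modulator is an immigration-death (Poisson)
  environment; optional leak gives the death propensity
  ``(c6 z + leak) x``.
* ``make_e3`` — the modulator's synthesis is itself gated by a second
  telegraph switch, giving a Markov-modulated birth-death modulator on the
  product state space.
* ``make_controller`` — a sensing species U produced proportionally to the
  environment drives the birth of X, whose death the environment
  modulates; the Q.SS setpoint ``c5 c1 / (c2 c6)`` is independent of the
  environment mean.
* ``make_toggle`` / ``make_oscillator`` — two-species gene circuits with
  linearized repression (and induction), modulated by a product
  environment (Z1, Z2); free expression rates are matched so that the
  Q.SS means hit prescribed targets.

Zeroth-order birth modulators are collapsed to their mean by default
(exact at the mean level); a flag re-introduces them as an explicit
environment component for simulator cross-checks.
"""

from __future__ import annotations

import numpy as np

from . import environment as envmod
from .crn_model import LinearSubsystem, ModulatedCRN, RateStructure


class ZooError(ValueError):
    pass


def _scalar_label(z):
    """Death-modulator value from a scalar or tuple label."""
    return z if np.isscalar(z) else z[0]


def make_e1(
    qss_mean: float = 10.0,
    p_off: float = 0.5,
    ratio: float = 1e-3,
    c6: float = 1.0,
    level: float = 1.0,
    explicit_birth_modulator: bool = False,
    birth_mod_speed: float | None = None,
) -> ModulatedCRN:
    """Telegraph-gated death: birth at constant rate, death ``c6*level*z*x``
    with ``z in {0, 1}``.

    The switch rates are chosen so that ``P[Z=0] = p_off`` and the relative
    correlation time ``(c6*level)/(rate_on + rate_off)`` equals ``ratio``;
    the birth rate is set so the Q.SS mean equals ``qss_mean``.  With
    ``level != 1`` the On-state death rate is ``c6*level`` and the
    subsystem relaxation time is ``1/(c6*level)``.
    """
    if not 0.0 < p_off < 1.0:
        raise ZooError("p_off must lie strictly between 0 and 1 "
                       "(the environment degenerates otherwise)")
    if ratio <= 0 or qss_mean <= 0 or c6 <= 0 or level <= 0:
        raise ZooError("qss_mean, ratio, c6 and level must be positive")
    death_on = c6 * level
    total_switch = death_on / ratio
    rate_off = p_off * total_switch       # 1 -> 0
    rate_on = (1.0 - p_off) * total_switch  # 0 -> 1
    lam = qss_mean * death_on * (1.0 - p_off)
    env = envmod.telegraph(rate_on=rate_on, rate_off=rate_off)
    meta = {"zoo": "e1", "qss_mean": qss_mean, "p_off": p_off,
            "ratio": ratio, "c6": c6, "level": level, "birth": lam}
    if explicit_birth_modulator:
        return _with_birth_modulator(env, lam, c6,
                                     lambda z: death_on * _scalar_label(z),
                                     birth_mod_speed, meta)
    sub = LinearSubsystem(["X"], S=[[0, 1]], P=[[1, 0]])
    rates = RateStructure(
        Gamma=lambda z: [[0.0], [death_on * z]],
        gamma=lambda z: [lam, 0.0],
        states=env.states,
    )
    return ModulatedCRN(sub, rates, env, meta=meta)


def make_e2(
    qss_mean: float = 10.0,
    env_mean: float = 8.0,
    ratio: float = 1e-3,
    leak: float = 0.0,
    c6: float = 1.0,
    tail_mass: float = 1e-12,
    explicit_birth_modulator: bool = False,
    birth_mod_speed: float | None = None,
) -> ModulatedCRN:
    """Immigration-death modulator: environment birth ``c3``, death
    ``c4*z`` with ``c3/c4 = env_mean``; subsystem death ``(c6 z + leak) x``
    and constant birth matching the Q.SS mean.  The relative correlation
    time is ``c6/c4 = ratio``.
    """
    if min(qss_mean, env_mean, ratio, c6) <= 0 or leak < 0:
        raise ZooError("parameters must be positive (leak nonnegative)")
    c4 = c6 / ratio
    c3 = env_mean * c4
    lam = qss_mean * (c6 * env_mean + leak)
    env = envmod.birth_death(birth=c3, death=c4, tail_mass=tail_mass)
    meta = {"zoo": "e2", "qss_mean": qss_mean, "env_mean": env_mean,
            "ratio": ratio, "leak": leak, "c6": c6, "birth": lam,
            "c3": c3, "c4": c4}
    death_coeff = lambda z: c6 * _scalar_label(z) + leak
    if explicit_birth_modulator:
        return _with_birth_modulator(env, lam, c6, death_coeff,
                                     birth_mod_speed, meta)
    sub = LinearSubsystem(["X"], S=[[0, 1]], P=[[1, 0]])
    rates = RateStructure(
        Gamma=lambda z: [[0.0], [death_coeff(z)]],
        gamma=lambda z: [lam, 0.0],
        states=env.states,
    )
    return ModulatedCRN(sub, rates, env, meta=meta)


def _with_birth_modulator(base_env, lam, c6, death_coeff, birth_mod_speed,
                          meta):
    """Re-introduce the zeroth-order birth modulator as an explicit
    environment component (mean ``lam/c6``, i.e. ``c5 = c6``): the joint
    environment becomes (Z1, base) and the birth propensity ``c6 * z1``."""
    z1_mean = lam / c6
    speed = birth_mod_speed if birth_mod_speed is not None else 10.0 * c6
    z1_env = envmod.birth_death(birth=z1_mean * speed, death=speed,
                                tail_mass=1e-10)
    env = envmod.product_environment(z1_env, base_env)
    sub = LinearSubsystem(["X"], S=[[0, 1]], P=[[1, 0]])
    rates = RateStructure(
        Gamma=lambda z: [[0.0], [death_coeff(z[1:] if len(z) > 2 else z[1])]],
        gamma=lambda z: [c6 * z[0], 0.0],
        states=env.states,
    )
    meta = dict(meta, explicit_birth_modulator=True)
    return ModulatedCRN(sub, rates, env, meta=meta)


def make_e3(
    qss_mean: float = 10.0,
    env2_mean: float = 8.0,
    ratio: float = 1e-3,
    switch_ratio: float = 10.0,
    switch_on_fraction: float = 0.8,
    c6: float = 1.0,
    tail_mass: float = 1e-12,
) -> ModulatedCRN:
    """Mutable modulator synthesis: the modulator Z2 (birth ``c3 * z3``,
    death ``c4 * z2``) is gated by a telegraph switch Z3 with
    ``E[Z3] = switch_on_fraction`` and switch correlation-time ratio
    ``(c7 + c8)/c4 = switch_ratio``.

    The joint (Z2, Z3) environment is Markov, so the exact solver applies
    even though Z2 alone is not Markov.  ``c3`` is chosen so the stationary
    modulator mean is ``env2_mean`` (exact: the modulator is linear in the
    switch), and the subsystem birth matches the Q.SS mean.
    """
    if not 0.0 < switch_on_fraction < 1.0:
        raise ZooError("switch_on_fraction must lie strictly in (0, 1)")
    if min(qss_mean, env2_mean, ratio, switch_ratio, c6) <= 0:
        raise ZooError("parameters must be positive")
    c4 = c6 / ratio
    total = switch_ratio * c4
    c7 = switch_on_fraction * total       # off -> on
    c8 = (1.0 - switch_on_fraction) * total
    c3 = env2_mean * c4 / switch_on_fraction
    lam = qss_mean * c6 * env2_mean
    env = envmod.modulated_birth_death(
        birth=c3, death=c4, switch_on=c7, switch_off=c8, tail_mass=tail_mass)
    sub = LinearSubsystem(["X"], S=[[0, 1]], P=[[1, 0]])
    rates = RateStructure(
        Gamma=lambda z: [[0.0], [c6 * z[0]]],
        gamma=lambda z: [lam, 0.0],
        states=env.states,
    )
    meta = {"zoo": "e3", "qss_mean": qss_mean, "env2_mean": env2_mean,
            "ratio": ratio, "switch_ratio": switch_ratio,
            "switch_on_fraction": switch_on_fraction, "c6": c6,
            "c3": c3, "c4": c4, "c7": c7, "c8": c8, "birth": lam}
    return ModulatedCRN(sub, rates, env, meta=meta)


def make_controller(
    c1: float = 1000.0,
    c2: float = 100.0,
    c5: float = 1.0,
    c6: float = 1.0,
    env_mean: float = 4.0,
    env_speed: float = 1.0,
    tail_mass: float = 1e-12,
    sensing: str = "proportional",
) -> ModulatedCRN:
    """Environment-sensing controller: U is produced at rate ``c1 * z``
    (proportional sensing) and decays at rate ``c2 u``; X is born at rate
    ``c5 u`` and degraded at rate ``c6 z x``.  The environment is an
    immigration-death chain of mean ``env_mean`` with ``c6/c4 =
    env_speed``.

    The Q.SS mean of X is ``c5 c1/(c2 c6)`` — independent of the
    environment mean, which is the controller's design point.  With
    ``sensing="indicator"`` U is produced at rate ``c1 * 1(z >= 1)``
    instead (an alternative sensing law, provided without fidelity claims
    for the published excursion analysis, which assumes proportionality).
    """
    if min(c1, c2, c5, c6, env_mean, env_speed) <= 0:
        raise ZooError("all controller parameters must be positive")
    if sensing not in ("proportional", "indicator"):
        raise ZooError(f"unknown sensing mode {sensing!r}")
    c4 = c6 / env_speed
    c3 = env_mean * c4
    env = envmod.birth_death(birth=c3, death=c4, tail_mass=tail_mass)
    sub = LinearSubsystem(
        ["U", "X"],
        S=[[0, 1, 1, 0], [0, 0, 0, 1]],
        P=[[1, 0, 1, 0], [0, 0, 1, 0]],
    )
    if sensing == "proportional":
        sense = lambda z: c1 * z
    else:
        sense = lambda z: c1 * (1.0 if z >= 1 else 0.0)
    rates = RateStructure(
        Gamma=lambda z: [[0.0, 0.0], [c2, 0.0], [c5, 0.0], [0.0, c6 * z]],
        gamma=lambda z: [sense(z), 0.0, 0.0, 0.0],
        states=env.states,
    )
    meta = {"zoo": "controller", "c1": c1, "c2": c2, "c5": c5, "c6": c6,
            "env_mean": env_mean, "env_speed": env_speed, "sensing": sensing}
    return ModulatedCRN(sub, rates, env, meta=meta)


def match_qss_rates(
    kind: str,
    x1_target: float,
    x2_target: float,
    b1: float,
    b2: float | None,
    e_z1: float,
    death_rate: float,
) -> dict:
    """Solve the Q.SS balance equations for the free expression rates.

    ``death_rate`` is the environment-averaged first-order decay rate
    ``c6 * E[Z2]``.  For the toggle (repression both ways) the balance is::

        E[Z1] (a1 - b1 x2*) = death_rate * x1*
        E[Z1] (a2 - b2 x1*) = death_rate * x2*

    solved for ``(a1, a2)``.  For the oscillator (X1 induces X2)::

        E[Z1] (a1 - b1 x2*) = death_rate * x1*
        E[Z1] b2 x1*        = death_rate * x2*

    solved for ``(a1, b2)``.  Raises when a solution is nonpositive,
    naming the infeasible target.
    """
    if min(x1_target, x2_target, e_z1, death_rate) <= 0:
        raise ZooError("targets, E[Z1] and death rate must be positive")
    a1 = death_rate * x1_target / e_z1 + b1 * x2_target
    if kind == "toggle":
        if b2 is None:
            raise ZooError("toggle matching requires b2")
        a2 = death_rate * x2_target / e_z1 + b2 * x1_target
        out = {"a1": a1, "a2": a2}
    elif kind == "oscillator":
        b2_matched = death_rate * x2_target / (e_z1 * x1_target)
        out = {"a1": a1, "b2": b2_matched}
    else:
        raise ZooError(f"unknown network kind {kind!r}")
    for name, val in out.items():
        if val <= 0:
            raise ZooError(
                f"Q.SS matching infeasible: {name} = {val:.4g} <= 0 for "
                f"targets ({x1_target}, {x2_target})"
            )
    return out


def _toggle_like_env(c1, c2, env2_mean, c6, ratio, tail_mass):
    c4 = c6 / ratio
    c3 = env2_mean * c4
    z1_env = envmod.birth_death(birth=c1, death=c2, tail_mass=tail_mass)
    z2_env = envmod.birth_death(birth=c3, death=c4, tail_mass=tail_mass)
    return envmod.product_environment(z1_env, z2_env), c3, c4


def make_toggle(
    x1_qss: float = 30.0,
    x2_qss: float = 25.0,
    b1: float = 0.02,
    b2: float = 0.02,
    c1: float = 300.0,
    c2: float = 100.0,
    env2_mean: float = 10.0,
    c6: float = 0.01,
    ratio: float = 1e-3,
    tail_mass: float = 1e-8,
) -> ModulatedCRN:
    """Toggle switch under a product environment (Z1, Z2).

    X1 and X2 are produced at rates ``z1 (a1 - b1 x2)`` and
    ``z1 (a2 - b2 x1)`` (linearized mutual repression) and degraded at
    rates ``c6 z2 x_i``; ``a1, a2`` are matched so the Q.SS means equal
    ``(x1_qss, x2_qss)``.  Linearized repression puts negative first-order
    coefficients in the rate structure, so the share-based validity report
    is the decisive applicability gate.
    """
    e_z1 = c1 / c2
    matched = match_qss_rates("toggle", x1_qss, x2_qss, b1, b2, e_z1,
                              c6 * env2_mean)
    a1, a2 = matched["a1"], matched["a2"]
    env, c3, c4 = _toggle_like_env(c1, c2, env2_mean, c6, ratio, tail_mass)
    sub = LinearSubsystem(
        ["X1", "X2"],
        S=[[0, 0, 1, 0], [0, 0, 0, 1]],
        P=[[1, 0, 0, 0], [0, 1, 0, 0]],
    )
    rates = RateStructure(
        Gamma=lambda z: [[0.0, -b1 * z[0]],
                         [-b2 * z[0], 0.0],
                         [c6 * z[1], 0.0],
                         [0.0, c6 * z[1]]],
        gamma=lambda z: [a1 * z[0], a2 * z[0], 0.0, 0.0],
        states=env.states,
    )
    meta = {"zoo": "toggle", "a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "c3": c3, "c4": c4, "c6": c6,
            "env2_mean": env2_mean, "ratio": ratio,
            "x1_qss": x1_qss, "x2_qss": x2_qss}
    return ModulatedCRN(sub, rates, env, meta=meta)


def make_oscillator(
    x1_qss: float = 40.0,
    x2_qss: float = 20.0,
    b1: float = 0.02,
    c1: float = 300.0,
    c2: float = 100.0,
    env2_mean: float = 10.0,
    c6: float = 0.01,
    ratio: float = 1e-3,
    tail_mass: float = 1e-8,
) -> ModulatedCRN:
    """Oscillator variant of the toggle: X2 is *induced* by X1 at rate
    ``z1 b2 x1`` instead of being repressed; ``a1`` and ``b2`` are matched
    to the Q.SS targets.  The per-state mean dynamics are rotational
    (purely imaginary eigenvalues when the degradation channel is off).
    """
    e_z1 = c1 / c2
    matched = match_qss_rates("oscillator", x1_qss, x2_qss, b1, None, e_z1,
                              c6 * env2_mean)
    a1, b2 = matched["a1"], matched["b2"]
    env, c3, c4 = _toggle_like_env(c1, c2, env2_mean, c6, ratio, tail_mass)
    sub = LinearSubsystem(
        ["X1", "X2"],
        S=[[0, 0, 1, 0], [0, 0, 0, 1]],
        P=[[1, 0, 0, 0], [0, 1, 0, 0]],
    )
    rates = RateStructure(
        Gamma=lambda z: [[0.0, -b1 * z[0]],
                         [b2 * z[0], 0.0],
                         [c6 * z[1], 0.0],
                         [0.0, c6 * z[1]]],
        gamma=lambda z: [a1 * z[0], 0.0, 0.0, 0.0],
        states=env.states,
    )
    meta = {"zoo": "oscillator", "a1": a1, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "c3": c3, "c4": c4, "c6": c6,
            "env2_mean": env2_mean, "ratio": ratio,
            "x1_qss": x1_qss, "x2_qss": x2_qss}
    return ModulatedCRN(sub, rates, env, meta=meta)


def asymmetry_ratios(means, qss_means) -> tuple[float, float, float]:
    """Asymmetry diagnostics ``(r, r0, R)``: the ratio of the stationary
    means, the ratio of the Q.SS means, and the relative change
    ``R = r / r0``."""
    m1, m2 = float(means[0]), float(means[1])
    q1, q2 = float(qss_means[0]), float(qss_means[1])
    if m2 == 0 or q2 == 0 or q1 == 0:
        raise ZeroDivisionError("asymmetry ratio undefined: zero denominator")
    r = m1 / m2
    r0 = q1 / q2
    return r, r0, r / r0


ZOO = {
    "e1": make_e1,
    "e2": make_e2,
    "e3": make_e3,
    "controller": make_controller,
    "toggle": make_toggle,
    "oscillator": make_oscillator,
}
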