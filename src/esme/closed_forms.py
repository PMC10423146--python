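"""Analytic reference formulas for the case-study models.

These closed forms serve both as user-facing conveniences and as oracles
for the block solver: the telegraph-modulated death model has an exact
stationary mean, the birth-death-modulated variant an approximation valid
in the extreme time-scale regimes, the division-dilution lineage model an
exact mean in terms of the division-time law, and the environment-sensing
controller two simple laws for its accuracy/speed trade-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class TelegraphDeathParams:
    """Birth-death subsystem whose death channel is gated by a two-state
    switch: ``qss_mean`` is the environment-averaged reference mean,
    ``p_off`` the stationary probability of the Off (zero-death) state and
    ``ratio`` the relative correlation time tau_Z / tau_X."""

    qss_mean: float
    p_off: float
    ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_off <= 1.0:
            raise ValueError("p_off must lie in [0, 1]")
        if self.ratio < 0:
            raise ValueError("ratio must be nonnegative")
        if self.qss_mean <= 0:
            raise ValueError("qss_mean must be positive")


@dataclass
class DivisionDilutionParams:
    """Lineage model: births at rate ``birth_rate`` between divisions,
    binomial halving at division; the division time has the given mean and
    variance."""

    birth_rate: float
    mean_division_time: float
    var_division_time: float

    def __post_init__(self) -> None:
        if self.birth_rate <= 0 or self.mean_division_time <= 0:
            raise ValueError("birth rate and mean division time must be positive")
        if self.var_division_time < 0:
            raise ValueError("division-time variance must be nonnegative")


def telegraph_mean(p: TelegraphDeathParams) -> float:
    """Exact stationary mean of the telegraph-death model:
    ``qss_mean * (1 + p_off * ratio)``.

    The deviation from the Q.SS reference is exactly ``p_off * ratio``:
    proportional to the fraction of time the death channel is off and to
    the time-scale separation.
    """
    return p.qss_mean * (1.0 + p.p_off * p.ratio)


def e2_matched_curve(qss_mean: float, env_mean: float, ratio: float) -> float:
    """Telegraph-matched approximation for a birth-death death-modulator:
    ``qss_mean * (1 + ratio * exp(-env_mean))``.

    Obtained by substituting ``p_off = exp(-env_mean)`` (the Poisson zero
    probability) and ``tau_Z = 1/c4`` into the telegraph formula.  Valid in
    the two extreme regimes (ratio -> 0 and ratio -> inf); a systematic
    discrepancy appears at intermediate ratios, where sub-mean non-zero
    environment states dominate the stationary mean.
    """
    if env_mean <= 0:
        raise ValueError("env_mean must be positive")
    if ratio < 0:
        raise ValueError("ratio must be nonnegative")
    return qss_mean * (1.0 + ratio * math.exp(-env_mean))


def division_dilution_mean(p: DivisionDilutionParams) -> float:
    """Exact lineage stationary mean
    ``(lambda/2) * (3 E[tau] + Var[tau]/E[tau])``.

    Randomness in the division time increases the mean: the term
    ``Var[tau]/E[tau]`` vanishes for deterministic divisions.
    """
    lam = p.birth_rate
    m, v = p.mean_division_time, p.var_division_time
    return 0.5 * lam * (3.0 * m + v / m)


def division_dilution_mean_erlang(birth_rate: float, n_stages: int,
                                  mean_division_time: float) -> float:
    """Erlang(N, N/y) division-time convenience: ``(lambda/2)(3y + y/N)``."""
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    y = mean_division_time
    return division_dilution_mean(DivisionDilutionParams(
        birth_rate=birth_rate, mean_division_time=y,
        var_division_time=y * y / n_stages))


def controller_laws(qss_mean: float, c6: float, c2: float,
                    delta_star: float) -> tuple[float, float]:
    """Accuracy laws for the environment-sensing controller.

    Returns ``(plateau_deviation, critical_speed_ratio)``:

    * ``plateau_deviation = qss_mean * c6 / c2`` — the asymptotic excess of
      the controlled species over its setpoint during an infinitely long
      zero-environment excursion (the controller's residual error).
    * ``critical_speed_ratio = 1 / delta_star`` — the relative controller
      speed ``c2/c6`` needed to keep the relative deviation below
      ``delta_star`` for every environment mean and speed.
    """
    if min(qss_mean, c6, c2) <= 0:
        raise ValueError("qss_mean, c6 and c2 must be positive")
    if delta_star <= 0:
        raise ValueError("delta_star must be positive")
    return qss_mean * c6 / c2, 1.0 / delta_star


def slow_env_slope(mean_at_ratio, ratio_lo: float, ratio_hi: float) -> float:
    """Log-log secant slope of the stationary mean between two large
    relative correlation times.

    ``mean_at_ratio`` is a callable ratio -> stationary mean (typically a
    model-zoo constructor composed with the block solver).  In the slow-
    environment regime the mean of the uncontrolled case studies grows
    linearly in the ratio, so the slope tends to one; a homogeneous model
    gives slope zero.
    """
    if min(ratio_lo, ratio_hi) < 1e2:
        raise ValueError("slope estimation requires ratios >= 100")
    m_lo = float(mean_at_ratio(ratio_lo))
    m_hi = float(mean_at_ratio(ratio_hi))
    if m_lo <= 0 or m_hi <= 0:
        raise ValueError("stationary means must be positive for a log-log slope")
    return math.log(m_hi / m_lo) / math.log(ratio_hi / ratio_lo)
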