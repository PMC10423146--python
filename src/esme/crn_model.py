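"""Linear subsystems with environment-modulated rates.

A linear CRN has propensities affine in the species counts,
``f(x | z) = Gamma(z) x + gamma(z)``: only zeroth- and first-order
reactions under mass action, although the affine form also admits
linearized regulatory terms such as repression ``a - b * x_other``.
The per-state mean dynamics are ``d/dt E[X] = b(z) - A(z) E[X]`` with
``A(z) = -N Gamma(z)`` and ``b(z) = N gamma(z)``, where ``N = P - S``
is the stoichiometric matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import MarkovEnvironment


class ModelError(ValueError):
    """Raised for structurally invalid model definitions."""


class StabilityError(ModelError):
    """Raised when the ergodicity assumptions are violated."""


def build_stoichiometry(S, P) -> np.ndarray:
    """Stoichiometric matrix ``N = P - S`` from substrate/product coefficients.

    Both inputs are (d species x M reactions) nonnegative integer matrices.
    """
    S = np.asarray(S, dtype=int)
    P = np.asarray(P, dtype=int)
    if S.shape != P.shape:
        raise ModelError(f"shape mismatch: S {S.shape} vs P {P.shape}")
    if np.any(S < 0) or np.any(P < 0):
        raise ModelError("stoichiometric coefficients must be nonnegative")
    return P - S


@dataclass
class LinearSubsystem:
    """Species and stoichiometry of a linear subsystem.

    Every reaction must have total substrate order at most one, counting
    subsystem species only (environment species do not appear here).
    """

    species_names: list
    S: np.ndarray
    P: np.ndarray
    N: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=int)
        self.P = np.asarray(self.P, dtype=int)
        if self.S.shape[0] != len(self.species_names):
            raise ModelError("substrate matrix rows must match species count")
        self.N = build_stoichiometry(self.S, self.P)
        orders = self.S.sum(axis=0)
        if np.any(orders > 1):
            bad = np.nonzero(orders > 1)[0].tolist()
            raise ModelError(
                f"reactions {bad} have substrate order >= 2; only zeroth- and "
                "first-order reactions are admissible in a linear subsystem"
            )

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]


class RateStructure:
    """Environment-indexed affine rate coefficients.

    ``Gamma(z)`` is the (M x d) matrix of first-order coefficients and
    ``gamma(z)`` the length-M vector of constant propensity terms, so the
    propensity vector in environment state ``z`` is
    ``f(x | z) = Gamma(z) x + gamma(z)``.

    Rates may be supplied either as explicit per-state tables (dicts keyed
    by state label) or as callables of the state label; callables are
    tabulated over the finite state list at construction.
    """

    def __init__(self, Gamma, gamma, states):
        self.states = list(states)
        self._Gamma = {}
        self._gamma = {}
        for z in self.states:
            G = Gamma(z) if callable(Gamma) else Gamma[z]
            g = gamma(z) if callable(gamma) else gamma[z]
            G = np.asarray(G, dtype=float)
            g = np.asarray(g, dtype=float)
            if not (np.all(np.isfinite(G)) and np.all(np.isfinite(g))):
                raise ModelError(f"non-finite rate coefficients at state {z!r}")
            if np.any(g < 0):
                raise ModelError(
                    f"negative zeroth-order propensity at state {z!r}"
                )
            self._Gamma[z] = G
            self._gamma[z] = g

    def Gamma(self, z) -> np.ndarray:
        return self._Gamma[z]

    def gamma(self, z) -> np.ndarray:
        return self._gamma[z]

    @property
    def has_negative_first_order(self) -> bool:
        """True when any first-order coefficient is negative (linearized
        repression); such models are gated by the validity report rather
        than by the per-state eigenvalue check."""
        return any(np.any(G < 0) for G in self._Gamma.values())


@dataclass
class StabilityReport:
    min_real_parts: dict
    violating_states: list
    qss_hurwitz: bool
    qss_min_real: float
    passed: bool

    def __str__(self) -> str:
        lines = [f"Q.SS Hurwitz: {self.qss_hurwitz} "
                 f"(min Re eigenvalue {self.qss_min_real:.3e})"]
        worst = min(self.min_real_parts.values())
        lines.append(f"per-state min Re eigenvalue of A(z): {worst:.3e}")
        if self.violating_states:
            lines.append(f"states below tolerance: {self.violating_states}")
        lines.append("PASS" if self.passed else "FAIL")
        return "\n".join(lines)


class ModulatedCRN:
    """Linear subsystem + rate structure + Markov environment."""

    def __init__(
        self,
        subsystem: LinearSubsystem,
        rates: RateStructure,
        environment: MarkovEnvironment,
        validate: bool = True,
        eps_stab: float = 1e-9,
        meta: dict | None = None,
    ):
        self.subsystem = subsystem
        self.rates = rates
        self.environment = environment
        self.meta = dict(meta or {})
        d, M = subsystem.n_species, subsystem.n_reactions
        for z in environment.states:
            if rates.Gamma(z).shape != (M, d):
                raise ModelError(
                    f"Gamma({z!r}) has shape {rates.Gamma(z).shape}, "
                    f"expected {(M, d)}"
                )
            if rates.gamma(z).shape != (M,):
                raise ModelError(f"gamma({z!r}) must have length {M}")
        if validate:
            self.stability_report = validate_stability(self, eps_stab)
        else:
            self.stability_report = None

    @property
    def n_species(self) -> int:
        return self.subsystem.n_species

    def rate_matrices_at(self, z):
        """Per-state mean dynamics matrices ``(A(z), b(z))``."""
        return rate_matrices_at(self, z)

    def propensities(self, x, z) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.rates.Gamma(z) @ x + self.rates.gamma(z)

    def qss_matrices(self):
        """Environment-averaged ``(A_bar, b_bar)`` of the Q.SS reference."""
        env = self.environment
        Gbar = sum(p * self.rates.Gamma(z)
                   for z, p in zip(env.states, env.pi))
        gbar = sum(p * self.rates.gamma(z)
                   for z, p in zip(env.states, env.pi))
        N = self.subsystem.N
        return -N @ Gbar, N @ gbar


def rate_matrices_at(crn: ModulatedCRN, z):
    """``A(z) = -N Gamma(z)`` and ``b(z) = N gamma(z)`` for one state."""
    if z not in crn.rates._Gamma:
        raise ModelError(f"unknown environment state {z!r}")
    N = crn.subsystem.N
    A = -N @ crn.rates.Gamma(z)
    b = N @ crn.rates.gamma(z)
    return A, b


def validate_stability(crn: ModulatedCRN, eps_stab: float = 1e-9) -> StabilityReport:
    """Check the ergodicity assumptions of the stationary-mean theory.

    Per state, ``A(z)`` must have eigenvalues with real part >= -eps_stab
    (zero is allowed: a switched-off degradation channel contributes a zero
    eigenvalue).  The environment-averaged ``A_bar`` must be strictly
    Hurwitz, which guarantees convergence to a stationary mean.

    Raises :class:`StabilityError` when ``A_bar`` is not Hurwitz, or when a
    per-state violation occurs in a model without linearized repression
    terms.  Models with negative first-order coefficients may violate the
    per-state bound inside their declared validity region; for those the
    violation is recorded in the report and the share-based validity report
    is the decisive gate.
    """
    min_real = {}
    violating = []
    for z in crn.environment.states:
        A, _ = rate_matrices_at(crn, z)
        mr = float(np.min(np.linalg.eigvals(A).real))
        min_real[z] = mr
        if mr < -eps_stab:
            violating.append(z)
    Abar, _ = crn.qss_matrices()
    eig = np.linalg.eigvals(Abar)
    qss_min = float(np.min(eig.real))
    hurwitz = qss_min > eps_stab
    if not hurwitz:
        raise StabilityError(
            f"Q.SS matrix is not Hurwitz (min Re eigenvalue {qss_min:.3e}); "
            "the model has no stationary mean"
        )
    if violating and not crn.rates.has_negative_first_order:
        raise StabilityError(
            f"A(z) has eigenvalues with real part < -{eps_stab:g} in states "
            f"{violating}"
        )
    return StabilityReport(
        min_real_parts=min_real,
        violating_states=violating,
        qss_hurwitz=hurwitz,
        qss_min_real=qss_min,
        passed=hurwitz,
    )
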