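"""Structural kinetic models and the observation likelihood.

The tracer is injected into a depot (the CSF space), transfers to the central
compartment (blood) by a first-order process with rate constant ``ka`` after
an absorption lag ``tlag``, optionally distributes to a peripheral tissue
compartment (``kcp``/``kpc``), and is eliminated from the central compartment
with first-order rate ``ke``:

    dAd/dt = -ka * Ad                                   (for t > tlag)
    dAc/dt =  ka * Ad - (ke + kcp) * Ac + kpc * Ap
    dAp/dt =  kcp * Ac - kpc * Ap
    C(t)   =  Ac / V

The system is linear, so profiles are evaluated in closed form (partial
fractions over the three exponentials exp(-ka t), exp(-alpha t),
exp(-beta t)) with no step-size-dependent error.

Units are fixed so that no conversion constants appear anywhere: amounts in
umol, volume in L, concentration in uM (= umol/L), time in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GROUPS",
    "ONE_COMPARTMENT",
    "TWO_COMPARTMENT",
    "STRUCTURE_PARAMS",
    "AssayErrorModel",
    "DoseEvent",
    "Observation",
    "PKParameters",
    "SubjectRecord",
    "solve_amounts",
    "solve_profile",
    "subject_loglik",
]

#: Diagnosis groups of the study cohort.
GROUPS = ("REF", "PC", "AC", "SIH", "IIH", "iNPH", "CommHC", "NonCommHC")

ONE_COMPARTMENT = "one_compartment"
TWO_COMPARTMENT = "two_compartment"

#: Structural parameters estimated per model structure (in fitting order).
STRUCTURE_PARAMS = {
    ONE_COMPARTMENT: ("ka", "tlag", "v", "ke"),
    TWO_COMPARTMENT: ("ka", "tlag", "v", "ke", "kcp", "kpc"),
}

Structure = Literal["one_compartment", "two_compartment"]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class ParameterDomainError(ValueError):
    """A kinetic parameter violates its physical domain."""


@dataclass(frozen=True)
class PKParameters:
    """Structural model parameter vector.

    ka : absorption rate constant CSF -> blood (1/h), > 0
    tlag : absorption lag time (h), >= 0
    v : central volume of distribution (L), > 0
    ke : first-order elimination rate from central (1/h), >= 0
         (ke = 0 only for degenerate mass-balance checks)
    kcp, kpc : central<->peripheral transfer rates (1/h), >= 0;
         the one-compartment structure is kcp = kpc = 0
    """

    ka: float
    tlag: float
    v: float
    ke: float
    kcp: float = 0.0
    kpc: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.ka, self.tlag, self.v, self.ke, self.kcp, self.kpc)
        if not all(math.isfinite(x) for x in vals):
            raise ParameterDomainError(f"non-finite parameter in {vals}")
        if self.ka <= 0:
            raise ParameterDomainError(f"ka must be > 0, got {self.ka}")
        if self.v <= 0:
            raise ParameterDomainError(f"v must be > 0, got {self.v}")
        if self.tlag < 0:
            raise ParameterDomainError(f"tlag must be >= 0, got {self.tlag}")
        if self.ke < 0 or self.kcp < 0 or self.kpc < 0:
            raise ParameterDomainError(
                f"rate constants must be >= 0, got ke={self.ke} "
                f"kcp={self.kcp} kpc={self.kpc}"
            )

    @property
    def structure(self) -> Structure:
        return ONE_COMPARTMENT if self.kcp == 0.0 and self.kpc == 0.0 else TWO_COMPARTMENT

    def as_array(self, structure: Structure) -> np.ndarray:
        return np.array([getattr(self, n) for n in STRUCTURE_PARAMS[structure]])

    @classmethod
    def from_array(cls, values: Sequence[float], structure: Structure) -> "PKParameters":
        names = STRUCTURE_PARAMS[structure]
        return cls(**dict(zip(names, (float(x) for x in values))))


@dataclass(frozen=True)
class DoseEvent:
    """One intrathecal (depot) dose.

    amount : tracer amount in umol (dose in mmol x 1000)
    time : hours, 0 at injection
    """

    amount: float
    time: float = 0.0
    route: str = "depot"

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")

    @property
    def dose_mmol(self) -> float:
        return self.amount / 1000.0


@dataclass(frozen=True)
class Observation:
    """A single blood sample.

    time : hours post-dose; concentration : uM; matrix : "plasma" or
    "whole_blood"; below_loq flags samples under the assay detection
    threshold (excluded from the likelihood by default policy).
    """

    time: float
    concentration: float
    matrix: str = "plasma"
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")
        if self.concentration < 0:
            raise ValueError(
                f"concentration must be >= 0, got {self.concentration}"
            )
        if self.matrix not in ("plasma", "whole_blood"):
            raise ValueError(f"unknown matrix {self.matrix!r}")


@dataclass(frozen=True)
class SubjectRecord:
    """One patient: dose event, ordered observation series, group label."""

    id: str
    group: str
    dose: DoseEvent
    observations: tuple[Observation, ...]
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        obs = tuple(self.observations)
        object.__setattr__(self, "observations", obs)
        times = [o.time for o in obs]
        if times != sorted(times):
            raise ValueError(f"subject {self.id}: observations not sorted by time")

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def usable_observations(self) -> tuple[Observation, ...]:
        """Observations entering the likelihood (non-BLQ)."""
        return tuple(o for o in self.observations if not o.below_loq)

    @property
    def obs_times(self) -> np.ndarray:
        return np.array([o.time for o in self.usable_observations()])

    @property
    def obs_conc(self) -> np.ndarray:
        return np.array([o.concentration for o in self.usable_observations()])


@dataclass(frozen=True)
class AssayErrorModel:
    """Polynomial assay error: SD(C) = c0 + c1 * C.

    c0 is the additive floor in uM (strictly positive so the SD never
    vanishes at zero concentration), c1 the proportional coefficient.
    """

    c0: float = 0.002
    c1: float = 0.05

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError(f"c0 must be > 0, got {self.c0}")
        if self.c1 < 0:
            raise ValueError(f"c1 must be >= 0, got {self.c1}")

    def sd(self, conc: np.ndarray | float) -> np.ndarray | float:
        return self.c0 + self.c1 * np.asarray(conc, dtype=float)


def _disposition_eigenvalues(ke: float, kcp: float, kpc: float) -> tuple[float, float]:
    """Roots alpha >= beta >= 0 of s^2 + (ke+kcp+kpc) s + ke*kpc.

    beta is computed from the product alpha*beta = ke*kpc to avoid
    cancellation when the roots are far apart.
    """
    s = ke + kcp + kpc
    disc = s * s - 4.0 * ke * kpc
    root = math.sqrt(max(disc, 0.0))
    alpha = 0.5 * (s + root)
    beta = (ke * kpc / alpha) if alpha > 0.0 else 0.0
    return alpha, beta


def _deconflict(params: PKParameters) -> tuple[float, float, float]:
    """Return (ka, alpha, beta) with degeneracies perturbed away.

    The partial-fraction solution divides by (ka - alpha), (ka - beta) and
    (alpha - beta). Confluent cases are handled by a 1e-9 relative
    perturbation of ka (and of ke for a repeated disposition root); the
    induced profile error is orders of magnitude below assay noise.
    """
    ka, ke = params.ka, params.ke
    alpha, beta = _disposition_eigenvalues(ke, params.kcp, params.kpc)
    if alpha > 0 and abs(alpha - beta) < 1e-9 * alpha:
        alpha, beta = _disposition_eigenvalues(ke * (1.0 + 1e-7), params.kcp, params.kpc)
    for _ in range(3):
        scale = max(ka, alpha, 1e-30)
        if abs(ka - alpha) > 1e-9 * scale and abs(ka - beta) > 1e-9 * scale:
            break
        ka *= 1.0 + 1e-9
    return ka, alpha, beta


def solve_amounts(
    params: PKParameters, dose: DoseEvent, times: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form depot, central and peripheral amounts (umol) over time.

    Before the absorption lag the full dose sits in the depot. Afterwards the
    depot drains as D*exp(-ka*(t - tlag)) and the central/peripheral amounts
    follow from partial fractions over the three system exponentials.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted")

    depot = np.full_like(t, float(dose.amount))
    central = np.zeros_like(t)
    peripheral = np.zeros_like(t)
    if dose.amount == 0.0:
        return depot, central, peripheral

    ka, alpha, beta = _deconflict(params)
    ts = t - params.tlag
    active = ts > 0.0
    if not np.any(active):
        return depot, central, peripheral
    ts = ts[active]

    ea = np.exp(-alpha * ts)
    eb = np.exp(-beta * ts)
    ek = np.exp(-ka * ts)

    d = float(dose.amount)
    kpc = params.kpc
    # Ac(s) = ka*D*(s+kpc) / ((s+ka)(s+alpha)(s+beta))
    c1 = (kpc - alpha) / ((ka - alpha) * (beta - alpha))
    c2 = (kpc - beta) / ((ka - beta) * (alpha - beta))
    c3 = (kpc - ka) / ((alpha - ka) * (beta - ka))
    ac = ka * d * (c1 * ea + c2 * eb + c3 * ek)
    # Ap(s) = ka*kcp*D / ((s+ka)(s+alpha)(s+beta))
    d1 = 1.0 / ((ka - alpha) * (beta - alpha))
    d2 = 1.0 / ((ka - beta) * (alpha - beta))
    d3 = 1.0 / ((alpha - ka) * (beta - ka))
    ap = ka * params.kcp * d * (d1 * ea + d2 * eb + d3 * ek)

    depot[active] = d * ek
    central[active] = np.maximum(ac, 0.0)
    peripheral[active] = np.maximum(ap, 0.0)
    return depot, central, peripheral


def solve_profile(
    params: PKParameters,
    dose: DoseEvent,
    times: Sequence[float],
    structure: Structure = TWO_COMPARTMENT,
) -> np.ndarray:
    """Concentration profile C(t) = Ac(t)/V in uM at the requested times.

    ``structure`` must be consistent with the parameter vector: the
    one-compartment model requires kcp = kpc = 0.
    """
    if structure not in STRUCTURE_PARAMS:
        raise ValueError(f"unknown structure {structure!r}")
    if structure == ONE_COMPARTMENT and (params.kcp != 0.0 or params.kpc != 0.0):
        raise ParameterDomainError(
            "one-compartment structure requires kcp = kpc = 0"
        )
    _, central, _ = solve_amounts(params, dose, times)
    return central / params.v


def subject_loglik(
    subject: SubjectRecord,
    params: PKParameters,
    error: AssayErrorModel,
    structure: Structure | None = None,
) -> float:
    """Gaussian log-likelihood (nats) of a subject's usable observations.

    Residuals observed - predicted are scored against N(0, SD^2) with
    SD = c0 + c1 * C_obs: the assay-error polynomial is applied to the
    measured concentration, so the weighting of an observation does not
    depend on the candidate parameters (a prediction-based SD rewards
    systematic underprediction through the -log SD term). Observations must
    already be expressed in plasma-equivalent uM (see
    :func:`csfclear.metrics.convert_matrix`).
    """
    times = subject.obs_times
    if times.size == 0:
        raise ValueError(f"subject {subject.id} has no usable observations")
    if structure is None:
        structure = params.structure
    pred = solve_profile(params, subject.dose, times, structure)
    sd = np.asarray(error.sd(subject.obs_conc))
    resid = subject.obs_conc - pred
    return float(np.sum(-np.log(sd) - _LOG_SQRT_2PI - 0.5 * (resid / sd) ** 2))


def replace_params(params: PKParameters, **kwargs) -> PKParameters:
    """Functional update of a parameter vector."""
    return replace(params, **kwargs)
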