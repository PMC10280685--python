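"""Measurement models for the joint analysis of response accuracy and response times.

Two level-1 models are evaluated here, both stateless:

* a normal-ogive (probit) IRT model for binary response accuracy, optionally
  with a lower-asymptote guessing parameter (3PL), and
* a log-normal model for response times, in which a person's working speed
  shortens the expected log-time of an item through the item's
  time-discrimination parameter.

Both models exist in two algebraically equivalent bracketings of the mean
term.  In the non-bracketed form the success probability is
``Phi(a*theta - b)`` and the expected log-RT is ``lambda - phi*zeta``; in the
bracketed form the difficulty/time-intensity are expressed on the latent
scale itself, ``Phi(a*(theta - b))`` and ``phi*(lambda - zeta)``.  A third
convention treats the time discrimination as the reciprocal of the residual
standard deviation, in which case the mean log-RT is simply
``lambda - zeta``.  The :class:`Parameterization` flag records which
convention is in force so difficulties on different scales are never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

__all__ = [
    "ItemParameters",
    "PersonParameters",
    "Parameterization",
    "success_probability",
    "expected_log_rt",
    "probit_logistic_transform",
    "LOGISTIC_SCALE_FACTOR",
]

#: Scale factor relating logistic and probit item parameters.
LOGISTIC_SCALE_FACTOR = 1.7


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class ItemParameters:
    """Per-item parameters of the joint model.

    Parameters
    ----------
    a : array_like
        Discrimination, positive.
    b : array_like
        Difficulty.  Interpreted on the ``a*theta - b`` scale unless the
        bracketed convention is used, in which case it is on the theta scale.
    c : array_like
        Guessing probability (lower asymptote), in ``[0, 1)``.
    phi : array_like
        Time discrimination, positive.
    lam : array_like
        Time intensity in log-seconds.
    sigma2 : array_like
        Residual variance of the log-RT, positive.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray = field(default=0.0)  # type: ignore[assignment]
    phi: np.ndarray = field(default=1.0)  # type: ignore[assignment]
    lam: np.ndarray = field(default=0.0)  # type: ignore[assignment]
    sigma2: np.ndarray = field(default=1.0)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.a = _as_float_array(self.a, "a")
        self.b = _as_float_array(self.b, "b")
        self.c = _as_float_array(self.c, "c")
        self.phi = _as_float_array(self.phi, "phi")
        self.lam = _as_float_array(self.lam, "lam")
        self.sigma2 = _as_float_array(self.sigma2, "sigma2")
        if np.any(self.a <= 0):
            raise ValueError("discrimination a must be positive")
        if np.any(self.phi <= 0):
            raise ValueError("time discrimination phi must be positive")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be positive")
        if np.any((self.c < 0) | (self.c >= 1)):
            raise ValueError("guessing probability c must lie in [0, 1)")

    @property
    def n_items(self) -> int:
        return int(
            np.broadcast(self.a, self.b, self.c, self.phi, self.lam, self.sigma2).size
        )


@dataclass
class PersonParameters:
    """Latent ability (theta) and working speed (zeta) per person."""

    theta: np.ndarray
    zeta: np.ndarray = field(default=0.0)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.theta = _as_float_array(self.theta, "theta")
        self.zeta = _as_float_array(self.zeta, "zeta")


@dataclass(frozen=True)
class Parameterization:
    """Which bracketing conventions are in force.

    ``bracketed_ra`` selects the same-scale difficulty convention,
    ``bracketed_rt`` the same-scale time-intensity convention, and ``wl`` the
    reciprocal-error-SD time-discrimination convention.  ``wl`` and
    ``bracketed_rt`` are mutually exclusive.
    """

    bracketed_ra: bool = False
    bracketed_rt: bool = False
    wl: bool = False

    def __post_init__(self) -> None:
        if self.wl and self.bracketed_rt:
            raise ValueError("wl and bracketed_rt conventions are mutually exclusive")


def linear_predictor(
    person: PersonParameters, item: ItemParameters, par: Parameterization | None = None
) -> np.ndarray:
    """Probit-scale linear predictor ``a*theta - b`` (or bracketed form).

    Broadcasts persons against items: 1-d ``theta`` of length N with 1-d item
    vectors of length K yields an N x K matrix.
    """
    par = par or Parameterization()
    theta = np.atleast_1d(person.theta)[..., None]
    if par.bracketed_ra:
        eta = item.a * (theta - item.b)
    else:
        eta = item.a * theta - item.b
    return eta


def success_probability(
    person: PersonParameters, item: ItemParameters, par: Parameterization | None = None
):
    """Probability of a correct response under the (3-parameter) probit model.

    Returns ``c + (1 - c) * Phi(a*theta - b)`` with the mean term bracketed
    according to ``par``.  The result lies in ``[c, 1)``.
    """
    eta = linear_predictor(person, item, par)
    p = item.c + (1.0 - item.c) * ndtr(eta)
    out = np.squeeze(np.asarray(p))
    return float(out) if out.ndim == 0 else out


def expected_log_rt(
    person: PersonParameters, item: ItemParameters, par: Parameterization | None = None
):
    """Expected log response time given working speed and item parameters.

    ``lambda - phi*zeta`` in the non-bracketed convention,
    ``phi*(lambda - zeta)`` in the bracketed one, and ``lambda - zeta`` under
    the reciprocal-error-SD convention (where the residual SD is ``1/phi``).
    """
    par = par or Parameterization()
    zeta = np.atleast_1d(person.zeta)[..., None]
    if par.wl:
        mu = item.lam - zeta + 0.0 * item.phi
    elif par.bracketed_rt:
        mu = item.phi * (item.lam - zeta)
    else:
        mu = item.lam - item.phi * zeta
    out = np.squeeze(np.asarray(mu))
    return float(out) if out.ndim == 0 else out


def rt_error_sd(item: ItemParameters, par: Parameterization | None = None) -> np.ndarray:
    """Residual SD of the log-RT model; ``1/phi`` under the wl convention."""
    par = par or Parameterization()
    if par.wl:
        return 1.0 / np.asarray(item.phi, dtype=float)
    return np.sqrt(np.asarray(item.sigma2, dtype=float))


def probit_logistic_transform(a, b, direction: str = "probit_to_logistic"):
    """Convert discrimination/difficulty between probit and logistic scales.

    The logistic scale factor 1.7 makes the two item characteristic curves
    nearly coincide: going from probit to logistic divides the discrimination
    by 1.7 and multiplies the difficulty by 1.7; the reverse direction
    inverts this, so a round trip is the identity.
    """
    a = _as_float_array(a, "a")
    b = _as_float_array(b, "b")
    if np.any(a <= 0):
        raise ValueError("discrimination a must be positive")
    if direction == "probit_to_logistic":
        a_out, b_out = a / LOGISTIC_SCALE_FACTOR, b * LOGISTIC_SCALE_FACTOR
    elif direction == "logistic_to_probit":
        a_out, b_out = a * LOGISTIC_SCALE_FACTOR, b / LOGISTIC_SCALE_FACTOR
    else:
        raise ValueError("direction must be 'probit_to_logistic' or 'logistic_to_probit'")
    if a_out.ndim == 0:
        return float(a_out), float(b_out)
    return a_out, b_out
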