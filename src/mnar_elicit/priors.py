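"""Bivariate normal priors on the pattern-mixture sensitivity parameters.

Each expert's three elicited distributions are converted into a bivariate
normal prior on (delta_O, delta_E), the per-arm offsets between the mean
outcome of patients with missing versus observed quality-of-life data, on
the 0-1 utility scale.  The marginals come from the two unconditional
answers re-expressed relative to the observed-patient anchor scores; the
correlation comes from the conditional answer about the eEVAR score given a
stated open-arm score, using the closed-form conditional of a bivariate
normal.

Two correlation readouts are provided.  For a bivariate normal with
marginals (m_O, s_O) and (m_E, s_E), the conditional of delta_E given
delta_O = v is normal with

    mean = m_E + rho * (s_E / s_O) * (v - m_O)
    sd   = s_E * sqrt(1 - rho^2)

``mean_shift`` inverts the mean equation (signed); ``sd_ratio`` inverts the
sd equation (magnitude only, sign supplied separately).  When the three
elicited distributions are exactly consistent with one bivariate normal the
two agree in absolute value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .elicitation import (
    UTILITY_SCALE,
    AnchorScores,
    ElicitedNormal,
    ExpertResponse,
)

__all__ = [
    "NormalSpec",
    "SensitivityPrior",
    "to_delta",
    "derive_correlation",
    "build_expert_prior",
]

#: Plausible range of the sensitivity offsets on the utility scale: the
#: elicitation scale is -20..100 and anchors sit in 0..100, so an offset
#: can range over about [-1.2, 1].
DELTA_RANGE = (-1.2, 1.0)


@dataclass(frozen=True)
class NormalSpec:
    """A univariate normal given by mean and standard deviation."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class SensitivityPrior:
    """Bivariate normal prior over (delta_O, delta_E) on the utility scale."""

    expert_id: str
    mean_O: float
    sd_O: float
    mean_E: float
    sd_E: float
    rho: float

    def __post_init__(self) -> None:
        if self.sd_O <= 0 or self.sd_E <= 0:
            raise ValueError("sensitivity prior SDs must be > 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [-1, 1], got {self.rho}")

    @property
    def mean(self) -> np.ndarray:
        """Mean vector, ordered (delta_O, delta_E)."""
        return np.array([self.mean_O, self.mean_E])

    @property
    def cov(self) -> np.ndarray:
        """2x2 covariance matrix, ordered (delta_O, delta_E)."""
        c = self.rho * self.sd_O * self.sd_E
        return np.array([[self.sd_O**2, c], [c, self.sd_E**2]])


def to_delta(
    elicited: ElicitedNormal, anchor: float, scale: float = UTILITY_SCALE
) -> NormalSpec:
    """Re-express an elicited score as a sensitivity offset on the utility scale.

    The offset is (missing-patient score - same-arm observed-patient anchor),
    divided by ``scale`` (100 maps the elicitation scale onto EQ-5D
    utilities; pass 1.0 to stay on the elicitation scale).
    """
    return NormalSpec(mean=(elicited.mode - anchor) / scale, sd=elicited.sd / scale)


def derive_correlation(
    marg_O: NormalSpec,
    marg_E: NormalSpec,
    cond_value: float,
    cond_dist: NormalSpec,
    method: str = "mean_shift",
    sign_hint: str = "auto",
) -> float:
    """Correlation between (delta_O, delta_E) implied by the conditional answer.

    Parameters
    ----------
    marg_O, marg_E : NormalSpec
        Marginal offset distributions for the open and eEVAR arms, on the
        utility scale.
    cond_value : float
        The open-arm offset the expert was conditioned on (utility scale).
    cond_dist : NormalSpec
        The elicited eEVAR offset distribution given that value.
    method : {"mean_shift", "sd_ratio"}
        ``mean_shift`` uses the displacement of the conditional mean and is
        signed; ``sd_ratio`` uses the shrinkage of the conditional sd and
        returns a magnitude whose sign comes from ``sign_hint``.
    sign_hint : {"auto", "+", "-"}
        Sign attached to the ``sd_ratio`` magnitude.  ``auto`` takes the sign
        of the mean-shift formula (0 if that is undefined).

    Returns
    -------
    float
        Correlation clamped to [-1, 1]; a clamp or an unusable sd ratio
        raises a UserWarning.
    """
    if method not in ("mean_shift", "sd_ratio"):
        raise ValueError(f"unknown method {method!r}")

    shift_denom = (cond_value - marg_O.mean) * marg_E.sd
    mean_shift_defined = abs(shift_denom) > 0

    def _mean_shift() -> float:
        raw = (cond_dist.mean - marg_E.mean) * marg_O.sd / shift_denom
        if raw < -1.0 or raw > 1.0:
            warnings.warn(
                f"mean-shift correlation {raw:.3f} outside [-1, 1]; clamped",
                UserWarning,
                stacklevel=3,
            )
        return float(min(1.0, max(-1.0, raw)))

    if method == "mean_shift":
        if not mean_shift_defined:
            raise ValueError(
                "uninformative conditioning point: the conditioning value "
                "equals the open-arm marginal mean, so the mean shift carries "
                "no correlation information"
            )
        return _mean_shift()

    # sd_ratio
    ratio = cond_dist.sd / marg_E.sd
    if ratio > 1.0:
        warnings.warn(
            "conditional sd exceeds the marginal sd; no real correlation "
            "root, returning 0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    magnitude = math.sqrt(max(0.0, 1.0 - ratio**2))
    if sign_hint == "+":
        return magnitude
    if sign_hint == "-":
        return -magnitude
    if sign_hint != "auto":
        raise ValueError(f"unknown sign_hint {sign_hint!r}")
    if not mean_shift_defined:
        return 0.0
    shift = (cond_dist.mean - marg_E.mean) / shift_denom
    return math.copysign(magnitude, shift) if shift != 0 else 0.0


def build_expert_prior(
    r: ExpertResponse,
    anchors: AnchorScores,
    method: str = "mean_shift",
    respect_categorical: bool = False,
    scale: float = UTILITY_SCALE,
) -> SensitivityPrior:
    """Convert one expert's session into a bivariate normal sensitivity prior.

    Marginals come from :func:`to_delta` applied to the two unconditional
    answers; the correlation from :func:`derive_correlation` applied to the
    conditional answer.  If ``respect_categorical`` is set and the expert
    gave a categorical correlation statement, a "zero" statement forces
    rho = 0 and "positive"/"negative" force the sign of the derived value.
    """
    marg_O = to_delta(r.open_missing, anchors.open_observed, scale)
    marg_E = to_delta(r.evar_missing, anchors.evar_observed, scale)
    cond_value = (r.evar_given_open.conditioning_value - anchors.open_observed) / scale
    cond_dist = to_delta(r.evar_given_open.distribution, anchors.evar_observed, scale)

    rho = derive_correlation(marg_O, marg_E, cond_value, cond_dist, method=method)
    if respect_categorical and r.correlation_statement is not None:
        if r.correlation_statement == "zero":
            rho = 0.0
        elif r.correlation_statement == "positive":
            rho = abs(rho)
        elif r.correlation_statement == "negative":
            rho = -abs(rho)

    prior = SensitivityPrior(
        expert_id=r.expert_id,
        mean_O=marg_O.mean,
        sd_O=marg_O.sd,
        mean_E=marg_E.mean,
        sd_E=marg_E.sd,
        rho=rho,
    )
    _warn_if_mass_outside(prior)
    return prior


def _warn_if_mass_outside(prior: SensitivityPrior, threshold: float = 0.05) -> None:
    # Elicited normals are used untruncated; flag priors that put real mass
    # beyond the offsets the bounded QoL scale can produce.
    from scipy.stats import norm

    for name, m, s in (("delta_O", prior.mean_O, prior.sd_O), ("delta_E", prior.mean_E, prior.sd_E)):
        outside = norm.cdf(DELTA_RANGE[0], m, s) + norm.sf(DELTA_RANGE[1], m, s)
        if outside > threshold:
            warnings.warn(
                f"{prior.expert_id}: {outside:.1%} of the {name} prior mass lies "
                f"outside the feasible offset range {DELTA_RANGE}",
                UserWarning,
                stacklevel=3,
            )
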