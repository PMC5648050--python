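"""Synthetic trials and expert panels with known truth.

No public data exist for this class of analysis (the motivating trial's
patient records are confidential and the raw elicitation responses were
never deposited), so every downstream module is exercised against generated
data with a fully known generating mechanism.

Trials
    Two-arm trials with normal utility outcomes and outcome-dependent
    (MNAR) missingness:  P(missing | Y = y) = logit^-1(a + b y)  per arm.
    A negative slope b makes patients in worse health likelier to drop out.
    The generating sensitivity offsets delta_a = E[Y | missing] -
    E[Y | observed] are computed by Gauss-Hermite quadrature, so tests have
    a near-exact target rather than a stored approximation.

Panels
    Experts whose beliefs are *exactly* bivariate normal over the two
    offsets.  Each expert's three elicited distributions (two marginals and
    one conditional) are written down from the closed-form conditional of
    their bivariate normal, so the prior-construction pipeline applied to a
    generated panel must recover every generating parameter to numerical
    precision — a strong round-trip oracle.

Default parameter values emulate the study conditions this package is built
around: a ~600-patient trial with roughly 18%/24% missing utility outcomes
per arm, and a 26-expert panel (9 nurses, 17 doctors) whose average beliefs
put the non-responders a few utility points below the responders, with
moderate positive correlation between the two arms' offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .elicitation import (
    QOL_MAX,
    QOL_MIN,
    UTILITY_SCALE,
    AnchorScores,
    ConditionalElicitation,
    ElicitationSet,
    ElicitedNormal,
    ExpertResponse,
    Role,
    Venue,
)
from .pattern_mixture import ARM_EVAR, ARM_OPEN

__all__ = [
    "TrialGenConfig",
    "PanelGenConfig",
    "TruthRecord",
    "generate_trial",
    "generate_panel",
    "truth_delta",
    "calibrate_missingness",
    "DEFAULT_ANCHORS",
]

#: Observed-patient anchor scores used by default for synthetic panels
#: (elicitation scale): chosen so the default panel's elicited modes sit in
#: the low-60s/low-70s like a realistic post-surgical cohort.
DEFAULT_ANCHORS = AnchorScores(open_observed=65.0, evar_observed=73.0)

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(80)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@dataclass(frozen=True)
class TrialGenConfig:
    """Generating mechanism for a two-arm MNAR trial.

    Defaults: 200 patients per arm, true means 0.67 (open) / 0.74 (eEVAR)
    so the true difference is 0.07 utility units, outcome SD 0.25, and a
    logistic missingness slope of -1 per utility unit with intercepts
    calibrated to ~24% / ~18% missingness (implying generating offsets of
    about -0.06 per arm).
    """

    n_per_arm: int = 200
    true_mean_O: float = 0.67
    true_mean_E: float = 0.74
    sd_O: float = 0.25
    sd_E: float = 0.25
    miss_intercept_O: float = -0.4987
    miss_intercept_E: float = -0.7962
    miss_slope_O: float = -1.0
    miss_slope_E: float = -1.0
    covariate_effect: float = 0.0
    miss_covariate_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if self.sd_O <= 0 or self.sd_E <= 0:
            raise ValueError("outcome SDs must be > 0")

    def arm(self, arm: str) -> tuple[float, float, float, float]:
        """(mean, sd, miss_intercept, miss_slope) for one arm label."""
        if arm.upper().startswith("O"):
            return self.true_mean_O, self.sd_O, self.miss_intercept_O, self.miss_slope_O
        return self.true_mean_E, self.sd_E, self.miss_intercept_E, self.miss_slope_E


@dataclass(frozen=True)
class TruthRecord:
    """Generating truth accompanying a synthetic trial."""

    delta_true: float  # true_mean_E - true_mean_O
    delta_O_true: float
    delta_E_true: float
    pi_O_true: float
    pi_E_true: float
    config: TrialGenConfig


def _arm_quadrature(mean: float, sd: float, a: float, b: float) -> tuple[float, float]:
    """(expected missingness, delta = E[Y|miss] - E[Y|obs]) by quadrature."""
    y = mean + sd * _GH_NODES
    p = expit(a + b * y)
    e_p = float(np.sum(_GH_WEIGHTS * p))
    if e_p <= 0.0 or e_p >= 1.0:
        return e_p, 0.0
    e_yp = float(np.sum(_GH_WEIGHTS * p * y))
    e_y = float(np.sum(_GH_WEIGHTS * y))
    miss_mean = e_yp / e_p
    obs_mean = (e_y - e_yp) / (1.0 - e_p)
    return e_p, miss_mean - obs_mean


def truth_delta(cfg: TrialGenConfig) -> tuple[float, float]:
    """Generating offsets (delta_O_true, delta_E_true) by numeric integration."""
    _, d_o = _arm_quadrature(*cfg.arm("O"))
    _, d_e = _arm_quadrature(*cfg.arm("E"))
    return d_o, d_e


def expected_missingness(cfg: TrialGenConfig) -> tuple[float, float]:
    """Expected missing proportions (pi_O, pi_E) under the mechanism."""
    p_o, _ = _arm_quadrature(*cfg.arm("O"))
    p_e, _ = _arm_quadrature(*cfg.arm("E"))
    return p_o, p_e


def calibrate_missingness(
    cfg: TrialGenConfig,
    target_delta: tuple[float, float],
    target_pi: tuple[float, float],
) -> TrialGenConfig:
    """Solve per-arm (intercept, slope) so the mechanism hits given truths.

    Returns a config whose generating offsets equal ``target_delta`` and
    whose expected missing proportions equal ``target_pi``.  Used to build
    trials whose truth matches a draw from a prior ("matched truth").
    """
    new = {}
    for arm, d_target, pi_target in (
        ("O", target_delta[0], target_pi[0]),
        ("E", target_delta[1], target_pi[1]),
    ):
        mean, sd, a0, b0 = cfg.arm(arm)
        # achievable |delta| is bounded by the selection strength of a
        # logistic in y; keep targets comfortably inside
        limit = 2.0 * sd
        if abs(d_target) >= limit:
            raise ValueError(
                f"target delta {d_target} not achievable with outcome sd {sd}"
            )

        def eqs(x, mean=mean, sd=sd, d_target=d_target, pi_target=pi_target):
            a, b = x
            pi, d = _arm_quadrature(mean, sd, a, b)
            return [pi - pi_target, d - d_target]

        guess = [math.log(pi_target / (1 - pi_target)), d_target / (sd**2)]
        sol = optimize.fsolve(eqs, guess, full_output=True)
        x, _, ier, msg = sol
        if ier != 1:
            raise RuntimeError(f"missingness calibration failed for arm {arm}: {msg}")
        new[f"miss_intercept_{arm}"] = float(x[0])
        new[f"miss_slope_{arm}"] = float(x[1])
    return TrialGenConfig(**{**asdict(cfg), **new})


def generate_trial(
    cfg: TrialGenConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate a two-arm trial under the configured MNAR mechanism.

    Returns the patient-level frame (columns patient_id, arm, qol, missing,
    and x when a covariate effect is configured) and a :class:`TruthRecord`
    with the quadrature-computed generating offsets.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    frames = []
    for arm in (ARM_OPEN, ARM_EVAR):
        mean, sd, a, b = cfg.arm(arm)
        x = rng.standard_normal(cfg.n_per_arm)
        y = rng.normal(mean, sd, size=cfg.n_per_arm) + cfg.covariate_effect * x
        p_miss = expit(a + b * y + cfg.miss_covariate_slope * x)
        miss = rng.random(cfg.n_per_arm) < p_miss
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": [f"{arm}-{i:04d}" for i in range(cfg.n_per_arm)],
                    "arm": arm,
                    "qol": np.where(miss, np.nan, y),
                    "missing": miss,
                    "x": x,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    if cfg.covariate_effect == 0.0 and cfg.miss_covariate_slope == 0.0:
        data = data.drop(columns=["x"])
    d_o, d_e = truth_delta(cfg)
    pi_o, pi_e = expected_missingness(cfg)
    truth = TruthRecord(
        delta_true=cfg.true_mean_E - cfg.true_mean_O,
        delta_O_true=d_o,
        delta_E_true=d_e,
        pi_O_true=pi_o,
        pi_E_true=pi_e,
        config=cfg,
    )
    return data, truth


# ---------------------------------------------------------------------------
# expert panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelGenConfig:
    """Generating beliefs for a synthetic expert panel (utility scale).

    Defaults emulate a 26-expert panel (9 nurses, 17 doctors) centred on
    offsets of -0.04 (open) and -0.01 (eEVAR), with between-expert spread
    0.16, typical within-expert (elicited) SD 0.15, and correlation 0.3.
    """

    n_experts: int = 26
    true_delta_O: float = -0.04
    true_delta_E: float = -0.01
    within_expert_sd: float = 0.15
    between_expert_sd: float = 0.16
    within_sd_spread: float = 0.05
    rho_true: float = 0.3
    rho_spread: float = 0.0
    n_nurses: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        if self.within_expert_sd <= 0 or self.between_expert_sd < 0:
            raise ValueError("panel SDs must be positive")
        if not -1.0 <= self.rho_true <= 1.0:
            raise ValueError("rho_true must be in [-1, 1]")
        if self.n_nurses > self.n_experts:
            raise ValueError("n_nurses cannot exceed n_experts")


def generate_panel(
    cfg: PanelGenConfig,
    anchors: AnchorScores = DEFAULT_ANCHORS,
    rng: Optional[np.random.Generator] = None,
    rho_values: Optional[Sequence[float]] = None,
    delta_means: Optional[Sequence[tuple[float, float]]] = None,
) -> ElicitationSet:
    """Simulate an elicitation session for a panel of experts.

    Each expert k holds an exact bivariate normal belief over
    (delta_O, delta_E) with means drawn around the configured truths,
    elicited SDs drawn around ``within_expert_sd``, and correlation around
    ``rho_true``.  Their three recorded answers are the analytic marginals
    and the analytic conditional at a conditioning point one elicited SD
    above the open-arm mode, so downstream prior construction inverts the
    generator exactly.  ``rho_values`` / ``delta_means`` override the random
    per-expert parameters (for panels with a prescribed belief structure).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    responses = []
    sd_floor, sd_cap = 0.02, 0.28  # utility units
    # modes are truncated to this band so that every derived answer —
    # including the conditional mode, shifted by at most |rho|*sd_cap*100
    # toward the scale centre — stays on the -20..100 scale
    mode_lo, mode_hi = -15.0, 95.0

    def _draw_mode(anchor: float, centre: float) -> float:
        # rejection-sample the expert's mean so the slider answer stays on
        # the scale (truncation, not clipping, to avoid a point mass)
        for _ in range(200):
            mode = anchor + UTILITY_SCALE * rng.normal(centre, cfg.between_expert_sd)
            if mode_lo <= mode <= mode_hi:
                return mode
        return float(np.clip(anchor + UTILITY_SCALE * centre, mode_lo, mode_hi))

    for k in range(cfg.n_experts):
        if delta_means is not None:
            m_o, m_e = delta_means[k]
            mode_o = anchors.open_observed + UTILITY_SCALE * m_o
            mode_e = anchors.evar_observed + UTILITY_SCALE * m_e
        else:
            mode_o = _draw_mode(anchors.open_observed, cfg.true_delta_O)
            mode_e = _draw_mode(anchors.evar_observed, cfg.true_delta_E)
        s_o = float(np.clip(rng.normal(cfg.within_expert_sd, cfg.within_sd_spread), sd_floor, sd_cap))
        s_e = float(np.clip(rng.normal(cfg.within_expert_sd, cfg.within_sd_spread), sd_floor, sd_cap))
        if rho_values is not None:
            rho = float(rho_values[k])
        else:
            rho = float(np.clip(rng.normal(cfg.rho_true, cfg.rho_spread), -0.9, 0.9))

        # condition one elicited SD away from the open-arm mode (never at
        # the mode, which would carry no correlation information), in the
        # direction that keeps the implied conditional mode on the scale
        want_shift = 1.0 if mode_e < 40.0 else -1.0
        direction = want_shift * (1.0 if rho >= 0 else -1.0)
        cond_value = float(np.clip(mode_o + direction * UTILITY_SCALE * s_o, QOL_MIN + 1.0, QOL_MAX - 1.0))
        if cond_value == mode_o:
            cond_value += 1.0 if mode_o < 50.0 else -1.0
        cond_mode = mode_e + rho * (s_e / s_o) * (cond_value - mode_o)
        cond_sd = UTILITY_SCALE * s_e * math.sqrt(1.0 - rho**2)
        cond_sd = max(cond_sd, 1e-9)  # |rho| = 1 would degenerate

        role = Role.NURSE if k < cfg.n_nurses else Role.DOCTOR
        responses.append(
            ExpertResponse(
                expert_id=f"expert-{k + 1:02d}",
                role=role,
                venue=Venue.CONFERENCE if k % 2 == 0 else Venue.EMAIL,
                open_missing=ElicitedNormal(mode=mode_o, sd=UTILITY_SCALE * s_o),
                evar_missing=ElicitedNormal(mode=mode_e, sd=UTILITY_SCALE * s_e),
                evar_given_open=ConditionalElicitation(
                    conditioning_value=cond_value,
                    distribution=ElicitedNormal(mode=cond_mode, sd=cond_sd),
                ),
            )
        )
    return ElicitationSet(responses, anchors=anchors)
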