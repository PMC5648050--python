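"""Linear opinion pooling of expert sensitivity priors.

Equal-weight linear pooling of K bivariate normal priors yields a finite
mixture with density f(x) = sum_k w_k f_k(x).  The mixture is what enters
the Bayesian model; its first two moments feed the closed-form moment
estimator.  The "community of priors" used for sensitivity analysis consists
of the pool over all experts, role subgroups (doctors, nurses), and the two
extreme individuals: the most sceptical expert (prior mean of
delta_E - delta_O most negative, i.e. believes the open-repair
non-responders fare relatively best) and the most enthusiastic (most
positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import numpy as np
from scipy.stats import multivariate_normal

from .elicitation import ElicitationSet, Role
from .priors import SensitivityPrior

__all__ = [
    "PooledPrior",
    "linear_pool",
    "pool_moments",
    "sample_pool",
    "select_community",
    "most_sceptical",
    "most_enthusiastic",
    "read_priors",
    "write_priors",
]

_WEIGHT_TOL = 1e-12


@dataclass
class PooledPrior:
    """A weighted mixture of bivariate normal sensitivity priors."""

    components: list[SensitivityPrior]
    weights: np.ndarray
    label: str = "all"

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("a pooled prior needs at least one component")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.components),):
            raise ValueError(
                f"{len(self.components)} components but {self.weights.size} weights"
            )
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights sum to {self.weights.sum()!r}, not 1")

    def __len__(self) -> int:
        return len(self.components)

    def pdf(self, points: np.ndarray) -> np.ndarray:
        """Mixture density at (n, 2) points ordered (delta_O, delta_E)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(points.shape[0])
        for w, c in zip(self.weights, self.components):
            out += w * multivariate_normal.pdf(
                points, mean=c.mean, cov=c.cov, allow_singular=True
            )
        return out

    def marginal_pdf(self, arm: str, grid: np.ndarray) -> np.ndarray:
        """Mixture marginal density of one arm's offset on a 1-D grid."""
        grid = np.asarray(grid, dtype=float)
        out = np.zeros_like(grid)
        for w, c in zip(self.weights, self.components):
            m, s = (c.mean_O, c.sd_O) if arm.upper().startswith("O") else (c.mean_E, c.sd_E)
            out += w * np.exp(-0.5 * ((grid - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        return out


def linear_pool(
    priors: Sequence[SensitivityPrior],
    weights: Optional[Sequence[float]] = None,
    label: str = "all",
) -> PooledPrior:
    """Pool expert priors as a mixture; default weights are equal (1/N)."""
    priors = list(priors)
    if not priors:
        raise ValueError("cannot pool an empty list of priors")
    if weights is None:
        weights = np.full(len(priors), 1.0 / len(priors))
    return PooledPrior(priors, np.asarray(weights, dtype=float), label=label)


def pool_moments(pool: PooledPrior) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance matrix of the mixture, ordered (delta_O, delta_E).

    mean = sum_k w_k mu_k ;  cov = sum_k w_k (Sigma_k + mu_k mu_k^T) - mu mu^T.
    """
    mean = np.zeros(2)
    second = np.zeros((2, 2))
    for w, c in zip(pool.weights, pool.components):
        mu = c.mean
        mean += w * mu
        second += w * (c.cov + np.outer(mu, mu))
    cov = second - np.outer(mean, mean)
    # symmetrise against accumulation error
    return mean, (cov + cov.T) / 2.0


def sample_pool(
    pool: PooledPrior,
    n: int,
    seed: Union[int, np.random.Generator, None] = None,
    return_components: bool = False,
):
    """Draw n (delta_O, delta_E) pairs from the mixture.

    Reproducible under a fixed seed.  With ``return_components`` the latent
    component index of each draw is returned as well.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    comp = rng.choice(len(pool), size=n, p=pool.weights)
    draws = np.empty((n, 2))
    z = rng.standard_normal((n, 2))
    for k, c in enumerate(pool.components):
        idx = comp == k
        if not np.any(idx):
            continue
        chol = np.linalg.cholesky(c.cov + 1e-15 * np.eye(2))
        draws[idx] = c.mean + z[idx] @ chol.T
    if return_components:
        return draws, comp
    return draws


def _effect_lean(prior: SensitivityPrior) -> float:
    # prior mean of (delta_E - delta_O): how much the expert's beliefs about
    # the missing patients favour the eEVAR arm
    return prior.mean_E - prior.mean_O


def most_sceptical(priors: Sequence[SensitivityPrior]) -> SensitivityPrior:
    """Expert whose prior mean of (delta_E - delta_O) is most negative."""
    return min(priors, key=_effect_lean)


def most_enthusiastic(priors: Sequence[SensitivityPrior]) -> SensitivityPrior:
    """Expert whose prior mean of (delta_E - delta_O) is most positive."""
    return max(priors, key=_effect_lean)


def select_community(
    eset: ElicitationSet,
    priors: Sequence[SensitivityPrior],
    group: str,
) -> PooledPrior:
    """Equal-weight pool over a named subgroup of the panel.

    ``group`` may be "all", "doctors", "nurses", the operational extremes
    "sceptic"/"enthusiast", or an explicit expert_id (a single-expert pool).
    """
    priors = list(priors)
    by_id = {p.expert_id: p for p in priors}
    roles = {r.expert_id: r.role for r in eset.responses}

    if group == "all":
        subset = priors
    elif group in ("doctors", "nurses"):
        role = Role.DOCTOR if group == "doctors" else Role.NURSE
        subset = [p for p in priors if roles.get(p.expert_id) == role]
    elif group == "sceptic":
        subset = [most_sceptical(priors)] if priors else []
    elif group == "enthusiast":
        subset = [most_enthusiastic(priors)] if priors else []
    elif group in by_id:
        subset = [by_id[group]]
    else:
        raise ValueError(
            f"group {group!r} is neither a known subgroup nor an expert_id"
        )
    if not subset:
        raise ValueError(f"subgroup {group!r} is empty")
    return linear_pool(subset, label=group)


# ---------------------------------------------------------------------------
# prior files
# ---------------------------------------------------------------------------

def write_priors(priors: Sequence[SensitivityPrior], sink: Union[str, Path, IO[str]]) -> None:
    payload = [asdict(p) for p in priors]
    if hasattr(sink, "write"):
        json.dump(payload, sink, indent=2)  # type: ignore[arg-type]
    else:
        Path(sink).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_priors(source: Union[str, Path, IO[str]]) -> list[SensitivityPrior]:
    if hasattr(source, "read"):
        payload = json.load(source)  # type: ignore[arg-type]
    else:
        payload = json.loads(Path(source).read_text(encoding="utf-8"))
    return [SensitivityPrior(**d) for d in payload]
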