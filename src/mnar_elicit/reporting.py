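"""Density strips, prior overlays, and the community-of-priors report.

A density strip renders a full posterior as a one-dimensional greyscale
band: darkness proportional to the estimated density, darkest at the mode.
The community report lines up one strip per analysis (complete-case, MAR,
and the MNAR fits under each member of the community of priors) with the
posterior mean, 95% credible interval and MCID exceedance probability, so
the sensitivity of the conclusion to the choice of prior is visible at a
glance.  Strips are numeric objects first — plots are rendered from them —
so results can be asserted on and round-tripped without touching pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .pattern_mixture import PatternMixtureResults
from .pooling import PooledPrior
from .priors import SensitivityPrior

__all__ = [
    "DensityStrip",
    "make_density_strip",
    "community_report",
    "CommunityReport",
    "prior_overlay",
    "plot_community",
]

#: Default grid for treatment-difference strips: wide enough to cover every
#: interval the analyses produce.
DEFAULT_GRID = (-0.3, 0.4, 701)


@dataclass
class DensityStrip:
    """Max-normalised density of a posterior on an ordered grid."""

    grid: np.ndarray
    intensity: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.shape != self.intensity.shape:
            raise ValueError("grid and intensity must have equal length")
        if np.any(self.intensity < 0) or not np.isclose(self.intensity.max(), 1.0):
            raise ValueError("intensities must be non-negative with max exactly 1")

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "intensity": self.intensity.tolist(),
            "annotations": self.annotations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DensityStrip":
        return cls(np.array(d["grid"]), np.array(d["intensity"]), dict(d["annotations"]))


def make_density_strip(
    draws: Sequence[float],
    grid_spec: tuple[float, float, int] = DEFAULT_GRID,
    mcid: float = 0.03,
) -> DensityStrip:
    """Kernel-density strip of posterior draws, max-normalised to [0, 1]."""
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if draws.size < 1000:
        raise ValueError(f"need at least 1000 draws for a stable strip, got {draws.size}")
    lo, hi, n = grid_spec
    grid = np.linspace(lo, hi, int(n))
    if np.ptp(draws) < 1e-12:
        # degenerate sample: a single saturated cell at the point mass
        intensity = np.zeros_like(grid)
        intensity[np.argmin(np.abs(grid - draws[0]))] = 1.0
    else:
        dens = gaussian_kde(draws)(grid)
        intensity = dens / dens.max()
    q_lo, q_hi = np.percentile(draws, [2.5, 97.5])
    return DensityStrip(
        grid=grid,
        intensity=intensity,
        annotations={
            "mean": float(draws.mean()),
            "ci_low": float(q_lo),
            "ci_high": float(q_hi),
            "p_mcid": float(np.mean(draws >= mcid)),
        },
    )


@dataclass
class CommunityReport:
    """Aligned strips and summary rows for a set of labelled analyses."""

    rows: pd.DataFrame
    strips: dict  # label -> DensityStrip

    def to_json(self, sink: Union[str, Path, IO[str], None] = None) -> Optional[str]:
        payload = {
            "rows": self.rows.to_dict(orient="records"),
            "strips": {k: v.to_dict() for k, v in self.strips.items()},
        }
        text = json.dumps(payload, indent=2)
        if sink is None:
            return text
        if hasattr(sink, "write"):
            sink.write(text)  # type: ignore[union-attr]
        else:
            Path(sink).write_text(text, encoding="utf-8")
        return None

    @classmethod
    def from_json(cls, source: Union[str, Path, IO[str]]) -> "CommunityReport":
        if hasattr(source, "read"):
            payload = json.load(source)  # type: ignore[union-attr]
        else:
            text = Path(source).read_text(encoding="utf-8") if Path(source).exists() else str(source)
            payload = json.loads(text)
        return cls(
            rows=pd.DataFrame(payload["rows"]),
            strips={k: DensityStrip.from_dict(v) for k, v in payload["strips"].items()},
        )


def community_report(
    results: Mapping[str, PatternMixtureResults],
    grid_spec: tuple[float, float, int] = DEFAULT_GRID,
) -> CommunityReport:
    """One strip + summary row per labelled analysis.

    ``results`` maps labels (e.g. complete_case, mar, all, doctors, nurses,
    sceptic, enthusiast) to fitted results; labels must be unique, which the
    mapping type enforces — passing duplicate labels collapses silently, so
    a list of pairs is also accepted and checked.
    """
    if not isinstance(results, Mapping):
        pairs = list(results)
        labels = [k for k, _ in pairs]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate labels in community report")
        results = dict(pairs)
    if not results:
        raise ValueError("community report needs at least one labelled result")
    rows = []
    strips = {}
    for label, res in results.items():
        strips[label] = make_density_strip(
            res.delta_draws, grid_spec=grid_spec, mcid=res.config.mcid
        )
        rows.append(
            {
                "label": label,
                "mean": res.posterior_mean,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_mcid": res.p_mcid,
                "max_rhat": max(res.rhat.values()) if res.rhat else float("nan"),
                "min_ess": min(res.ess.values()) if res.ess else float("nan"),
            }
        )
    return CommunityReport(rows=pd.DataFrame(rows), strips=strips)


def prior_overlay(
    priors: Sequence[SensitivityPrior],
    pool: PooledPrior,
    arm: str,
    grid: Optional[np.ndarray] = None,
) -> dict:
    """Per-expert marginal density curves plus the pooled mixture curve.

    Returns a dict with ``grid``, ``experts`` (mapping expert_id to curve)
    and ``pooled``; the pooled curve equals the weighted pointwise sum of
    the component curves by construction of the mixture.
    """
    if not priors:
        raise ValueError("no priors to overlay")
    if grid is None:
        grid = np.linspace(-0.8, 0.8, 801)
    grid = np.asarray(grid, dtype=float)
    experts = {}
    for p in priors:
        m, s = (p.mean_O, p.sd_O) if arm.upper().startswith("O") else (p.mean_E, p.sd_E)
        experts[p.expert_id] = np.exp(-0.5 * ((grid - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
    return {"grid": grid, "experts": experts, "pooled": pool.marginal_pdf(arm, grid)}


def plot_community(report: CommunityReport, path: Optional[Union[str, Path]] = None):
    """Render the community report as stacked density strips (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(report.strips)
    fig, ax = plt.subplots(figsize=(7, 0.7 * len(labels) + 1.5))
    for i, label in enumerate(labels):
        strip = report.strips[label]
        y = len(labels) - 1 - i
        ax.imshow(
            strip.intensity[np.newaxis, :],
            extent=(strip.grid[0], strip.grid[-1], y - 0.35, y + 0.35),
            aspect="auto",
            cmap="Greys",
            vmin=0,
            vmax=1,
        )
        a = strip.annotations
        ax.plot([a["mean"]], [y], "k|", markersize=14)
        ax.plot([a["ci_low"], a["ci_high"]], [y - 0.35, y - 0.35], "k-", linewidth=0.8)
        ax.text(
            strip.grid[-1],
            y,
            f"  {a['mean']:.3f} ({a['ci_low']:.3f}, {a['ci_high']:.3f})  "
            f"P(Δ≥0.03)={a['p_mcid']:.2f}",
            va="center",
            fontsize=8,
        )
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(reversed(labels))
    ax.axvline(0.0, color="0.6", linewidth=0.8, linestyle=":")
    ax.set_xlabel("difference in mean QoL at 3 months (eEVAR − OPEN)")
    ax.set_xlim(report.strips[labels[0]].grid[0], report.strips[labels[0]].grid[-1] * 1.9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
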