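"""Correlation-cutoff selection by the scale-free topological criterion.

For a grid of candidate cutoffs the class-restricted regulatory network
(only TF- or only miRNA-regulator edges, all acceptance conditions
applied) is rebuilt, and the empirical in- and out-degree distributions
are fit to

    power law              P(k) ~ k^-gamma
    truncated power law    P(k) ~ k^-lambda * exp(-alpha k)

by ordinary least squares on log-transformed frequencies.  The R^2 of
the better-fitting model, per direction, traces how scale-free the
network becomes as the cutoff rises; the selected cutoff is the
smallest one at which both curves have reached a steady state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coexpression
from .candidate_network import InteractionSet
from .coexpression import RegulatoryNetwork
from .expression import RatioMatrix

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(np.round(np.arange(0.0, 0.9001, 0.05), 2))
DEFAULT_TOL = 0.05
DEFAULT_WINDOW = 2


@dataclass(frozen=True)
class DegreeDistribution:
    """Relative frequencies of node degrees >= 1 in one direction."""

    direction: str  # "in" | "out"
    support: np.ndarray  # degrees k >= 1 with nonzero frequency
    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.direction not in ("in", "out"):
            raise ValueError("direction must be 'in' or 'out'")
        if len(self.support) != len(self.probs):
            raise ValueError("support/probs length mismatch")
        if len(self.support) and (
            (self.support < 1).any() or not np.isclose(self.probs.sum(), 1.0)
        ):
            raise ValueError("support must be >= 1 and probs sum to 1")


@dataclass(frozen=True)
class DegreeFit:
    model: str  # "power_law" | "truncated_power_law"
    params: dict[str, float]
    r_squared: float


@dataclass
class CutoffScanResult:
    """Per-cutoff fit quality and network size for one regulator class."""

    regulator_class: str
    table: pd.DataFrame  # cutoff, r2_in, r2_out, model_in, model_out, n_nodes, n_edges, n_regulators

    def __post_init__(self) -> None:
        grid = self.table["cutoff"].values
        if len(grid) == 0:
            raise ValueError("empty scan")
        if not (np.diff(grid) > 0).all():
            raise ValueError("cutoff grid must be strictly increasing")


def degrees_from_counts(counts: pd.Series, direction: str) -> DegreeDistribution:
    """Degree distribution from a node→degree Series (zeros excluded)."""
    counts = counts[counts >= 1]
    if counts.empty:
        raise ValueError("all degrees are zero")
    freq = counts.value_counts().sort_index()
    support = freq.index.to_numpy(dtype=float)
    probs = freq.to_numpy(dtype=float) / freq.sum()
    return DegreeDistribution(direction=direction, support=support, probs=probs)


def degree_distribution(net, direction: str) -> DegreeDistribution:
    """Empirical in- or out-degree distribution of a directed network.

    Accepts a RegulatoryNetwork or a networkx DiGraph.  Nodes of degree
    zero in the requested direction are excluded from the support.
    """
    graph = net.graph if isinstance(net, RegulatoryNetwork) else net
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if direction == "in":
        deg = dict(graph.in_degree())
    elif direction == "out":
        deg = dict(graph.out_degree())
    else:
        raise ValueError("direction must be 'in' or 'out'")
    return degrees_from_counts(pd.Series(deg, dtype=float), direction)


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS coefficients and R^2; R^2 defined as 0 when y has no variance."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= np.finfo(float).eps * max(1.0, float(np.abs(y).max()) ** 2) * y.size:
        return coef, 0.0
    return coef, 1.0 - sse / sst


def fit_power_law(dist: DegreeDistribution) -> DegreeFit:
    """Least-squares line on (log k, log P(k)); gamma = -slope.

    With fewer than 3 support points the fit is undefined and R^2 is
    reported as 0 (the convention used for degenerate networks).
    """
    k, p = dist.support, dist.probs
    if len(k) < 3:
        return DegreeFit("power_law", {"gamma": float("nan")}, 0.0)
    X = np.column_stack([np.ones_like(k), np.log(k)])
    coef, r2 = _ols_r2(X, np.log(p))
    return DegreeFit("power_law", {"gamma": float(-coef[1]), "intercept": float(coef[0])}, r2)


def fit_truncated_power_law(dist: DegreeDistribution) -> DegreeFit:
    """OLS of log P(k) on (log k, k); lambda and the truncation rate alpha.

    The model is bilinear in its log form, so noise-free truncated
    power laws are recovered exactly.  Fewer than 4 support points →
    undefined fit, R^2 = 0.
    """
    k, p = dist.support, dist.probs
    if len(k) < 4:
        return DegreeFit(
            "truncated_power_law",
            {"lambda": float("nan"), "alpha_trunc": float("nan")},
            0.0,
        )
    X = np.column_stack([np.ones_like(k), np.log(k), k])
    coef, r2 = _ols_r2(X, np.log(p))
    return DegreeFit(
        "truncated_power_law",
        {
            "lambda": float(-coef[1]),
            "alpha_trunc": float(-coef[2]),
            "intercept": float(coef[0]),
        },
        r2,
    )


def best_fit(dist: DegreeDistribution) -> DegreeFit:
    """The better of the two model fits (power law wins exact ties)."""
    pl = fit_power_law(dist)
    tr = fit_truncated_power_law(dist)
    return tr if tr.r_squared > pl.r_squared else pl


def scan_cutoffs(
    candidates: InteractionSet,
    ratios: RatioMatrix,
    regulator_class: str,
    grid=DEFAULT_GRID,
    cooks_threshold: float = coexpression.DEFAULT_COOKS_THRESHOLD,
    min_samples: int = coexpression.DEFAULT_MIN_SAMPLES,
) -> CutoffScanResult:
    """Fit quality and size of the class-restricted GRN along the cutoff grid.

    Candidate edges are scored once; each grid point then applies the
    full acceptance rule (sign constraint for miRNA regulators plus the
    |r| cutoff) and refits both degree-distribution models.
    """
    grid = [float(c) for c in grid]
    if any(not 0.0 <= c < 1.0 for c in grid):
        raise ValueError("grid values must lie in [0, 1)")
    restricted = InteractionSet(
        rec for rec in candidates if rec.regulator_class == regulator_class
    )
    scores = coexpression.score_candidates(
        restricted, ratios, cooks_threshold=cooks_threshold, min_samples=min_samples
    )
    if len(scores):
        sign_ok = (scores["regulator_class"] != "miRNA") | (scores["r"] < 0)
        scores = scores[sign_ok]
    rows = []
    for c in grid:
        sel = scores[scores["r"].abs() > c] if len(scores) else scores
        if len(sel) == 0:
            rows.append(
                {
                    "cutoff": c,
                    "r2_in": 0.0,
                    "r2_out": 0.0,
                    "model_in": "none",
                    "model_out": "none",
                    "n_nodes": 0,
                    "n_edges": 0,
                    "n_regulators": 0,
                }
            )
            continue
        out_fit = best_fit(
            degrees_from_counts(sel["regulator"].value_counts().astype(float), "out")
        )
        in_fit = best_fit(
            degrees_from_counts(sel["target"].value_counts().astype(float), "in")
        )
        rows.append(
            {
                "cutoff": c,
                "r2_in": in_fit.r_squared,
                "r2_out": out_fit.r_squared,
                "model_in": in_fit.model,
                "model_out": out_fit.model,
                "n_nodes": len(set(sel["regulator"]) | set(sel["target"])),
                "n_edges": len(sel),
                "n_regulators": sel["regulator"].nunique(),
            }
        )
    return CutoffScanResult(regulator_class=regulator_class, table=pd.DataFrame(rows))


def select_cutoff(
    scan: CutoffScanResult,
    tol: float = DEFAULT_TOL,
    window: int = DEFAULT_WINDOW,
) -> float:
    """Smallest cutoff whose R^2 curves have reached a steady state.

    A grid point qualifies when, for both the in- and out-direction
    curves, all of its next ``window`` grid points stay within ``tol``
    of its own R^2 (points without a full window of successors cannot
    qualify).  If no point qualifies, the cutoff maximizing
    min(R^2_in, R^2_out) is returned with a warning.
    """
    t = scan.table
    r2_in = t["r2_in"].to_numpy()
    r2_out = t["r2_out"].to_numpy()
    grid = t["cutoff"].to_numpy()
    n = len(grid)
    for i in range(n - window):
        if all(
            abs(curve[j] - curve[i]) <= tol
            for curve in (r2_in, r2_out)
            for j in range(i + 1, i + 1 + window)
        ):
            return float(grid[i])
    fallback = int(np.argmax(np.minimum(r2_in, r2_out)))
    logger.warning(
        "select_cutoff: no steady state found for %s; falling back to argmax "
        "min(R2_in, R2_out) at cutoff %.3g",
        scan.regulator_class,
        grid[fallback],
    )
    return float(grid[fallback])


def write_scan(scan: CutoffScanResult, path) -> None:
    out = scan.table.copy()
    out.insert(0, "regulator_class", scan.regulator_class)
    out.to_csv(path, sep="\t", index=False)


def plot_scan(scan: CutoffScanResult, path) -> None:
    """R^2 and network size versus cutoff (the cutoff-selection figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = scan.table
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.plot(t["cutoff"], t["r2_in"], "o-", label="in-degree")
    ax1.plot(t["cutoff"], t["r2_out"], "s-", label="out-degree")
    ax1.set_xlabel("|r| cutoff")
    ax1.set_ylabel("$R^2$")
    ax1.set_ylim(-0.05, 1.05)
    ax1.legend()
    ax2.plot(t["cutoff"], t["n_edges"], "o-", color="k")
    ax2.set_xlabel("|r| cutoff")
    ax2.set_ylabel("edges")
    fig.suptitle(f"{scan.regulator_class} regulators")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
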