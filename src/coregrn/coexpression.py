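"""Outlier-robust co-expression scoring and the three-condition edge filter.

For every candidate regulator→target pair, a univariate regression of the
regulator profile (y) on the target profile (x) is fit and samples with
Cook's distance above 0.5 are discarded as outliers; the Pearson
correlation is then computed on the retained samples.  A candidate edge
enters the regulatory network iff

1. it exists in the candidate interaction set,
2. for miRNA regulators the correlation is negative, and
3. |r| exceeds the cutoff of the regulator's class
   (defaults 0.6 for TFs, 0.45 for miRNAs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .candidate_network import InteractionSet
from .expression import RatioMatrix

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = {"TF": 0.6, "miRNA": 0.45}
DEFAULT_COOKS_THRESHOLD = 0.5
DEFAULT_MIN_SAMPLES = 10


@dataclass(frozen=True)
class EdgeScore:
    regulator: str
    target: str
    r: float
    n_used: int
    outliers: tuple[int, ...]

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"|r| > 1 for {self.regulator}->{self.target}")


@dataclass
class RegulatoryNetwork:
    """Directed regulator→target graph of accepted, correlation-weighted edges.

    Nodes carry ``entity_class``; edges carry ``r``, ``n_used``,
    ``evidence`` and ``weight = |r|``.
    """

    graph: nx.DiGraph
    class_cutoffs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "regulator": u,
                "regulator_class": self.graph.nodes[u].get("entity_class", ""),
                "target": v,
                "target_class": self.graph.nodes[v].get("entity_class", ""),
                "r": d["r"],
                "n_used": d["n_used"],
                "evidence": ";".join(sorted(d.get("evidence", ()))),
            }
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "regulator",
                "regulator_class",
                "target",
                "target_class",
                "r",
                "n_used",
                "evidence",
            ],
        )


def cooks_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cook's distance of each sample under the simple regression y ~ x.

    Closed form for a two-parameter fit: D_i = e_i^2 h_ii / (2 s^2 (1-h_ii)^2)
    with leverage h_ii = 1/n + (x_i - xbar)^2 / Sxx and s^2 = SSE/(n-2).
    A perfect fit (SSE = 0) has all distances zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired values")
    dx = x - x.mean()
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ZeroDivisionError("zero variance in x: regression undefined")
    beta = float(dx @ (y - y.mean())) / sxx
    resid = y - (y.mean() + beta * dx)
    h = 1.0 / n + dx**2 / sxx
    s2 = float(resid @ resid) / (n - 2)
    # numerically perfect fit: residuals at rounding level of the data scale
    scale = max(1.0, float(np.abs(y).max()))
    if s2 <= (1e-12 * scale) ** 2:
        return np.zeros(n)
    return resid**2 * h / (2.0 * s2 * (1.0 - h) ** 2)


def cooks_outliers(
    x: np.ndarray, y: np.ndarray, threshold: float = DEFAULT_COOKS_THRESHOLD
) -> np.ndarray:
    """Indices of samples with Cook's distance above ``threshold``."""
    return np.flatnonzero(cooks_distances(x, y) > threshold)


def robust_pearson(
    x: np.ndarray,
    y: np.ndarray,
    cooks_threshold: float = DEFAULT_COOKS_THRESHOLD,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    regulator: str = "y",
    target: str = "x",
) -> EdgeScore | None:
    """Pearson r after single-pass Cook's-distance outlier removal.

    Returns ``None`` for unscorable pairs: fewer than 4 samples, zero
    variance in either profile (before or after removal), or fewer than
    ``min_samples`` samples retained.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    idx = np.flatnonzero(finite)
    x, y = x[idx], y[idx]
    if x.size < max(4, min_samples):
        return None
    try:
        out_local = cooks_outliers(x, y, cooks_threshold)
    except ZeroDivisionError:
        return None
    keep = np.setdiff1d(np.arange(x.size), out_local, assume_unique=True)
    if keep.size < min_samples:
        return None
    xk, yk = x[keep], y[keep]
    if xk.std() == 0.0 or yk.std() == 0.0:
        return None
    r = float(np.corrcoef(xk, yk)[0, 1])
    return EdgeScore(
        regulator=regulator,
        target=target,
        r=r,
        n_used=int(keep.size),
        outliers=tuple(int(i) for i in idx[out_local]),
    )


def score_candidates(
    candidates: InteractionSet,
    ratios: RatioMatrix,
    cooks_threshold: float = DEFAULT_COOKS_THRESHOLD,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> pd.DataFrame:
    """Robust correlation for every scorable candidate edge.

    Returns one row per candidate with columns regulator,
    regulator_class, target, target_class, r, n_used, n_outliers,
    evidence.  Pairs with a missing expression profile or an undefined
    correlation are dropped (counted in the log).
    """
    values = ratios.values
    index = {e: i for i, e in enumerate(values.index)}
    mat = values.values
    rows = []
    n_missing = n_unscorable = 0
    for rec in candidates:
        ri = index.get(rec.regulator)
        ti = index.get(rec.target)
        if ri is None or ti is None:
            n_missing += 1
            continue
        score = robust_pearson(
            mat[ti],
            mat[ri],
            cooks_threshold=cooks_threshold,
            min_samples=min_samples,
            regulator=rec.regulator,
            target=rec.target,
        )
        if score is None:
            n_unscorable += 1
            continue
        rows.append(
            {
                "regulator": rec.regulator,
                "regulator_class": rec.regulator_class,
                "target": rec.target,
                "target_class": rec.target_class,
                "r": score.r,
                "n_used": score.n_used,
                "n_outliers": len(score.outliers),
                "evidence": ";".join(sorted(rec.evidence)),
            }
        )
    if n_missing or n_unscorable:
        logger.info(
            "score_candidates: %d pairs missing a profile, %d unscorable",
            n_missing,
            n_unscorable,
        )
    return pd.DataFrame(
        rows,
        columns=[
            "regulator",
            "regulator_class",
            "target",
            "target_class",
            "r",
            "n_used",
            "n_outliers",
            "evidence",
        ],
    )


def apply_conditions(scores: pd.DataFrame, class_cutoffs: dict[str, float]) -> pd.Series:
    """Boolean mask of scored candidate edges passing conditions 2 and 3."""
    for cls, c in class_cutoffs.items():
        if not 0.0 <= c < 1.0:
            raise ValueError(f"cutoff for {cls} must be in [0, 1)")
    if scores.empty:
        return pd.Series(dtype=bool)
    cutoff = scores["regulator_class"].map(class_cutoffs)
    if cutoff.isna().any():
        missing = sorted(set(scores.loc[cutoff.isna(), "regulator_class"]))
        raise ValueError(f"no cutoff for regulator class(es) {missing}")
    sign_ok = (scores["regulator_class"] != "miRNA") | (scores["r"] < 0)
    return sign_ok & (scores["r"].abs() > cutoff)


def network_from_scores(
    scores: pd.DataFrame, class_cutoffs: dict[str, float]
) -> RegulatoryNetwork:
    graph = nx.DiGraph()
    for row in scores.itertuples(index=False):
        graph.add_node(row.regulator, entity_class=row.regulator_class)
        graph.add_node(row.target, entity_class=row.target_class)
        graph.add_edge(
            row.regulator,
            row.target,
            r=float(row.r),
            weight=abs(float(row.r)),
            n_used=int(row.n_used),
            evidence=frozenset(row.evidence.split(";")) if row.evidence else frozenset(),
        )
    return RegulatoryNetwork(graph=graph, class_cutoffs=dict(class_cutoffs))


def build_grn(
    candidates: InteractionSet,
    ratios: RatioMatrix,
    class_cutoffs: dict[str, float] | None = None,
    cooks_threshold: float = DEFAULT_COOKS_THRESHOLD,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> RegulatoryNetwork:
    """Assemble the regulatory network from candidates passing all three conditions."""
    cutoffs = dict(DEFAULT_CUTOFFS if class_cutoffs is None else class_cutoffs)
    scores = score_candidates(
        candidates, ratios, cooks_threshold=cooks_threshold, min_samples=min_samples
    )
    passed = scores[apply_conditions(scores, cutoffs)] if len(scores) else scores
    return network_from_scores(passed, cutoffs)
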