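"""Paired tumor/normal intensities to penalized log-ratios.

The pipeline starts from RMA-normalized intensity matrices measured on
paired tumor (TU) and adjacent non-tumor (AN) tissue from the same
patients.  Per-probe relative expression is summarized as a penalized
log2 ratio

    ratio = log2((TU + alpha) / (AN + alpha))

where the penalty ``alpha`` — the mean of the 25% intensity quantiles of
the two matrices — damps the explosive ratios that division of small
intensities would otherwise produce.  Probe-level ratios are then merged
to entity level (gene / TF / miRNA) by averaging, and a one-sample
t-test of each entity's ratios against zero gives the differential
expression statistic (positive t = up in tumor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ENTITY_CLASSES = ("gene", "TF", "miRNA")


@dataclass
class ExpressionPanel:
    """Paired positive intensity matrices plus the probe→entity map.

    ``tu`` and ``an`` are probes × patients DataFrames with identical
    index and columns; ``probe_map`` has columns ``probe_id``,
    ``entity_id``, ``entity_class``.
    """

    tu: pd.DataFrame
    an: pd.DataFrame
    probe_map: pd.DataFrame

    def __post_init__(self) -> None:
        if self.tu.shape != self.an.shape:
            raise ValueError("TU and AN matrices must have identical shape")
        if not self.tu.index.equals(self.an.index) or not self.tu.columns.equals(
            self.an.columns
        ):
            raise ValueError("TU and AN must share row and column order")
        if self.tu.size == 0:
            raise ValueError("empty intensity matrices")
        if (self.tu.values <= 0).any() or (self.an.values <= 0).any():
            raise ValueError("intensities must be strictly positive")
        required = {"probe_id", "entity_id", "entity_class"}
        if not required.issubset(self.probe_map.columns):
            raise ValueError(f"probe_map needs columns {sorted(required)}")
        if self.probe_map["probe_id"].duplicated().any():
            raise ValueError("a probe maps to more than one entity")
        unknown = set(self.probe_map["entity_class"]) - set(ENTITY_CLASSES)
        if unknown:
            raise ValueError(f"unknown entity classes: {sorted(unknown)}")
        unmapped = self.tu.index.difference(self.probe_map["probe_id"])
        if len(unmapped):
            raise ValueError(f"probes without entity mapping: {list(unmapped[:5])}")

    @property
    def n_patients(self) -> int:
        return self.tu.shape[1]

    def entity_classes(self) -> dict[str, str]:
        """entity id → class, deduplicated over probes."""
        return dict(
            zip(self.probe_map["entity_id"], self.probe_map["entity_class"])
        )


@dataclass
class RatioMatrix:
    """Log2 penalized ratios (rows = probes or entities, cols = patients)."""

    values: pd.DataFrame
    alpha: float
    t_values: pd.Series | None = field(default=None)
    p_values: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not np.isfinite(self.values.values).all():
            raise ValueError("ratio values must be finite")


def compute_alpha(panel: ExpressionPanel) -> float:
    """Penalty alpha = mean of the pooled 25% quantiles of TU and AN.

    The quantile is taken over all entries of each matrix (linear
    interpolation between order statistics).
    """
    q_tu = float(np.quantile(panel.tu.values, 0.25))
    q_an = float(np.quantile(panel.an.values, 0.25))
    return (q_tu + q_an) / 2.0


def compute_ratios(panel: ExpressionPanel, alpha: float) -> RatioMatrix:
    """Probe-level penalized log2 ratios log2((TU+a)/(AN+a))."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    values = np.log2((panel.tu + alpha) / (panel.an + alpha))
    return RatioMatrix(values=values, alpha=float(alpha))


def merge_probes(ratios: RatioMatrix, probe_map: pd.DataFrame) -> RatioMatrix:
    """Collapse probe rows to entity rows by per-patient arithmetic mean."""
    mapping = probe_map.set_index("probe_id")["entity_id"]
    missing = ratios.values.index.difference(mapping.index)
    if len(missing):
        raise ValueError(f"probe without entity: {missing[0]!r}")
    entity = ratios.values.groupby(mapping.reindex(ratios.values.index)).mean()
    entity.index.name = "entity_id"
    entity = entity.sort_index()
    return RatioMatrix(values=entity, alpha=ratios.alpha)


def differential_stats(ratios: RatioMatrix) -> tuple[pd.Series, pd.Series]:
    """One-sample two-sided t-test of each row against zero.

    Rows with zero variance have no defined t statistic and are reported
    as NaN rather than raising.  Requires at least 3 patients.
    """
    x = ratios.values.values
    n = x.shape[1]
    if n < 3:
        raise ValueError("need at least 3 patients for the t-test")
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    p = np.where(np.isnan(t), np.nan, 2.0 * stats.t.sf(np.abs(t), df=n - 1))
    n_undef = int(np.isnan(t).sum())
    if n_undef:
        logger.warning("%d zero-variance rows: t reported as missing", n_undef)
    idx = ratios.values.index
    t_s = pd.Series(t, index=idx, name="t")
    p_s = pd.Series(p, index=idx, name="p")
    ratios.t_values = t_s
    ratios.p_values = p_s
    return t_s, p_s


def read_panel(tu_path, an_path, probe_map_path) -> ExpressionPanel:
    """Read TU/AN intensity TSVs (rows=probes) and the probe-map TSV."""
    tu = pd.read_csv(tu_path, sep="\t", index_col=0)
    an = pd.read_csv(an_path, sep="\t", index_col=0)
    probe_map = pd.read_csv(probe_map_path, sep="\t", dtype=str)
    return ExpressionPanel(tu=tu, an=an, probe_map=probe_map)


def write_ratios(ratios: RatioMatrix, path) -> None:
    ratios.values.to_csv(path, sep="\t")


def write_stats(ratios: RatioMatrix, path) -> None:
    if ratios.t_values is None:
        raise ValueError("call differential_stats first")
    df = pd.DataFrame({"t": ratios.t_values, "p": ratios.p_values})
    df.index.name = "entity_id"
    df.to_csv(path, sep="\t")
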