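"""Over-representation analysis for module gene lists and miRNA lists.

Generic hypergeometric enrichment against user-supplied annotation
collections (GMT files), with Benjamini–Hochberg FDR adjustment.  The
annotation background (e.g. all annotated miRNAs) is explicit, since
enrichment p-values are meaningless without it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCollection:
    terms: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.terms.items():
            if not members <= self.background:
                raise ValueError(f"term {name!r} has members outside the background")

    @classmethod
    def from_gmt(cls, path, background=None) -> "AnnotationCollection":
        """Read a GMT file (term <tab> description <tab> member...).

        Without an explicit background, the union of all term members
        is used.
        """
        terms: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3 or not fields[0]:
                    continue
                terms[fields[0]] = frozenset(m for m in fields[2:] if m)
        if background is None:
            background = frozenset().union(*terms.values()) if terms else frozenset()
        return cls(terms=terms, background=frozenset(background))


def hypergeom_enrich(query, annotations: AnnotationCollection) -> pd.DataFrame:
    """One-sided hypergeometric upper-tail enrichment of a query set.

    For each term, p = P[overlap >= observed] drawing |query| ids
    without replacement from the background.  Query ids outside the
    background are dropped with a warning.  Rows are sorted by p-value
    (ties broken by term name) and carry BH-adjusted FDRs.
    """
    query = set(query)
    outside = query - set(annotations.background)
    if outside:
        logger.warning(
            "dropping %d query id(s) outside the background", len(outside)
        )
        query -= outside
    columns = [
        "term",
        "overlap",
        "query_size",
        "term_size",
        "background_size",
        "p_value",
        "fdr",
    ]
    if not query:
        logger.warning("empty query after background restriction")
        return pd.DataFrame(columns=columns)
    N = len(annotations.background)
    n = len(query)
    rows = []
    for term, members in sorted(annotations.terms.items()):
        K = len(members)
        k = len(query & members)
        # sf(k-1) = P[X >= k] for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "term": term,
                "overlap": k,
                "query_size": n,
                "term_size": K,
                "background_size": N,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows, columns=columns[:-1])
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def write_enrichment(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
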