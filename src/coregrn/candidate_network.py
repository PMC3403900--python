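"""Candidate regulatory interactions from predicted and experimental sources.

The candidate network is the union of sequence-based target predictions
(TF→gene, TF→miRNA, miRNA→gene) and experimentally supported
interactions, read from TSV adjacency lists.  It carries evidence flags
per edge and is restricted to entities actually measured on the arrays
before any expression filtering happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

REGULATOR_CLASSES = ("TF", "miRNA")
TARGET_CLASSES = ("gene", "TF", "miRNA")

#: admissible (regulator_class, target_class) pairs; no miRNA→miRNA edges.
VALID_EDGE_CLASSES = frozenset(
    [
        ("TF", "gene"),
        ("TF", "TF"),
        ("TF", "miRNA"),
        ("miRNA", "gene"),
        ("miRNA", "TF"),
    ]
)


@dataclass(frozen=True)
class InteractionRecord:
    regulator: str
    regulator_class: str
    target: str
    target_class: str
    evidence: frozenset[str]
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.regulator == self.target:
            raise ValueError(f"self-loop: {self.regulator}")
        key = (self.regulator_class, self.target_class)
        if key not in VALID_EDGE_CLASSES:
            raise ValueError(f"invalid edge class {key} for {self.regulator}->{self.target}")


class InteractionSet:
    """Deduplicated candidate edges keyed by (regulator, target)."""

    def __init__(self, records: Iterable[InteractionRecord] = ()) -> None:
        self._records: dict[tuple[str, str], InteractionRecord] = {}
        for rec in records:
            self._add(rec)

    def _add(self, rec: InteractionRecord) -> None:
        key = (rec.regulator, rec.target)
        old = self._records.get(key)
        if old is None:
            self._records[key] = rec
            return
        if (old.regulator_class, old.target_class) != (
            rec.regulator_class,
            rec.target_class,
        ):
            raise ValueError(
                f"class conflict for pair {key}: "
                f"{(old.regulator_class, old.target_class)} vs "
                f"{(rec.regulator_class, rec.target_class)}"
            )
        self._records[key] = replace(
            old,
            evidence=old.evidence | rec.evidence,
            sources=tuple(dict.fromkeys(old.sources + rec.sources)),
        )

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self._records[k] for k in sorted(self._records))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._records

    def get(self, regulator: str, target: str) -> InteractionRecord | None:
        return self._records.get((regulator, target))

    def entities(self) -> set[str]:
        out: set[str] = set()
        for rec in self._records.values():
            out.add(rec.regulator)
            out.add(rec.target)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "regulator": r.regulator,
                "regulator_class": r.regulator_class,
                "target": r.target,
                "target_class": r.target_class,
                "evidence": ";".join(sorted(r.evidence)),
            }
            for r in self
        ]
        return pd.DataFrame(
            rows,
            columns=["regulator", "regulator_class", "target", "target_class", "evidence"],
        )

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def load_interactions(path, evidence_label: str = "predicted") -> InteractionSet:
    """Parse a TSV adjacency list into an InteractionSet.

    Expected columns: regulator, regulator_class, target, target_class
    (header row required; an optional ``evidence`` column overrides
    ``evidence_label``).  Self-loops and invalid edge classes (e.g.
    miRNA→miRNA) are dropped with a logged count; an unknown class token
    raises with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["regulator", "regulator_class", "target", "target_class"]
    if not set(required).issubset(df.columns):
        raise ValueError(f"{path}: expected columns {required}")
    if df.empty:
        logger.warning("%s: empty interaction file", path)
        return InteractionSet()
    records = []
    n_self = n_invalid = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        rc, tc = row.regulator_class, row.target_class
        if rc not in REGULATOR_CLASSES or tc not in TARGET_CLASSES:
            raise ValueError(f"{path}:{i}: unknown class token {rc!r}/{tc!r}")
        if row.regulator == row.target:
            n_self += 1
            continue
        if (rc, tc) not in VALID_EDGE_CLASSES:
            n_invalid += 1
            continue
        if hasattr(row, "evidence") and isinstance(row.evidence, str) and row.evidence:
            evidence = frozenset(row.evidence.split(";"))
        else:
            evidence = frozenset([evidence_label])
        records.append(
            InteractionRecord(
                regulator=row.regulator,
                regulator_class=rc,
                target=row.target,
                target_class=tc,
                evidence=evidence,
                sources=(str(path),),
            )
        )
    if n_self:
        logger.warning("%s: dropped %d self-loops", path, n_self)
    if n_invalid:
        logger.warning("%s: dropped %d invalid-class edges (e.g. miRNA->miRNA)", path, n_invalid)
    return InteractionSet(records)


def merge_sets(a: InteractionSet, b: InteractionSet) -> InteractionSet:
    """Union on (regulator, target); evidence flags OR-combined."""
    merged = InteractionSet(a)
    for rec in b:
        merged._add(rec)
    return merged


def restrict_to_measured(iset: InteractionSet, entity_ids: Iterable[str]) -> InteractionSet:
    """Keep only edges whose both endpoints were measured."""
    measured = set(entity_ids)
    kept, dropped = [], 0
    for rec in iset:
        if rec.regulator in measured and rec.target in measured:
            kept.append(rec)
        else:
            dropped += 1
    if dropped:
        logger.info("restrict_to_measured: dropped %d of %d records", dropped, len(iset))
    return InteractionSet(kept)
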