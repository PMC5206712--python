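"""Parsing of PhenomiR-style fold-change records into a validated dataset.

Each input row reports one observation: a study measured a miRNA's
fold-change in a disease, citing a PubMed ID.  A (miRNA, disease) pair is
treated downstream as a single network vertex (an *MD node*), so the same
miRNA under two diseases yields two distinct vertices with independent
expression profiles.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionRecord",
    "MDNode",
    "Dataset",
    "DropReport",
    "CANONICAL_FIELDS",
    "parse_records",
    "build_md_index",
    "write_records",
]

#: Canonical column names of the record schema, in order.
CANONICAL_FIELDS = ("study_id", "pmid", "disease", "mirna", "fc_min", "fc_max")


@dataclass(frozen=True)
class ExpressionRecord:
    """One (study, PMID, disease, miRNA, fold-change) observation.

    ``fc_min`` is the minimum reported fold-change and is always present and
    finite; ``fc_max`` is the maximum fold-change and may be ``None`` when the
    source row reported a single value.
    """

    study_id: str
    pmid: str
    disease: str
    mirna: str
    fc_min: float
    fc_max: float | None = None

    def __post_init__(self) -> None:
        if not self.mirna or not self.disease:
            raise ValueError("mirna and disease must be non-empty")
        if not np.isfinite(self.fc_min):
            raise ValueError("fc_min must be finite")
        if self.fc_max is not None and not np.isfinite(self.fc_max):
            raise ValueError("fc_max must be finite when present")


@dataclass(frozen=True, order=True)
class MDNode:
    """A (miRNA, disease) pair treated as one network vertex."""

    mirna: str
    disease: str

    @property
    def label(self) -> str:
        return f"{self.disease}:{self.mirna}"


@dataclass
class DropReport:
    """Counts of input rows discarded during parsing, by reason."""

    total_rows: int = 0
    missing_fold_change: int = 0
    misformatted: int = 0

    @property
    def dropped(self) -> int:
        return self.missing_fold_change + self.misformatted

    @property
    def retained(self) -> int:
        return self.total_rows - self.dropped


@dataclass
class Dataset:
    """Validated records plus the deterministic MD-node universe.

    Nodes are indexed lexicographically by (disease, mirna) so that any
    permutation of the input rows yields the same indexing.
    """

    records: list[ExpressionRecord]
    nodes: list[MDNode]
    studies: list[str]
    drop_report: DropReport = field(default_factory=DropReport)

    def __post_init__(self) -> None:
        self._node_index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def node_of(self, record: ExpressionRecord) -> MDNode:
        return MDNode(record.mirna, record.disease)

    def index_of(self, node: MDNode) -> int:
        return self._node_index[node]

    def node_labels(self) -> list[str]:
        return [n.label for n in self.nodes]


def _normalize_name(value: str) -> str:
    return str(value).strip().casefold()


def _parse_float(value) -> float | None:
    """Return a finite float, or None for an absent/misformatted cell."""
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    text = str(value).strip()
    if not text or text.lower() in {"na", "nan", "none", "null"}:
        return None
    try:
        out = float(text)
    except ValueError:
        raise _Misformatted(text)
    if not np.isfinite(out):
        raise _Misformatted(text)
    return out


class _Misformatted(ValueError):
    pass


def parse_records(
    source: str | Path | io.IOBase,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> Dataset:
    """Parse a delimited record file into a validated :class:`Dataset`.

    Parameters
    ----------
    source
        Path or open text stream holding a header plus one row per
        observation.
    dialect
        Optional mapping from canonical field names (``study_id``, ``pmid``,
        ``disease``, ``mirna``, ``fc_min``, ``fc_max``) to the column names
        actually present, to adapt foreign exports.  Unmapped fields default
        to their canonical names.
    sep
        Field separator; autodetected (tab vs comma) when omitted.

    Rows missing every fold-change value, or whose fold-change fields fail to
    parse as finite numbers, are dropped and counted in the returned dataset's
    ``drop_report``.  Duplicate (study, miRNA, disease) observations collapse
    to one record by averaging ``fc_min`` (and ``fc_max`` over rows where it
    is present).
    """
    mapping = dict.fromkeys(CANONICAL_FIELDS)
    for k in mapping:
        mapping[k] = (dialect or {}).get(k, k)
    try:
        frame = pd.read_csv(source, sep=sep, engine="python", dtype=str)
    except (OSError, pd.errors.EmptyDataError) as exc:
        if isinstance(exc, pd.errors.EmptyDataError):
            return build_md_index([])
        raise
    missing_cols = [
        mapping[k] for k in ("study_id", "pmid", "disease", "mirna", "fc_min")
        if mapping[k] not in frame.columns
    ]
    if missing_cols:
        raise KeyError(f"dialect maps to absent column(s): {missing_cols}")
    has_max = mapping["fc_max"] in frame.columns

    report = DropReport(total_rows=len(frame))
    rows: list[ExpressionRecord] = []
    for row in frame.itertuples(index=False):
        row = dict(zip(frame.columns, row))
        try:
            fc_min = _parse_float(row[mapping["fc_min"]])
            fc_max = _parse_float(row[mapping["fc_max"]]) if has_max else None
        except _Misformatted:
            report.misformatted += 1
            continue
        if fc_min is None and fc_max is None:
            report.missing_fold_change += 1
            continue
        if fc_min is None:
            # only a maximum was reported: treat it as the single known value
            fc_min, fc_max = fc_max, None
        mirna = _normalize_name(row[mapping["mirna"]])
        disease = _normalize_name(row[mapping["disease"]])
        if not mirna or not disease:
            report.misformatted += 1
            continue
        rows.append(
            ExpressionRecord(
                study_id=str(row[mapping["study_id"]]).strip(),
                pmid=str(row[mapping["pmid"]]).strip(),
                disease=disease,
                mirna=mirna,
                fc_min=fc_min,
                fc_max=fc_max,
            )
        )
    dataset = build_md_index(_collapse_duplicates(rows))
    dataset.drop_report = report
    return dataset


def _collapse_duplicates(records: Sequence[ExpressionRecord]) -> list[ExpressionRecord]:
    """Average fc_min/fc_max over duplicate (study, mirna, disease) rows."""
    groups: dict[tuple[str, str, str], list[ExpressionRecord]] = {}
    order: list[tuple[str, str, str]] = []
    for rec in records:
        key = (rec.study_id, rec.mirna, rec.disease)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    out = []
    for key in order:
        grp = groups[key]
        if len(grp) == 1:
            out.append(grp[0])
            continue
        maxes = [r.fc_max for r in grp if r.fc_max is not None]
        out.append(
            ExpressionRecord(
                study_id=grp[0].study_id,
                pmid=grp[0].pmid,
                disease=grp[0].disease,
                mirna=grp[0].mirna,
                fc_min=float(np.mean([r.fc_min for r in grp])),
                fc_max=float(np.mean(maxes)) if maxes else None,
            )
        )
    return out


def build_md_index(records: Iterable[ExpressionRecord]) -> Dataset:
    """Build the MD-node universe: one node per distinct (miRNA, disease).

    Node order is lexicographic by (disease, mirna); study order follows
    first appearance in the record stream.
    """
    records = list(records)
    nodes = sorted(
        {MDNode(r.mirna, r.disease) for r in records},
        key=lambda n: (n.disease, n.mirna),
    )
    studies = list(dict.fromkeys(r.study_id for r in records))
    return Dataset(records=records, nodes=nodes, studies=studies)


def write_records(dataset: Dataset, sink: str | Path | io.IOBase, sep: str = ",") -> None:
    """Serialize records in the canonical schema (round-trips via parse)."""
    frame = pd.DataFrame(
        [
            {
                "study_id": r.study_id,
                "pmid": r.pmid,
                "disease": r.disease,
                "mirna": r.mirna,
                "fc_min": r.fc_min,
                "fc_max": "" if r.fc_max is None else r.fc_max,
            }
            for r in dataset.records
        ],
        columns=list(CANONICAL_FIELDS),
    )
    frame.to_csv(sink, sep=sep, index=False)
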