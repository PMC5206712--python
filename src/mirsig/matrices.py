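"""Build the three study x MD-node fold-change matrices.

Three scoring schemes turn dual-valued (min, max) fold-change records into a
single expression matrix:

``average``
    cell = mean(fc_min, fc_max) when both are reported, else fc_min.
``maxmin``
    any study holding at least one dual-valued record is duplicated into a
    ``:min`` row (all minima) and a ``:max`` row (maxima where reported,
    minima repeated elsewhere), so both data points survive.
``missingmax``
    a record lacking fc_max first borrows the mean fc_max of the same MD node
    across all other studies where one was reported (falling back to its own
    fc_min when none exists anywhere), then the average rule is applied.

Cells never observed in a study stay missing (NaN) and are resolved only by
an explicit completion policy before inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import Dataset, ExpressionRecord

__all__ = ["ExpressionMatrix", "build_matrix", "MATRIX_METHODS"]

MATRIX_METHODS = ("average", "maxmin", "missingmax")


@dataclass
class ExpressionMatrix:
    """Samples x MD-nodes fold-change matrix with explicit missingness.

    ``data`` is a DataFrame whose rows are sample labels (study ids, possibly
    suffixed ``:min``/``:max``), whose columns are MD-node labels
    (``disease:mirna``), and whose NaN cells mark unobserved pairs.
    """

    data: pd.DataFrame
    method: str

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def completed(self, policy: str = "zero_fill") -> pd.DataFrame:
        """Resolve missing cells for scorers that need a complete matrix.

        ``zero_fill`` scores an unobserved MD in a study as 0, i.e. no
        reported differential expression.  ``pairwise_complete`` returns the
        NaN-bearing frame unchanged for scorers that drop incomplete pairs
        themselves.
        """
        if policy == "zero_fill":
            return self.data.fillna(0.0)
        if policy == "pairwise_complete":
            return self.data
        raise ValueError(f"unknown missing-cell policy: {policy!r}")

    def to_csv(self, sink: str | Path) -> None:
        self.data.to_csv(sink, index_label="sample")

    @classmethod
    def from_csv(cls, source: str | Path, method: str = "average") -> "ExpressionMatrix":
        frame = pd.read_csv(source, index_col="sample")
        frame.index = frame.index.astype(str)
        return cls(data=frame, method=method)


def _cell_average(rec: ExpressionRecord) -> float:
    if rec.fc_max is None:
        return rec.fc_min
    return (rec.fc_min + rec.fc_max) / 2.0


def _empty_frame(data: Dataset, rows: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        np.full((len(rows), data.n_nodes), np.nan),
        index=pd.Index(rows, name="sample"),
        columns=data.node_labels(),
    )


def build_average_matrix(data: Dataset) -> ExpressionMatrix:
    """One row per study; dual-valued cells hold mean(fc_min, fc_max)."""
    frame = _empty_frame(data, list(data.studies))
    for rec in data.records:
        frame.loc[rec.study_id, data.node_of(rec).label] = _cell_average(rec)
    return ExpressionMatrix(frame, "average")


def build_maxmin_matrix(data: Dataset) -> ExpressionMatrix:
    """Expand dual-valued studies into separate min and max sample rows."""
    by_study: dict[str, list[ExpressionRecord]] = {s: [] for s in data.studies}
    for rec in data.records:
        by_study[rec.study_id].append(rec)

    rows: list[str] = []
    for study in data.studies:
        if any(r.fc_max is not None for r in by_study[study]):
            rows.extend([f"{study}:min", f"{study}:max"])
        else:
            rows.append(study)
    frame = _empty_frame(data, rows)
    for study in data.studies:
        expanded = any(r.fc_max is not None for r in by_study[study])
        for rec in by_study[study]:
            label = data.node_of(rec).label
            if expanded:
                frame.loc[f"{study}:min", label] = rec.fc_min
                # single-valued records repeat their minimum in the max row
                frame.loc[f"{study}:max", label] = (
                    rec.fc_max if rec.fc_max is not None else rec.fc_min
                )
            else:
                frame.loc[study, label] = rec.fc_min
    return ExpressionMatrix(frame, "maxmin")


def build_missing_max_matrix(data: Dataset) -> ExpressionMatrix:
    """Impute absent fc_max from the MD's other studies, then average."""
    max_by_node: dict[str, list[float]] = {}
    for rec in data.records:
        if rec.fc_max is not None:
            max_by_node.setdefault(data.node_of(rec).label, []).append(rec.fc_max)

    frame = _empty_frame(data, list(data.studies))
    for rec in data.records:
        label = data.node_of(rec).label
        fc_max = rec.fc_max
        if fc_max is None:
            others = max_by_node.get(label, [])
            fc_max = float(np.mean(others)) if others else rec.fc_min
        frame.loc[rec.study_id, label] = (rec.fc_min + fc_max) / 2.0
    return ExpressionMatrix(frame, "missingmax")


_BUILDERS = {
    "average": build_average_matrix,
    "maxmin": build_maxmin_matrix,
    "missingmax": build_missing_max_matrix,
}


def build_matrix(data: Dataset, method: str = "average") -> ExpressionMatrix:
    """Dispatch to one of the three matrix builders by name."""
    try:
        builder = _BUILDERS[method]
    except KeyError:
        raise ValueError(f"unknown matrix method {method!r}; expected one of {MATRIX_METHODS}")
    return builder(data)
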