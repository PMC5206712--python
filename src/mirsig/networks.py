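"""Edge taxonomy, disease-specific miRNA networks, and signature mining.

An MD-MD edge falls into one of four types by whether its endpoints share
the miRNA and/or the disease:

    1  same miRNA,      same disease      (self-loop, unused)
    2  same miRNA,      different disease
    3  different miRNA, same disease      (feeds all downstream analysis)
    4  different miRNA, different disease

Type-3 edges above a confidence threshold form, per disease, the
disease-specific miRNA interaction network (DMIN).  Intersecting the DMINs
of every disease in a class yields the class's conserved signature
component: the miRNA-miRNA edges confidently predicted in all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import networkx as nx
import pandas as pd

from .consensus import ConsensusResult, Edge

__all__ = [
    "DEFAULT_DISEASE_CLASSES",
    "split_label",
    "classify_edge_type",
    "DMIN",
    "SignatureComponent",
    "build_dmin",
    "top_fraction_threshold",
    "intersect_class_signature",
    "export_edgelist_csv",
    "read_edgelist_csv",
]

#: Cancer classes bundled as the default class layout, grouped by
#: tissue/organ specificity; users supply their own mapping for other data.
DEFAULT_DISEASE_CLASSES: dict[str, list[str]] = {
    "gastrointestinal": [
        "esophageal cancer",
        "gastroesophageal cancer",
        "gastrointestinal cancer",
        "gastric cancer",
        "colorectal cancer",
    ],
    "endocrine": [
        "hepatocellular carcinoma",
        "pancreatic cancer",
        "thyroid carcinoma follicular",
        "thyroid carcinoma papillary",
    ],
    "leukemia": [
        "hematological tumors",
        "acute myeloid leukemia",
        "chronic lymphatic leukemia",
        "acute myelogenous leukemia",
    ],
    "nerve": ["neuroblastoma", "medulloblastoma", "glioblastoma"],
}


def split_label(label: str) -> tuple[str, str]:
    """Split a ``disease:mirna`` node label into (disease, mirna)."""
    disease, _, mirna = label.rpartition(":")
    if not disease or not mirna:
        raise ValueError(f"not a disease:mirna label: {label!r}")
    return disease, mirna


def classify_edge_type(edge: Edge) -> int:
    """Classify an ordered MD-node pair into taxonomy types 1-4."""
    disease_a, mirna_a = split_label(edge[0])
    disease_b, mirna_b = split_label(edge[1])
    same_mirna = mirna_a == mirna_b
    same_disease = disease_a == disease_b
    if same_mirna:
        return 1 if same_disease else 2
    return 3 if same_disease else 4


@dataclass
class DMIN:
    """Disease-specific miRNA interaction network.

    Undirected, weighted by consensus confidence in [0, 1]; vertices are the
    endpoint union of the retained edges, no self-edges.
    """

    disease: str
    edges: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def vertices(self) -> set[str]:
        return set().union(*self.edges) if self.edges else set()

    def __len__(self) -> int:
        return len(self.edges)

    def edge_keys(self) -> set[frozenset[str]]:
        return set(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(disease=self.disease)
        for pair, w in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, weight=w)
        return g


@dataclass
class SignatureComponent:
    """miRNA-miRNA edges conserved across every disease of a class."""

    disease_class: str
    member_diseases: list[str]
    edges: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def mirnas(self) -> set[str]:
        return set().union(*self.edges) if self.edges else set()

    def __len__(self) -> int:
        return len(self.edges)

    def connected_components(self) -> list["SignatureComponent"]:
        """Split the signature into its connected pieces, largest first."""
        g = nx.Graph()
        for pair, w in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, weight=w)
        parts = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
        out = []
        for members in parts:
            sub = {p: w for p, w in self.edges.items() if p <= members}
            out.append(
                SignatureComponent(self.disease_class, list(self.member_diseases), sub)
            )
        return out


def build_dmin(
    consensus: ConsensusResult, disease: str, min_confidence: float = 0.9
) -> DMIN:
    """Collect the disease's type-3 edges at or above the confidence cutoff.

    The two orientations of a pair collapse to one undirected edge whose
    weight is the larger of the two directed confidences.  An unknown
    disease yields an empty network with a warning.
    """
    edges: dict[frozenset[str], float] = {}
    seen_disease = False
    for (src, dst), score in consensus.final_rank.items():
        if classify_edge_type((src, dst)) != 3:
            continue
        d, mirna_a = split_label(src)
        _, mirna_b = split_label(dst)
        if d != disease:
            continue
        seen_disease = True
        if score < min_confidence:
            continue
        key = frozenset((mirna_a, mirna_b))
        edges[key] = max(edges.get(key, 0.0), score)
    if not seen_disease:
        warnings.warn(f"no edges found for disease {disease!r}", stacklevel=2)
    return DMIN(disease=disease, edges=edges)


def top_fraction_threshold(consensus: ConsensusResult, fraction: float = 0.1) -> float:
    """Confidence cutoff keeping the top ``fraction`` of consensus edges."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores = sorted(consensus.final_rank.values(), reverse=True)
    k = max(1, int(round(fraction * len(scores))))
    return scores[k - 1]


def intersect_class_signature(
    dmins: Sequence[DMIN], class_name: str
) -> SignatureComponent:
    """Edges present (at confidence) in every member DMIN of the class.

    A surviving edge's weight is its minimum confidence across the members —
    the weakest link of its conservation.  Any empty member empties the
    signature.
    """
    dmins = list(dmins)
    if not dmins:
        raise ValueError("need at least one DMIN to intersect")
    common = set(dmins[0].edge_keys())
    for d in dmins[1:]:
        common &= d.edge_keys()
    edges = {pair: min(d.edges[pair] for d in dmins) for pair in common}
    return SignatureComponent(
        disease_class=class_name,
        member_diseases=[d.disease for d in dmins],
        edges=edges,
    )


def export_edgelist_csv(network: DMIN | SignatureComponent, sink: str | Path) -> None:
    """Write one row per edge: mirna_a, mirna_b, disease_or_class, confidence."""
    context = network.disease if isinstance(network, DMIN) else network.disease_class
    rows = [
        {"mirna_a": a, "mirna_b": b, "disease_or_class": context, "confidence": w}
        for (a, b), w in sorted(
            ((tuple(sorted(pair)), w) for pair, w in network.edges.items())
        )
    ]
    pd.DataFrame(
        rows, columns=["mirna_a", "mirna_b", "disease_or_class", "confidence"]
    ).to_csv(sink, index=False)


def read_edgelist_csv(source: str | Path) -> DMIN:
    """Read an exported edge list back into a DMIN (context from first row)."""
    frame = pd.read_csv(source)
    edges = {
        frozenset((str(r.mirna_a), str(r.mirna_b))): float(r.confidence)
        for r in frame.itertuples(index=False)
    }
    context = str(frame["disease_or_class"].iloc[0]) if len(frame) else ""
    return DMIN(disease=context, edges=edges)
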