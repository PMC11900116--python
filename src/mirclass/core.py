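"""Core containers shared across the pipeline.

A cohort is a list of :class:`MiRNARecord`; its annotations (predicted gene
targets with confidence scores, pathway assignments with enrichment p-values)
live in an :class:`AnnotationSet`; the merged design matrix handed to the
learners is a :class:`FeatureTable`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

RNA_ALPHABET = frozenset("ACGU")
PATHWAY_ID_RE = re.compile(r"^hsa\d{5}$")

LABEL_SELECTED = "selected"
LABEL_RANDOM = "random"
LABEL_UNLABELED = "unlabeled"
LABELS = (LABEL_SELECTED, LABEL_RANDOM, LABEL_UNLABELED)

#: column-kind tags for FeatureTable provenance
KIND_DESCRIPTOR = "descriptor"
KIND_GENE = "gene"
KIND_PATHWAY = "pathway"


class AlphabetError(ValueError):
    """Sequence contains a character outside {A, C, G, U} after normalization."""


class SchemaError(ValueError):
    """A delimited input file is missing a required column."""


@dataclass(frozen=True)
class MiRNARecord:
    """One mature miRNA: id, RNA sequence, and an optional class label."""

    mirna_id: str
    sequence: str
    label: str = LABEL_UNLABELED

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.mirna_id!r}")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence of {self.mirna_id!r} contains non-ACGU characters: "
                f"{sorted(bad)}"
            )
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r} for {self.mirna_id!r}")


@dataclass(frozen=True)
class TargetRecord:
    """A predicted miRNA→gene interaction with a confidence score in [0, 100]."""

    mirna_id: str
    gene: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 100.0:
            raise ValueError(
                f"target score {self.score} for ({self.mirna_id}, {self.gene}) "
                "outside [0, 100]"
            )


@dataclass(frozen=True)
class PathwayRecord:
    """A pathway assignment (id ``hsaNNNNN``) with an enrichment p-value."""

    mirna_id: str
    pathway_id: str
    p_value: float

    def __post_init__(self) -> None:
        if not PATHWAY_ID_RE.match(self.pathway_id):
            raise ValueError(f"malformed pathway id {self.pathway_id!r}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(
                f"p-value {self.p_value} for ({self.mirna_id}, {self.pathway_id}) "
                "outside (0, 1]"
            )


@dataclass
class AnnotationSet:
    """Gene-target and pathway annotations for a cohort, grouped by miRNA id."""

    targets: list[TargetRecord] = field(default_factory=list)
    pathways: list[PathwayRecord] = field(default_factory=list)

    def targets_of(self, mirna_id: str) -> list[TargetRecord]:
        return [t for t in self.targets if t.mirna_id == mirna_id]

    def pathways_of(self, mirna_id: str) -> list[PathwayRecord]:
        return [p for p in self.pathways if p.mirna_id == mirna_id]


@dataclass
class FeatureTable:
    """Design matrix with named, provenance-tagged columns and class labels.

    ``column_kinds[j]`` is one of ``descriptor`` / ``gene`` / ``pathway`` and
    records where column ``j`` came from; gene and pathway columns are binary
    one-hot indicators.
    """

    row_ids: list[str]
    feature_names: list[str]
    matrix: np.ndarray
    labels: list[str]
    column_kinds: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, m = self.matrix.shape
        if len(self.row_ids) != n or len(self.labels) != n:
            raise ValueError("row_ids/labels length does not match matrix rows")
        if len(self.feature_names) != m or len(self.column_kinds) != m:
            raise ValueError("feature_names/column_kinds do not match matrix columns")
        if len(set(self.feature_names)) != m:
            raise ValueError("feature_names must be unique")
        onehot = [
            j
            for j, k in enumerate(self.column_kinds)
            if k in (KIND_GENE, KIND_PATHWAY)
        ]
        if onehot:
            block = self.matrix[:, onehot]
            if not np.isin(block, (0.0, 1.0)).all():
                raise ValueError("gene/pathway columns must be binary 0/1")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def y(self) -> np.ndarray:
        """Binary class vector: selected → 1, random → 0."""
        if any(lab == LABEL_UNLABELED for lab in self.labels):
            raise ValueError("table contains unlabeled rows")
        return np.array([1 if lab == LABEL_SELECTED else 0 for lab in self.labels])

    def select_columns(self, indices: list[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            row_ids=list(self.row_ids),
            feature_names=[self.feature_names[j] for j in idx],
            matrix=self.matrix[:, idx].copy(),
            labels=list(self.labels),
            column_kinds=[self.column_kinds[j] for j in idx],
        )

    def select_rows(self, indices) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            row_ids=[self.row_ids[i] for i in idx],
            feature_names=list(self.feature_names),
            matrix=self.matrix[idx, :].copy(),
            labels=[self.labels[i] for i in idx],
            column_kinds=list(self.column_kinds),
        )

    def is_binary_column(self, j: int) -> bool:
        vals = np.unique(self.matrix[:, j])
        return bool(np.isin(vals, (0.0, 1.0)).all())
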