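"""Assemble the one-hot feature table from descriptors and filtered annotations.

Target genes are kept only when their prediction score reaches 97 (the
boundary is inclusive: scores of 97–100 pass); pathways only when their
enrichment p-value is strictly below 0.05.  The surviving annotations become
binary indicator columns appended after the sequence-descriptor block.  In
validation mode the column vocabulary is frozen from training so matrices
always align by name; annotations unseen at training time are dropped, and
miRNAs already used for training are excluded from validation cohorts.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import (
    KIND_GENE,
    KIND_PATHWAY,
    AnnotationSet,
    FeatureTable,
    MiRNARecord,
)
from .formats_io import GENE_PREFIX, PATHWAY_PREFIX
from .seq_descriptors import descriptor_block

logger = logging.getLogger(__name__)

SCORE_MIN_DEFAULT = 97.0
P_MAX_DEFAULT = 0.05


def filter_annotations(
    ann: AnnotationSet,
    score_min: float = SCORE_MIN_DEFAULT,
    p_max: float = P_MAX_DEFAULT,
) -> AnnotationSet:
    """Apply the confidence filters: score ≥ ``score_min``, p < ``p_max``.

    Order is preserved; the input is not mutated.
    """
    return AnnotationSet(
        targets=[t for t in ann.targets if t.score >= score_min],
        pathways=[p for p in ann.pathways if p.p_value < p_max],
    )


def build_table(
    cohort: list[MiRNARecord],
    ann: AnnotationSet,
    vocab: tuple[list[str], list[str]] | None = None,
) -> FeatureTable:
    """One row per miRNA: descriptor block, then gene one-hots, then pathways.

    When ``vocab`` (``(genes, pathway_ids)``) is absent, the vocabulary is the
    sorted union of post-filter annotations over the cohort, excluding genes
    and pathways attached to no cohort member.  When present (validation
    mode) the columns match it exactly and unseen annotations are dropped.
    Annotations referencing ids outside the cohort are ignored with a logged
    warning.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    ids = [r.mirna_id for r in cohort]
    id_set = set(ids)
    stray = {t.mirna_id for t in ann.targets if t.mirna_id not in id_set} | {
        p.mirna_id for p in ann.pathways if p.mirna_id not in id_set
    }
    if stray:
        logger.warning(
            "ignoring annotations for %d id(s) not in cohort (e.g. %s)",
            len(stray),
            sorted(stray)[0],
        )

    gene_sets = {i: set() for i in ids}
    for t in ann.targets:
        if t.mirna_id in id_set:
            gene_sets[t.mirna_id].add(t.gene)
    pathway_sets = {i: set() for i in ids}
    for p in ann.pathways:
        if p.mirna_id in id_set:
            pathway_sets[p.mirna_id].add(p.pathway_id)

    if vocab is None:
        genes = sorted(set().union(*gene_sets.values()))
        pathways = sorted(set().union(*pathway_sets.values()))
    else:
        genes, pathways = list(vocab[0]), list(vocab[1])

    desc_mat, desc_names, desc_kinds = descriptor_block(cohort)
    gene_mat = np.array(
        [[1.0 if g in gene_sets[i] else 0.0 for g in genes] for i in ids]
    ).reshape(len(ids), len(genes))
    pw_mat = np.array(
        [[1.0 if p in pathway_sets[i] else 0.0 for p in pathways] for i in ids]
    ).reshape(len(ids), len(pathways))

    return FeatureTable(
        row_ids=ids,
        feature_names=desc_names
        + [GENE_PREFIX + g for g in genes]
        + [PATHWAY_PREFIX + p for p in pathways],
        matrix=np.hstack([desc_mat, gene_mat, pw_mat]),
        labels=[r.label for r in cohort],
        column_kinds=desc_kinds + [KIND_GENE] * len(genes) + [KIND_PATHWAY] * len(pathways),
    )


def vocabulary_of(table: FeatureTable) -> tuple[list[str], list[str]]:
    """Recover the (genes, pathways) vocabulary from a built table."""
    genes = [
        n[len(GENE_PREFIX):]
        for n, k in zip(table.feature_names, table.column_kinds)
        if k == KIND_GENE
    ]
    pathways = [
        n[len(PATHWAY_PREFIX):]
        for n, k in zip(table.feature_names, table.column_kinds)
        if k == KIND_PATHWAY
    ]
    return genes, pathways


def exclude_overlap(
    validation: list[MiRNARecord], training_ids: set[str] | list[str]
) -> list[MiRNARecord]:
    """Drop validation miRNAs that were already used for training."""
    training_ids = set(training_ids)
    kept = [r for r in validation if r.mirna_id not in training_ids]
    removed = len(validation) - len(kept)
    if removed:
        logger.info("excluded %d validation miRNA(s) overlapping training", removed)
    return kept
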