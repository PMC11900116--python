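"""Synthetic labeled miRNA cohorts with class-conditional structure.

Because curated disease-associated miRNA panels are not redistributable, the
pipeline is exercised on generated cohorts that mimic the shape of the real
study design: 44 disease-associated ("selected") and 44 control ("random")
mature miRNAs of 18–25 nt, a gene-target table with prediction scores, and a
pathway table with enrichment p-values.

Class signal enters through three channels, each with a per-class carriage
probability:

* marker genes — selected miRNAs are annotated with each marker gene with
  probability ``p_marker_pos`` (default 0.9) versus ``p_marker_neg`` (0.1)
  for controls; scores are drawn uniformly over [90, 100] so the score ≥ 97
  confidence filter removes a real fraction of annotations.
* marker pathways — same carriage mechanism; marker p-values are drawn over
  [0.001, 0.06] (mostly passing the p < 0.05 filter) and background pathway
  p-values over [0.03, 0.5] (mostly failing it).
* sequence motifs — each biased tetramer is implanted at a random position
  with a per-class probability, on top of uniform random sequence.

Background genes and pathways are annotated class-independently and carry no
signal.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    LABEL_RANDOM,
    LABEL_SELECTED,
    AnnotationSet,
    MiRNARecord,
    PathwayRecord,
    TargetRecord,
)

BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of a generated cohort."""

    n_selected: int = 44
    n_random: int = 44
    seq_len_range: tuple[int, int] = (18, 25)
    marker_genes: int = 5
    background_genes: int = 40
    marker_pathways: int = 2
    background_pathways: int = 10
    p_marker_pos: float = 0.9
    p_marker_neg: float = 0.1
    p_background: float = 0.3
    motif_bias: tuple[tuple[str, float, float], ...] = (
        ("AACA", 0.9, 0.1),
        ("UCGU", 0.85, 0.15),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_selected < 1 or self.n_random < 1:
            raise ValueError("both classes need at least one miRNA")
        lo, hi = self.seq_len_range
        if not (4 <= lo <= hi):
            raise ValueError(f"bad sequence length range {self.seq_len_range}")
        for p in (self.p_marker_pos, self.p_marker_neg, self.p_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for motif, p_pos, p_neg in self.motif_bias:
            if len(motif) != 4 or set(motif) - set("ACGU"):
                raise ValueError(f"bad biased motif {motif!r}")
            if not (0.0 <= p_pos <= 1.0 and 0.0 <= p_neg <= 1.0):
                raise ValueError(f"bad motif probabilities for {motif!r}")

    @property
    def marker_gene_names(self) -> list[str]:
        return [f"MG{i + 1:03d}" for i in range(self.marker_genes)]

    @property
    def background_gene_names(self) -> list[str]:
        return [f"BG{i + 1:03d}" for i in range(self.background_genes)]

    @property
    def marker_pathway_ids(self) -> list[str]:
        return [f"hsa9{i + 1:04d}" for i in range(self.marker_pathways)]

    @property
    def background_pathway_ids(self) -> list[str]:
        return [f"hsa8{i + 1:04d}" for i in range(self.background_pathways)]


def _draw_sequence(rng: np.random.Generator, cfg: SyntheticConfig, positive: bool) -> str:
    lo, hi = cfg.seq_len_range
    length = int(rng.integers(lo, hi + 1))
    seq = rng.choice(BASES, size=length)
    for motif, p_pos, p_neg in cfg.motif_bias:
        if rng.random() < (p_pos if positive else p_neg):
            pos = int(rng.integers(0, length - 3))
            seq[pos : pos + 4] = list(motif)
    return "".join(seq)


def _annotate(
    rng: np.random.Generator, cfg: SyntheticConfig, records: list[MiRNARecord]
) -> AnnotationSet:
    targets: list[TargetRecord] = []
    pathways: list[PathwayRecord] = []
    for rec in records:
        positive = rec.label == LABEL_SELECTED
        p_marker = cfg.p_marker_pos if positive else cfg.p_marker_neg
        for gene in cfg.marker_gene_names:
            if rng.random() < p_marker:
                targets.append(
                    TargetRecord(rec.mirna_id, gene, float(rng.uniform(90.0, 100.0)))
                )
        for gene in cfg.background_gene_names:
            if rng.random() < cfg.p_background:
                targets.append(
                    TargetRecord(rec.mirna_id, gene, float(rng.uniform(90.0, 100.0)))
                )
        for pw in cfg.marker_pathway_ids:
            if rng.random() < p_marker:
                pathways.append(
                    PathwayRecord(rec.mirna_id, pw, float(rng.uniform(0.001, 0.06)))
                )
        for pw in cfg.background_pathway_ids:
            if rng.random() < cfg.p_background:
                pathways.append(
                    PathwayRecord(rec.mirna_id, pw, float(rng.uniform(0.03, 0.5)))
                )
    return AnnotationSet(targets=targets, pathways=pathways)


def _make_records(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    n_selected: int,
    n_random: int,
    prefix: str,
) -> list[MiRNARecord]:
    labels = [LABEL_SELECTED] * n_selected + [LABEL_RANDOM] * n_random
    return [
        MiRNARecord(
            mirna_id=f"{prefix}-{i + 1:04d}",
            sequence=_draw_sequence(rng, cfg, lab == LABEL_SELECTED),
            label=lab,
        )
        for i, lab in enumerate(labels)
    ]


def generate_cohort(cfg: SyntheticConfig) -> tuple[list[MiRNARecord], AnnotationSet]:
    """Generate the training cohort and its annotation tables."""
    rng = np.random.default_rng(cfg.seed)
    records = _make_records(rng, cfg, cfg.n_selected, cfg.n_random, "syn-mir")
    return records, _annotate(rng, cfg, records)


def generate_validation(
    cfg: SyntheticConfig, training_ids: set[str] | list[str], n: int = 18
) -> tuple[list[MiRNARecord], AnnotationSet]:
    """Generate an independent validation cohort of ``n`` fresh miRNAs.

    Ids are disjoint from ``training_ids`` by construction; classes are
    balanced (ceil/floor split) so threshold-free metrics remain defined.
    The class-conditional mechanism is identical to training.
    """
    rng = np.random.default_rng(cfg.seed + 7919)  # distinct stream per cohort
    n_sel = (n + 1) // 2
    records = _make_records(rng, cfg, n_sel, n - n_sel, "syn-val")
    taken = set(training_ids)
    clash = [r.mirna_id for r in records if r.mirna_id in taken]
    if clash:  # only possible if a caller reuses the "syn-val" prefix
        raise ValueError(f"validation ids collide with training: {clash[:3]}")
    return records, _annotate(rng, cfg, records)
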