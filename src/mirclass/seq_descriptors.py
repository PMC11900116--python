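"""Per-miRNA sequence descriptors.

For each mature miRNA the pipeline computes length, mononucleotide
composition, GC fraction, a hydrogen-bond count, the mean residue mass, and a
binary presence flag for every tetramer over {A, C, G, U}.  All descriptors
are functions of sequence composition and substring content only; no
secondary structure is predicted.

Conventions (the literature names these features without fixing formulas):

* hydrogen-bond count — each base contributes its Watson–Crick pairing
  capacity: A and U count 2, G and C count 3, so
  ``hbonds = 2·(nA + nU) + 3·(nG + nC)``.
* mean mass — the average internal-residue mass of the ribonucleotide
  monophosphates, using A=329.21, C=305.18, G=345.21, U=306.17 Da.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .core import RNA_ALPHABET, KIND_DESCRIPTOR, MiRNARecord

#: internal residue masses (Da) of ribonucleotide monophosphates
RESIDUE_MASS = {"A": 329.21, "C": 305.18, "G": 345.21, "U": 306.17}

#: hydrogen bonds contributed by each base in a Watson–Crick pair
HBONDS_PER_BASE = {"A": 2, "U": 2, "G": 3, "C": 3}

#: all 256 tetramers over {A,C,G,U}, lexicographically sorted
TETRAMERS: tuple[str, ...] = tuple(
    "".join(p) for p in product(sorted(RNA_ALPHABET), repeat=4)
)

NUMERIC_DESCRIPTOR_NAMES = (
    "len",
    "frac_A",
    "frac_C",
    "frac_G",
    "frac_U",
    "gc",
    "hbonds",
    "mean_mass",
)

#: stable column order of the full descriptor block
DESCRIPTOR_NAMES: tuple[str, ...] = NUMERIC_DESCRIPTOR_NAMES + tuple(
    f"motif_{t}" for t in TETRAMERS
)


def motif_present(sequence: str, motif: str) -> int:
    """1 iff ``motif`` (a tetramer) occurs as a contiguous substring.

    Overlapping occurrences count the same as a single one — the feature is
    presence, not a count.
    """
    if len(motif) != 4:
        raise ValueError(f"motif must have length 4, got {motif!r}")
    if set(motif) - RNA_ALPHABET:
        raise ValueError(f"motif {motif!r} contains non-ACGU characters")
    return 1 if motif in sequence else 0


@dataclass(frozen=True)
class DescriptorVector:
    """Computed descriptors for one miRNA sequence."""

    length: int
    frac_A: float
    frac_C: float
    frac_G: float
    frac_U: float
    gc_fraction: float
    hbond_count: int
    mean_mass: float
    motif_presence: dict[str, int]

    def as_row(self) -> np.ndarray:
        """Values in :data:`DESCRIPTOR_NAMES` order."""
        head = [
            self.length,
            self.frac_A,
            self.frac_C,
            self.frac_G,
            self.frac_U,
            self.gc_fraction,
            self.hbond_count,
            self.mean_mass,
        ]
        return np.array(head + [self.motif_presence[t] for t in TETRAMERS])


def compute_descriptors(record: MiRNARecord) -> DescriptorVector:
    """Compute the full descriptor vector for one miRNA.

    Sequences shorter than 4 nt get an all-zero motif block rather than an
    error.  Deterministic and pure.
    """
    seq = record.sequence
    n = len(seq)
    counts = {b: seq.count(b) for b in "ACGU"}
    hbonds = sum(HBONDS_PER_BASE[b] * c for b, c in counts.items())
    mean_mass = sum(RESIDUE_MASS[b] * c for b, c in counts.items()) / n
    if n >= 4:
        motifs = {t: motif_present(seq, t) for t in TETRAMERS}
    else:
        motifs = {t: 0 for t in TETRAMERS}
    return DescriptorVector(
        length=n,
        frac_A=counts["A"] / n,
        frac_C=counts["C"] / n,
        frac_G=counts["G"] / n,
        frac_U=counts["U"] / n,
        gc_fraction=(counts["G"] + counts["C"]) / n,
        hbond_count=hbonds,
        mean_mass=mean_mass,
        motif_presence=motifs,
    )


def descriptor_block(cohort: list[MiRNARecord]) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack descriptor rows for a cohort.

    Returns ``(matrix, names, kinds)`` with one row per record; every column
    is tagged ``descriptor``.
    """
    rows = [compute_descriptors(r).as_row() for r in cohort]
    names = list(DESCRIPTOR_NAMES)
    return np.vstack(rows), names, [KIND_DESCRIPTOR] * len(names)
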