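"""Bundled reference dataset: a published case-control study of the
MTHFR C677T (rs1801133) and A1298C (rs1801131) polymorphisms in 97
locally advanced rectal-cancer patients and 119 healthy controls
(Serbian cohort), with the patients further split into responders
(Mandard TRG 1-2, n=30) and non-responders (TRG 3-5, n=65) to
neoadjuvant chemoradiotherapy, and by sex.

All tables are genotype counts as published; the haplotype counts are
the study's own printed chromosome counts (kept separate because they
are not derivable from — and not fully consistent with — the genotype
grids; see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_data import (
    MTHFR_A1298C,
    MTHFR_C677T,
    GenotypeCounts,
    TwoLocusCounts,
)

__all__ = ["MthfrRectalCohort", "load_mthfr_rectal_cohort"]

_LOCI = {loc.name: loc for loc in (MTHFR_C677T, MTHFR_A1298C)}

# genotype counts (hom-ref, het, hom-alt) per locus and group
_GENOTYPE_COUNTS = {
    "MTHFR C677T": {
        "patients": (50, 44, 3),
        "controls": (38, 67, 14),
        "responders": (13, 15, 2),
        "non-responders": (35, 29, 1),
        "male patients": (34, 31, 2),
        "male controls": (22, 35, 10),
        "female patients": (16, 13, 1),
        "female controls": (16, 32, 4),
    },
    "MTHFR A1298C": {
        "patients": (54, 39, 4),
        "controls": (45, 64, 10),
        "responders": (17, 13, 0),
        "non-responders": (36, 25, 4),
        "male patients": (39, 24, 4),
        "male controls": (28, 35, 4),
        "female patients": (15, 15, 0),
        "female controls": (17, 29, 6),
    },
}

# joint 3x3 genotype grids, rows = C677T (CC, CT, TT), cols = A1298C (AA, AC, CC)
_TWO_LOCUS = {
    "patients": [[24, 24, 2], [29, 13, 2], [1, 2, 0]],
    "controls": [[15, 19, 4], [23, 39, 5], [7, 6, 1]],
    "responders": [[7, 6, 0], [10, 5, 0], [0, 2, 0]],
    "non-responders": [[16, 17, 2], [19, 8, 2], [1, 0, 0]],
}

# published per-chromosome haplotype counts (CA, CC, TA, TC)
_HAPLOTYPE_COUNTS = {
    "patients": (90, 41, 47, 17),
    "controls": (95, 67, 75, 51),
}


@dataclass(frozen=True)
class MthfrRectalCohort:
    """Accessor over the bundled count tables."""

    def genotype_counts(self, locus_name: str, group: str) -> GenotypeCounts:
        """Single-locus genotype counts for one group.

        Groups: ``patients``, ``controls``, ``responders``,
        ``non-responders``, and the sex-specific
        ``male/female patients/controls``.
        """
        locus = _LOCI[locus_name]
        counts = _GENOTYPE_COUNTS[locus_name][group]
        return GenotypeCounts(locus, *counts)

    def two_locus_counts(self, group: str) -> TwoLocusCounts:
        """Joint 3x3 genotype grid for one group."""
        return TwoLocusCounts(
            MTHFR_C677T, MTHFR_A1298C, np.array(_TWO_LOCUS[group])
        )

    def haplotype_counts(self, group: str) -> np.ndarray:
        """The study's printed haplotype chromosome counts (CA, CC, TA, TC)."""
        return np.array(_HAPLOTYPE_COUNTS[group], dtype=float)

    @property
    def genotype_groups(self) -> tuple:
        return tuple(_GENOTYPE_COUNTS["MTHFR C677T"])

    @property
    def two_locus_groups(self) -> tuple:
        return tuple(_TWO_LOCUS)


def load_mthfr_rectal_cohort() -> MthfrRectalCohort:
    """Load the bundled rectal-cancer case-control count tables."""
    return MthfrRectalCohort()
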