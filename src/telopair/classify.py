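"""Read-pair classification into F1/F2/F3/F4 and the boundary count F2a.

The categories are keyed to which mate is a *complete* telomere read and to
the literal repeat the complete mate carries:

* **F1** — both mates complete (pair wholly inside a telomere).
* **F2** — exactly one mate complete, reading CCCTAA.  These arise at the
  telomere/subtelomere boundary (F2a) and on one side of an interstitial
  telomeric repeat (F2b); the two are sequence-identical.
* **F4** — exactly one mate complete, reading TTAGGG.  A chromosome does
  not continue beyond its telomere, so F4 pairs can only come from the far
  side of an ITR — which is why ``F2a = F2 − F4`` cancels ITR
  contamination (each ITR produces an F2b and an F4 boundary on average).
* **F3** — neither mate complete.

A read is complete when at least 90% of its loci match the repeat, or when
its (λ, z) cell lies inside the error profile mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

from .error_profile import (
    ErrorProfile,
    find_mismatching_loci,
    summarize_read,
)
from .telbam import (
    CSTRAND_HEXAMER,
    GSTRAND_HEXAMER,
    SequencingRead,
    TelbamHandle,
    iter_read_pairs,
)

logger = logging.getLogger(__name__)

#: Fraction of loci that must match the repeat for a read to be complete.
#: Thresholds above 0.90 are reported to decrease accuracy.
DEFAULT_COMPLETENESS = 0.90

ORIENT_G = "G-strand"
ORIENT_C = "C-strand"
ORIENT_NONE = "none"


@dataclass
class ReadStats:
    """Cached per-read profile used by both tallying and classification."""

    z: int
    lam: Optional[int]
    frac_telomere: float
    orientation: str


@dataclass
class ReadPairCounts:
    """Per-sample tallies of the four pair categories."""

    f1: int = 0
    f2: int = 0
    f3: int = 0
    f4: int = 0
    sample_id: str = ""

    @property
    def f2a(self) -> int:
        """Boundary pair count, F2 − F4 clamped at zero."""
        raw = self.f2 - self.f4
        if raw < 0:
            logger.warning(
                "sample %s: F4 (%d) exceeds F2 (%d); clamping F2a to 0",
                self.sample_id,
                self.f4,
                self.f2,
            )
            return 0
        return raw

    @property
    def total(self) -> int:
        return self.f1 + self.f2 + self.f3 + self.f4


def read_orientation(sequence: str) -> str:
    """Dominant repeat orientation by non-overlapping hexamer counts."""
    g = sequence.count(GSTRAND_HEXAMER)
    c = sequence.count(CSTRAND_HEXAMER)
    if g > c:
        return ORIENT_G
    if c > g:
        return ORIENT_C
    return ORIENT_NONE


def compute_read_stats(read: SequencingRead, p_min: int) -> ReadStats:
    """Profile one read: mismatch count, λ, telomere fraction, orientation."""
    orientation = read_orientation(read.sequence)
    unit = CSTRAND_HEXAMER if orientation == ORIENT_C else GSTRAND_HEXAMER
    mv = find_mismatching_loci(read, unit=unit)
    z = mv.z
    L = len(read) or 1
    lam = summarize_read(mv, read.phred, p_min).lam if z >= 1 else None
    return ReadStats(z=z, lam=lam, frac_telomere=(L - z) / L, orientation=orientation)


def is_fully_telomeric(
    read_or_stats,
    E: Optional[ErrorProfile],
    p_min: int = 0,
    completeness: float = DEFAULT_COMPLETENESS,
) -> Tuple[bool, str]:
    """Decide completeness: ≥ 90% repeat, or (λ, z) inside the error mask."""
    stats = (
        read_or_stats
        if isinstance(read_or_stats, ReadStats)
        else compute_read_stats(read_or_stats, p_min)
    )
    complete = stats.frac_telomere >= completeness
    if not complete and E is not None and stats.z >= 1 and stats.lam is not None:
        complete = E.contains(stats.lam, stats.z)
    return complete, stats.orientation


def classify_pair(
    r1,
    r2,
    E: Optional[ErrorProfile] = None,
    p_min: int = 0,
    completeness: float = DEFAULT_COMPLETENESS,
) -> str:
    """Assign a mate pair to F1/F2/F3/F4.

    Accepts either ``SequencingRead`` or precomputed ``ReadStats``.  A pair
    whose single complete read has tied repeat content is unresolvable and
    falls back to F3.
    """
    c1, o1 = is_fully_telomeric(r1, E, p_min, completeness)
    c2, o2 = is_fully_telomeric(r2, E, p_min, completeness)
    if c1 and c2:
        return "F1"
    if c1 or c2:
        orientation = o1 if c1 else o2
        if orientation == ORIENT_C:
            return "F2"
        if orientation == ORIENT_G:
            return "F4"
        logger.info("complete read with tied repeat orientation; classified F3")
        return "F3"
    return "F3"


def count_pairs(
    telbam,
    E: Optional[ErrorProfile] = None,
    p_min: int = 0,
    completeness: float = DEFAULT_COMPLETENESS,
    sample_id: str = "",
    pairs: Optional[Iterable[Tuple]] = None,
) -> ReadPairCounts:
    """Tally every pair of a TELBAM into the four categories.

    ``pairs`` may supply an in-memory iterable of mate tuples (reads or
    stats) to avoid re-reading the file.
    """
    if pairs is None:
        path = telbam.path if isinstance(telbam, TelbamHandle) else telbam
        pairs = iter_read_pairs(path)
        if not sample_id:
            import os

            sample_id = os.path.basename(str(path)).split(".")[0]
    counts = ReadPairCounts(sample_id=sample_id)
    for r1, r2 in pairs:
        category = classify_pair(r1, r2, E, p_min, completeness)
        setattr(counts, category.lower(), getattr(counts, category.lower()) + 1)
    return counts
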