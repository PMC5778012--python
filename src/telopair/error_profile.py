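"""Sequencing-error profiling for telomeric reads.

Telomeres are near-perfect tandem repeats, so every read can be compared
against a hypothetical infinite repeat to find its *mismatching loci* —
positions that diverge from the repeat through biology or sequencing error.
Genuine sequencing errors concentrate at low Phred scores, which this
module exploits: it tallies the joint distribution of (mean Phred at
mismatches, number of mismatches) over all reads (matrix ``X``), builds the
same tally with the mismatch positions replaced by random loci (matrix
``Y``), and thresholds the excess ``D = X − Y`` into a binary error mask
``E``.  Reads whose (λ, z) cell falls inside ``E`` are treated downstream
as complete telomere sequence suffering from sequencing error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .telbam import CSTRAND_HEXAMER, GSTRAND_HEXAMER, SequencingRead

logger = logging.getLogger(__name__)

#: Minimum length at which a non-repeat segment is phase-aligned rather
#: than marked wholesale.
MIN_ALIGNED_SEGMENT = 4


@dataclass
class MismatchVector:
    """Binary divergence indicator over the read's loci."""

    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.int8)

    @property
    def z(self) -> int:
        return int(self.m.sum())


@dataclass
class MismatchSummary:
    """Mismatch count ``z`` and offset mean Phred at mismatches ``lam``."""

    z: int
    lam: int


@dataclass
class ErrorProfile:
    """Binary mask over (Phred − P_min, mismatch count) cells."""

    E: np.ndarray
    k: int
    p_min: int
    p_max: int

    def contains(self, lam: int, z: int) -> bool:
        if 0 <= lam < self.E.shape[0] and 0 <= z < self.E.shape[1]:
            return bool(self.E[lam, z])
        return False


def dominant_unit(sequence: str) -> str:
    """Repeat unit (TTAGGG or CCCTAA) the read is compared against.

    Ties go to TTAGGG; orientation-sensitive decisions are made later, in
    classification, where ties are treated as unresolved.
    """
    g = sequence.count(GSTRAND_HEXAMER)
    c = sequence.count(CSTRAND_HEXAMER)
    return CSTRAND_HEXAMER if c > g else GSTRAND_HEXAMER


def _phase_runs(seq: str, unit: str) -> List[Tuple[int, int]]:
    """Greedy left-to-right maximal runs matching the tandem repeat.

    A run is a maximal substring consistent with the infinite repeat of
    ``unit`` under a single phase offset (partial hexamers at either end
    included).  Positions matching no phase (e.g. C within TTAGGG) separate
    runs.
    """
    L = len(seq)
    k = len(unit)
    runs: List[Tuple[int, int]] = []
    i = 0
    while i < L:
        best = 0
        for o in range(k):
            j = i
            while j < L and seq[j] == unit[(j - i + o) % k]:
                j += 1
            if j - i > best:
                best = j - i
                if best == L - i:
                    break
        if best == 0:
            i += 1
        else:
            runs.append((i, i + best))
            i += best
    return runs


def _align_segment(
    seq: str, phred: np.ndarray, start: int, end: int, unit: str
) -> List[int]:
    """Best-of-all-phase-offsets Hamming alignment of a non-repeat segment.

    Returns the mismatching loci under the lowest-Hamming-distance offset;
    ties are broken by the lowest mean Phred over the mismatching loci.
    """
    k = len(unit)
    best: Optional[List[int]] = None
    best_key: Tuple[float, float] = (np.inf, np.inf)
    for o in range(k):
        mism = [i for i in range(start, end) if seq[i] != unit[(i - start + o) % k]]
        mean_phred = float(np.mean(phred[mism])) if mism else 0.0
        key = (len(mism), mean_phred)
        if key < best_key:
            best_key = key
            best = mism
    return best if best is not None else []


def find_mismatching_loci(read: SequencingRead, unit: Optional[str] = None) -> MismatchVector:
    """Locate loci diverging from the telomere repeat by fragmentary alignment.

    The read is decomposed into maximal repeat-phase runs.  Chains of
    directly adjacent runs containing at least one complete hexamer are
    telomeric: their loci match, except that each internal phase break (a
    deletion/insertion event) contributes one mismatch at the lower-Phred
    of the two junction loci.  Remaining intervals of length ≥ 4 are
    Hamming-aligned against every phase offset of the repeat (lowest
    distance wins, ties broken by lowest mean Phred at mismatches); shorter
    intervals are marked mismatching wholesale.  N bases never match.
    """
    seq = read.sequence
    phred = read.phred
    L = len(seq)
    if unit is None:
        unit = dominant_unit(seq)
    m = np.ones(L, dtype=np.int8)
    if L < len(unit):
        return MismatchVector(m)

    # fast path: the read is a pure substring of the infinite repeat
    if seq in unit * (L // len(unit) + 2):
        return MismatchVector(np.zeros(L, dtype=np.int8))

    runs = _phase_runs(seq, unit)
    qualifies = [seq.find(unit, s, e) != -1 for s, e in runs]

    # chain directly adjacent runs; a chain is telomeric if any member
    # contains a complete hexamer
    covered = np.zeros(L, dtype=bool)
    idx = 0
    while idx < len(runs):
        j = idx
        while j + 1 < len(runs) and runs[j][1] == runs[j + 1][0]:
            j += 1
        if any(qualifies[idx : j + 1]):
            start, end = runs[idx][0], runs[j][1]
            covered[start:end] = True
            m[start:end] = 0
            for t in range(idx, j):  # internal junctions: indel events
                junction = runs[t][1]
                left, right = junction - 1, junction
                locus = left if phred[left] <= phred[right] else right
                m[locus] = 1
        idx = j + 1

    # residual non-telomeric intervals
    i = 0
    while i < L:
        if covered[i]:
            i += 1
            continue
        j = i
        while j < L and not covered[j]:
            j += 1
        if j - i >= MIN_ALIGNED_SEGMENT:
            m[i:j] = 0
            mism = _align_segment(seq, phred, i, j, unit)
            if mism:
                m[mism] = 1
        # intervals shorter than MIN_ALIGNED_SEGMENT stay marked
        i = j
    return MismatchVector(m)


def summarize_read(
    m: MismatchVector, phred: Sequence[int], p_min: int
) -> MismatchSummary:
    """Collapse a mismatch vector to (z, λ).

    λ is the floored mean Phred over mismatching loci, shifted down by the
    global minimum observed Phred so it indexes matrix rows from zero.
    Reads with z = 0 have no defined λ and must not enter the tallies.
    """
    mv = np.asarray(m.m, dtype=np.int64)
    z = int(mv.sum())
    if z == 0:
        raise ValueError("read has no mismatching loci; excluded from X and Y")
    phred = np.asarray(phred, dtype=np.int64)
    lam = int(np.floor(float((mv * phred).sum()) / z)) - p_min
    return MismatchSummary(z=z, lam=lam)


def random_loci_summary(
    z: int, phred: Sequence[int], p_min: int, rng: np.random.Generator
) -> MismatchSummary:
    """(z, μ) at z uniformly-sampled distinct loci of the same read."""
    phred = np.asarray(phred, dtype=np.int64)
    loci = rng.choice(len(phred), size=z, replace=False)
    mu = int(np.floor(float(phred[loci].sum()) / z)) - p_min
    return MismatchSummary(z=z, lam=mu)


def build_joint_matrices(
    reads: Iterable[SequencingRead],
    seed: int = 0,
    p_min: Optional[int] = None,
    p_max: Optional[int] = None,
    read_length: Optional[int] = None,
    summaries: Optional[Sequence[Tuple[int, int, np.ndarray]]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Tally X (observed λ, z) and Y (random-loci μ, z) over a read set.

    Rows index Phred − P_min in [0, P_max − P_min]; columns index the
    mismatch count z in [0, L] (the z = L column exists so fully divergent
    reads are representable).  Reads with z = 0 contribute to neither
    matrix, hence ΣX = ΣY = number of reads with z ≥ 1.

    ``summaries`` may carry precomputed ``(z, lam, phred)`` triples (z ≥ 1
    only) to avoid re-deriving mismatch vectors.
    """
    rng = np.random.default_rng(seed)
    if summaries is None:
        reads = list(reads)
        if p_min is None or p_max is None:
            all_phred = np.concatenate([r.phred for r in reads]) if reads else np.array([0])
            p_min = int(all_phred.min()) if p_min is None else p_min
            p_max = int(all_phred.max()) if p_max is None else p_max
        if read_length is None:
            read_length = max((len(r) for r in reads), default=0)
        summaries = []
        for r in reads:
            mv = find_mismatching_loci(r)
            if mv.z >= 1:
                s = summarize_read(mv, r.phred, p_min)
                summaries.append((s.z, s.lam, r.phred))
    else:
        if p_min is None or p_max is None or read_length is None:
            raise ValueError("p_min, p_max and read_length required with summaries")

    p = p_max - p_min
    X = np.zeros((p + 1, read_length + 1), dtype=np.int64)
    Y = np.zeros_like(X)
    for z, lam, phred in summaries:
        X[lam, z] += 1
        mu = random_loci_summary(z, phred, p_min, rng).lam
        Y[mu, z] += 1
    return X, Y


def build_error_mask(X: np.ndarray, Y: np.ndarray) -> ErrorProfile:
    """Threshold the excess D = X − Y into the binary error mask E.

    The threshold ``k`` is the maximum of D over the high-Phred, high-z
    quadrant (rows p/2 < i ≤ p, columns L/2 < j ≤ L), a region where no
    genuine error signal is expected.  The raw mask ``d > k`` is then
    refined: only 4-connected components touching the low-Phred rows
    (0..⌊p/4⌋) survive, isolated single cells are dropped, and finally all
    low-Phred cells up to the rightmost masked low-Phred column with any
    positive excess are filled in.
    """
    X = np.asarray(X)
    Y = np.asarray(Y)
    if X.shape != Y.shape:
        raise ValueError(f"matrix shapes differ: {X.shape} vs {Y.shape}")
    D = X - Y
    p = D.shape[0] - 1
    L = D.shape[1] - 1
    quadrant = D[p // 2 + 1 :, L // 2 + 1 :]
    k = int(quadrant.max()) if quadrant.size else 0

    E = D > k

    # noise removal: keep 4-connected components anchored at low Phred
    r0 = p // 4
    labels, n_components = ndimage.label(E)
    if n_components:
        anchored = np.unique(labels[: r0 + 1][labels[: r0 + 1] > 0])
        sizes = np.bincount(labels.ravel())
        keep = [lab for lab in anchored if sizes[lab] >= 2]
        E = np.isin(labels, keep)

    # low-Phred capture: fill every positive-excess cell in the low-Phred
    # rows left of (and including) the rightmost column already masked there
    low_cols = np.nonzero(E[: r0 + 1].any(axis=0))[0]
    if low_cols.size:
        jmax = int(low_cols.max())
        fill = np.zeros_like(E)
        fill[: r0 + 1, : jmax + 1] = D[: r0 + 1, : jmax + 1] > 0
        E = E | fill

    p_min = 0  # offsets are relative; caller re-attaches absolute values
    return ErrorProfile(E=E.astype(bool), k=k, p_min=p_min, p_max=p)


def write_profile_tables(
    directory: str,
    X: np.ndarray,
    Y: np.ndarray,
    E: np.ndarray,
    heatmap: bool = False,
) -> None:
    """Write X, Y, D and E as TSV (and optionally a heatmap) diagnostics."""
    import os

    os.makedirs(directory, exist_ok=True)
    D = np.asarray(X) - np.asarray(Y)
    for name, mat in (("X", X), ("Y", Y), ("D", D), ("E", np.asarray(E, dtype=int))):
        np.savetxt(os.path.join(directory, f"{name}.tsv"), mat, fmt="%d", delimiter="\t")
    if heatmap:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:  # diagnostics only
            logger.warning("matplotlib unavailable; skipping heatmap")
            return
        fig, axes = plt.subplots(1, 4, figsize=(16, 4))
        for ax, (name, mat) in zip(
            axes, (("X", X), ("Y", Y), ("D", D), ("E", np.asarray(E, dtype=int)))
        ):
            ax.imshow(mat, aspect="auto", origin="lower", interpolation="nearest")
            ax.set_title(name)
            ax.set_xlabel("mismatch count z")
            ax.set_ylabel("Phred − P_min")
        fig.tight_layout()
        fig.savefig(os.path.join(directory, "profile.png"), dpi=120)
        plt.close(fig)
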