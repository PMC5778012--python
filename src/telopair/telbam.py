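"""TELBAM extraction and insert-size estimation.

A TELBAM is the subset of a paired-end BAM containing every read pair in
which at least one mate carries two or more telomeric hexamer occurrences
(TTAGGG on either strand).  All downstream length estimation operates on
this subset, so extraction is deliberately permissive: orientation and
mapping position are ignored here and resolved during classification.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Tuple

import numpy as np
import pysam
from scipy.stats.mstats import winsorize

logger = logging.getLogger(__name__)

GSTRAND_HEXAMER = "TTAGGG"
CSTRAND_HEXAMER = "CCCTAA"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequencingRead:
    """One read of a pair: sequence, Phred vector and pair linkage."""

    sequence: str
    phred: np.ndarray
    reversed_flag: bool = False
    query_name: str = ""
    mate: Optional["SequencingRead"] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.phred = np.asarray(self.phred, dtype=np.int64)
        if len(self.sequence) != len(self.phred):
            raise ValueError(
                f"sequence length {len(self.sequence)} != phred length "
                f"{len(self.phred)} for read {self.query_name!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TelbamHandle:
    """Pointer to an extracted TELBAM plus its basic metadata."""

    path: str
    pair_count: int
    read_length: int
    phred_offset: int = 33


@dataclass
class InsertSizeModel:
    """Normal model of the sequencing insert (outer fragment) length."""

    mean_insert: float
    sd_insert: float
    read_length: int
    n_observations: int

    def __post_init__(self) -> None:
        if self.sd_insert < 0:
            raise ValueError("sd_insert must be non-negative")


def hexamer_occurrences(sequence: str, hexamer: str = GSTRAND_HEXAMER) -> int:
    """Non-overlapping occurrence count of the hexamer on the better strand.

    Both the hexamer and its reverse complement are scanned independently;
    the larger of the two counts is returned, which makes capture
    orientation-agnostic.
    """
    return max(sequence.count(hexamer), sequence.count(reverse_complement(hexamer)))


def _is_usable(read: pysam.AlignedSegment) -> bool:
    return not (read.is_secondary or read.is_supplementary or read.is_qcfail)


def _to_sequencing_read(read: pysam.AlignedSegment) -> SequencingRead:
    quals = read.query_qualities
    phred = np.array(quals, dtype=np.int64) if quals is not None else np.zeros(
        len(read.query_sequence or ""), dtype=np.int64
    )
    return SequencingRead(
        sequence=read.query_sequence or "",
        phred=phred,
        reversed_flag=bool(read.is_reverse),
        query_name=read.query_name,
    )


def iter_read_pairs(path: str) -> Iterator[Tuple[SequencingRead, SequencingRead]]:
    """Yield mate pairs from a BAM/SAM, matched by query name in one pass."""
    with pysam.AlignmentFile(path, check_sq=False) as handle:
        pending: dict = {}
        for read in handle.fetch(until_eof=True):
            if not _is_usable(read):
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
            else:
                r1, r2 = _to_sequencing_read(mate), _to_sequencing_read(read)
                r1.mate, r2.mate = r2, r1
                yield r1, r2
        if pending:
            logger.warning("dropped %d unpaired reads at end of %s", len(pending), path)


def extract_telbam(
    bam_path: str,
    out_path: Optional[str] = None,
    hexamer: str = GSTRAND_HEXAMER,
    min_occurrences: int = 2,
) -> TelbamHandle:
    """Extract candidate telomeric read pairs into a TELBAM.

    A pair is retained when at least one mate contains ``min_occurrences``
    non-overlapping copies of ``hexamer`` or of its reverse complement.
    Both mates of a retained pair are written; the source file is not
    modified.  Secondary, supplementary and QC-fail records are ignored.
    """
    if out_path is None:
        base = bam_path
        for suffix in (".bam", ".sam"):
            if base.endswith(suffix):
                base = base[: -len(suffix)]
        out_path = base + ".telbam.bam"

    try:
        src = pysam.AlignmentFile(bam_path, check_sq=False)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read alignment file {bam_path!r}: {exc}") from exc

    header = src.header.to_dict()
    header.setdefault("PG", []).append(
        {
            "ID": "telopair-bam2telbam",
            "PN": "telopair",
            "CL": f"bam2telbam {bam_path} -o {out_path} --hexamer {hexamer}",
        }
    )

    pair_count = 0
    read_length = 0
    pending: dict = {}
    n_unpaired = 0
    with pysam.AlignmentFile(out_path, "wb", header=header) as out:
        for read in src.fetch(until_eof=True):
            if not _is_usable(read):
                continue
            if not read.is_paired:
                src.close()
                raise ValueError(
                    f"{bam_path!r} contains single-end read "
                    f"{read.query_name!r}; paired-end data required"
                )
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            seqs = (mate.query_sequence or "", read.query_sequence or "")
            if any(hexamer_occurrences(s, hexamer) >= min_occurrences for s in seqs):
                out.write(mate)
                out.write(read)
                pair_count += 1
                read_length = max(read_length, len(seqs[0]), len(seqs[1]))
        n_unpaired = len(pending)
    src.close()
    if n_unpaired:
        logger.warning("dropped %d reads without a recoverable mate", n_unpaired)
    return TelbamHandle(path=out_path, pair_count=pair_count, read_length=read_length)


def estimate_insert_size(
    path: str,
    override: Optional[Tuple[float, float]] = None,
    read_length: Optional[int] = None,
) -> InsertSizeModel:
    """Estimate the insert-length distribution from template-length fields.

    One observation is taken per properly-paired template (the positive
    TLEN).  Observations are winsorised at the empirical 1st/99th
    percentiles (by rank, so small samples are untouched) before taking the
    sample mean and standard deviation.  ``override=(mean, sd)`` bypasses
    estimation entirely and is recorded with ``n_observations = 0``.
    """
    observed_length = 0
    tlens: list[int] = []
    if os.path.exists(path):
        with pysam.AlignmentFile(path, check_sq=False) as handle:
            for read in handle.fetch(until_eof=True):
                if not _is_usable(read):
                    continue
                if read.query_sequence:
                    observed_length = max(observed_length, len(read.query_sequence))
                if read.is_proper_pair and read.template_length > 0:
                    tlens.append(read.template_length)

    L = read_length if read_length is not None else observed_length

    if override is not None:
        mean, sd = override
        return InsertSizeModel(float(mean), float(sd), L, 0)

    if not tlens:
        raise ValueError(
            f"no properly-paired template lengths in {path!r}; supply "
            "--insert-mean/--insert-sd to provide the insert model directly"
        )

    arr = np.abs(np.asarray(tlens, dtype=np.float64))
    arr = np.asarray(winsorize(arr, limits=[0.01, 0.01]))
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return InsertSizeModel(mean, sd, L, int(arr.size))
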