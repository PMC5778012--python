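"""Synthetic paired-end BAM generator with known telomere ground truth.

Every stage of the pipeline is testable without controlled-access WGS data
by generating samples whose telomere length, interstitial telomeric repeat
(ITR) content and error structure are known exactly.

Reference constructs:

* a *telomere* contig per chromosome end — CCCTAA repeats of the requested
  length followed by random subtelomere, so the repeat tract sits at the
  contig start and has exactly one boundary;
* an *ITR* contig per copy — a TTAGGG run embedded between random flanks,
  so the run has two boundaries by construction.

Reads are emitted with their **as-sequenced** base strings: the left mate
stores its reference slice, the right (reverse) mate stores the reverse
complement of its slice.  This reproduces the strand physics the F2/F4
distinction rests on — the complete mate of a true-telomere boundary pair
reads CCCTAA, while an ITR emits one CCCTAA-complete (F2b) and one
TTAGGG-complete (F4) boundary pair population.  Mapping coordinates and
template lengths are written correctly so insert-size estimation works,
but the pipeline never interprets positions.

The per-base quality model is two-level: most loci carry ``phred_high``, a
seeded random subset carries ``phred_low``, and a fraction
``low_phred_bias`` of injected errors is forced onto low-Phred loci.  This
reproduces the association between few mismatches and low Phred scores
that the error-profile stage is designed to detect.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .telbam import CSTRAND_HEXAMER, GSTRAND_HEXAMER, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Generative description of one synthetic sample."""

    tl_bp: int
    n_telomeres: int = 12
    subtelomere_bp: int = 600
    itr_list: List[Tuple[int, int]] = field(default_factory=list)
    coverage_x: float = 50.0
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 30.0
    error_rate: float = 0.01
    low_phred_bias: float = 0.9
    low_phred_fraction: float = 0.2
    indel_fraction: float = 0.1
    phred_high: int = 37
    phred_low: int = 11
    seed: int = 0
    sample_id: str = "sample"

    def validate(self) -> None:
        if self.n_telomeres < 0 or (self.n_telomeres > 0 and self.tl_bp <= 0):
            raise ValueError("tl_bp must be positive when telomeres are requested")
        if self.n_telomeres == 0 and not self.itr_list:
            raise ValueError("sample must contain at least one telomere or ITR")
        for length, copies in self.itr_list:
            if length <= 0 or copies <= 0:
                raise ValueError("ITR lengths and copy numbers must be positive")
        if self.subtelomere_bp <= 0 or self.read_length <= 0:
            raise ValueError("subtelomere_bp and read_length must be positive")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must lie in [0, 1)")
        for name in ("low_phred_bias", "low_phred_fraction", "indel_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean must be at least twice the read length")
        if self.insert_sd < 0 or self.coverage_x <= 0:
            raise ValueError("insert_sd must be ≥ 0 and coverage_x > 0")


@dataclass
class TruthRecord:
    """Ground-truth origin counts for every emitted pair."""

    sample_id: str
    tl_bp: int
    n_telomeres: int
    n_pairs: int = 0
    f1: int = 0
    f2a_boundary: int = 0
    itr_f2b: int = 0
    itr_f4: int = 0
    itr_f1: int = 0
    other: int = 0

    def as_dict(self) -> Dict:
        return asdict(self)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _repeat_tract(unit: str, length: int) -> str:
    return (unit * (length // len(unit) + 1))[:length]


def _inject_errors(
    seq: str,
    low: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> str:
    """Substitutions/indels at rate error_rate, biased onto low-Phred loci."""
    L = len(seq)
    n_err = rng.binomial(L, spec.error_rate)
    if n_err == 0:
        return seq
    bases = list(seq)
    for _ in range(n_err):
        if low.size and rng.random() < spec.low_phred_bias:
            i = int(rng.choice(low))
        else:
            i = int(rng.integers(L))
        if rng.random() < spec.indel_fraction:
            if rng.random() < 0.5:  # deletion: shift left, pad the tail
                del bases[i]
                bases.append(str(rng.choice(_BASES)))
            else:  # insertion: shift right, truncate
                bases.insert(i, str(rng.choice(_BASES)))
                bases.pop()
        else:
            current = bases[i]
            alternatives = [b for b in "ACGT" if b != current]
            bases[i] = str(rng.choice(alternatives))
    return "".join(bases)


def _make_pair(
    out: pysam.AlignmentFile,
    name: str,
    tid: int,
    start: int,
    insert: int,
    contig_seq: str,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> None:
    L = spec.read_length
    left_slice = contig_seq[start : start + L]
    right_slice = contig_seq[start + insert - L : start + insert]
    for is_read1, pos, raw in (
        (True, start, left_slice),
        (False, start + insert - L, reverse_complement(right_slice)),
    ):
        # two quality levels with small per-locus jitter: sequencers emit a
        # continuum of qualities, and a strictly 2-valued string would make
        # the (Phred, mismatch) histogram a degenerate lattice
        low = rng.random(L) < spec.low_phred_fraction
        phred = np.where(
            low,
            spec.phred_low + rng.integers(-2, 3, L),
            spec.phred_high + rng.integers(-3, 4, L),
        ).astype(np.int32)
        np.clip(phred, 2, 41, out=phred)
        low_idx = np.nonzero(low)[0]
        seq = _inject_errors(raw, low_idx, spec, rng) if spec.error_rate > 0 else raw
        a = pysam.AlignedSegment(out.header)
        a.query_name = name
        a.query_sequence = seq
        a.flag = 99 if is_read1 else 147
        a.reference_id = tid
        a.reference_start = pos
        a.mapping_quality = 60
        a.cigartuples = [(0, L)]
        a.next_reference_id = tid
        a.next_reference_start = (start + insert - L) if is_read1 else start
        a.template_length = insert if is_read1 else -insert
        a.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in phred)
        )
        out.write(a)


def generate_sample(
    spec: SyntheticSpec, out_path: str
) -> Tuple[str, TruthRecord]:
    """Write a synthetic paired-end BAM and return its ground truth.

    Fragment counts per contig give ``coverage_x`` read coverage; each
    fragment draws its insert from Normal(insert_mean, insert_sd)
    truncated below at twice the read length and starts uniformly over the
    contig.  The truth record tallies every pair by its generative origin
    (telomere-interior F1, telomere-boundary F2a, ITR-side F2b/F4, other).

    Per-contig random streams are derived from ``spec.seed`` and the
    contig name, so adding ITR contigs to a spec leaves the telomere-derived
    reads of its ITR-free twin byte-identical.
    """
    spec.validate()
    if out_path.endswith("/") or os.path.isdir(out_path):
        out_path = os.path.join(out_path, f"{spec.sample_id}.bam")
    os.makedirs(os.path.dirname(os.path.abspath(out_path)), exist_ok=True)

    L = spec.read_length
    flank = int(spec.insert_mean + 4.0 * max(spec.insert_sd, 1.0)) + 2 * L

    # (name, builder) pairs; sequences built lazily with per-contig streams
    contigs: List[Tuple[str, str, Tuple[int, int], str]] = []
    for t in range(spec.n_telomeres):
        name = f"tel{t}"
        crng = _contig_rng(spec.seed, name)
        seq = _repeat_tract(CSTRAND_HEXAMER, spec.tl_bp) + _random_sequence(
            crng, max(spec.subtelomere_bp, flank)
        )
        contigs.append((name, seq, (0, spec.tl_bp), "telomere"))
    for idx, (itr_len, copies) in enumerate(spec.itr_list):
        for c in range(copies):
            name = f"itr{idx}_{c}"
            crng = _contig_rng(spec.seed, name)
            seq = (
                _random_sequence(crng, flank)
                + _repeat_tract(GSTRAND_HEXAMER, itr_len)
                + _random_sequence(crng, flank)
            )
            contigs.append((name, seq, (flank, flank + itr_len), "itr"))

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq, _, _ in contigs],
        "PG": [{"ID": "telopair-simulate", "PN": "telopair"}],
    }

    truth = TruthRecord(
        sample_id=spec.sample_id, tl_bp=spec.tl_bp, n_telomeres=spec.n_telomeres
    )
    with pysam.AlignmentFile(out_path, "wb", header=header) as out:
        for tid, (name, seq, (a, b), kind) in enumerate(contigs):
            crng = _contig_rng(spec.seed, name + ":frags")
            n_frag = int(round(spec.coverage_x * len(seq) / (2.0 * L)))
            for f in range(n_frag):
                insert = max(2 * L, int(round(crng.normal(spec.insert_mean, spec.insert_sd))))
                if insert > len(seq):
                    continue
                start = int(crng.integers(0, len(seq) - insert + 1))
                left_in = a <= start and start + L <= b
                right_in = a <= start + insert - L and start + insert <= b
                if kind == "telomere":
                    if left_in and right_in:
                        truth.f1 += 1
                    elif left_in:
                        truth.f2a_boundary += 1
                    else:
                        truth.other += 1
                else:
                    if left_in and right_in:
                        truth.itr_f1 += 1
                    elif right_in:
                        truth.itr_f2b += 1
                    elif left_in:
                        truth.itr_f4 += 1
                    else:
                        truth.other += 1
                truth.n_pairs += 1
                # start/insert encoded in the name so tests can recover
                # per-read ground truth without re-reading the reference
                _make_pair(
                    out, f"{spec.sample_id}:{name}:{f}:{start}:{insert}",
                    tid, start, insert, seq, spec, crng,
                )

    with open(_truth_path(out_path), "w") as fh:
        json.dump(truth.as_dict(), fh, indent=1)
    return out_path, truth


def _contig_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, abs(hash_name(name)) % (2**31)])
    )


def hash_name(name: str) -> int:
    """Stable (non-salted) string hash for per-contig seed derivation."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31)
    return h


def _truth_path(bam_path: str) -> str:
    base = bam_path[:-4] if bam_path.endswith(".bam") else bam_path
    return base + ".truth.json"


def generate_cohort(
    specs: Sequence[SyntheticSpec], directory: str
) -> pd.DataFrame:
    """Generate a cohort of samples; return (and write) the truth manifest."""
    if not specs:
        raise ValueError("cohort requires at least one sample spec")
    ids = [s.sample_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids in cohort: {sorted(ids)}")
    os.makedirs(directory, exist_ok=True)
    rows = []
    for spec in specs:
        bam_path, truth = generate_sample(spec, os.path.join(directory, f"{spec.sample_id}.bam"))
        row = truth.as_dict()
        row["bam"] = bam_path
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(directory, "manifest.csv"), index=False)
    return manifest
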