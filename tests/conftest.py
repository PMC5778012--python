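"""Shared fixtures: tiny in-memory reads and small synthetic BAM samples."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from telopair import SequencingRead, SyntheticSpec, generate_sample


def make_read(sequence: str, phred=30, name: str = "r", reverse: bool = False) -> SequencingRead:
    if np.isscalar(phred):
        phred = np.full(len(sequence), phred, dtype=np.int64)
    return SequencingRead(
        sequence=sequence,
        phred=np.asarray(phred, dtype=np.int64),
        reversed_flag=reverse,
        query_name=name,
    )


def write_pairs_bam(path, pairs, contig_len: int = 100_000) -> str:
    """Write (seq1, seq2) tuples as proper mate pairs for extraction tests."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": "chr_synth", "LN": contig_len}],
    }
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for i, (s1, s2) in enumerate(pairs):
            for is_read1, seq in ((True, s1), (False, s2)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"pair{i}"
                a.query_sequence = seq
                a.flag = 99 if is_read1 else 147
                a.reference_id = 0
                a.reference_start = 1000 * i + (0 if is_read1 else 200)
                a.mapping_quality = 60
                a.cigartuples = [(0, len(seq))]
                a.next_reference_id = 0
                a.next_reference_start = 1000 * i + (200 if is_read1 else 0)
                a.template_length = 300 if is_read1 else -300
                a.query_qualities = [30] * len(seq)
                out.write(a)
    return path


@pytest.fixture(scope="session")
def telomere_sample(tmp_path_factory):
    """A clean 5 kb telomere sample at moderate coverage (no error)."""
    outdir = tmp_path_factory.mktemp("telsample")
    spec = SyntheticSpec(
        tl_bp=5000, n_telomeres=4, coverage_x=30, error_rate=0.0,
        seed=101, sample_id="clean5k",
    )
    bam, truth = generate_sample(spec, str(outdir / "clean5k.bam"))
    return spec, bam, truth


@pytest.fixture(scope="session")
def itr_only_sample(tmp_path_factory):
    """A sample with interstitial repeats and no telomere at all."""
    outdir = tmp_path_factory.mktemp("itrsample")
    spec = SyntheticSpec(
        tl_bp=0, n_telomeres=0, itr_list=[(400, 4)], coverage_x=40,
        error_rate=0.0, seed=202, sample_id="itronly",
    )
    bam, truth = generate_sample(spec, str(outdir / "itronly.bam"))
    return spec, bam, truth
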