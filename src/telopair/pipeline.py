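"""End-to-end orchestration: TELBAM → error profile → counts → length.

``profile_telbam`` performs the per-sample work (one pass computing every
read's mismatch profile, reused for both the joint matrices and pair
classification); ``run`` maps it over a cohort and fits the length model.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .classify import ReadPairCounts, compute_read_stats, count_pairs
from .cohort import DEFAULT_COHORT_WEIGHT, compute_psi
from .error_profile import ErrorProfile, build_error_mask, build_joint_matrices
from .length import TelomereLengthModel, TelomereLengthResults
from .telbam import InsertSizeModel, estimate_insert_size, iter_read_pairs

logger = logging.getLogger(__name__)


@dataclass
class SampleProfile:
    """Everything derived from one TELBAM before length estimation."""

    sample_id: str
    counts: ReadPairCounts
    X: np.ndarray
    Y: np.ndarray
    error_profile: ErrorProfile
    psi: float
    insert_model: InsertSizeModel
    p_min: int
    p_max: int
    read_length: int


def sample_id_from_path(path: str) -> str:
    name = os.path.basename(path)
    for suffix in (".telbam.bam", ".telbam", ".bam", ".sam"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def profile_telbam(
    path: str,
    seed: int = 0,
    insert_override: Optional[Tuple[float, float]] = None,
    completeness: float = 0.90,
    sample_id: Optional[str] = None,
) -> SampleProfile:
    """Profile one TELBAM: joint matrices, error mask, pair counts, ψ."""
    if sample_id is None:
        sample_id = sample_id_from_path(path)
    pairs = list(iter_read_pairs(path))
    reads = [r for pair in pairs for r in pair]

    if not reads:
        logger.warning("TELBAM %s holds no read pairs", path)
        X = np.zeros((1, 1), dtype=np.int64)
        profile = ErrorProfile(E=np.zeros((1, 1), dtype=bool), k=0, p_min=0, p_max=0)
        try:
            model = estimate_insert_size(path, override=insert_override)
        except ValueError:
            model = InsertSizeModel(0.0, 0.0, 0, 0)
        return SampleProfile(
            sample_id, ReadPairCounts(sample_id=sample_id), X, X.copy(),
            profile, 0.0, model, 0, 0, 0,
        )

    p_min = int(min(r.phred.min() for r in reads))
    p_max = int(max(r.phred.max() for r in reads))
    read_length = max(len(r) for r in reads)

    stats_pairs = [
        (compute_read_stats(r1, p_min), compute_read_stats(r2, p_min))
        for r1, r2 in pairs
    ]
    summaries = [
        (s.z, s.lam, r.phred)
        for pair, spair in zip(pairs, stats_pairs)
        for r, s in zip(pair, spair)
        if s.z >= 1
    ]
    X, Y = build_joint_matrices(
        [], seed=seed, p_min=p_min, p_max=p_max,
        read_length=read_length, summaries=summaries,
    )
    error_profile = build_error_mask(X, Y)
    counts = count_pairs(
        None, error_profile, p_min, completeness,
        sample_id=sample_id, pairs=stats_pairs,
    )
    psi = compute_psi(X)
    insert_model = estimate_insert_size(path, override=insert_override)
    return SampleProfile(
        sample_id, counts, X, Y, error_profile, psi, insert_model,
        p_min, p_max, read_length,
    )


def run(
    telbam_paths: Sequence[str],
    seed: int = 0,
    insert_override: Optional[Tuple[float, float]] = None,
    cohort_correction: bool = True,
    cohort_weight: float = DEFAULT_COHORT_WEIGHT,
    eq9_as_printed: bool = False,
    platforms: Optional[Sequence[str]] = None,
    n_sim: int = 10_000,
    completeness: float = 0.90,
) -> Tuple[TelomereLengthResults, List[SampleProfile]]:
    """Profile a cohort of TELBAMs and fit the length model."""
    profiles = [
        profile_telbam(
            p, seed=seed, insert_override=insert_override, completeness=completeness
        )
        for p in telbam_paths
    ]
    model = TelomereLengthModel(
        [p.counts for p in profiles],
        [p.insert_model for p in profiles],
        psi=[p.psi for p in profiles],
        platforms=platforms,
        cohort_correction=cohort_correction,
        cohort_weight=cohort_weight,
        eq9_as_printed=eq9_as_printed,
    )
    return model.fit(n_sim=n_sim, seed=seed), profiles
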