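"""Telomere length estimation from the F1:F2a ratio.

Boundary pairs (F2a) count telomeres — every telomere has exactly one
subtelomere boundary — while complete pairs (F1) count telomere *content*.
Their ratio therefore encodes mean telomere length independently of
ploidy.  The conversion is done generatively: fragments with the observed
insert-length distribution are placed uniformly over a model telomere of
trial length ``tl``, each fragment is scored F1 (wholly inside the
telomere) or F2a (telomere-proximal read complete, mate crossing the
boundary), and ``tl`` is solved by bisection so the simulated ratio
matches the observed one.

In the noiseless limit (sd_insert = 0, insert I, read length L) every
integer start position can be enumerated and the expected ratio has the
closed form (tl − I + 1)/(I − L), which serves as an independent oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ReadPairCounts
from .cohort import DEFAULT_COHORT_WEIGHT, CohortRecord, correct_theta
from .telbam import InsertSizeModel

logger = logging.getLogger(__name__)

DEFAULT_N_SIM = 10_000
DEFAULT_TOL_BP = 1.0
MAX_BISECTIONS = 60
MAX_BRACKET_EXPANSIONS = 60


@dataclass
class LengthEstimate:
    """A telomere length in bp with the inputs that produced it."""

    tl_bp: float
    f1: int
    f2a_used: float
    insert_model: InsertSizeModel
    n_sim: int
    seed: int
    platform: str = ""
    tl_bp_corrected: Optional[float] = None


def _draw_fragments(
    model: InsertSizeModel, n_sim: int, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Insert lengths (truncated below at 2L) and uniform placement draws."""
    rng = np.random.default_rng(seed)
    L = model.read_length
    lower = 2 * L
    if model.sd_insert == 0:
        inserts = np.full(n_sim, max(model.mean_insert, lower))
    else:
        a = (lower - model.mean_insert) / model.sd_insert
        inserts = stats.truncnorm.rvs(
            a, np.inf, loc=model.mean_insert, scale=model.sd_insert,
            size=n_sim, random_state=rng,
        )
    inserts = np.round(inserts).astype(np.int64)
    u = rng.random(n_sim)
    return inserts, u


def _score_ratio(
    tl: float, inserts: np.ndarray, u: np.ndarray, read_length: int
) -> float:
    """F1:F2a ratio for fragments placed on a telomere of length tl."""
    T = int(round(tl))
    if T <= read_length:
        return 0.0
    starts = np.floor(u * T).astype(np.int64)
    ends = starts + inserts
    n_f1 = int(np.count_nonzero(ends <= T))
    n_f2a = int(np.count_nonzero((starts + read_length <= T) & (ends > T)))
    if n_f2a == 0:
        warnings.warn(
            f"no simulated boundary fragments at tl={T}; increase n_sim "
            "or the trial length is far too large",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.inf
    return n_f1 / n_f2a


def simulate_expected_ratio(
    tl: float,
    model: InsertSizeModel,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
) -> float:
    """Monte-Carlo expected F1:F2a ratio for a telomere of length ``tl``.

    Fragments draw insert lengths from Normal(mean, sd) truncated below at
    twice the read length and start uniformly over the telomere, with
    ample subtelomere beyond the boundary.
    """
    if tl <= model.read_length:
        raise ValueError("tl must exceed the read length")
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    inserts, u = _draw_fragments(model, n_sim, seed)
    return _score_ratio(tl, inserts, u, model.read_length)


def estimate_length(
    counts,
    model: InsertSizeModel,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    tol: float = DEFAULT_TOL_BP,
    f2a_override: Optional[float] = None,
    platform: str = "",
) -> LengthEstimate:
    """Invert the fragment-placement simulation to a length in bp.

    ``counts`` is a :class:`~telopair.classify.ReadPairCounts` (or any
    object with ``f1``/``f2a``); ``f2a_override`` substitutes the
    cohort-corrected boundary count when available.  The same fragment
    draws are reused at every trial length (common random numbers), so the
    simulated ratio is monotone in ``tl`` and a fixed seed gives a
    bit-reproducible estimate.
    """
    f1 = int(counts.f1)
    f2a = float(f2a_override) if f2a_override is not None else float(counts.f2a)
    if f2a <= 0:
        raise ValueError("no boundary reads; cannot normalise telomere content")
    target = f1 / f2a

    inserts, u = _draw_fragments(model, n_sim, seed)
    L = model.read_length

    def g(tl: float) -> float:
        return _score_ratio(tl, inserts, u, L)

    lo = float(L + 1)
    if g(lo) >= target:
        if f1 == 0:
            warnings.warn(
                "F1 = 0: telomere shorter than the insert length; "
                "estimate is the degenerate lower bound",
                RuntimeWarning,
                stacklevel=2,
            )
        return LengthEstimate(lo, f1, f2a, model, n_sim, seed, platform)

    hi = max(2.0 * model.mean_insert, lo + 1.0)
    expansions = 0
    while g(hi) < target:
        hi *= 2.0
        expansions += 1
        if expansions > MAX_BRACKET_EXPANSIONS:
            raise RuntimeError(
                f"cannot bracket F1/F2a = {target:.3g} "
                f"(insert {model.mean_insert}±{model.sd_insert}, L={L}); "
                "the observed ratio is unattainably large"
            )

    for _ in range(MAX_BISECTIONS):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        if g(mid) < target:
            lo = mid
        else:
            hi = mid
    return LengthEstimate(0.5 * (lo + hi), f1, f2a, model, n_sim, seed, platform)


def batch_correct(
    estimates: Sequence[LengthEstimate],
    platform_labels: Optional[Sequence[str]] = None,
    reference: Optional[str] = None,
    offsets: Optional[Dict[str, float]] = None,
) -> List[LengthEstimate]:
    """Mean-match estimates across sequencing platforms.

    Platforms differ systematically in quality (estimates from one machine
    run shorter on average), so each non-reference group is shifted by the
    difference of group means.  The reference group is the alphabetically
    first label unless specified.  ``offsets`` may supply explicit
    per-platform shifts instead, for when only one platform is present.
    Within-group differences are preserved exactly.
    """
    estimates = list(estimates)
    if platform_labels is not None:
        if len(platform_labels) != len(estimates):
            raise ValueError("platform_labels must match estimates in length")
        estimates = [replace(e, platform=lab) for e, lab in zip(estimates, platform_labels)]

    labels = sorted({e.platform for e in estimates})
    if offsets is not None:
        return [
            replace(e, tl_bp_corrected=e.tl_bp + offsets.get(e.platform, 0.0))
            for e in estimates
        ]
    if len(labels) < 2:
        logger.info("single platform group; batch correction is a no-op")
        return [replace(e, tl_bp_corrected=e.tl_bp) for e in estimates]

    ref = reference if reference is not None else labels[0]
    means = {
        lab: float(np.mean([e.tl_bp for e in estimates if e.platform == lab]))
        for lab in labels
    }
    shifts = {lab: means[ref] - means[lab] for lab in labels}
    return [replace(e, tl_bp_corrected=e.tl_bp + shifts[e.platform]) for e in estimates]


RESULT_COLUMNS = [
    "sample", "F1", "F2", "F3", "F4", "F2a_raw", "F2a_corrected", "psi",
    "theta_obs", "theta_cor", "insert_mean", "insert_sd", "read_len",
    "tl_bp", "tl_bp_corrected", "seed",
]


class TelomereLengthModel:
    """Telomere length model over one or more samples' read-pair counts.

    Parameters
    ----------
    counts
        One :class:`ReadPairCounts` or a sequence of them (one per sample).
    insert_models
        A single :class:`InsertSizeModel` shared by all samples, or one per
        sample.
    psi
        Per-sample dispersion statistics of the error-profile matrix X,
        used to weight the cohort correction; defaults to 0 (full shrinkage
        to the cohort mean) when omitted.
    cohort_correction
        Shrink each sample's boundary fraction θ toward the cohort mean
        (applies only with ≥ 2 samples).
    """

    def __init__(
        self,
        counts,
        insert_models,
        psi: Optional[Sequence[float]] = None,
        platforms: Optional[Sequence[str]] = None,
        cohort_correction: bool = True,
        cohort_weight: float = DEFAULT_COHORT_WEIGHT,
        eq9_as_printed: bool = False,
    ) -> None:
        if isinstance(counts, ReadPairCounts):
            counts = [counts]
        self.counts: List[ReadPairCounts] = list(counts)
        n = len(self.counts)
        if isinstance(insert_models, InsertSizeModel):
            insert_models = [insert_models] * n
        self.insert_models: List[InsertSizeModel] = list(insert_models)
        if len(self.insert_models) != n:
            raise ValueError("need one insert model per sample (or one shared)")
        self.psi = list(psi) if psi is not None else [0.0] * n
        self.platforms = list(platforms) if platforms is not None else [""] * n
        self.cohort_correction = cohort_correction
        self.cohort_weight = cohort_weight
        self.eq9_as_printed = eq9_as_printed

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        insert_models,
        **kwargs,
    ) -> "TelomereLengthModel":
        """Build from a frame with columns sample, F1, F2, F3, F4 [, psi, platform]."""
        counts = [
            ReadPairCounts(
                f1=int(row["F1"]), f2=int(row["F2"]), f3=int(row["F3"]),
                f4=int(row["F4"]), sample_id=str(row["sample"]),
            )
            for _, row in frame.iterrows()
        ]
        if "psi" in frame.columns and "psi" not in kwargs:
            kwargs["psi"] = frame["psi"].astype(float).tolist()
        if "platform" in frame.columns and "platforms" not in kwargs:
            kwargs["platforms"] = frame["platform"].astype(str).tolist()
        return cls(counts, insert_models, **kwargs)

    @classmethod
    def from_telbams(
        cls,
        paths: Sequence[str],
        seed: int = 0,
        insert_override: Optional[Tuple[float, float]] = None,
        **kwargs,
    ) -> "TelomereLengthModel":
        """Run profiling + classification on TELBAM files, then build the model."""
        from .pipeline import profile_telbam

        counts, models, psis = [], [], []
        for path in paths:
            profile = profile_telbam(path, seed=seed, insert_override=insert_override)
            counts.append(profile.counts)
            models.append(profile.insert_model)
            psis.append(profile.psi)
        return cls(counts, models, psi=psis, **kwargs)

    def fit(
        self,
        n_sim: int = DEFAULT_N_SIM,
        seed: int = 0,
        tol: float = DEFAULT_TOL_BP,
    ) -> "TelomereLengthResults":
        """Estimate each sample's length; apply cohort and batch corrections."""
        records = [
            CohortRecord(sample_id=c.sample_id, f2=c.f2, f4=c.f4, psi=p)
            for c, p in zip(self.counts, self.psi)
        ]
        apply_cohort = self.cohort_correction and len(records) >= 2
        if apply_cohort:
            correct_theta(records, w=self.cohort_weight, eq9_as_printed=self.eq9_as_printed)
        else:
            for rec in records:
                rec.theta_cor = rec.theta_obs
                rec.f2a_adjusted = float(max(rec.f2 - rec.f4, 0))

        estimates: List[LengthEstimate] = []
        for counts, model, rec, platform in zip(
            self.counts, self.insert_models, records, self.platforms
        ):
            f2a_used = rec.f2a_adjusted if apply_cohort else None
            estimates.append(
                estimate_length(
                    counts, model, n_sim=n_sim, seed=seed, tol=tol,
                    f2a_override=f2a_used, platform=platform,
                )
            )
        estimates = batch_correct(estimates)
        return TelomereLengthResults(self, records, estimates, seed=seed)


class TelomereLengthResults:
    """Fitted per-sample telomere lengths with their diagnostics."""

    def __init__(
        self,
        model: TelomereLengthModel,
        records: List[CohortRecord],
        estimates: List[LengthEstimate],
        seed: int,
    ) -> None:
        self.model = model
        self.records = records
        self.estimates = estimates
        self.seed = seed

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for counts, rec, est in zip(self.model.counts, self.records, self.estimates):
            rows.append(
                {
                    "sample": counts.sample_id,
                    "F1": counts.f1, "F2": counts.f2, "F3": counts.f3, "F4": counts.f4,
                    "F2a_raw": counts.f2a,
                    "F2a_corrected": est.f2a_used,
                    "psi": rec.psi,
                    "theta_obs": rec.theta_obs,
                    "theta_cor": rec.theta_cor,
                    "insert_mean": est.insert_model.mean_insert,
                    "insert_sd": est.insert_model.sd_insert,
                    "read_len": est.insert_model.read_length,
                    "tl_bp": est.tl_bp,
                    "tl_bp_corrected": est.tl_bp_corrected,
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)

    def to_csv(self, path: str) -> None:
        """Write the per-sample results table (stable float formatting)."""
        self.frame.to_csv(path, index=False, float_format="%.6f")

    def summary(self) -> str:
        frame = self.frame
        lines = ["Telomere length estimates", "=" * 70]
        for _, row in frame.iterrows():
            lines.append(
                f"{row['sample']:<20s} tl = {row['tl_bp']:>10.1f} bp  "
                f"(F1={int(row['F1'])}, F2a={row['F2a_corrected']:.1f}, "
                f"insert {row['insert_mean']:.0f}±{row['insert_sd']:.0f})"
            )
        lines.append("=" * 70)
        lines.append(
            f"{len(frame)} sample(s); cohort correction "
            f"{'on' if self.model.cohort_correction and len(frame) > 1 else 'off'}; "
            f"seed {self.seed}"
        )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of per-sample estimates (corrected values hatched)."""
        import matplotlib.pyplot as plt

        frame = self.frame
        if ax is None:
            _, ax = plt.subplots(figsize=(max(4, 0.8 * len(frame)), 4))
        x = np.arange(len(frame))
        ax.bar(x, frame["tl_bp"], width=0.6, label="estimate")
        if frame["tl_bp_corrected"].notna().any() and not np.allclose(
            frame["tl_bp"], frame["tl_bp_corrected"]
        ):
            ax.bar(x, frame["tl_bp_corrected"], width=0.3, hatch="//",
                   alpha=0.7, label="platform-corrected")
            ax.legend()
        ax.set_xticks(x, frame["sample"], rotation=45, ha="right")
        ax.set_ylabel("telomere length (bp)")
        return ax

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TelomereLengthResults: {len(self.estimates)} sample(s)>"
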