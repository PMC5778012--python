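"""Cohort-wide shrinkage of the boundary-pair fraction θ = F2a/(F2+F4).

Boundary pairs are the rarest category, so a single sample's θ is noisy.
When several TELBAMs are processed together, each sample's θ is shrunk
toward the cohort mean θ_exp by a weight that reflects how informative the
sample's own error profile is: ψ, the variance-to-mean ratio of the
low-Phred region of the sample's X matrix.  A dispersed (information-rich)
X keeps θ close to the observed value; a flat X defers to the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_COHORT_WEIGHT = 3.0


@dataclass
class CohortRecord:
    """Per-sample quantities entering and leaving the correction."""

    sample_id: str
    f2: int
    f4: int
    psi: float
    theta_obs: float = field(init=False)
    theta_cor: Optional[float] = None
    f2a_adjusted: Optional[float] = None

    def __post_init__(self) -> None:
        denom = self.f2 + self.f4
        f2a = max(self.f2 - self.f4, 0)
        self.theta_obs = f2a / denom if denom > 0 else 0.0


def compute_psi(X: np.ndarray, p: Optional[int] = None, L: Optional[int] = None) -> float:
    """Variance-to-mean ratio of X over rows 1..⌊2p/5⌋ and columns 1..L.

    The mean and the population variance are taken over the same cells.
    A zero mean leaves ψ undefined; 0 is recorded, which downstream makes
    the correction defer fully to the cohort mean.
    """
    X = np.asarray(X)
    if p is None:
        p = X.shape[0] - 1
    if L is None:
        L = X.shape[1] - 1
    top = int(np.floor(0.4 * p))
    region = X[1 : top + 1, 1 : L + 1].astype(np.float64)
    if region.size == 0:
        logger.warning("empty ψ region (p=%d); recording ψ = 0", p)
        return 0.0
    mu = float(region.mean())
    if mu == 0.0:
        logger.warning("ψ undefined (μ = 0); recording ψ = 0, deferring to cohort mean")
        return 0.0
    sigma = float(((region - mu) ** 2).mean())
    return sigma / mu


def correct_theta(
    cohort: List[CohortRecord],
    w: float = DEFAULT_COHORT_WEIGHT,
    eq9_as_printed: bool = False,
) -> List[CohortRecord]:
    """Shrink each sample's θ toward the cohort mean, in place.

    The default combines θ_obs and θ_exp as the convex weighted mean
    (θ_obs·ψ + θ_exp·w)/(ψ + w), for which a cohort of identical θ is a
    fixed point and θ_cor always lies between θ_obs and θ_exp.
    ``eq9_as_printed=True`` instead divides by ψ·w, a strict transcription
    of the published formula (which lacks the fixed-point property).
    Single-sample cohorts are returned uncorrected.
    """
    if not cohort:
        raise ValueError("cohort must contain at least one sample")
    theta_exp = float(np.mean([rec.theta_obs for rec in cohort]))
    for rec in cohort:
        if len(cohort) == 1:
            logger.info("single-sample cohort; correction disabled")
            rec.theta_cor = rec.theta_obs
        elif eq9_as_printed:
            denom = rec.psi * w
            if denom == 0.0:
                logger.warning(
                    "sample %s: ψ·w = 0 under the as-printed rule; using θ_exp",
                    rec.sample_id,
                )
                rec.theta_cor = theta_exp
            else:
                rec.theta_cor = (rec.theta_obs * rec.psi + theta_exp * w) / denom
        else:
            rec.theta_cor = (rec.theta_obs * rec.psi + theta_exp * w) / (rec.psi + w)
        rec.f2a_adjusted = rec.theta_cor * (rec.f2 + rec.f4)
    return cohort
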