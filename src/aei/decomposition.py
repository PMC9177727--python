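"""Variance decomposition of net allelic expression into copy-number and
cis-regulatory components.

Because gamma = alpha - beta by construction, the cohort variance of the
net expression ratio obeys the exact identity

    Var(alpha) = Var(beta) + Var(gamma) + 2 Cov(beta, gamma)

and the share attributable to cis-regulation is
(Var(gamma) + Cov(beta, gamma)) / Var(alpha).  All quantities are computed
on MAP point estimates with the n-1 denominator; samples whose MAP is an
infinite sentinel (a zero read count on one allele) are excluded up front,
since their variance is undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from aei.inference import SampleProfile

logger = logging.getLogger(__name__)


class DecompositionError(ValueError):
    pass


@dataclass(frozen=True)
class DecompositionResult:
    var_alpha: float
    var_beta: float
    var_gamma: float
    cov_beta_gamma: float
    cis_contribution: float
    cn_contribution: float
    r_alpha_beta: float
    r_alpha_gamma: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _finite_pairs(beta_maps, gamma_maps) -> tuple[np.ndarray, np.ndarray]:
    beta = np.asarray(beta_maps, dtype=float)
    gamma = np.asarray(gamma_maps, dtype=float)
    if beta.shape != gamma.shape:
        raise DecompositionError("beta and gamma vectors must be paired")
    keep = np.isfinite(beta) & np.isfinite(gamma)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("excluding %d sample(s) with non-finite MAP from decomposition", dropped)
    return beta[keep], gamma[keep]


def variance_decomposition(beta_maps, gamma_maps) -> DecompositionResult:
    """Decompose Var(alpha) over a cohort of paired beta/gamma MAPs.

    ``alpha`` is reconstructed as beta + gamma, so the identity holds to
    machine precision by construction; the informative outputs are the
    component variances, their covariance, and the cis fraction.
    """
    beta, gamma = _finite_pairs(beta_maps, gamma_maps)
    n = beta.size
    if n < 3:
        raise DecompositionError(f"need >= 3 finite samples, got {n}")
    alpha = beta + gamma
    var_alpha = float(np.var(alpha, ddof=1))
    if var_alpha == 0.0:
        raise DecompositionError("zero variance in net allelic expression")
    var_beta = float(np.var(beta, ddof=1))
    var_gamma = float(np.var(gamma, ddof=1))
    cov_bg = float(np.cov(beta, gamma, ddof=1)[0, 1])
    cis = (var_gamma + cov_bg) / var_alpha
    cn = (var_beta + cov_bg) / var_alpha
    r_ab = float(stats.pearsonr(alpha, beta)[0]) if var_beta > 0 else float("nan")
    r_ag = float(stats.pearsonr(alpha, gamma)[0]) if var_gamma > 0 else float("nan")
    return DecompositionResult(
        var_alpha=var_alpha,
        var_beta=var_beta,
        var_gamma=var_gamma,
        cov_beta_gamma=cov_bg,
        cis_contribution=cis,
        cn_contribution=cn,
        r_alpha_beta=r_ab,
        r_alpha_gamma=r_ag,
        n=n,
    )


def correlations(alpha_maps, beta_maps, gamma_maps) -> tuple[float, float]:
    """Pearson correlations of net expression with copy number and with
    cis-regulation, on MAP values.

    Raises on a constant vector, where the correlation is undefined.
    """
    alpha = np.asarray(alpha_maps, dtype=float)
    beta = np.asarray(beta_maps, dtype=float)
    gamma = np.asarray(gamma_maps, dtype=float)
    keep = np.isfinite(alpha) & np.isfinite(beta) & np.isfinite(gamma)
    alpha, beta, gamma = alpha[keep], beta[keep], gamma[keep]
    if alpha.size < 3:
        raise DecompositionError(f"need >= 3 finite samples, got {alpha.size}")
    for name, v in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if np.var(v) == 0.0:
            raise DecompositionError(f"constant {name} vector: correlation undefined")
    r_ab = float(stats.pearsonr(alpha, beta)[0])
    r_ag = float(stats.pearsonr(alpha, gamma)[0])
    return r_ab, r_ag


# quadrant keys, in display order
Q_GAMMA_POS_BETA_NEG = "gamma_pos_beta_neg"
Q_GAMMA_POS_BETA_POS = "gamma_pos_beta_pos"
Q_GAMMA_NEG_BETA_NEG = "gamma_neg_beta_neg"
Q_GAMMA_NEG_BETA_POS = "gamma_neg_beta_pos"
Q_TIE = "tie"
Q_ALPHA_POS_BETA_NEG = "alpha_pos_beta_neg"


def quadrant_classification(profiles: list[SampleProfile]) -> dict[str, int]:
    """Count samples per beta/gamma sign quadrant.

    Each sample lands in exactly one quadrant; exact zeros go to a separate
    tie bucket.  The auxiliary count ``alpha_pos_beta_neg`` tallies tumors
    that overexpress the mutant allele despite it being in lower copy
    number.
    """
    counts = {
        Q_GAMMA_POS_BETA_NEG: 0,
        Q_GAMMA_POS_BETA_POS: 0,
        Q_GAMMA_NEG_BETA_NEG: 0,
        Q_GAMMA_NEG_BETA_POS: 0,
        Q_TIE: 0,
        Q_ALPHA_POS_BETA_NEG: 0,
    }
    for p in profiles:
        b, g, a = p.beta.map, p.gamma.map, p.alpha.map
        if b == 0.0 or g == 0.0:
            counts[Q_TIE] += 1
        elif g > 0 and b < 0:
            counts[Q_GAMMA_POS_BETA_NEG] += 1
        elif g > 0 and b > 0:
            counts[Q_GAMMA_POS_BETA_POS] += 1
        elif g < 0 and b < 0:
            counts[Q_GAMMA_NEG_BETA_NEG] += 1
        else:
            counts[Q_GAMMA_NEG_BETA_POS] += 1
        if a > 0 and b < 0:
            counts[Q_ALPHA_POS_BETA_NEG] += 1
    return counts
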