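"""Exact binomial test of mutant-allele preference among imbalanced tumors.

Among tumors whose cis-regulatory (gamma) ratio is significantly
imbalanced, are mutant-preferring tumors more common than chance?  With k
mutant-preferring out of n imbalanced, the null is Binomial(n, 1/2): the
two-sided P sums the probabilities of all outcomes no more likely than the
observed one (the minimum-likelihood method), and the interval is the
exact Clopper–Pearson interval at the 89% level used throughout the
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from scipy import stats

from aei.inference import SampleProfile

DEFAULT_LEVEL = 0.89


@dataclass(frozen=True)
class PrevalenceResult:
    k: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    level: float = DEFAULT_LEVEL

    def to_dict(self) -> dict:
        return asdict(self)


def mutant_preference_test(
    k: int, n: int, p0: float = 0.5, level: float = DEFAULT_LEVEL
) -> PrevalenceResult:
    """Exact two-sided binomial test of k successes in n trials against p0.

    Returns the point estimate k/n, the exact Clopper–Pearson CI at
    ``level``, and the minimum-likelihood two-sided P value.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    test = stats.binomtest(k, n, p0, alternative="two-sided")
    ci = test.proportion_ci(confidence_level=level, method="exact")
    return PrevalenceResult(
        k=k,
        n=n,
        estimate=k / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(test.pvalue),
        level=level,
    )


def prevalence_from_profiles(
    profiles: list[SampleProfile], level: float = DEFAULT_LEVEL
) -> PrevalenceResult:
    """Run the preference test on the gamma calls of a profiled cohort."""
    imbalanced = [p for p in profiles if p.gamma.call != "balanced"]
    k = sum(1 for p in imbalanced if p.gamma.call == "mutant")
    n = len(imbalanced)
    if n == 0:
        raise ValueError("no gamma-imbalanced samples in cohort")
    return mutant_preference_test(k, n, level=level)
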