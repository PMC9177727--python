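"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generators:

* :func:`simulate_cohort` — a tumor cohort with paired DNA/RNA allelic
  read counts.  Each tumor gets a true copy-number log-odds (beta0) and a
  true cis-regulatory log-odds (gamma0); DNA counts are Beta-Binomial
  around logistic(beta0) and RNA counts around logistic(beta0 + gamma0 *
  cellularity), so tumor cellularity attenuates the cis effect on the RNA
  side only.  Clinical marker labels and exponential survival times are
  linked to gamma0, letting the downstream association and survival
  stages be exercised against a known truth table.

* :func:`simulate_microarray` — a normal-tissue allelic-intensity panel:
  one unmeasured causal regulatory variant (rSNP) in incomplete LD with a
  measured variant, AE ratios shifted in heterozygotes that carry the
  regulatory allele, plus unlinked noise variants.

Defaults mirror the study conditions: 94 tumors (METABRIC-like missense
cohort), ~100x mean depth, and a 64-sample microarray panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from aei.ingest import AllelicCount, ClinicalRecord, Locus
from aei.dae import AEMatrix

#: PIK3CA-like locus used for simulated tumor mutations (hg19-era coords)
SIM_CHROM = "3"
SIM_POS = 178_936_091

LN2 = np.log(2.0)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generative parameters.

    Log-odds are in log2 units throughout, matching the alpha/beta/gamma
    scale.  ``rho`` is the Beta-Binomial overdispersion (0 = pure
    binomial); ``cellularity_range`` bounds the per-tumor fraction of
    tumor cells, which scales the cis effect seen in RNA.
    """

    n_samples: int = 94
    depth_dna: float = 100.0
    depth_rna: float = 100.0
    depth_dispersion: float = 5.0      # negative-binomial size parameter
    p_cn_imbalance: float = 0.5
    cn_logodds_sd: float = 0.8
    p_cis_effect: float = 0.3
    cis_logodds_mean: float = 1.0      # positive = mutant-preferring mass
    cis_logodds_sd: float = 0.5
    rho: float = 0.01
    cellularity_range: tuple[float, float] = (0.6, 1.0)
    clin_gamma_coef: float = 0.8       # log-odds of marker-negativity per log2 gamma
    baseline_hazard: float = 0.08      # events per year
    hr_gamma_mut: float = 2.5
    followup_years: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_cn_imbalance", "p_cis_effect"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must be in [0, 1]")
        if not 0 <= self.rho < 1:
            raise SimulationError("rho must be in [0, 1)")
        lo, hi = self.cellularity_range
        if not 0 <= lo <= hi <= 1:
            raise SimulationError("cellularity_range must be within [0, 1]")
        if self.n_samples < 1 or self.depth_dna <= 0 or self.depth_rna <= 0:
            raise SimulationError("infeasible cohort size or depth")


def _expit2(logodds: np.ndarray) -> np.ndarray:
    """Inverse of p -> log2(p/(1-p))."""
    return 1.0 / (1.0 + np.exp(-logodds * LN2))


def _betabinom_draw(rng, n: np.ndarray, p: np.ndarray, rho: float) -> np.ndarray:
    """Beta-Binomial counts with mean n*p and overdispersion rho."""
    if rho == 0.0:
        return rng.binomial(n, p)
    scale = (1.0 - rho) / rho
    q = rng.beta(np.clip(p * scale, 1e-9, None), np.clip((1.0 - p) * scale, 1e-9, None))
    return rng.binomial(n, q)


def _nb_depth(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial depths with the given mean; floor at 1 read."""
    p = dispersion / (dispersion + mean)
    return np.maximum(rng.negative_binomial(dispersion, p, size=size), 1)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[AllelicCount], pd.DataFrame, list[ClinicalRecord]]:
    """Generate one tumor cohort.

    Returns ``(counts, truth, clinical)``: interleaved DNA/RNA
    :class:`AllelicCount` records, a per-sample truth table (true beta0 /
    gamma0 / cellularity / depths), and clinical records with ER/PR/HER2
    labels and overall / disease-specific survival linked to gamma0.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    locus = Locus(SIM_CHROM, SIM_POS, "G")

    has_cn = rng.random(n) < config.p_cn_imbalance
    beta0 = np.where(has_cn, rng.normal(0.0, config.cn_logodds_sd, n), 0.0)
    has_cis = rng.random(n) < config.p_cis_effect
    gamma0 = np.where(
        has_cis, rng.normal(config.cis_logodds_mean, config.cis_logodds_sd, n), 0.0
    )
    lo, hi = config.cellularity_range
    cellularity = rng.uniform(lo, hi, n)

    p_dna = _expit2(beta0)
    p_rna = _expit2(beta0 + gamma0 * cellularity)
    depth_dna = _nb_depth(rng, config.depth_dna, config.depth_dispersion, n)
    depth_rna = _nb_depth(rng, config.depth_rna, config.depth_dispersion, n)
    mut_dna = _betabinom_draw(rng, depth_dna, p_dna, config.rho)
    mut_rna = _betabinom_draw(rng, depth_rna, p_rna, config.rho)

    counts: list[AllelicCount] = []
    for i, sid in enumerate(sample_ids):
        counts.append(AllelicCount(sid, locus, "DNA", int(depth_dna[i] - mut_dna[i]),
                                   int(mut_dna[i]), "missense"))
        counts.append(AllelicCount(sid, locus, "RNA", int(depth_rna[i] - mut_rna[i]),
                                   int(mut_rna[i]), "missense"))

    # clinical markers: gamma0 pushes toward ER-/PR-negative, HER2-positive
    def marker(base_logodds: float, sign: float) -> np.ndarray:
        lo_ = base_logodds + sign * config.clin_gamma_coef * gamma0
        return rng.random(n) < 1.0 / (1.0 + np.exp(-lo_))

    er_neg = marker(-1.4, +1.0)
    pr_neg = marker(-1.0, +1.0)
    her2_pos = marker(-1.8, +1.0)

    hazard = config.baseline_hazard * np.where(gamma0 > 0, config.hr_gamma_mut, 1.0)
    death_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, config.followup_years, n)
    os_time = np.minimum(death_time, censor_time)
    os_event = (death_time <= censor_time).astype(int)
    disease_death = rng.random(n) < 0.8  # fraction of deaths that are disease-specific
    dss_event = os_event * disease_death.astype(int)

    clinical = [
        ClinicalRecord(
            sample_id=sid,
            er_status="negative" if er_neg[i] else "positive",
            pr_status="negative" if pr_neg[i] else "positive",
            her2_status="positive" if her2_pos[i] else "negative",
            age=float(np.round(rng.normal(60, 10), 1)),
            size=float(np.round(np.abs(rng.normal(25, 10)) + 5, 1)),
            grade=int(rng.integers(1, 4)),
            os_time=float(os_time[i]),
            os_event=int(os_event[i]),
            dss_time=float(os_time[i]),
            dss_event=int(dss_event[i]),
        )
        for i, sid in enumerate(sample_ids)
    ]

    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "beta0": beta0,
        "gamma0": gamma0,
        "cellularity": cellularity,
        "depth_dna": depth_dna,
        "depth_rna": depth_rna,
        "p_dna": p_dna,
        "p_rna": p_rna,
        "cis_effect": has_cis,
        "cn_imbalance": has_cn,
    })
    return counts, truth, clinical


def _ld_haplotypes(rng, n: int, p_a: float, p_b: float, r2: float):
    """Draw n diploid genotype pairs for two loci at LD r = sqrt(r2).

    Returns (haps1, haps2): each an (n, 2) array of 0/1 alleles with
    haplotype phase preserved across the two loci.
    """
    if not 0 <= r2 <= 1:
        raise SimulationError("ld_r2 must be in [0, 1]")
    r = np.sqrt(r2)
    d = r * np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
    # haplotype frequencies for allele pairs (1,1), (1,0), (0,1), (0,0)
    f11 = p_a * p_b + d
    f10 = p_a * (1 - p_b) - d
    f01 = (1 - p_a) * p_b - d
    f00 = (1 - p_a) * (1 - p_b) + d
    freqs = np.array([f11, f10, f01, f00])
    if (freqs < -1e-12).any():
        raise SimulationError("requested LD infeasible for these allele frequencies")
    freqs = np.clip(freqs, 0, None)
    freqs /= freqs.sum()
    draws = rng.choice(4, size=(n, 2), p=freqs)
    alleles_a = (draws < 2).astype(int)       # locus 1 carries allele 1 for codes 0,1
    alleles_b = np.isin(draws, (0, 2)).astype(int)
    return alleles_a, alleles_b


def _genotype_labels(haps: np.ndarray) -> np.ndarray:
    g = haps.sum(axis=1)
    return np.array(["BB", "AB", "AA"])[g]


def simulate_microarray(
    n_variants: int = 12,
    n_samples: int = 64,
    daesnp_effect: float = 1.0,
    ld_r2: float = 0.5,
    seed: int = 0,
    maf: float = 0.3,
    noise_sd: float = 0.2,
) -> tuple[AEMatrix, dict]:
    """Generate a normal-tissue allelic-intensity panel with one planted
    regulatory signal.

    Variant ``v000`` is the measured daeSNP; the causal rSNP (genotyped
    but carrying no AE signal of its own measurement) sits 50 kb away at
    LD ``ld_r2`` with it.  Heterozygotes at the rSNP express the linked
    allele ``daesnp_effect`` log2 units higher; the phase with the daeSNP
    determines the sign observed at the daeSNP, so at high LD the AE
    distribution is unilateral.  Remaining variants are unlinked noise,
    one of them placed outside the ±250 kb mapping window.

    Returns ``(matrix, truth)`` with truth carrying the planted ids,
    effect, genotypes, and per-sample true AE shifts.
    """
    if n_variants < 3:
        raise SimulationError("need at least 3 variants (daeSNP, rSNP, noise)")
    rng = np.random.default_rng(seed)
    sample_ids = [f"N{i:03d}" for i in range(n_samples)]
    variant_ids = [f"v{i:03d}" for i in range(n_variants)]
    daesnp_id, rsnp_id = variant_ids[0], variant_ids[1]

    dae_haps, rsnp_haps = _ld_haplotypes(rng, n_samples, maf, maf, ld_r2)

    positions = {daesnp_id: 178_900_000, rsnp_id: 178_950_000}
    far_id = variant_ids[-1]
    for j, vid in enumerate(variant_ids[2:], start=2):
        positions[vid] = 178_900_000 + j * 20_000
    positions[far_id] = 178_900_000 + 260_000  # outside the ±250 kb window

    genotype = pd.DataFrame(index=variant_ids, columns=sample_ids, dtype=object)
    rna = pd.DataFrame(0.0, index=variant_ids, columns=sample_ids)
    dna = pd.DataFrame(0.0, index=variant_ids, columns=sample_ids)

    # true per-sample cis shift, driven by the rSNP haplotypes: each copy of
    # the regulatory allele (coded 1) boosts the cis-linked haplotype
    ae_shift = np.zeros(n_samples)
    rsnp_het = rsnp_haps.sum(axis=1) == 1
    dae_het = dae_haps.sum(axis=1) == 1
    for i in range(n_samples):
        if rsnp_het[i] and dae_het[i]:
            # sign: is the regulatory allele on the same haplotype as daeSNP allele A?
            same_phase = (rsnp_haps[i] == dae_haps[i]).all()
            ae_shift[i] = daesnp_effect if same_phase else -daesnp_effect

    hom_sep = 2.0  # homozygote log-ratio separation in both channels
    for row, haps in ((daesnp_id, dae_haps), (rsnp_id, rsnp_haps)):
        labels = _genotype_labels(haps)
        genotype.loc[row] = labels
        base = np.where(labels == "AA", hom_sep, np.where(labels == "BB", -hom_sep, 0.0))
        dna.loc[row] = base + rng.normal(0, 0.05, n_samples)
        shift = ae_shift if row == daesnp_id else 0.0
        rna.loc[row] = dna.loc[row] + shift + rng.normal(0, noise_sd, n_samples)

    for vid in variant_ids[2:]:
        haps, _ = _ld_haplotypes(rng, n_samples, maf, maf, 0.0)
        labels = _genotype_labels(haps)
        genotype.loc[vid] = labels
        base = np.where(labels == "AA", hom_sep, np.where(labels == "BB", -hom_sep, 0.0))
        dna.loc[vid] = base + rng.normal(0, 0.05, n_samples)
        rna.loc[vid] = dna.loc[vid] + rng.normal(0, noise_sd, n_samples)

    variants = pd.DataFrame({
        "variant_id": variant_ids,
        "chrom": SIM_CHROM,
        "pos": [positions[v] for v in variant_ids],
        "alleleA": "A",
        "alleleB": "C",
        "rna_mean_intensity": np.round(rng.normal(11.0, 0.4, n_variants), 3),
    }).set_index("variant_id")

    matrix = AEMatrix(
        rna_log_ratio=rna,
        dna_log_ratio=dna,
        genotype=genotype,
        rna_mean_intensity=variants["rna_mean_intensity"],
        variants=variants,
    )
    truth = {
        "daesnp_id": daesnp_id,
        "rsnp_id": rsnp_id,
        "far_variant_id": far_id,
        "effect": daesnp_effect,
        "ld_r2": ld_r2,
        "ae_shift": ae_shift,
        "rsnp_genotype": _genotype_labels(rsnp_haps),
        "daesnp_genotype": _genotype_labels(dae_haps),
    }
    return matrix, truth
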