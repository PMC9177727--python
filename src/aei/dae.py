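"""Differential allelic expression (DAE) analysis of normal-tissue
microarray data.

For each variant the two allelic intensity channels A and B give a log
ratio log2(A) - log2(B) in RNA and in DNA; the allelic-expression ratio

    AE = RNA log-ratio - DNA log-ratio

is defined only in heterozygous (AB) samples, where the DNA term
normalizes away allelic content differences.  A heterozygote displays DAE
when |AE| >= 0.58, i.e. at least a 1.5-fold difference between alleles
(log2(1.5) ~ 0.585).  A variant is a daeSNP when at least 10% of its
heterozygotes, and no fewer than three, display DAE.

Mapping then asks which nearby variants could be the causal regulatory
variant (rSNP): stratify the daeSNP's |AE| ratios by the genotype at each
candidate within ±250 kb and test, one-sided Mann–Whitney, whether
heterozygotes at the candidate have larger |AE| than the combined
homozygotes — the signature expected when the candidate is in incomplete
LD with the causal variant.  P values are BH-corrected per daeSNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: |AE| at or above this is a 1.5-fold or greater allelic difference
DAE_THRESHOLD = math.log2(1.5)

MIN_INTENSITY = 9.5
MIN_HET = 5
DAE_MIN_FRAC = 0.10
DAE_MIN_COUNT = 3
MAPPING_WINDOW = 250_000

HET = "AB"
HOMS = ("AA", "BB")


class DaeError(ValueError):
    pass


@dataclass
class AEMatrix:
    """Variant × sample allelic log-ratios with genotypes.

    ``rna_log_ratio`` and ``dna_log_ratio`` are DataFrames (variants as
    rows, samples as columns) of log2(A) - log2(B); ``genotype`` holds
    {AA, AB, BB, missing}; ``variants`` is the sidecar table with columns
    ``variant_id chrom pos alleleA alleleB`` indexed by variant_id.
    Allele A vs B is fixed by alphabetical ordering of the alleles.
    """

    rna_log_ratio: pd.DataFrame
    dna_log_ratio: pd.DataFrame
    genotype: pd.DataFrame
    rna_mean_intensity: pd.Series
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.rna_log_ratio.index, self.rna_log_ratio.columns
        for name, df in (("dna_log_ratio", self.dna_log_ratio), ("genotype", self.genotype)):
            if not (df.index.equals(idx) and df.columns.equals(cols)):
                raise DaeError(f"{name} is not aligned with rna_log_ratio")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.rna_log_ratio.index)

    def n_het(self, variant_id: str) -> int:
        return int((self.genotype.loc[variant_id] == HET).sum())

    def ae_ratios(self, variant_id: str) -> pd.Series:
        """AE ratio per heterozygous sample at ``variant_id``."""
        het = self.genotype.loc[variant_id] == HET
        ae = self.rna_log_ratio.loc[variant_id] - self.dna_log_ratio.loc[variant_id]
        return ae[het].dropna()

    @classmethod
    def from_tsv(cls, rna_path, dna_path, genotype_path, variants_path) -> "AEMatrix":
        rna = pd.read_csv(rna_path, sep="\t", index_col=0)
        dna = pd.read_csv(dna_path, sep="\t", index_col=0)
        geno = pd.read_csv(genotype_path, sep="\t", index_col=0)
        variants = pd.read_csv(variants_path, sep="\t", index_col="variant_id")
        # mean over samples of per-variant RNA intensity sidecar column, if present
        if "rna_mean_intensity" in variants.columns:
            intensity = variants["rna_mean_intensity"]
        else:
            raise DaeError("variants table must carry rna_mean_intensity")
        return cls(rna, dna, geno, intensity, variants)


@dataclass(frozen=True)
class DaeResult:
    variant_id: str
    n_het: int
    n_dae: int
    frac_dae: float
    is_daesnp: bool
    het_vs_hom_p: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MappingResult:
    dae_snp_id: str
    candidate_snp_id: str
    distance: int
    p_value: float
    q_value: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def filter_variants(matrix: AEMatrix) -> list[str]:
    """Variants informative for DAE analysis.

    Retained iff mean RNA log2 allelic intensity strictly exceeds 9.5 and
    the variant is heterozygous in at least five samples.
    """
    retained = []
    for vid in matrix.variant_ids:
        if matrix.rna_mean_intensity[vid] > MIN_INTENSITY and matrix.n_het(vid) >= MIN_HET:
            retained.append(vid)
    return retained


def het_vs_hom_test(rna_log_ratios, genotypes) -> float | None:
    """Two-sample t-test of RNA log ratios, heterozygotes vs homozygotes.

    A genuine allelic signal splits heterozygote ratios away from the
    homozygote cluster.  Returns the two-sided P, or None when either
    group has fewer than two samples (variant skipped).
    """
    ratios = np.asarray(rna_log_ratios, dtype=float)
    geno = np.asarray(genotypes, dtype=object)
    het = ratios[(geno == HET) & np.isfinite(ratios)]
    hom = ratios[np.isin(geno, HOMS) & np.isfinite(ratios)]
    if het.size < 2 or hom.size < 2:
        return None
    return float(stats.ttest_ind(het, hom, equal_var=True).pvalue)


def call_dae(
    ae_ratios, threshold: float = DAE_THRESHOLD, variant_id: str = "", het_vs_hom_p=None
) -> tuple[np.ndarray, DaeResult]:
    """Flag per-heterozygote DAE and classify the variant.

    A sample shows DAE when |AE| >= threshold (inclusive).  The variant is
    a daeSNP when the DAE fraction is at least 10% and at least three
    heterozygotes are flagged.
    """
    ae = np.asarray(ae_ratios, dtype=float)
    ae = ae[np.isfinite(ae)]
    if ae.size == 0:
        raise DaeError("no heterozygous samples: DAE undefined")
    flags = np.abs(ae) >= threshold
    n_het, n_dae = int(ae.size), int(flags.sum())
    frac = n_dae / n_het
    result = DaeResult(
        variant_id=variant_id,
        n_het=n_het,
        n_dae=n_dae,
        frac_dae=frac,
        is_daesnp=(frac >= DAE_MIN_FRAC and n_dae >= DAE_MIN_COUNT),
        het_vs_hom_p=het_vs_hom_p,
    )
    return flags, result


def _mannwhitney_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Mann–Whitney P(x stochastically greater than y).

    Exact enumeration for small tie-free groups, normal approximation with
    tie correction otherwise (scipy's auto policy).
    """
    return float(stats.mannwhitneyu(x, y, alternative="greater", method="auto").pvalue)


def dae_mapping(
    ae_matrix: AEMatrix,
    dae_snp: str,
    candidates: list[str] | None = None,
    window: int = MAPPING_WINDOW,
    bh_alpha: float = 0.05,
) -> list[MappingResult]:
    """Map candidate regulatory variants for one daeSNP.

    For every candidate within ±``window`` bp (inclusive) of the daeSNP,
    split the daeSNP's heterozygote |AE| ratios by candidate genotype and
    test het > combined homozygotes (one-sided Mann–Whitney).  Candidates
    with fewer than two samples in either group are skipped.  Q values are
    BH-adjusted across the candidates actually tested.
    """
    if dae_snp not in ae_matrix.variants.index:
        raise DaeError(f"unknown daeSNP {dae_snp!r}")
    pos0 = int(ae_matrix.variants.loc[dae_snp, "pos"])
    chrom0 = ae_matrix.variants.loc[dae_snp, "chrom"]
    ae = ae_matrix.ae_ratios(dae_snp).abs()

    if candidates is None:
        candidates = [v for v in ae_matrix.variant_ids if v != dae_snp]

    tested: list[MappingResult] = []
    for cand in candidates:
        if cand not in ae_matrix.variants.index:
            continue
        if ae_matrix.variants.loc[cand, "chrom"] != chrom0:
            continue
        dist = int(ae_matrix.variants.loc[cand, "pos"]) - pos0
        if abs(dist) > window:
            continue
        geno = ae_matrix.genotype.loc[cand, ae.index]
        het_vals = ae[geno == HET].to_numpy()
        hom_vals = ae[geno.isin(HOMS)].to_numpy()
        if het_vals.size < 2 or hom_vals.size < 2:
            continue
        p = _mannwhitney_greater(het_vals, hom_vals)
        tested.append(MappingResult(dae_snp, cand, dist, p))

    if not tested:
        return []
    _, qvals, _, _ = multipletests([r.p_value for r in tested], method="fdr_bh")
    return [
        MappingResult(r.dae_snp_id, r.candidate_snp_id, r.distance, r.p_value, float(q))
        for r, q in zip(tested, qvals)
    ]


def eqtl_test(expression, genotypes) -> float:
    """Rank-based test of total expression against genotype groups.

    Wilcoxon rank-sum for two genotype groups, Kruskal–Wallis for three.
    Groups with fewer than two samples are dropped; fewer than two usable
    groups is an error.
    """
    expr = np.asarray(expression, dtype=float)
    geno = np.asarray(genotypes, dtype=object)
    groups = []
    for g in pd.unique(geno):
        vals = expr[(geno == g) & np.isfinite(expr)]
        if vals.size >= 2:
            groups.append(vals)
    if len(groups) < 2:
        raise DaeError("need >= 2 genotype groups with >= 2 samples each")
    if len(groups) == 2:
        return float(stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided").pvalue)
    return float(stats.kruskal(*groups).pvalue)
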