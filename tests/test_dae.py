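import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from aei.dae import (
    AEMatrix,
    DaeError,
    DAE_THRESHOLD,
    filter_variants,
    het_vs_hom_test,
    call_dae,
    dae_mapping,
    eqtl_test,
)


def _panel(intensities, genotypes, rna=None, dna=None, positions=None):
    """Small AEMatrix builder for targeted scenarios."""
    variants = list(genotypes.keys())
    samples = [f"s{i}" for i in range(len(next(iter(genotypes.values()))))]
    geno = pd.DataFrame(genotypes, index=samples).T
    zero = pd.DataFrame(0.0, index=variants, columns=samples)
    rna_df = pd.DataFrame(rna, index=samples).T if rna else zero.copy()
    dna_df = pd.DataFrame(dna, index=samples).T if dna else zero.copy()
    vtab = pd.DataFrame({
        "variant_id": variants,
        "chrom": "3",
        "pos": [positions[v] if positions else 100 + i for i, v in enumerate(variants)],
        "alleleA": "A",
        "alleleB": "C",
        "rna_mean_intensity": [intensities[v] for v in variants],
    }).set_index("variant_id")
    return AEMatrix(rna_df, dna_df, geno, vtab["rna_mean_intensity"], vtab)


class TestFilterVariants:
    @pytest.mark.parametrize(
        "intensity,n_het,kept",
        [
            (10.2, 6, True),
            (9.5, 6, False),   # boundary: strictly greater than 9.5
            (11.0, 4, False),  # too few heterozygotes
            (9.6, 5, True),
        ],
    )
    def test_intensity_and_het_rule(self, intensity, n_het, kept):
        genotypes = {"v": ["AB"] * n_het + ["AA"] * (8 - n_het)}
        m = _panel({"v": intensity}, genotypes)
        assert (["v"] if kept else []) == filter_variants(m)


class TestHetVsHomTest:
    def test_identical_groups_fail(self):
        ratios = [0.4, 0.5, 0.6, 0.4, 0.5, 0.6]
        geno = ["AB", "AB", "AB", "AA", "AA", "BB"]
        p = het_vs_hom_test(ratios, geno)
        assert p == pytest.approx(1.0)  # equal group means carry no signal

    def test_matches_textbook_t_oracle(self):
        het = [1.2, 1.0, 1.4, -1.1, -1.3]
        hom = [0.0, 0.1, -0.1, 0.05]
        p = het_vs_hom_test(het + hom, ["AB"] * 5 + ["AA"] * 2 + ["BB"] * 2)
        # pooled-variance two-sample t computed from first principles
        x, y = np.array(het), np.array(hom)
        n1, n2 = len(x), len(y)
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        expected = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_single_hom_sample_skipped(self):
        p = het_vs_hom_test([1.0, 0.9, 0.2], ["AB", "AB", "AA"])
        assert p is None


class TestCallDae:
    def test_threshold_is_log2_of_1_5(self):
        assert DAE_THRESHOLD == pytest.approx(math.log2(1.5))
        assert round(DAE_THRESHOLD, 2) == 0.58

    def test_threshold_inclusive(self):
        flags, res = call_dae([DAE_THRESHOLD, 0.5, -DAE_THRESHOLD])
        assert flags.tolist() == [True, False, True]
        assert res.n_dae == 2

    def test_daesnp_rule_three_of_ten(self):
        ae = [0.9, 0.7, -0.8] + [0.0] * 7
        _, res = call_dae(ae, variant_id="v1")
        assert (res.n_het, res.n_dae) == (10, 3)
        assert res.is_daesnp  # 30% >= 10% and 3 >= 3

    def test_daesnp_rule_needs_ten_percent(self):
        ae = [0.9, 0.7, -0.8] + [0.0] * 37
        _, res = call_dae(ae)
        assert res.n_dae == 3 and not res.is_daesnp  # 7.5% < 10%

    def test_no_hets_is_error(self):
        with pytest.raises(DaeError):
            call_dae([])

    @given(
        ae=st.lists(st.floats(-2, 2, width=32), min_size=1, max_size=30),
        t1=st.floats(0.1, 1.0),
        t2=st.floats(0.1, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_threshold_monotone(self, ae, t1, t2):
        lo, hi = sorted((t1, t2))
        _, res_lo = call_dae(ae, threshold=lo)
        _, res_hi = call_dae(ae, threshold=hi)
        assert res_hi.n_dae <= res_lo.n_dae


def test_ae_ratio_antisymmetric_under_allele_swap():
    """Swapping alleles A and B flips the sign of the AE ratio."""
    rna = {"v": [1.2, -0.3, 0.8]}
    dna = {"v": [0.2, -0.1, 0.3]}
    geno = {"v": ["AB", "AB", "AB"]}
    m = _panel({"v": 11.0}, geno, rna=rna, dna=dna)
    ae = m.ae_ratios("v")
    m_swapped = _panel({"v": 11.0}, geno,
                       rna={"v": [-x for x in rna["v"]]},
                       dna={"v": [-x for x in dna["v"]]})
    ae_swapped = m_swapped.ae_ratios("v")
    assert np.allclose(ae.to_numpy(), -ae_swapped.to_numpy())


def exhaustive_mw_greater_p(x, y):
    """One-sided Mann-Whitney P by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b
    )
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for a in gx for b in gy if a > b) + 0.5 * sum(
            1 for a in gx for b in gy if a == b
        )
        total += 1
        if u >= u_obs - 1e-12:
            count += 1
    return count / total


class TestDaeMapping:
    def _mapping_panel(self, candidate_pos=150_000):
        # daeSNP with 6 hets; candidate genotype splits |AE| high (het) vs low (hom)
        geno = {
            "dae": ["AB"] * 6 + ["AA", "BB"],
            "cand": ["AB", "AB", "AB", "AA", "BB", "AA", "AA", "BB"],
        }
        ae = [0.9, 1.1, 1.0, 0.1, 0.2, 0.0, 0.0, 0.0]
        rna = {"dae": ae, "cand": [0.0] * 8}
        m = _panel({"dae": 11.0, "cand": 11.0}, geno, rna=rna,
                   positions={"dae": 100_000, "cand": candidate_pos})
        return m

    def test_complete_separation_matches_enumeration(self):
        m = self._mapping_panel()
        results = dae_mapping(m, "dae", ["cand"])
        assert len(results) == 1
        expected = exhaustive_mw_greater_p([0.9, 1.1, 1.0], [0.1, 0.2, 0.0])
        assert expected == pytest.approx(1 / 20)  # 1 / C(6,3)
        assert results[0].p_value == pytest.approx(expected, rel=1e-9)

    def test_identical_groups_p_about_half(self):
        from aei.dae import _mannwhitney_greater
        p = _mannwhitney_greater(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert p == pytest.approx(0.5, abs=0.11)

    def test_window_boundary_exclusive_beyond_250kb(self):
        inside = dae_mapping(self._mapping_panel(candidate_pos=350_000), "dae", ["cand"])
        assert len(inside) == 1  # 250,000 away: inclusive
        outside = dae_mapping(self._mapping_panel(candidate_pos=350_001), "dae", ["cand"])
        assert outside == []

    def test_bh_correction_properties(self, rng):
        pvals = rng.uniform(0.001, 1.0, 25)
        _, q, _, _ = multipletests(pvals, method="fdr_bh")
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()  # q monotone in rank of P
        bonf = np.minimum(pvals * len(pvals), 1.0)
        assert set(np.where(bonf <= 0.05)[0]) <= set(np.where(q <= 0.05)[0])


class TestEqtlTest:
    def test_identical_distributions(self, rng):
        expr = rng.normal(size=60)
        geno = np.repeat(["AA", "AB", "BB"], 20)
        assert eqtl_test(expr, geno) > 0.05

    def test_power_at_one_sd_shift(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            expr = np.concatenate([r.normal(0, 1, 30), r.normal(1, 1, 30)])
            geno = np.repeat(["AA", "AB"], 30)
            if eqtl_test(expr, geno) < 0.05:
                hits += 1
        assert hits >= 8

    def test_single_group_is_error(self):
        with pytest.raises(DaeError):
            eqtl_test([1.0, 2.0, 3.0], ["AB", "AB", "AB"])

    def test_three_groups_dispatch_kruskal(self, rng):
        expr = np.concatenate([rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(3, 1, 15)])
        geno = np.repeat(["AA", "AB", "BB"], 15)
        assert eqtl_test(expr, geno) < 0.05
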