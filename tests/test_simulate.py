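"""Liability-threshold cohort simulator: genotypes, effects, onset, ascertainment."""

import numpy as np
import pandas as pd
import pytest

from snph2 import (
    AgeOnsetModel,
    ArchitectureSpec,
    ascertain,
    draw_effects,
    simulate_genotypes,
    simulate_liability_onset,
)


class TestSimulateGenotypes:
    def test_dosage_range_and_shape(self):
        G = simulate_genotypes(4, 10, ld_rho=0.0, seed=1)
        assert G.dosages.shape == (4, 10)
        assert set(np.unique(G.dosages)) <= {0, 1, 2}

    def test_deterministic_given_seed(self):
        a = simulate_genotypes(50, 30, ld_rho=0.7, seed=9)
        b = simulate_genotypes(50, 30, ld_rho=0.7, seed=9)
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.snp_meta, b.snp_meta)

    def test_positions_strictly_increasing(self):
        G = simulate_genotypes(10, 200, seed=3)
        assert np.all(np.diff(G.snp_meta["pos_bp"]) > 0)

    def test_metadata_frequency_is_realized_frequency(self):
        G = simulate_genotypes(100, 50, seed=5)
        assert np.allclose(G.snp_meta["allele_freq"], G.dosages.mean(axis=0) / 2.0)

    def test_independence_without_ld(self):
        G = simulate_genotypes(3000, 40, ld_rho=0.0, ld_block_size=10, seed=7)
        r = np.corrcoef(G.dosages.T)
        off = r[np.triu_indices(40, 1)]
        assert np.mean(np.abs(off)) < 0.03  # Monte-Carlo noise scale ~ 1/sqrt(n)

    def test_ld_concentrated_within_blocks(self):
        # oracle: direct Pearson r^2 on the emitted matrix
        G = simulate_genotypes(2000, 200, ld_rho=0.8, ld_block_size=20, seed=11)
        r2 = np.corrcoef(G.dosages.T) ** 2
        blocks = np.arange(200) // 20
        same = blocks[:, None] == blocks[None, :]
        triu = np.triu(np.ones((200, 200), bool), 1)
        adjacent = np.zeros_like(same)
        idx = np.arange(199)
        adjacent[idx, idx + 1] = same[idx, idx + 1]
        assert r2[adjacent].mean() > 5 * r2[triu & ~same].mean()

    @pytest.mark.parametrize("bad_range", [(0.0, 0.5), (0.1, 0.6), (-0.1, 0.3), (0.4, 0.2)])
    def test_invalid_maf_range_rejected(self, bad_range):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 10, maf_range=bad_range, seed=0)

    def test_invalid_ld_rho_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 10, ld_rho=1.0, seed=0)


@pytest.fixture(scope="module")
def meta():
    return simulate_genotypes(400, 500, seed=21).snp_meta


class TestDrawEffects:

    def test_total_variance_identity(self, meta):
        arch = ArchitectureSpec(h2_liability_total=0.5)
        eff = draw_effects(meta, arch, seed=1)
        p = meta["allele_freq"].to_numpy()
        total = np.sum(eff.beta_allele**2 * 2 * p * (1 - p))
        assert total == pytest.approx(0.5, abs=1e-10)

    def test_group_shares_exact(self, meta):
        arch = ArchitectureSpec(h2_liability_total=0.4, major_locus_share=0.2, geneset_h2_share=0.7)
        eff = draw_effects(meta, arch, seed=2)
        assert eff.variance_in(eff.geneset_index) == pytest.approx(0.7 * 0.4, abs=1e-10)
        assert eff.beta_std[eff.major_index] ** 2 == pytest.approx(0.2 * 0.4, abs=1e-10)

    def test_zero_major_share_gives_no_major_locus(self, meta):
        arch = ArchitectureSpec(major_locus_share=0.0, geneset_h2_share=0.7)
        eff = draw_effects(meta, arch, seed=3)
        assert eff.major_index is None

    def test_geneset_size_matches_fraction(self, meta):
        arch = ArchitectureSpec(geneset_snp_fraction=0.03)
        eff = draw_effects(meta, arch, seed=4)
        assert len(eff.geneset_index) == round(0.03 * len(meta))

    def test_oversized_geneset_rejected(self, meta):
        arch = ArchitectureSpec(geneset_snp_fraction=1.0)
        with pytest.raises(ValueError):
            draw_effects(meta, arch, seed=5)

    def test_inconsistent_shares_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(major_locus_share=0.5, geneset_h2_share=0.6)


@pytest.fixture(scope="module")
def population():
    G = simulate_genotypes(6000, 400, ld_rho=0.5, seed=31)
    # dense causal background keeps the liability tails Gaussian enough
    # for exceedance rates to track the prevalence anchors
    arch = ArchitectureSpec(h2_liability_total=0.5, n_causal=200)
    eff = draw_effects(G.snp_meta, arch, seed=32)
    pop = simulate_liability_onset(G, eff, AgeOnsetModel(), seed=33)
    return G, eff, pop


@pytest.fixture(scope="module")
def ascertain_population():
    G = simulate_genotypes(8000, 300, seed=51)
    arch = ArchitectureSpec(h2_liability_total=0.5)
    eff = draw_effects(G.snp_meta, arch, seed=52)
    return simulate_liability_onset(G, eff, AgeOnsetModel(), seed=53)


class TestLiabilityOnset:

    def test_unit_liability_variance_and_exact_decomposition(self, population):
        G, eff, pop = population
        L = pop["liability_true"].to_numpy()
        assert L.var() == pytest.approx(1.0, abs=1e-9)
        # genetic variance share is exact by construction
        p = G.snp_meta["allele_freq"].to_numpy()
        het = 2 * p * (1 - p)
        c = eff.causal_index
        Z = (G.dosages[:, c] - 2 * p[c]) / np.sqrt(het[c])
        g = Z @ eff.beta_std[c]
        slope = (L - L.mean()) @ (g - g.mean()) / ((g - g.mean()) @ (g - g.mean()))
        explained = np.var(slope * g)
        assert explained / L.var() == pytest.approx(0.5, abs=1e-9)

    def test_population_rate_matches_prevalence_curve(self, population):
        _, _, pop = population
        model = AgeOnsetModel()
        L = pop["liability_true"].to_numpy()
        for age, K in [(65, 0.02), (75, 0.05), (85, 0.15)]:
            rate = float(np.mean(L >= model.threshold(age)))
            assert rate == pytest.approx(K, abs=3 * np.sqrt(K * (1 - K) / len(L)))

    def test_every_case_onsets_before_assessment(self, population):
        _, _, pop = population
        cases = pop[pop["status"] == 1]
        assert (cases["onset_age_years"] <= cases["age_years"]).all()

    def test_risk_allele_frequency_declines_with_age_in_unaffected(self, population):
        G, eff, pop = population
        # oracle: stratified allele-frequency computation among the unaffected
        risk_sign = np.sign(eff.beta_std)
        heavy = np.argsort(np.abs(eff.beta_std))[::-1][:40]  # largest effects
        unaffected = (pop["status"] == 0).to_numpy()
        age = pop["age_years"].to_numpy()
        bins = [(55, 65), (65, 75), (75, 90)]
        freqs = []
        for lo, hi in bins:
            sel = unaffected & (age >= lo) & (age < hi)
            f = (G.dosages[np.ix_(sel, heavy)].mean(axis=0) / 2.0) * risk_sign[heavy]
            freqs.append(f.mean())
        assert freqs[0] > freqs[-1]

    def test_no_genetics_no_onset_genotype_association(self):
        G = simulate_genotypes(3000, 200, seed=41)
        arch = ArchitectureSpec(h2_liability_total=0.0, major_locus_share=0.0, geneset_h2_share=0.0)
        eff = draw_effects(G.snp_meta, arch, seed=42)
        pop = simulate_liability_onset(G, eff, AgeOnsetModel(), seed=43)
        onset = pop["onset_age_years"].to_numpy()
        score = G.dosages @ np.random.default_rng(44).standard_normal(200)
        have = np.isfinite(onset)
        r = np.corrcoef(onset[have], score[have])[0, 1]
        assert abs(r) < 0.08

    def test_misaligned_effects_rejected(self, population):
        G, eff, _ = population
        G2 = simulate_genotypes(10, 30, seed=1)
        with pytest.raises(ValueError, match="aligned"):
            simulate_liability_onset(G2, eff, AgeOnsetModel(), seed=0)


class TestAscertain:

    def test_screened_matched_labels_equal_truth(self, ascertain_population):
        asc = ascertain(ascertain_population, 300, 300, (75, 90), (75, 90), screened=True, seed=1)
        cases = asc.cohort[asc.cohort["status"] == 1]
        controls = asc.cohort[asc.cohort["status"] == 0]
        assert (cases["onset_age_years"] <= cases["age_years"]).all()
        assert controls["onset_age_years"].isna().all()
        assert asc.latent_control_fraction == 0.0

    def test_misdiagnosis_fraction(self, ascertain_population):
        asc = ascertain(ascertain_population, 400, 100, (75, 90), (75, 90), misdiagnosis_rate=0.3, seed=2)
        cases = asc.cohort[asc.cohort["status"] == 1]
        frac_no_onset = cases["onset_age_years"].isna().mean()
        assert frac_no_onset == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / 400))
        assert asc.n_misdiagnosed == int(cases["misdiagnosed"].sum())

    def test_age_mismatched_unscreened_controls_contain_latent_cases(self, ascertain_population):
        asc = ascertain(
            ascertain_population, 200, 400, (80, 90), (55, 62), screened=False, seed=3
        )
        assert asc.latent_control_fraction > 0
        latent = asc.cohort[asc.cohort["latent_case"]]
        assert ((latent["onset_age_years"] > latent["age_years"]) & (latent["status"] == 0)).all()

    def test_infeasible_request_names_stratum(self, ascertain_population):
        with pytest.raises(ValueError, match="case"):
            ascertain(ascertain_population, 10_000, 10, (75, 90), (75, 90), seed=4)

    def test_deterministic(self, ascertain_population):
        a = ascertain(ascertain_population, 150, 150, (75, 90), (70, 85), screened=False, seed=5)
        b = ascertain(ascertain_population, 150, 150, (75, 90), (70, 85), screened=False, seed=5)
        pd.testing.assert_frame_equal(a.cohort, b.cohort)
        assert a.latent_control_fraction == b.latent_control_fraction
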