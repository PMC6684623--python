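"""F2 cross simulator: meiosis, linkage, gene action, phenotypes, SCAR calls."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from chemoseg import (
    GeneActionModel,
    PlantGenotype,
    StudyConfig,
    cross,
    default_loci,
    enumerate_class_probabilities,
    make_gamete,
    phenotype,
    phenotype_class,
    scar_genotype,
    simulate_f2_study,
)
from chemoseg.simulate import (
    A1_C3,
    A1_C5,
    A2_C3,
    A2_C5,
    B_CBDAS,
    B_THCAS,
    M_CBDAS,
    M_THCAS,
)


def het_plant(plant_id="het"):
    """Doubly heterozygous plant with coupling haplotypes (C3 with THCAS)."""
    return PlantGenotype(
        plant_id,
        (A2_C3, A1_C3, B_THCAS, M_THCAS),
        (A2_C5, A1_C5, B_CBDAS, M_CBDAS),
    )


class TestMakeGamete:
    def test_complete_linkage_cosegregates(self, rng):
        loci = default_loci(r_a1_a2=0.5, r_a1_b=0.0)
        plant = het_plant()
        for _ in range(200):
            g = make_gamete(plant, loci, rng)
            # A1 (index 1) and B (index 2) always from the same haplotype
            assert (g[1] == A1_C3) == (g[2] == B_THCAS)

    def test_unlinked_loci_independent(self, rng):
        loci = default_loci(r_a1_a2=0.5, r_a1_b=0.5)
        plant = het_plant()
        co = sum(
            (g[1] == A1_C3) == (g[2] == B_THCAS)
            for g in (make_gamete(plant, loci, rng) for _ in range(10_000))
        )
        # binomial oracle: p=0.5, 3 SE ≈ 0.015 at n=10,000
        assert co / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_homozygous_parent_transmits_identically(self, rng):
        hap = (A2_C3, A1_C3, B_THCAS, M_THCAS)
        plant = PlantGenotype("hom", hap, hap)
        for r in (0.0, 0.2, 0.5):
            loci = default_loci(r_a1_a2=r, r_a1_b=r)
            assert make_gamete(plant, loci, rng) == hap

    def test_recombination_fraction_recovered(self):
        """Configured r is reproduced by simulated meioses within 3 binomial SE."""
        rng = np.random.default_rng(1234)
        plant = het_plant()
        n = 10_000
        for r in (0.1, 0.25):
            loci = default_loci(r_a1_a2=0.5, r_a1_b=r)
            rec = sum(
                (g[1] == A1_C3) != (g[2] == B_THCAS)
                for g in (make_gamete(plant, loci, rng) for _ in range(n))
            )
            se = np.sqrt(r * (1 - r) / n)
            assert abs(rec / n - r) < 3 * se


class TestCross:
    def test_divergent_homozygotes_give_uniform_f1(self, rng):
        loci = default_loci()
        p1 = PlantGenotype("P1", *[(A2_C3, A1_C3, B_THCAS, M_THCAS)] * 2)
        p2 = PlantGenotype("P2", *[(A2_C5, A1_C5, B_CBDAS, M_CBDAS)] * 2)
        for child in cross(p1, p2, 20, loci, rng):
            for i in range(4):
                assert child.maternal_haplotype[i] != child.paternal_haplotype[i]

    def test_f1_cross_segregates_one_to_two_to_one(self, rng):
        loci = default_loci()
        f1a, f1b = het_plant("a"), het_plant("b")
        offspring = cross(f1a, f1b, 10_000, loci, rng)
        counts = [0, 0, 0]
        for child in offspring:
            counts[sum(a == B_CBDAS for a in child.alleles_at(2))] += 1
        chi2 = stats.chisquare(counts, [2500, 5000, 2500]).statistic
        assert chi2 <= stats.chi2.ppf(0.99, 2)

    def test_complete_linkage_limit(self, rng):
        # with A1-B at r=0, every CBDAS homozygote is homozygous for the
        # A1 allele coupled with CBDAS
        loci = default_loci(r_a1_a2=0.5, r_a1_b=0.0)
        f1a, f1b = het_plant("a"), het_plant("b")
        for child in cross(f1a, f1b, 300, loci, rng):
            if set(child.alleles_at(2)) == {B_CBDAS}:
                assert set(child.alleles_at(1)) == {A1_C5}

    def test_allele_conservation(self, rng):
        loci = default_loci()
        offspring = cross(het_plant("a"), het_plant("b"), 2000, loci, rng)
        for locus_idx in range(4):
            ref = het_plant().maternal_haplotype[locus_idx]
            freq = np.mean(
                [sum(a == ref for a in c.alleles_at(locus_idx)) / 2 for c in offspring]
            )
            se = np.sqrt(0.25 / (2 * 2000))
            assert abs(freq - 0.5) < 3 * se


class TestPhenotypeClass:
    @pytest.mark.parametrize(
        "kind,expected",
        [
            ("additive", [1, 4, 6, 4, 1]),
            ("digenic_dominant", [9, 3, 3, 1]),
            ("epistatic_7_6_3", [7, 6, 3]),
        ],
    )
    def test_exhaustive_enumeration_matches_mendelian_ratio(self, kind, expected):
        probs = enumerate_class_probabilities(kind)
        assert probs == [Fraction(e, 16) for e in expected]
        assert sum(probs) == 1

    def test_double_homozygote_extreme_classes(self):
        model = StudyConfig(gene_action="additive").build_model()
        hap_c3 = (A2_C3, A1_C3, B_THCAS, M_THCAS)
        hap_c5 = (A2_C5, A1_C5, B_CBDAS, M_CBDAS)
        assert phenotype_class(PlantGenotype("hi", hap_c3, hap_c3), model) == 4
        assert phenotype_class(PlantGenotype("lo", hap_c5, hap_c5), model) == 0

    def test_monte_carlo_matches_enumeration(self, rng):
        loci = default_loci()
        model = StudyConfig(gene_action="epistatic_7_6_3").build_model()
        offspring = cross(het_plant("a"), het_plant("b"), 5000, loci, rng)
        classes = np.bincount([phenotype_class(c, model, loci) for c in offspring], minlength=3)
        for k, p in enumerate(enumerate_class_probabilities("epistatic_7_6_3")):
            se = np.sqrt(float(p) * (1 - float(p)) / 5000)
            assert abs(classes[k] / 5000 - float(p)) < 3 * se


class TestPhenotype:
    def test_zero_noise_returns_class_means(self, rng):
        model = StudyConfig(gene_action="additive", noise_sd=0.0, b_noise_sd=0.0).build_model()
        hap = (A2_C3, A1_C3, B_THCAS, M_THCAS)
        fr = phenotype(PlantGenotype("p", hap, hap), model, rng)
        assert fr.F_C3 == model.class_means_FC3[4]
        assert fr.F_dicyclic == model.b_class_means_Fdi[0]

    def test_fractions_stay_in_range_near_boundary(self, rng):
        model = GeneActionModel(
            "epistatic_7_6_3", (0.8, 45.0, 88.3), 2.0, (0.9, 48.5, 96.1), 2.0
        )
        hap = (A2_C5, A1_C5, B_CBDAS, M_CBDAS)
        plant = PlantGenotype("lo", hap, hap)
        values = [phenotype(plant, model, rng).F_C3 for _ in range(500)]
        assert min(values) >= 0.0 and max(values) <= 100.0

    def test_class_sample_means_near_class_means(self):
        rng = np.random.default_rng(3)
        model = StudyConfig(gene_action="additive", noise_sd=3.0).build_model()
        hap = (A2_C3, A1_C3, B_THCAS, M_THCAS)
        plant = PlantGenotype("p", hap, hap)
        draws = np.array([phenotype(plant, model, rng).F_C3 for _ in range(400)])
        se = 3.0 / np.sqrt(400)
        assert abs(draws.mean() - model.class_means_FC3[4]) < 3 * se


class TestScarGenotype:
    def test_perfect_marker_concordance(self, rng):
        assert scar_genotype(het_plant(), 0.0, rng) == "THCAS/CBDAS"

    def test_homozygote_call_unambiguous(self, rng):
        hap = (A2_C3, A1_C3, B_THCAS)
        plant = PlantGenotype("hom", hap, hap)  # no marker locus: co-simulated
        loci = default_loci()[:3]
        for _ in range(100):
            assert scar_genotype(plant, 0.4, rng, loci) == "THCAS/THCAS"

    def test_marker_discordance_rate(self, rng):
        """Per-gamete marker-B discordance equals marker_r (binomial oracle)."""
        loci = default_loci(marker_r=0.1)
        plant = het_plant()
        n = 10_000
        disc = sum(
            (g[2] == B_THCAS) != (g[3] == M_THCAS)
            for g in (make_gamete(plant, loci, rng) for _ in range(n))
        )
        assert abs(disc / n - 0.1) < 0.01


class TestSimulateStudy:
    def test_default_study_shape(self):
        study = simulate_f2_study(seed=123)
        assert len(study.f2) == 210 and len(study.f1) == 35 and len(study.parents) == 2
        df = study.to_dataframe()
        assert (df["generation"] == "F2").sum() == 210 * study.config.n_replicates

    def test_parents_anchor_parental_fractions(self):
        cfg = StudyConfig(noise_sd=0.0, b_noise_sd=0.0)
        study = simulate_f2_study(cfg, seed=1)
        p1, p2 = study.parents
        assert p1.fractions.F_C3 == pytest.approx(88.3)
        assert p1.fractions.F_dicyclic == pytest.approx(0.9)
        assert p2.fractions.F_C3 == pytest.approx(0.8)
        assert p2.fractions.F_dicyclic == pytest.approx(96.1)
        assert p1.scar_call == "THCAS/THCAS" and p2.scar_call == "CBDAS/CBDAS"

    def test_f1_uniformly_heterozygous_at_b(self):
        study = simulate_f2_study(seed=5)
        assert {p.scar_call for p in study.f1} == {"THCAS/CBDAS"}

    def test_deterministic_given_seed(self):
        a = simulate_f2_study(seed=77).to_dataframe().to_csv(index=False)
        b = simulate_f2_study(seed=77).to_dataframe().to_csv(index=False)
        assert a == b

    def test_f2_haplotypes_are_legal_recombinants(self):
        study = simulate_f2_study(seed=9)
        # every F1 is fully heterozygous, so any F1 carries both alleles per locus
        for plant in study.f2:
            for i in range(4):
                parental = set(study.f1[0].genotype.alleles_at(i))
                assert set(plant.genotype.alleles_at(i)) <= parental

    def test_unlinked_a_and_b_factorize(self):
        """At r = 0.5 everywhere the A-class and B genotype are independent."""
        cfg = StudyConfig(gene_action="epistatic_7_6_3", n_f2=10_000, n_replicates=1)
        pvals = []
        for seed in range(5):
            study = simulate_f2_study(cfg, seed=seed)
            table = np.zeros((3, 3))
            for p in study.f2:
                b = ("THCAS/THCAS", "THCAS/CBDAS", "CBDAS/CBDAS").index(p.scar_call)
                table[p.true_class, b] += 1
            pvals.append(stats.chi2_contingency(table).pvalue)
        assert min(pvals) > 0.01 / 5  # no seed shows dependence

    def test_linked_epistatic_distorts_thcas_subset(self):
        """A1 tightly linked to B distorts the THCAS-homozygote class ratio."""
        cfg = StudyConfig(gene_action="epistatic_7_6_3", n_f2=5000, r_a1_b=0.01, n_replicates=1)
        study = simulate_f2_study(cfg, seed=2)
        classes = [p.true_class for p in study.f2 if p.scar_call == "THCAS/THCAS"]
        counts = np.bincount(classes, minlength=3)
        expected = counts.sum() * np.array([7, 6, 3]) / 16.0
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        assert chi2 > stats.chi2.ppf(0.999, 2)

    def test_invalid_config_lists_fields(self):
        with pytest.raises(ValueError, match="r_a1_b"):
            simulate_f2_study(StudyConfig(r_a1_b=0.7), seed=0)
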