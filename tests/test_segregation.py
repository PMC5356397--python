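"""Segregation counts, Mendelian expectations, exact tests, and verdicts."""

import random
from fractions import Fraction
from itertools import product
from math import comb

import pytest

from pedseg import (
    CrossClass,
    DOMINANT_MODEL,
    Genotype,
    Litter,
    Pedigree,
    Phenotype,
    RECESSIVE_MODEL,
    Sex,
    binomial_segregation_test,
    conditional_offspring_risk,
    expected_affected_fraction,
    format_ratio,
    hypothesis_report,
    observed_segregation,
)
from pedseg.segregation import DEFAULT_AFFECTED_DAM_MIXTURE
from tests.test_pedigree import make_dog

# ---- independent oracles --------------------------------------------------

_ALLELES = {Genotype.RISK_HOM: "rr", Genotype.HET: "rn", Genotype.NORM_HOM: "nn"}


def enumerate_affected_fraction(mode: str, sire: Genotype,
                                dam: Genotype) -> Fraction:
    """Brute force over the four equally likely parental transmissions."""
    affected = 0
    for a, b in product(_ALLELES[sire], _ALLELES[dam]):
        n_risk = (a == "r") + (b == "r")
        if mode == "recessive":
            affected += n_risk == 2
        else:
            affected += n_risk >= 1
    return Fraction(affected, 4)


def brute_force_pvalue(k: int, n: int, p: Fraction) -> float:
    """Point-probability two-sided p: sum of outcomes no likelier than k."""
    pmf = [Fraction(comb(n, i)) * p ** i * (1 - p) ** (n - i)
           for i in range(n + 1)]
    return float(sum(x for x in pmf if x <= pmf[k]))


# ---- observed counts ------------------------------------------------------

class TestObservedSegregation:
    def test_cohort_k_affected_by_unaffected_pools_8_and_13(self, cohort_k):
        usable, phenotypes = cohort_k
        counts = observed_segregation(usable, phenotypes,
                                      CrossClass.AFF_X_UNAFF)
        assert (counts.affected, counts.unaffected) == (8, 13)
        assert counts.per_litter == {
            "K2": (1, 0), "K3": (2, 1), "K4": (2, 2), "K5": (0, 1),
            "K6": (1, 3), "K9": (2, 3), "K10": (0, 3),
        }

    def test_cohort_t_affected_by_unaffected_pools_18_and_5(self, cohort_t):
        usable, phenotypes = cohort_t
        counts = observed_segregation(usable, phenotypes,
                                      CrossClass.AFF_X_UNAFF)
        assert (counts.affected, counts.unaffected) == (18, 5)
        assert counts.per_litter == {"T3": (7, 2), "T6": (7, 3), "T7": (4, 0)}

    def test_cohort_t_unaffected_parents_litters_with_affected_pups(
            self, cohort_t):
        usable, phenotypes = cohort_t
        counts = observed_segregation(usable, phenotypes,
                                      litter_ids=["T1", "T2", "T8"])
        assert (counts.affected, counts.unaffected) == (5, 11)

    def test_empty_class_yields_zero_counts(self, cohort_t):
        usable, phenotypes = cohort_t
        counts = observed_segregation(usable, phenotypes, CrossClass.AFF_X_AFF)
        assert (counts.affected, counts.unaffected, counts.per_litter) \
            == (0, 0, {})


# ---- Mendelian expectations ----------------------------------------------

class TestExpectedAffectedFraction:
    @pytest.mark.parametrize("mode", ["recessive", "dominant"])
    @pytest.mark.parametrize("sire", list(Genotype))
    @pytest.mark.parametrize("dam", list(Genotype))
    def test_matches_transmission_enumeration_for_every_pure_cross(
            self, mode, sire, dam):
        model = RECESSIVE_MODEL if mode == "recessive" else DOMINANT_MODEL
        assert expected_affected_fraction(model, sire, dam) \
            == enumerate_affected_fraction(mode, sire, dam)

    @pytest.mark.parametrize("sire,dam,expected", [
        # the affected-dam x unaffected-sire table under dominance
        (Genotype.NORM_HOM, Genotype.HET, Fraction(1, 2)),
        (Genotype.NORM_HOM, Genotype.RISK_HOM, Fraction(1)),
        (Genotype.HET, Genotype.HET, Fraction(3, 4)),
        (Genotype.HET, Genotype.RISK_HOM, Fraction(1)),
        (Genotype.RISK_HOM, Genotype.HET, Fraction(1)),
        (Genotype.RISK_HOM, Genotype.RISK_HOM, Fraction(1)),
    ])
    def test_dominant_cross_table(self, sire, dam, expected):
        assert expected_affected_fraction(DOMINANT_MODEL, sire, dam) == expected

    def test_affected_dam_mixture_averages_to_three_quarters(self):
        assert expected_affected_fraction(
            DOMINANT_MODEL, Genotype.NORM_HOM, DEFAULT_AFFECTED_DAM_MIXTURE
        ) == Fraction(3, 4)

    def test_recessive_carrier_cross_halves(self):
        assert expected_affected_fraction(
            RECESSIVE_MODEL, Genotype.RISK_HOM, Genotype.HET) == Fraction(1, 2)
        assert expected_affected_fraction(
            RECESSIVE_MODEL, Genotype.RISK_HOM, Genotype.RISK_HOM) == 1

    def test_penetrance_scales_linearly(self):
        assert expected_affected_fraction(
            DOMINANT_MODEL, Genotype.NORM_HOM, Genotype.HET,
            penetrance=Fraction(4, 5)) == Fraction(2, 5)


# ---- exact binomial test --------------------------------------------------

class TestBinomialSegregationTest:
    def test_matches_brute_force_summation_exhaustively(self):
        for n in range(1, 26):
            for p in (Fraction(1, 4), Fraction(1, 2), Fraction(3, 4)):
                for k in range(n + 1):
                    got = binomial_segregation_test((k, n - k), p)
                    want = brute_force_pvalue(k, n, p)
                    assert got == pytest.approx(want, rel=1e-9), (k, n, p)

    def test_observation_at_the_mode_gives_p_one(self):
        assert binomial_segregation_test((9, 9), 0.5) == pytest.approx(1.0)

    def test_empty_counts_not_applicable(self):
        assert binomial_segregation_test((0, 0), 0.5) is None

    def test_degenerate_expectation_rejected(self):
        with pytest.raises(ValueError):
            binomial_segregation_test((1, 1), 1.0)


# ---- conditional risk -----------------------------------------------------

class TestConditionalRisk:
    def test_cohort_values(self, cohort_k, cohort_t):
        usable_k, ph_k = cohort_k
        usable_t, ph_t = cohort_t
        assert conditional_offspring_risk(usable_k, ph_k) == Fraction(8, 21)
        assert conditional_offspring_risk(usable_t, ph_t) == Fraction(18, 23)

    def test_invariant_to_litter_order_and_recombination(self, cohort_t):
        usable, phenotypes = cohort_t
        rng = random.Random(3)
        shuffled = Pedigree(dogs=dict(usable.dogs),
                            litters=rng.sample(usable.litters,
                                               len(usable.litters)),
                            cutoff_age=usable.cutoff_age)
        assert conditional_offspring_risk(shuffled, phenotypes) \
            == conditional_offspring_risk(usable, phenotypes)

    def test_no_affected_parents_not_applicable(self):
        dogs = {
            "DAD": make_dog("DAD", Sex.MALE),
            "MOM": make_dog("MOM"),
            "PUP": make_dog("PUP", sire="DAD", dam="MOM", age=9.0),
        }
        pedigree = Pedigree(dogs=dogs,
                            litters=[Litter("L1", "DAD", "MOM", ("PUP",))])
        phenotypes = {d: Phenotype.UNAFFECTED for d in dogs}
        assert conditional_offspring_risk(pedigree, phenotypes) is None


# ---- ratio display --------------------------------------------------------

class TestRatioDisplay:
    @pytest.mark.parametrize("a,u,text", [
        (8, 10, "0.8-to-1"), (8, 13, "0.62-to-1"), (5, 11, "0.45-to-1"),
        (18, 5, "3.6-to-1"), (4, 0, "4-to-0"), (0, 3, "0-to-1"),
    ])
    def test_display_form(self, a, u, text):
        assert format_ratio(a, u) == text


# ---- hypothesis report ----------------------------------------------------

class TestHypothesisReport:
    def test_recessive_side_selects_only_proven_carrier_crosses(self, cohort_k):
        usable, phenotypes = cohort_k
        report = hypothesis_report(usable, phenotypes)
        rec = report["modes"]["recessive"]
        assert rec["carrier_cross_litters"] == ["K2", "K3", "K4", "K5",
                                                "K6", "K9"]
        entry = rec["affected_x_carrier"]
        assert (entry["affected"], entry["unaffected"]) == (8, 10)
        assert entry["ratio_display"] == "0.8-to-1"
        assert rec["verdict"] == "consistent"

    def test_t_cohort_rejects_recessive_but_not_dominant(self, cohort_t):
        usable, phenotypes = cohort_t
        report = hypothesis_report(usable, phenotypes)
        rec = report["modes"]["recessive"]
        dom = report["modes"]["dominant"]
        assert rec["carrier_cross_litters"] == ["T3", "T6", "T7"]
        assert rec["verdict"] == "inconsistent"
        assert rec["affected_x_carrier"]["p_value"] < 0.05
        assert dom["verdict"] == "consistent"
        assert dom["affected_x_unaffected"]["expected_fraction"] == 0.75

    def test_k_dominant_deficit_is_hedged_not_rejected(self, cohort_k):
        usable, phenotypes = cohort_k
        report = hypothesis_report(usable, phenotypes)
        dom = report["modes"]["dominant"]
        assert dom["verdict"] == "questionable"
        assert dom["cannot_rule_out"]
        assert dom["affected_x_unaffected"]["ratio_display"] == "0.62-to-1"

    def test_flagged_unaffected_crosses_pool_5_to_11(self, cohort_t):
        usable, phenotypes = cohort_t
        entry = hypothesis_report(usable, phenotypes)["modes"]["dominant"][
            "carrier_flagged_unaff_x_unaff"]
        assert (entry["affected"], entry["unaffected"]) == (5, 11)
        assert entry["ratio_display"] == "0.45-to-1"

    def test_empty_pedigree_reports_not_applicable(self):
        pedigree = Pedigree(dogs={}, litters=[])
        report = hypothesis_report(pedigree, {})
        assert report["conditional_offspring_risk"] is None
        for mode, key in (("recessive", "affected_x_carrier"),
                          ("dominant", "affected_x_unaffected")):
            assert report["modes"][mode][key]["verdict"] == "not_applicable"
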