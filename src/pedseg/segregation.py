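"""Observed vs expected segregation ratios and the per-hypothesis verdict.

For each class of cross (affected x carrier, affected x unaffected,
unaffected x unaffected) we pool the affected/unaffected pup counts across
litters, compute the Mendelian affected-pup fraction expected under the
hypothesis being examined, and compare the two with a two-sided exact
binomial test (point-probability method).  Verdicts respect the asymmetry of
the two hypotheses: a *deficit* of affected pups can always be absorbed by
misassigned phenotypes or reduced penetrance, so only a significant deviation
in a direction the hypothesis cannot absorb is scored "inconsistent".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

from scipy.stats import binomtest

from .inference import (
    DOMINANT_MODEL,
    Genotype,
    InferenceResult,
    LocusModel,
    RECESSIVE_MODEL,
    infer_dominant,
    infer_recessive,
)
from .pedigree import CrossClass, Pedigree, Phenotype, classify_crosses

__all__ = [
    "CrossCounts",
    "SegregationResult",
    "DEFAULT_AFFECTED_DAM_MIXTURE",
    "observed_segregation",
    "expected_affected_fraction",
    "binomial_segregation_test",
    "conditional_offspring_risk",
    "hypothesis_report",
    "format_ratio",
]

# Genotype mixture for an affected parent under the dominant hypothesis when
# nothing else is known: heterozygous or risk-homozygous with equal weight.
DEFAULT_AFFECTED_DAM_MIXTURE: dict[Genotype, Fraction] = {
    Genotype.HET: Fraction(1, 2),
    Genotype.RISK_HOM: Fraction(1, 2),
}


@dataclass
class CrossCounts:
    """Affected/unaffected pup counts for a set of litters, per litter and pooled."""

    cross_class: CrossClass | None
    per_litter: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def affected(self) -> int:
        return sum(a for a, _u in self.per_litter.values())

    @property
    def unaffected(self) -> int:
        return sum(u for _a, u in self.per_litter.values())

    @property
    def total(self) -> int:
        return self.affected + self.unaffected


@dataclass
class SegregationResult:
    """One observed-vs-expected comparison with its exact-test outcome."""

    counts: CrossCounts
    expected_fraction: Fraction
    p_value: float | None
    verdict: str  # "consistent" | "inconsistent" | "questionable" | "not_applicable"
    note: str = ""


def observed_segregation(pedigree: Pedigree, phenotypes: Mapping[str, Phenotype],
                         cross_class: CrossClass | None = None,
                         litter_ids: list[str] | None = None) -> CrossCounts:
    """Count evaluable affected/unaffected pups over litters of one cross class.

    ``litter_ids`` restricts the pool to named litters (still filtered by
    ``cross_class`` when both are given).
    """
    crosses = classify_crosses(pedigree, phenotypes)
    per_litter: dict[str, tuple[int, int]] = {}
    for lit in pedigree.litters:
        if cross_class is not None and crosses[lit.litter_id] is not cross_class:
            continue
        if litter_ids is not None and lit.litter_id not in litter_ids:
            continue
        a = sum(1 for p in lit.pup_ids if phenotypes[p] is Phenotype.AFFECTED)
        u = sum(1 for p in lit.pup_ids if phenotypes[p] is Phenotype.UNAFFECTED)
        per_litter[lit.litter_id] = (a, u)
    return CrossCounts(cross_class=cross_class, per_litter=per_litter)


_ALLELE_COUNT = {Genotype.RISK_HOM: 2, Genotype.HET: 1, Genotype.NORM_HOM: 0}


def _transmit_risk_prob(genotype: Genotype) -> Fraction:
    return Fraction(_ALLELE_COUNT[genotype], 2)


def _normalize_mixture(g: Genotype | Mapping[Genotype, float | Fraction],
                       ) -> list[tuple[Genotype, Fraction]]:
    if isinstance(g, Genotype):
        return [(g, Fraction(1))]
    weights = {k: Fraction(v).limit_denominator(10**9) for k, v in g.items()}
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("mixture weights must sum to a positive value")
    return [(k, w / total) for k, w in weights.items()]


def expected_affected_fraction(
        model: LocusModel,
        sire_genotype: Genotype | Mapping[Genotype, float | Fraction],
        dam_genotype: Genotype | Mapping[Genotype, float | Fraction],
        penetrance: float | Fraction = 1) -> Fraction:
    """Mendelian affected-offspring probability for a cross, times penetrance.

    Either parent may be a single genotype or a weighted mixture of
    genotypes; the affected fraction is averaged over the mixture.
    """
    pen = Fraction(penetrance).limit_denominator(10**9)
    if not 0 <= pen <= 1:
        raise ValueError("penetrance must lie in [0, 1]")
    total = Fraction(0)
    for sire_g, ws in _normalize_mixture(sire_genotype):
        for dam_g, wd in _normalize_mixture(dam_genotype):
            ps, pd = _transmit_risk_prob(sire_g), _transmit_risk_prob(dam_g)
            p_risk_hom = ps * pd
            p_het = ps * (1 - pd) + (1 - ps) * pd
            if model.mode == "recessive":
                p_affected = p_risk_hom
            else:
                p_affected = p_risk_hom + p_het
            total += ws * wd * p_affected
    return total * pen


def binomial_segregation_test(counts: CrossCounts | tuple[int, int],
                              expected_fraction: float | Fraction) -> float | None:
    """Two-sided exact binomial p-value (point-probability method).

    Sums the probabilities of all outcomes no more likely than the observed
    affected count under Binomial(n, expected_fraction).  Returns ``None``
    for empty counts (no pups: the test is not applicable).
    """
    if isinstance(counts, CrossCounts):
        affected, n = counts.affected, counts.total
    else:
        affected, n = counts[0], counts[0] + counts[1]
    if n == 0:
        return None
    p = float(expected_fraction)
    if not 0 < p < 1:
        raise ValueError("expected_fraction must lie strictly inside (0, 1)")
    return binomtest(affected, n, p, alternative="two-sided").pvalue


def conditional_offspring_risk(pedigree: Pedigree,
                               phenotypes: Mapping[str, Phenotype],
                               ) -> Fraction | None:
    """Disease risk among evaluable pups with at least one affected parent."""
    affected = unaffected = 0
    for lit in pedigree.litters:
        if not any(phenotypes[p] is Phenotype.AFFECTED
                   for p in (lit.sire_id, lit.dam_id)):
            continue
        for pup in lit.pup_ids:
            ph = phenotypes[pup]
            if ph is Phenotype.AFFECTED:
                affected += 1
            elif ph is Phenotype.UNAFFECTED:
                unaffected += 1
    if affected + unaffected == 0:
        return None
    return Fraction(affected, affected + unaffected)


def format_ratio(affected: int, unaffected: int) -> str:
    """Render counts in the x-to-1 display form (e.g. 8:10 -> '0.8-to-1')."""
    if unaffected == 0:
        return f"{affected}-to-0"
    value = round(affected / unaffected, 2)
    text = f"{value:.2f}".rstrip("0").rstrip(".")
    return f"{text}-to-1"


def _verdict(mode: str, counts: CrossCounts, expected: Fraction,
             p_value: float | None, alpha: float) -> tuple[str, str]:
    if p_value is None:
        return "not_applicable", "no evaluable pups in this cross class"
    if p_value >= alpha:
        return "consistent", ""
    observed = Fraction(counts.affected, counts.total)
    if mode == "recessive" and observed > expected:
        # an excess of affected pups cannot come from censoring mistakes or
        # reduced penetrance; the recessive model has no way to absorb it
        return "inconsistent", (
            "affected-pup excess beyond the Mendelian expectation"
        )
    return "questionable", "low penetrance or alternative mode of inheritance"


def _carrier_cross_litters(pedigree: Pedigree, phenotypes: Mapping[str, Phenotype],
                           inference: InferenceResult) -> list[str]:
    """Litters of one affected parent x one proven obligate-carrier parent."""
    out = []
    for lit in pedigree.litters:
        parents = (lit.sire_id, lit.dam_id)
        phs = [phenotypes[p] for p in parents]
        if sorted(ph.value for ph in phs) != ["affected", "unaffected"]:
            continue
        unaff_parent = parents[phs.index(Phenotype.UNAFFECTED)]
        if unaff_parent in inference.obligate_carriers:
            out.append(lit.litter_id)
    return out


def hypothesis_report(pedigree: Pedigree, phenotypes: Mapping[str, Phenotype],
                      alpha: float = 0.05,
                      affected_parent_mixture: Mapping[Genotype, Fraction]
                      = None) -> dict:
    """Run both single-locus hypotheses and assemble the structured verdicts.

    Recessive side: constraint propagation finds the obligate carriers, then
    every affected x obligate-carrier litter is pooled against the 1-to-1
    (50%) Mendelian expectation.  Dominant side: all affected x unaffected
    litters are pooled against the 75% expectation (affected parent equally
    likely heterozygous or homozygous, full penetrance), and the
    unaffected x unaffected litters that produced affected pups are pooled
    against the 50% floor a single silent carrier would give.
    """
    if affected_parent_mixture is None:
        affected_parent_mixture = DEFAULT_AFFECTED_DAM_MIXTURE

    report: dict = {"alpha": alpha, "modes": {}}

    def seg_entry(counts: CrossCounts, expected: Fraction, mode: str) -> dict:
        p = binomial_segregation_test(counts, expected) if counts.total else None
        verdict, note = _verdict(mode, counts, expected, p, alpha)
        return {
            "litters": {k: list(v) for k, v in sorted(counts.per_litter.items())},
            "affected": counts.affected,
            "unaffected": counts.unaffected,
            "observed_fraction": (None if counts.total == 0
                                  else counts.affected / counts.total),
            "ratio_display": format_ratio(counts.affected, counts.unaffected),
            "expected_fraction": float(expected),
            "p_value": p,
            "verdict": verdict,
            "note": note,
        }

    # ---- recessive hypothesis -------------------------------------------
    rec = infer_recessive(pedigree, phenotypes)
    carrier_litters = _carrier_cross_litters(pedigree, phenotypes, rec)
    rec_counts = observed_segregation(pedigree, phenotypes,
                                      litter_ids=carrier_litters)
    rec_counts.cross_class = CrossClass.AFF_X_UNAFF
    rec_entry = seg_entry(rec_counts, Fraction(1, 2), "recessive")
    report["modes"]["recessive"] = {
        "obligate_carriers": sorted(rec.obligate_carriers),
        "autosomal_consistent": rec.autosomal_consistent,
        "autosomal_witnesses": rec.autosomal_witnesses,
        "contradictions": [list((rule, list(ids)))
                           for rule, ids in rec.contradictions],
        "carrier_cross_litters": sorted(carrier_litters),
        "affected_x_carrier": rec_entry,
        "verdict": ("inconsistent" if not rec.consistent
                    else rec_entry["verdict"]),
    }

    # ---- dominant hypothesis --------------------------------------------
    dom = infer_dominant(pedigree, phenotypes)
    dom_counts = observed_segregation(pedigree, phenotypes,
                                      cross_class=CrossClass.AFF_X_UNAFF)
    expected_dom = expected_affected_fraction(
        DOMINANT_MODEL, Genotype.NORM_HOM, dict(affected_parent_mixture))
    dom_entry = seg_entry(dom_counts, expected_dom, "dominant")

    flagged = [lit.litter_id for lit in pedigree.litters
               if (lit.sire_id, lit.dam_id) in dom.silent_carrier_flags]
    flagged_counts = observed_segregation(pedigree, phenotypes,
                                          litter_ids=flagged)
    flagged_counts.cross_class = CrossClass.UNAFF_X_UNAFF
    flagged_entry = seg_entry(flagged_counts, Fraction(1, 2), "dominant")

    cannot_rule_out = dom_entry["verdict"] == "questionable"
    report["modes"]["dominant"] = {
        "silent_carrier_flags": sorted(list(pair)
                                       for pair in dom.silent_carrier_flags),
        "affected_x_unaffected": dom_entry,
        "carrier_flagged_unaff_x_unaff": flagged_entry,
        "cannot_rule_out": cannot_rule_out,
        "verdict": dom_entry["verdict"],
    }

    risk = conditional_offspring_risk(pedigree, phenotypes)
    report["conditional_offspring_risk"] = None if risk is None else float(risk)
    return report
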