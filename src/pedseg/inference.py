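"""Rule-based single-locus genotype inference over a phenotyped pedigree.

Two hypotheses are supported.  Under the **recessive** hypothesis (risk
allele ``t``, full penetrance) phenotypes pin genotypes hard: affected dogs
are ``t/t``, unaffected dogs are ``T/t`` or ``T/T``, and Mendelian closure
propagates the risk allele through the family graph until a fixpoint —
an unaffected dog whose possibility set collapses to ``T/t`` is an
*obligate (silent) carrier*.  Under the **dominant** hypothesis (risk allele
``C``, high but incomplete penetrance) phenotypes constrain far less:
affected dogs carry at least one ``C``, and an affected pup from two
unaffected parents flags the parent pair as containing at least one silent
carrier — a disjunction that is recorded, not resolved.

The X-linkage question is settled the same way a pedigree analyst settles
it: a male obligate carrier is a witness that the locus is autosomal.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

from .pedigree import CrossClass, Pedigree, Phenotype, Sex, classify_crosses

__all__ = [
    "Genotype",
    "LocusModel",
    "RECESSIVE_MODEL",
    "DOMINANT_MODEL",
    "InferenceResult",
    "infer_recessive",
    "infer_dominant",
    "parent_genotype_likelihood_ratio",
    "check_autosomal_consistency",
]


class Genotype(str, enum.Enum):
    RISK_HOM = "RISK_HOM"   # two copies of the risk allele
    HET = "HET"             # one copy
    NORM_HOM = "NORM_HOM"   # no copies


ALL_GENOTYPES = frozenset(Genotype)


@dataclass(frozen=True)
class LocusModel:
    """Mode of expression plus the allele symbols used in reports."""

    mode: str  # "recessive" | "dominant"
    risk_symbol: str = ""
    normal_symbol: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("recessive", "dominant"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.risk_symbol:
            risk, normal = ("t", "T") if self.mode == "recessive" else ("C", "c")
            object.__setattr__(self, "risk_symbol", risk)
            object.__setattr__(self, "normal_symbol", normal)
        if self.risk_symbol == self.normal_symbol:
            raise ValueError("allele symbols must be distinct")

    def label(self, genotype: Genotype) -> str:
        r, n = self.risk_symbol, self.normal_symbol
        if genotype is Genotype.RISK_HOM:
            return f"{r}/{r}"
        if genotype is Genotype.NORM_HOM:
            return f"{n}/{n}"
        # heterozygote printed dominant-allele first
        return f"{n}/{r}" if self.mode == "recessive" else f"{r}/{n}"

    def is_at_risk(self, genotype: Genotype) -> bool:
        if self.mode == "recessive":
            return genotype is Genotype.RISK_HOM
        return genotype in (Genotype.RISK_HOM, Genotype.HET)


RECESSIVE_MODEL = LocusModel("recessive")
DOMINANT_MODEL = LocusModel("dominant")


@dataclass
class InferenceResult:
    """Outcome of constraint propagation under one hypothesis."""

    mode: str
    genotypes: dict[str, frozenset[Genotype]]
    obligate_carriers: set[str] = field(default_factory=set)
    silent_carrier_flags: set[tuple[str, str]] = field(default_factory=set)
    autosomal_consistent: bool | None = None
    autosomal_witnesses: list[str] = field(default_factory=list)
    contradictions: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.contradictions


def _initial_sets(phenotypes: Mapping[str, Phenotype],
                  mode: str) -> dict[str, set[Genotype]]:
    sets: dict[str, set[Genotype]] = {}
    for dog, ph in phenotypes.items():
        if ph is Phenotype.AFFECTED:
            if mode == "recessive":
                sets[dog] = {Genotype.RISK_HOM}
            else:
                sets[dog] = {Genotype.RISK_HOM, Genotype.HET}
        elif ph is Phenotype.UNAFFECTED and mode == "recessive":
            sets[dog] = {Genotype.HET, Genotype.NORM_HOM}
        else:
            # unknown phenotype, or any unaffected dog under incomplete
            # dominance: nothing can be excluded
            sets[dog] = set(ALL_GENOTYPES)
    return sets


def infer_recessive(pedigree: Pedigree, phenotypes: Mapping[str, Phenotype],
                    fixed_genotypes: Mapping[str, frozenset[Genotype]] | None = None,
                    ) -> InferenceResult:
    """Propagate recessive-hypothesis constraints to a fixpoint.

    Starting sets come from phenotype (affected -> {t/t}; unaffected ->
    {T/t, T/T}); Mendelian closure then removes ``T/T`` from every parent
    and every offspring of a ``t/t`` dog until nothing shrinks.  This
    subsumes the narrower carrier rules stated litter-by-litter: an
    unaffected parent of an affected pup, and an unaffected pup of an
    affected parent, both collapse to obligate carrier.

    ``fixed_genotypes`` lets callers intersect in external knowledge (e.g.
    a DNA-confirmed genotype); a contradiction — some dog's set emptied — is
    recorded rather than raised, so a whole-hypothesis verdict can still be
    reported.
    """
    sets = _initial_sets(phenotypes, "recessive")
    contradictions: list[tuple[str, tuple[str, ...]]] = []
    if fixed_genotypes:
        for dog, fixed in fixed_genotypes.items():
            sets[dog] &= set(fixed)
            if not sets[dog]:
                contradictions.append(("fixed_genotype", (dog,)))

    pairs = list(pedigree.parent_child_pairs())
    changed = True
    while changed:
        changed = False
        for parent, child in pairs:
            # every pup of a t/t dog carries t; every parent of a t/t pup carries t
            for src, dst, rule in ((parent, child, "offspring_of_risk_hom"),
                                   (child, parent, "parent_of_risk_hom")):
                if sets[src] == {Genotype.RISK_HOM} and Genotype.NORM_HOM in sets[dst]:
                    sets[dst] = sets[dst] - {Genotype.NORM_HOM}
                    changed = True
                    if not sets[dst]:
                        contradictions.append((rule, (src, dst)))

    genotypes = {dog: frozenset(s) for dog, s in sets.items()}
    carriers = {
        dog for dog, s in genotypes.items()
        if s == frozenset({Genotype.HET})
        and phenotypes.get(dog) is Phenotype.UNAFFECTED
    }
    result = InferenceResult(mode="recessive", genotypes=genotypes,
                             obligate_carriers=carriers,
                             contradictions=contradictions)
    ok, witnesses = check_autosomal_consistency(result, pedigree)
    result.autosomal_consistent = ok
    result.autosomal_witnesses = witnesses
    return result


def infer_dominant(pedigree: Pedigree,
                   phenotypes: Mapping[str, Phenotype]) -> InferenceResult:
    """Apply the dominant-with-incomplete-penetrance premises.

    Affected dogs carry at least one risk allele; unaffected dogs can be any
    genotype (penetrance is incomplete, so no elimination is sound).  An
    unaffected x unaffected litter containing an affected pup flags its
    parent pair as holding at least one silent carrier; the disjunction is
    kept at pair level — the premises alone cannot say which parent.
    """
    sets = _initial_sets(phenotypes, "dominant")
    flags: set[tuple[str, str]] = set()
    crosses = classify_crosses(pedigree, phenotypes)
    for lit in pedigree.litters:
        if crosses[lit.litter_id] is not CrossClass.UNAFF_X_UNAFF:
            continue
        if any(phenotypes[p] is Phenotype.AFFECTED for p in lit.pup_ids):
            flags.add((lit.sire_id, lit.dam_id))
    return InferenceResult(
        mode="dominant",
        genotypes={dog: frozenset(s) for dog, s in sets.items()},
        silent_carrier_flags=flags,
    )


def check_autosomal_consistency(result: InferenceResult,
                                pedigree: Pedigree) -> tuple[bool, list[str]]:
    """X-linkage check: the locus is autosomal iff a male obligate carrier exists.

    An X-linked recessive allele cannot hide in a male (he is hemizygous and
    would be affected), so every male proven to be an unaffected carrier is a
    witness for autosomal inheritance.
    """
    witnesses = sorted(
        dog for dog in result.obligate_carriers
        if pedigree.dogs[dog].sex is Sex.MALE
    )
    return bool(witnesses), witnesses


def parent_genotype_likelihood_ratio(
        pedigree: Pedigree, phenotypes: Mapping[str, Phenotype],
        parent_id: str, model: LocusModel, mate_genotype: Genotype,
        hypotheses: tuple[Genotype, Genotype],
        mate_id: str | None = None, penetrance: float = 1.0) -> float:
    """Binomial likelihood ratio for two candidate genotypes of one parent.

    Pools the affected/unaffected counts over the parent's litters (with
    ``mate_id`` if given, else all litters the parent produced), takes the
    Mendelian affected-pup probability implied by each hypothesized parent
    genotype crossed with the fixed ``mate_genotype``, and returns
    ``L(hypotheses[0]) / L(hypotheses[1])``.  This quantifies the
    "suggests but does not prove" reading of a litter ratio; it is never fed
    back into constraint propagation.

    A hypothesis with zero likelihood yields ``inf`` (or ``0.0`` for the
    numerator side); two impossible hypotheses yield ``nan``.
    """
    from .segregation import expected_affected_fraction  # local: avoid cycle

    affected = unaffected = 0
    for lit in pedigree.litters:
        if parent_id not in (lit.sire_id, lit.dam_id):
            continue
        if mate_id is not None and mate_id not in (lit.sire_id, lit.dam_id):
            continue
        for pup in lit.pup_ids:
            ph = phenotypes[pup]
            if ph is Phenotype.AFFECTED:
                affected += 1
            elif ph is Phenotype.UNAFFECTED:
                unaffected += 1

    def likelihood(parent_genotype: Genotype) -> float:
        p = float(expected_affected_fraction(
            model, parent_genotype, mate_genotype, penetrance=penetrance))
        if (p == 0 and affected) or (p == 1 and unaffected):
            return 0.0
        return (p ** affected) * ((1 - p) ** unaffected)

    num, den = likelihood(hypotheses[0]), likelihood(hypotheses[1])
    if num == 0 and den == 0:
        return math.nan
    if den == 0:
        return math.inf
    return num / den
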