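# pedseg

Pedigree segregation analysis for a late-onset, single-locus disease —
built around osteosarcoma in Scottish Deerhounds, a giant breed in which
bone cancer is the leading neoplasm (lifetime incidence ≈ 9% in males, 11%
in bitches) and typically strikes at 7–8 years of age.

`pedseg` is for geneticists and breed-health researchers who have family
pedigrees with ages and diagnosis status and want to ask: *is disease risk
segregating like a single Mendelian factor, and if so, is it recessive or
dominant?* It implements the classical desk workflow as tested code:

1. **Censoring-aware phenotyping.** A dog is *affected* if ever diagnosed;
   *unaffected* only if disease-free at a cutoff age (default 8.5 y);
   otherwise *unevaluable* and excluded. The chance of mislabeling an old
   disease-free dog is quantified from a binned age-of-onset table as
   P(onset > cutoff | affected) × lifetime incidence — with the packaged
   2011-survey table this is 33% × 9% ≈ 3% for males and 40% × 11% ≈ 4%
   for bitches.
2. **Rule-based genotype inference.** Under a recessive hypothesis (risk
   allele *t*, full penetrance): affected ⇒ *t/t*; unaffected ⇒ *T/t* or
   *T/T*; Mendelian closure propagates *t* through the family graph until a
   fixpoint, and unaffected dogs that collapse to {*T/t*} are **obligate
   carriers**. A male obligate carrier witnesses that the locus is autosomal
   (an X-linked recessive cannot hide in a hemizygous male). Under a
   dominant hypothesis with high but incomplete penetrance, an affected pup
   from two unaffected parents flags the pair as holding a silent carrier.
3. **Segregation statistics.** Affected × carrier litters are pooled against
   the Mendelian 1:1 expectation; affected × unaffected litters against the
   75% expectation for a dominant factor (affected parent equally likely
   *C/c* or *C/C*). Observed vs expected is scored with a two-sided exact
   binomial test (point-probability method). Verdicts are directional: a
   *deficit* of affected pups is absorbable (misassignment, reduced
   penetrance) and yields a hedged "cannot rule out"; an unabsorbable excess
   rejects the hypothesis.
4. **Gene-drop simulation.** Synthetic cohorts with configurable mode,
   penetrance, founder allele frequency, onset distribution, and lifespan
   censoring, for end-to-end validation and mode-recovery experiments.

Two reconstructed study families ship as fixtures: cohort K (91 dogs, 54
usable) and cohort T (104 dogs, 56 usable). See
`src/pedseg/data/FIXTURES.md` for their provenance.

## Worked example

```sh
pedseg report --pedigree src/pedseg/data/cohort_t.csv
```

prints (abridged):

```
Dogs: 104 total, 56 usable; litters: 12 total, 8 with evaluable pups

Risk to pups with an affected parent: 78%

== Single recessive risk factor ==
Obligate carriers: ABE, COCA, DENA, EDDA, FYN, GILA, IKE, JET, LAVE, RIF, SAM, VERA, VIK
Autosomal witnesses (male carriers): ABE, FYN, IKE, JET, RIF, SAM, VIK
Affected x obligate-carrier litters (expected affected fraction 0.50):
Litter        Affected  Unaffected  Affected%  Unaffected%
T3            7         2           78%        22%
T6            7         3           70%        30%
T7            4         0           100%       0%
Totals/Means  18        5           78%        22%
Observed 18 affected / 5 unaffected pups (3.6-to-1) against an expected
affected fraction of 0.50; exact binomial p = 0.01062 at alpha = 0.05.
Inconsistent with a single recessive risk factor.
```

Reading it: the 8.5-year cutoff leaves 56 usable dogs; a pup with an
affected parent carries a 78% risk. If the factor were recessive, every
affected × obligate-carrier litter should average 1 affected : 1 unaffected
pup, but the three such litters pool to 18:5 (p ≈ 0.011) — recessive
expression is rejected. The same 18:5 against the dominant-model 75%
expectation gives p = 1.0: a single dominant autosomal factor fits. Running
the same command on cohort K gives the mirror image: 8:10 against 1:1
(p ≈ 0.81, consistent with recessive), and 8:13 against 75% — a deficit the
dominant model can only absorb by reduced penetrance, reported as "cannot
rule out".

Other subcommands: `pedseg phenotype`, `pedseg onset`, `pedseg infer`,
`pedseg segregation`, `pedseg simulate` (see `--help`); everything is also
available as library functions (`pedseg.hypothesis_report`,
`pedseg.simulate_pedigree`, ...).

## Documentation

The model, its assumptions, the simulator's scope, and numerical
conventions are described in `docs/methods.md`.
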