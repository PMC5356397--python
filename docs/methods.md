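# Methods

## The problem

Osteosarcoma in Scottish Deerhounds is common (lifetime incidence ≈ 9% in
males, 11% in bitches), usually fatal, and late-onset (mean age at diagnosis
7–8 y). Late onset is what makes mode-of-inheritance analysis from pedigrees
hard: a disease-free dog may simply not have lived long enough to express
its genotype. `pedseg` implements a censoring-aware segregation analysis
for exactly this setting: family pedigrees with per-dog age (at death, or
current), diagnosis status, and litter structure.

## Phenotype model

A dog's phenotype is a three-valued function of its record and a cutoff age
`c` (default 8.5 y):

- diagnosed ⇒ **affected**, at any age;
- undiagnosed and age ≥ `c` ⇒ **unaffected** (alive or dead; a strict mode
  restricts this to deceased dogs);
- otherwise **unevaluable** — removed from litters before any analysis,
  though unevaluable *parents* are kept as structural nodes with unknown
  phenotype.

The cutoff trades sample size against label error. Both sides are
quantified from the binned age-of-onset table (counts per one-year half-open
bin `(lo, hi]`, by sex, open-ended final bin): raising `c` shrinks the
usable cohort (on the packaged fixtures, 8.5 y reduces 91→54 and 104→56
dogs), while the mislabeling probability for an old disease-free dog is

    P(mislabel) = P(onset > c | affected, sex) × lifetime incidence(sex).

All onset arithmetic is exact-rational (`fractions.Fraction`); queries at
ages interior to a bin resolve to the enclosing bin's upper edge rather
than interpolating, because the table is bin-granular and interpolation
would invent precision. Display rounding is to whole percent, half away
from zero, and happens only at the display layer — this reproduces every
printed percentage of the survey table (67%, 60%, 33%, 40%, 3%, and 4% for
an underlying 4.4%). A bin-midpoint mean-onset estimator exists for
diagnostics but is deliberately not used as a check: midpoints cannot
recover a mean computed from unbinned ages (they give ≈ 8.0 y for females
where the unbinned survey mean was 7.8 y).

## Genotype inference

### Recessive hypothesis

Assumptions: a single biallelic autosomal locus, risk allele `t`, penetrance
1 in homozygotes, negligible disease risk otherwise. Phenotypes then pin
genotype sets — affected ⇒ {t/t}; unaffected ⇒ {T/t, T/T} — and Mendelian
closure propagates the risk allele: every offspring and every parent of a
`t/t` dog loses `T/T`. These removals run to a fixpoint. Because removals
are monotone and each rule's trigger (a set equal to {t/t}) can never be
re-enabled differently by order, the fixpoint is confluent: any
application order yields the same sets (tested by randomized orderings).

The closure subsumes the narrower litter-by-litter carrier rules (an
unaffected parent of an affected pup; an unaffected pup of a mixed
affected×unaffected litter): both follow from having a `t/t` relative. The
literal mixed-litter form is strictly weaker than Mendel — it would skip
all-unaffected litters of an affected parent — so the engine uses full
closure.

An unaffected dog whose set collapses to {T/t} is an **obligate carrier**.
A male obligate carrier is a witness that the locus is autosomal: under
X-linkage a male is hemizygous and could not silently carry a recessive
risk allele. The X-linkage question is assessed only through this witness
test; no likelihood model of X-linked transmission is built.

Contradictions (an emptied genotype set) cannot arise from phenotypes
alone under these rules; they become possible when callers intersect in
externally fixed genotypes (e.g. DNA results). They are recorded, not
raised, so a whole-hypothesis verdict can still be reported.

### Dominant hypothesis

Assumptions: risk allele `C`, high but *incomplete* penetrance (a fully
penetrant dominant factor is refuted outright by any affected pup from two
unaffected parents). Affected ⇒ {C/C, C/c}; unaffected dogs exclude
nothing. The one sound deduction is disjunctive: an unaffected×unaffected
litter containing an affected pup implies at least one parent is a silent
carrier. The pair-level flag is retained as a disjunction; deciding *which*
parent carries would need the likelihood machinery, not the premises.

### Likelihood ratios for unresolvable parents

For parents the rules cannot pin down (typically censored dogs that died
young), a binomial likelihood ratio compares two candidate genotypes: pool
the parent's affected/unaffected pup counts with a fixed mate genotype,
take the Mendelian affected-pup probability under each candidate, and form
the ratio of binomial likelihoods (penetrance 1 in recessive mode). A
hypothesis with zero likelihood against observed data reports ∞/0. These
ratios are advisory — "suggests but does not prove" — and are never fed
back into constraint propagation, keeping deduction and plausibility
separate.

## Segregation statistics

Litters are classified by parental phenotype (affected×affected,
affected×unaffected, unaffected×unaffected, parent-unknown). Counts pool
across litters treating pups as independent Bernoulli draws; a per-litter
exact multinomial variant is out of scope.

Expected affected fractions come from enumerating parental transmissions,
averaged over genotype mixtures where a parent is uncertain and scaled by
penetrance. The default mixture for an affected parent under dominance is
½ C/c + ½ C/C, giving the 75% expectation for affected×(c/c) crosses; the
mixture is configurable.

Observed vs expected is scored with a **two-sided exact binomial test,
point-probability method** (the sum of probabilities of all outcomes no
likelier than the one observed), via `scipy.stats.binomtest`; the test
suite verifies it against an independent exact-rational pmf summation,
exhaustively for n ≤ 25 and expectations {¼, ½, ¾}. The source analysis
named no test; this is the smallest-assumption formalization of judging
"very close to 1-to-1" vs "so unlikely" on counts this small, and alpha
(default 0.05) is configurable.

Verdicts are directional. A deficit of affected pups is absorbable —
phenotype misassignment only ever converts would-be-affected dogs to
"unaffected", and incomplete penetrance acts the same way — so a
significant deficit yields "questionable" with an explicit cannot-rule-out
flag rather than rejection. An excess beyond the Mendelian expectation
under the recessive model is not absorbable and yields "inconsistent".
Under the dominant model an excess above 75% is absorbable too (more C/C
dams), so the dominant hypothesis is never hard-rejected by these crosses.

The recessive-side comparison uses **only litters whose unaffected parent
is a proven obligate carrier** — the expected 1:1 holds only for
t/t × T/t crosses. On the K fixture this selects exactly litters K2–K6 and
K9 and excludes K10, whose sire was never proven a carrier.

Also reported: the conditional offspring risk (affected fraction among
evaluable pups with ≥ 1 affected parent; 38% on fixture K, 78% on fixture
T) and ratios in the field's "x-to-1" display form, rounded to two
decimals (8:10 → 0.8-to-1, 8:13 → 0.62-to-1, 5:11 → 0.45-to-1, 18:5 →
3.6-to-1).

## Gene-drop simulator

`simulate_pedigree` emulates a closed breeding program: founders at
Hardy-Weinberg proportions for the configured risk-allele frequency,
random pairing within each generation, litter sizes Poisson around a mean
(minimum 1), one allele from each parent per pup, disease with probability
= penetrance for risk genotypes and = baseline risk otherwise, onset ages
from the packaged survey table (uniform within bin) or a normal, and
lifespans from a truncated normal. A diagnosed dog's recorded age is its
onset age (the disease is usually fatal); an undiagnosed dog's is its
lifespan. `censor_to_observed` strips the truth, leaving exactly the
observable CSV fields.

Parameter defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| risk_allele_freq | 0.3 | high enough that a ~100-dog closed family segregates many carriers, as both study families visibly did; no published estimate exists |
| penetrance | 1.0 | the recessive analysis assumes full penetrance; lower it for dominant-with-incomplete-penetrance scenarios |
| baseline_risk | 0.05 | the reported baseline risk for dogs without the major factor |
| n_founders / generations / litters | 12 / 3 / 5 per gen | ≈ 15 litters, ≈ 100 dogs: the scale of the real cohorts |
| litter_size_mean | 6.0 | typical giant-breed litters; no distribution was published, so Poisson(6) min 1 is a documented stand-in |
| lifespan | normal(9.5, 1.8) y, min 1 | calibrated so evaluability loss is of the same order as the real 91→54 / 104→56 reductions; a modeling choice, not a published value |
| onset_source | packaged survey table | the only published onset distribution |

A single seed governs all draws; mode-recovery replicates derive
per-replicate seeds deterministically from it.

What the simulator does *not* emulate: the real breeds' kinship structure
and inbreeding-targeted mate choice, multi-locus or fixed-modifier
architectures, diagnosis error, and competing-risk mortality beyond a
single lifespan draw. Passing tests on simulated data therefore show the
*pipeline* is sound under its own assumptions (e.g. zero genotype-set
violations over 1000 full-penetrance, no-misclassification pedigrees),
not that any real family satisfies those assumptions.

`mode_recovery_experiment` runs the full pipeline per replicate and
records whether the true mode escapes rejection. With full penetrance at
cohort scale, the recessive hypothesis is rejected markedly more often
under dominant truth than under recessive truth — but far from always,
because a C/c × c/c cross segregates 1:1 exactly like t/t × T/t; the
discrimination comes only from homozygous-carrier parents. This mirrors
the real analysis, where one family rejected recessiveness (18:5) and the
other could not reject either mode.

## Numerical and format conventions

- Primary I/O is a headered CSV (id, sire, dam, sex, diagnosed, age_years,
  alive, litter_id; empty field = unknown; UTF-8, "." decimal). Litters
  come from the explicit litter_id column — the same pair can produce
  several litters — and dogs appearing only as parents are auto-created
  with unknown vitals. A 6-column LINKAGE PED export is provided for
  interoperability; it cannot carry ages, so censoring information is lost
  on export by design.
- Validation rejects duplicate ids, unresolved parents, sex-inconsistent
  parent roles, and cyclic ancestry, naming the offending record.
- Exact rationals internally; floats only in JSON reports; whole-percent
  rounding (half away from zero) only at display.
- Report JSON is schema-stable and byte-identical for identical inputs.

## Known limitations

- The shipped cohort fixtures are *reconstructions*: litter compositions
  and named dogs are as published, but anonymous dogs' identities,
  parentage placements, and all unevaluable padding are synthetic (see
  `src/pedseg/data/FIXTURES.md`). Statistics over evaluable dogs are
  reproduced exactly; dog-level claims about unnamed animals are not data.
- Pooling across litters ignores litter-level overdispersion.
- No ascertainment correction: families enter such datasets because they
  contain affected dogs, which inflates affected fractions in
  unaffected×unaffected crosses.
- No probabilistic peeling or MCMC genotype probabilities; the set-valued
  logic plus binomial likelihood ratios reproduces the desk method, it
  does not extend it.
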