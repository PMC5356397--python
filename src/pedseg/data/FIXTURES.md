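# Fixture provenance

## `onset_2011_survey.csv`

Age-at-diagnosis counts by sex from the 2011 Scottish Deerhound Club of
America health survey, in one-year half-open bins `(low, high]` with an
open-ended final bin. Totals: 24 males, 35 females.

## `cohort_k.csv` and `cohort_t.csv`

Reconstructions of the two study families (K: 91 dogs / 15 litters; T: 104
dogs / 12 litters; 54 and 56 usable dogs after the 8.5-year cutoff). The
published record gives the litter compositions among evaluable dogs, the
parental phenotype of every analyzed litter, and a set of named dogs with
their roles and ages; it does not give a machine-readable pedigree. The files
therefore mix three provenance classes:

1. **Named dogs** (codes kept from the study narrative): TAL, LANG, OAN,
   CRY, ART, SON, KELL, PEN, LIUM, SPIG, AMP, MYCK in cohort K; ABE, LAVE,
   COCA, VIK, DENA, SAM, RIF in cohort T. Their ages, phenotypes, litter
   roles, and the documented cross-litter links (LANG is a pup of K8 and dam
   of K1; CRY is a pup of K11 and sire of K6 and K7; RIF is an unaffected pup
   of T3 and sire of T4) are as narrated.
2. **Anonymous evaluable dogs** whose existence and phenotype follow from the
   litter tables (e.g. the 2 affected / 2 unaffected pups of K4) but whose
   identities were never printed. They carry invented ids in the breed's
   3-letter-male / 4-letter-female style. Where the record leaves parentage
   open, parents were chosen so that every deduction the study reports goes
   through — e.g. the sire of K5 is an unaffected pup of K4, making him a
   deducible carrier, since the study pools K5 among the affected × carrier
   crosses; the affected dams of K2/K3 are the affected pups of K1, and the
   remaining affected dams are affected pups of K8 and K11 (T: of T2 and T8).
   These placements are *a* consistent realization, not published fact.
3. **Synthetic padding** (ids `KU…` / `TU…`, plus the unevaluable T4 dam
   `MIST`): young, undiagnosed, living dogs that the 8.5-year cutoff removes,
   added so the full files reduce from 91→54 and 104→56 usable dogs exactly
   as the study reports. They appear in the never-analyzed litters K13–K15 /
   T9–T12 and as extra young pups of analyzed litters, and can never affect a
   statistic: every analysis first drops unevaluable dogs.

Known limitations, kept deliberately:

* Two additional unaffected pups of PEN ("data not shown") are excluded;
  litter K10 holds only its three tabulated unaffected pups.
* The narrative counts 14 carrier pups across K3–K6, K9, K10, but the litter
  table for those litters sums to 13 unaffected pups; the fixture follows the
  table (the inference engine accordingly proves 13 such carriers, 12 pups of
  affected dams plus the K4-born sire of K5).
* The narrative is self-contradictory about litter T8 (listed once as having
  only one phenotyped parent, but analyzed with both parents unaffected and
  named); the fixture follows the analysis: T8 = ABE × COCA, both unaffected.
* Ages not stated in the narrative are plausible inventions consistent with
  the phenotype rules (affected: age at diagnosis; unaffected: death at or
  after 8.5 years, one living dog exactly at the cutoff).
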