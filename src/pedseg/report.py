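"""End-to-end cohort analysis: phenotype -> inference -> segregation -> verdict.

`run_cohort_analysis` strings the pipeline together for one pedigree file and
returns a JSON-serializable report mirroring how a segregation study is
written up: an evaluability summary, the censoring/misassignment arithmetic,
per-hypothesis inference digests with observed-vs-expected comparisons, and
narrative verdict strings that quote the hypothesis and the alpha level
rather than editorializing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

from .datasets import load_onset_table
from .onset import OnsetTable, misclassification_prob, percent, prob_onset_after
from .pedigree import (
    CrossClass,
    Phenotype,
    Sex,
    assign_phenotypes,
    classify_crosses,
    filter_evaluable,
    read_pedigree,
)
from .segregation import hypothesis_report, observed_segregation

__all__ = ["RunConfig", "run_cohort_analysis", "render_tables"]


@dataclass
class RunConfig:
    """Inputs and knobs for one cohort run."""

    pedigree_path: str | Path
    onset_table_path: str | Path | None = None
    cutoff_age: float = 8.5
    alpha: float = 0.05
    incidence_male: float = 0.09
    incidence_female: float = 0.11
    strict_deceased_only: bool = False
    json_out: str | Path | None = None
    text_out: str | Path | None = None


def _verdict_sentence(mode: str, entry: dict, alpha: float) -> str:
    verdict = entry["verdict"]
    if verdict == "not_applicable":
        return (f"No informative crosses: the single-{mode}-factor hypothesis "
                f"could not be tested.")
    p = entry["p_value"]
    base = (f"Observed {entry['affected']} affected / {entry['unaffected']} "
            f"unaffected pups ({entry['ratio_display']}) against an expected "
            f"affected fraction of {entry['expected_fraction']:.2f}; exact "
            f"binomial p = {p:.4g} at alpha = {alpha}.")
    if verdict == "consistent":
        return base + f" Consistent with a single {mode} risk factor."
    if verdict == "inconsistent":
        return base + (f" Inconsistent with a single {mode} risk factor "
                       f"({entry['note']}).")
    return base + (f" Deviation is in a direction the {mode} hypothesis can "
                   f"absorb; cannot rule out {entry['note']}.")


def run_cohort_analysis(config: RunConfig) -> dict:
    """Run both hypotheses on one pedigree file and assemble the cohort report."""
    pedigree = read_pedigree(config.pedigree_path, cutoff_age=config.cutoff_age)
    onset = (OnsetTable.from_csv(config.onset_table_path)
             if config.onset_table_path else load_onset_table())

    phenotypes_full = assign_phenotypes(
        pedigree, strict_deceased_only=config.strict_deceased_only)
    usable = filter_evaluable(pedigree, phenotypes_full)
    phenotypes = {d: phenotypes_full[d] for d in usable.dogs}
    n_usable = sum(1 for ph in phenotypes.values()
                   if ph is not Phenotype.UNEVALUABLE)

    report: dict = {
        "input": str(config.pedigree_path),
        "cutoff_age": config.cutoff_age,
        "alpha": config.alpha,
        "evaluability": {
            "total_dogs": len(pedigree.dogs),
            "usable_dogs": n_usable,
            "total_litters": len(pedigree.litters),
            "litters_with_evaluable_pups": len(usable.litters),
        },
        "phenotypes": {d: ph.value for d, ph in sorted(phenotypes.items())},
        "cross_classes": {k: v.value for k, v in
                          sorted(classify_crosses(usable, phenotypes).items())},
        "misassignment": {
            sex.value: {
                "p_onset_after_cutoff": float(
                    prob_onset_after(onset, sex, config.cutoff_age)),
                "lifetime_incidence": incidence,
                "p_mislabel_unaffected": float(misclassification_prob(
                    onset, sex, config.cutoff_age, incidence)),
                "p_mislabel_unaffected_pct": percent(misclassification_prob(
                    onset, sex, config.cutoff_age, Fraction(incidence)
                    .limit_denominator(10**6))),
            }
            for sex, incidence in ((Sex.MALE, config.incidence_male),
                                   (Sex.FEMALE, config.incidence_female))
        },
    }

    hypo = hypothesis_report(usable, phenotypes, alpha=config.alpha)
    report["conditional_offspring_risk"] = hypo["conditional_offspring_risk"]
    report["modes"] = hypo["modes"]
    for mode in ("recessive", "dominant"):
        key = ("affected_x_carrier" if mode == "recessive"
               else "affected_x_unaffected")
        report["modes"][mode]["narrative"] = _verdict_sentence(
            mode, report["modes"][mode][key], config.alpha)

    if config.json_out:
        Path(config.json_out).write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    if config.text_out:
        Path(config.text_out).write_text(render_tables(report), encoding="utf-8")
    return report


def _format_table(header: list[str], rows: list[list[str]]) -> str:
    widths = [max(len(str(cell)) for cell in col)
              for col in zip(header, *rows)] if rows else [len(h) for h in header]
    def fmt(row: list[str]) -> str:
        return "  ".join(str(cell).ljust(w) for cell, w in zip(row, widths)).rstrip()
    lines = [fmt(header), fmt(["-" * w for w in widths])]
    lines.extend(fmt(row) for row in rows)
    return "\n".join(lines)


def _litter_table(entry: dict) -> str:
    rows = []
    for litter_id, (a, u) in entry["litters"].items():
        n = a + u
        rows.append([
            litter_id, a, u,
            f"{percent(Fraction(a, n))}%" if n else "-",
            f"{percent(Fraction(u, n))}%" if n else "-",
        ])
    a, u = entry["affected"], entry["unaffected"]
    n = a + u
    rows.append([
        "Totals/Means", a, u,
        f"{percent(Fraction(a, n))}%" if n else "-",
        f"{percent(Fraction(u, n))}%" if n else "-",
    ])
    return _format_table(
        ["Litter", "Affected", "Unaffected", "Affected%", "Unaffected%"], rows)


def render_tables(report: dict) -> str:
    """Human-readable rendering: evaluability, per-litter tables, verdicts."""
    ev = report["evaluability"]
    out = [
        f"Pedigree: {report['input']}",
        f"Cutoff age: {report['cutoff_age']} y   alpha: {report['alpha']}",
        f"Dogs: {ev['total_dogs']} total, {ev['usable_dogs']} usable; "
        f"litters: {ev['total_litters']} total, "
        f"{ev['litters_with_evaluable_pups']} with evaluable pups",
        "",
    ]
    risk = report["conditional_offspring_risk"]
    if risk is not None:
        out.append(f"Risk to pups with an affected parent: {percent(Fraction(risk).limit_denominator(10**6))}%")
        out.append("")
    rec = report["modes"]["recessive"]
    out.append("== Single recessive risk factor ==")
    out.append("Obligate carriers: " + (", ".join(rec["obligate_carriers"]) or "none"))
    out.append("Autosomal witnesses (male carriers): "
               + (", ".join(rec["autosomal_witnesses"]) or "none"))
    out.append("Affected x obligate-carrier litters "
               f"(expected affected fraction {rec['affected_x_carrier']['expected_fraction']:.2f}):")
    out.append(_litter_table(rec["affected_x_carrier"]))
    out.append(rec["narrative"])
    out.append("")
    dom = report["modes"]["dominant"]
    out.append("== Single dominant risk factor (high penetrance) ==")
    flags = dom["silent_carrier_flags"]
    out.append("Parent pairs holding >=1 silent carrier: "
               + ("; ".join(" x ".join(p) for p in flags) or "none"))
    out.append("Affected x unaffected litters "
               f"(expected affected fraction {dom['affected_x_unaffected']['expected_fraction']:.2f}):")
    out.append(_litter_table(dom["affected_x_unaffected"]))
    if dom["carrier_flagged_unaff_x_unaff"]["litters"]:
        out.append("Unaffected x unaffected litters with affected pups "
                   "(expected >= 0.50 if one parent carries):")
        out.append(_litter_table(dom["carrier_flagged_unaff_x_unaff"]))
    out.append(dom["narrative"])
    if dom["cannot_rule_out"]:
        out.append("Flag: cannot rule out this mode "
                   "(deficit absorbable by reduced penetrance).")
    out.append("")
    return "\n".join(out)
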