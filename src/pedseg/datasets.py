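"""Packaged fixture data: the two study cohorts and the survey onset table.

The cohort files are reconstructions: litter compositions come from the
published litter tables and ratios, named dogs from the study narrative, and
everything else (ids for anonymous dogs, ages for dogs whose exact age is not
stated, the young unevaluable dogs the age cutoff removes) is synthetic.
See ``data/FIXTURES.md`` for the full provenance of every record.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .onset import OnsetTable
from .pedigree import Pedigree, read_pedigree

__all__ = ["fixture_path", "load_cohort_k", "load_cohort_t", "load_onset_table"]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(resources.files("pedseg").joinpath("data", name)))


def load_cohort_k() -> Pedigree:
    """Family K: 91 dogs in 15 litters (54 usable after the 8.5-y cutoff)."""
    return read_pedigree(fixture_path("cohort_k.csv"))


def load_cohort_t() -> Pedigree:
    """Family T: 104 dogs in 12 litters (56 usable after the 8.5-y cutoff)."""
    return read_pedigree(fixture_path("cohort_t.csv"))


def load_onset_table() -> OnsetTable:
    """2011 breed-survey age-at-diagnosis counts by sex (year bins)."""
    return OnsetTable.from_csv(fixture_path("onset_2011_survey.csv"))
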