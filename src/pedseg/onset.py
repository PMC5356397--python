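"""Age-of-onset tables, censoring arithmetic, and lifetime incidence.

The age-at-diagnosis distribution is kept as binned counts by sex, the form
breed health surveys report: half-open year bins ``(lower, upper]`` with an
open-ended final bin.  From it we get the probability that an affected dog
would only have been diagnosed *after* a phenotyping cutoff age — which,
multiplied by the lifetime incidence, is the probability of mislabeling an
old disease-free dog as unaffected.  All arithmetic is exact rational
(:class:`fractions.Fraction`); rounding to whole percent happens only at the
display layer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

from .pedigree import Sex

__all__ = [
    "OnsetTable",
    "IncidenceInput",
    "cumulative_onset_fraction",
    "prob_onset_after",
    "lifetime_incidence",
    "misclassification_prob",
    "percent",
]


def percent(value: Fraction | float) -> int:
    """Round a fraction to whole percent, half away from zero."""
    frac = Fraction(value) * 100
    if frac >= 0:
        return int((frac * 2 + 1) // 2)
    return -int((-frac * 2 + 1) // 2)


@dataclass(frozen=True)
class OnsetTable:
    """Binned age-at-diagnosis counts by sex.

    ``bin_edges`` are strictly increasing ages in years; bin *i* covers
    ``(bin_edges[i], bin_edges[i+1]]`` and the last bin is open-ended above
    ``bin_edges[-1]``, so counts lists have the same length as the edges.
    """

    bin_edges: tuple[float, ...]
    counts_by_sex: Mapping[Sex, tuple[int, ...]]

    def __post_init__(self) -> None:
        edges = self.bin_edges
        if len(edges) < 1:
            raise ValueError("need at least one bin edge")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        for sex, counts in self.counts_by_sex.items():
            if len(counts) != len(edges):
                raise ValueError(
                    f"{sex}: expected {len(edges)} counts, got {len(counts)}"
                )
            if any(c < 0 for c in counts):
                raise ValueError(f"{sex}: counts must be non-negative")

    def counts(self, sex: Sex) -> tuple[int, ...]:
        try:
            return tuple(self.counts_by_sex[sex])
        except KeyError:
            raise KeyError(f"no onset counts recorded for sex {sex!r}") from None

    def total(self, sex: Sex) -> int:
        return sum(self.counts(sex))

    @classmethod
    def from_csv(cls, path: str | Path) -> "OnsetTable":
        """Read columns bin_low,bin_high,male_count,female_count.

        The last row leaves bin_high empty (open-ended bin); each row's
        bin_low must equal the previous row's bin_high.
        """
        rows: list[tuple[float, float | None, int, int]] = []
        with open(path, newline="", encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.DictReader(fh), start=2):
                high = (row["bin_high"] or "").strip()
                rows.append((
                    float(row["bin_low"]),
                    float(high) if high else None,
                    int(row["male_count"]),
                    int(row["female_count"]),
                ))
        if not rows:
            raise ValueError(f"{path}: no onset bins")
        edges = [rows[0][0]]
        for i, (low, high, _m, _f) in enumerate(rows):
            if low != edges[-1]:
                raise ValueError(f"{path}: bins not contiguous at row {i + 2}")
            if high is not None:
                edges.append(high)
            elif i != len(rows) - 1:
                raise ValueError(f"{path}: only the last bin may be open-ended")
        return cls(
            bin_edges=tuple(edges),
            counts_by_sex={
                Sex.MALE: tuple(r[2] for r in rows),
                Sex.FEMALE: tuple(r[3] for r in rows),
            },
        )

    def to_csv(self, path: str | Path) -> None:
        male = self.counts(Sex.MALE)
        female = self.counts(Sex.FEMALE)
        edges = self.bin_edges
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["bin_low", "bin_high", "male_count", "female_count"])
            for i in range(len(edges)):
                high = edges[i + 1] if i + 1 < len(edges) else ""
                writer.writerow([edges[i], high, male[i], female[i]])


@dataclass(frozen=True)
class IncidenceInput:
    """Affected count out of a surveyed total."""

    affected: int
    total: int

    def __post_init__(self) -> None:
        if self.affected < 0 or self.total <= 0:
            raise ValueError("need affected >= 0 and total > 0")
        if self.affected > self.total:
            raise ValueError("affected cannot exceed total")


def cumulative_onset_fraction(table: OnsetTable, sex: Sex, age: float) -> Fraction:
    """Fraction of affected dogs of ``sex`` diagnosed at or before ``age``.

    Bin-granular: an age interior to a bin resolves to that bin's upper edge
    (the table does not support interpolation without inventing precision).
    """
    edges = table.bin_edges
    if age < edges[0]:
        raise ValueError(f"age {age} precedes the first bin edge {edges[0]}")
    counts = table.counts(sex)
    total = table.total(sex)
    if total == 0:
        raise ValueError(f"no affected dogs of sex {sex} in table")
    if age > edges[-1]:
        return Fraction(1)
    # number of closed bins whose upper edge is <= the enclosing upper edge
    included = sum(1 for upper in edges[1:] if upper < age)
    if age > edges[included]:  # interior: include the enclosing bin
        included += 1
    return Fraction(sum(counts[:included]), total)


def prob_onset_after(table: OnsetTable, sex: Sex, cutoff: float) -> Fraction:
    """P(diagnosis after ``cutoff`` | affected, sex); complements the cumulative."""
    if cutoff < table.bin_edges[0]:
        return Fraction(1)
    return 1 - cumulative_onset_fraction(table, sex, cutoff)


def lifetime_incidence(input: IncidenceInput) -> Fraction:
    """Lifetime disease incidence: affected / total surveyed."""
    return Fraction(input.affected, input.total)


def misclassification_prob(table: OnsetTable, sex: Sex, cutoff: float,
                           incidence: Fraction | float) -> Fraction:
    """P(an undiagnosed dog past ``cutoff`` is wrongly labeled unaffected).

    The product of the probability that an affected dog's onset falls after
    the cutoff and the lifetime incidence for that sex.
    """
    incidence = Fraction(incidence).limit_denominator(10**9)
    if not 0 <= incidence <= 1:
        raise ValueError("incidence must lie in [0, 1]")
    return prob_onset_after(table, sex, cutoff) * incidence


def mean_onset_from_bins(table: OnsetTable, sex: Sex,
                         open_bin_width: float = 1.0) -> float:
    """Bin-midpoint estimate of mean onset age (coarse; for diagnostics only)."""
    edges = table.bin_edges
    counts = table.counts(sex)
    mids: list[float] = []
    for i in range(len(counts)):
        if i + 1 < len(edges):
            mids.append((edges[i] + edges[i + 1]) / 2)
        else:
            mids.append(edges[i] + open_bin_width / 2)
    total = table.total(sex)
    return sum(m * c for m, c in zip(mids, counts)) / total
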