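"""Pedigree data model, I/O, phenotype assignment, and cross classification.

The central object is :class:`Pedigree`: a collection of dogs keyed by id plus
the litters they form.  Phenotypes are assigned relative to an age cutoff
(default 8.5 years): a diagnosed dog is AFFECTED at any age, an undiagnosed
dog is UNAFFECTED only once it has reached the cutoff osteosarcoma-free, and
an undiagnosed dog younger than the cutoff carries no information and is
UNEVALUABLE.  Because the disease is late-onset, this censoring rule is what
makes the downstream segregation arithmetic honest.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

DEFAULT_CUTOFF_AGE = 8.5

__all__ = [
    "DEFAULT_CUTOFF_AGE",
    "Sex",
    "Phenotype",
    "CrossClass",
    "DogRecord",
    "Litter",
    "Pedigree",
    "PedigreeValidationError",
    "read_pedigree",
    "write_pedigree",
    "write_ped",
    "assign_phenotypes",
    "filter_evaluable",
    "classify_crosses",
]


class PedigreeValidationError(ValueError):
    """Raised when a pedigree file or object violates a structural invariant."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Phenotype(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNEVALUABLE = "unevaluable"


class CrossClass(str, enum.Enum):
    """Parental phenotype class of a litter."""

    AFF_X_AFF = "AFFxAFF"
    AFF_X_UNAFF = "AFFxUNAFF"
    UNAFF_X_UNAFF = "UNAFFxUNAFF"
    PARENT_UNKNOWN = "PARENT_UNKNOWN"


@dataclass(frozen=True)
class DogRecord:
    """One individual: identity, parents, sex, and vital/diagnosis data.

    ``age_years`` is age at death for dead dogs and current age for living
    dogs; ``None`` means unknown (allowed only for structural parents that
    appear in the file solely as sire/dam of others).
    """

    id: str
    sire_id: str | None
    dam_id: str | None
    sex: Sex
    diagnosed: bool
    age_years: float | None
    alive: bool

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeValidationError("dog id must be non-empty")
        if self.age_years is not None and self.age_years < 0:
            raise PedigreeValidationError(
                f"dog {self.id!r}: age_years must be >= 0, got {self.age_years}"
            )


@dataclass(frozen=True)
class Litter:
    """A full-sib group: one sire, one dam, at least one pup."""

    litter_id: str
    sire_id: str
    dam_id: str
    pup_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.pup_ids:
            raise PedigreeValidationError(f"litter {self.litter_id!r} has no pups")


@dataclass
class Pedigree:
    """Directed family graph plus its litters; the unit every stage consumes."""

    dogs: dict[str, DogRecord] = field(default_factory=dict)
    litters: list[Litter] = field(default_factory=list)
    cutoff_age: float = DEFAULT_CUTOFF_AGE

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def litter(self, litter_id: str) -> Litter:
        for lit in self.litters:
            if lit.litter_id == litter_id:
                return lit
        raise KeyError(litter_id)

    def parents_of(self, dog_id: str) -> tuple[str | None, str | None]:
        rec = self.dogs[dog_id]
        return rec.sire_id, rec.dam_id

    def parent_ids(self) -> set[str]:
        out: set[str] = set()
        for rec in self.dogs.values():
            out.update(p for p in (rec.sire_id, rec.dam_id) if p)
        for lit in self.litters:
            out.update((lit.sire_id, lit.dam_id))
        return out

    def parent_child_pairs(self) -> Iterable[tuple[str, str]]:
        for rec in self.dogs.values():
            for parent in (rec.sire_id, rec.dam_id):
                if parent:
                    yield parent, rec.id

    def validate(self) -> None:
        seen_litters: set[str] = set()
        for lit in self.litters:
            if lit.litter_id in seen_litters:
                raise PedigreeValidationError(f"duplicate litter id {lit.litter_id!r}")
            seen_litters.add(lit.litter_id)
            for pid in (lit.sire_id, lit.dam_id, *lit.pup_ids):
                if pid not in self.dogs:
                    raise PedigreeValidationError(
                        f"litter {lit.litter_id!r} references unknown dog {pid!r}"
                    )
            for pup in lit.pup_ids:
                rec = self.dogs[pup]
                if rec.sire_id != lit.sire_id or rec.dam_id != lit.dam_id:
                    raise PedigreeValidationError(
                        f"pup {pup!r} of litter {lit.litter_id!r} does not list "
                        f"the litter's sire/dam as its parents"
                    )
        for rec in self.dogs.values():
            for parent, want in ((rec.sire_id, Sex.MALE), (rec.dam_id, Sex.FEMALE)):
                if parent is None:
                    continue
                if parent not in self.dogs:
                    raise PedigreeValidationError(
                        f"dog {rec.id!r} references unknown parent {parent!r}"
                    )
                if self.dogs[parent].sex is not want:
                    role = "sire" if want is Sex.MALE else "dam"
                    raise PedigreeValidationError(
                        f"dog {rec.id!r} lists {parent!r} as {role} but "
                        f"{parent!r} is recorded {self.dogs[parent].sex.value}"
                    )
        graph = nx.DiGraph()
        graph.add_nodes_from(self.dogs)
        graph.add_edges_from(self.parent_child_pairs())
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise PedigreeValidationError(
                f"cyclic ancestry involving {[edge[0] for edge in cycle]}"
            )


# -- I/O -------------------------------------------------------------------

CSV_COLUMNS = ["id", "sire", "dam", "sex", "diagnosed", "age_years", "alive", "litter_id"]

_TRUE = {"1", "true", "yes", "t", "y"}
_FALSE = {"0", "false", "no", "f", "n"}


def _parse_bool(token: str, where: str) -> bool:
    low = token.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise PedigreeValidationError(f"{where}: cannot parse boolean {token!r}")


def _parse_sex(token: str, where: str) -> Sex:
    low = token.strip().lower()
    if low in {"male", "m", "1"}:
        return Sex.MALE
    if low in {"female", "f", "2"}:
        return Sex.FEMALE
    raise PedigreeValidationError(f"{where}: cannot parse sex {token!r}")


def read_pedigree(path: str | Path, format: str = "csv",
                  cutoff_age: float = DEFAULT_CUTOFF_AGE) -> Pedigree:
    """Read a pedigree from the headered CSV dialect (or 6-column LINKAGE PED).

    Dogs appearing only as a sire or dam of others are auto-created with
    unknown age and sex inferred from the parental role, so that founders
    without their own records still anchor the family graph.
    """
    path = Path(path)
    if format == "csv":
        return _read_csv(path, cutoff_age)
    if format == "ped":
        return _read_ped(path, cutoff_age)
    raise ValueError(f"unknown pedigree format {format!r}")


def _read_csv(path: Path, cutoff_age: float) -> Pedigree:
    dogs: dict[str, DogRecord] = {}
    litter_members: dict[str, list[str]] = {}
    litter_parents: dict[str, tuple[str, str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise PedigreeValidationError(f"{path}: empty file (no header)")
        missing = set(CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise PedigreeValidationError(
                f"{path}: missing columns {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            dog_id = (row["id"] or "").strip()
            if not dog_id:
                raise PedigreeValidationError(f"{where}: empty dog id")
            if dog_id in dogs:
                raise PedigreeValidationError(f"{where}: duplicate dog id {dog_id!r}")
            sire = (row["sire"] or "").strip() or None
            dam = (row["dam"] or "").strip() or None
            age_token = (row["age_years"] or "").strip()
            rec = DogRecord(
                id=dog_id,
                sire_id=sire,
                dam_id=dam,
                sex=_parse_sex(row["sex"], where),
                diagnosed=_parse_bool(row["diagnosed"], where),
                age_years=float(age_token) if age_token else None,
                alive=_parse_bool(row["alive"], where),
            )
            dogs[dog_id] = rec
            litter_id = (row["litter_id"] or "").strip()
            if litter_id:
                if sire is None or dam is None:
                    raise PedigreeValidationError(
                        f"{where}: pup {dog_id!r} is in litter {litter_id!r} "
                        f"but lacks a sire or dam"
                    )
                members = litter_members.setdefault(litter_id, [])
                members.append(dog_id)
                prev = litter_parents.setdefault(litter_id, (sire, dam))
                if prev != (sire, dam):
                    raise PedigreeValidationError(
                        f"{where}: litter {litter_id!r} has inconsistent parents "
                        f"({prev} vs {(sire, dam)})"
                    )
    _autocreate_parents(dogs, litter_parents)
    litters = [
        Litter(litter_id=lid, sire_id=litter_parents[lid][0],
               dam_id=litter_parents[lid][1], pup_ids=tuple(litter_members[lid]))
        for lid in litter_members
    ]
    return Pedigree(dogs=dogs, litters=litters, cutoff_age=cutoff_age)


def _autocreate_parents(dogs: dict[str, DogRecord],
                        litter_parents: Mapping[str, tuple[str, str]]) -> None:
    """Create records for dogs referenced only as parents (unknown vitals)."""
    roles: dict[str, Sex] = {}
    for rec in list(dogs.values()):
        if rec.sire_id:
            roles.setdefault(rec.sire_id, Sex.MALE)
        if rec.dam_id:
            roles.setdefault(rec.dam_id, Sex.FEMALE)
    for sire, dam in litter_parents.values():
        roles.setdefault(sire, Sex.MALE)
        roles.setdefault(dam, Sex.FEMALE)
    for pid, sex in roles.items():
        if pid not in dogs:
            dogs[pid] = DogRecord(
                id=pid, sire_id=None, dam_id=None, sex=sex,
                diagnosed=False, age_years=None, alive=False,
            )


def _read_ped(path: Path, cutoff_age: float) -> Pedigree:
    """Read a 6-column LINKAGE PED file (age/censoring information absent).

    Affection code 2 maps to diagnosed; codes 1 and 0 map to undiagnosed with
    unknown age, so phenotype assignment will call them UNEVALUABLE — the PED
    format cannot carry the age data the cutoff rule needs.
    """
    dogs: dict[str, DogRecord] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) < 6:
                raise PedigreeValidationError(
                    f"{path}:{lineno}: expected 6 columns, got {len(tokens)}"
                )
            _family, dog_id, sire, dam, sex_tok, aff = tokens[:6]
            if dog_id in dogs:
                raise PedigreeValidationError(
                    f"{path}:{lineno}: duplicate dog id {dog_id!r}"
                )
            dogs[dog_id] = DogRecord(
                id=dog_id,
                sire_id=None if sire == "0" else sire,
                dam_id=None if dam == "0" else dam,
                sex=_parse_sex(sex_tok, f"{path}:{lineno}"),
                diagnosed=aff == "2",
                age_years=None,
                alive=False,
            )
    _autocreate_parents(dogs, {})
    return Pedigree(dogs=dogs, litters=[], cutoff_age=cutoff_age)


def _fmt_bool(value: bool) -> str:
    return "1" if value else "0"


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    """Write the headered CSV dialect (UTF-8, '.' decimal, empty = unknown)."""
    litter_of: dict[str, str] = {}
    for lit in pedigree.litters:
        for pup in lit.pup_ids:
            litter_of[pup] = lit.litter_id
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in pedigree.dogs.values():
            writer.writerow([
                rec.id,
                rec.sire_id or "",
                rec.dam_id or "",
                rec.sex.value,
                _fmt_bool(rec.diagnosed),
                "" if rec.age_years is None else repr(float(rec.age_years)),
                _fmt_bool(rec.alive),
                litter_of.get(rec.id, ""),
            ])


def write_ped(pedigree: Pedigree, phenotypes: Mapping[str, Phenotype],
              path: str | Path, family_id: str = "FAM1") -> None:
    """Export a 6-column LINKAGE PED file (1/2/0 = unaffected/affected/unknown).

    Age and censoring information is lost on export by design of the format.
    """
    code = {Phenotype.UNAFFECTED: "1", Phenotype.AFFECTED: "2",
            Phenotype.UNEVALUABLE: "0"}
    with open(path, "w", encoding="utf-8") as fh:
        for rec in pedigree.dogs.values():
            fh.write(" ".join([
                family_id,
                rec.id,
                rec.sire_id or "0",
                rec.dam_id or "0",
                "1" if rec.sex is Sex.MALE else "2",
                code[phenotypes[rec.id]],
            ]) + "\n")


# -- phenotype assignment and filtering ------------------------------------

def assign_phenotypes(pedigree: Pedigree, cutoff: float | None = None,
                      strict_deceased_only: bool = False) -> dict[str, Phenotype]:
    """Assign AFFECTED / UNAFFECTED / UNEVALUABLE under the age cutoff.

    A diagnosed dog is AFFECTED regardless of age.  An undiagnosed dog is
    UNAFFECTED once it has reached the cutoff age disease-free — whether alive
    or dead, mirroring the survey convention; pass ``strict_deceased_only`` to
    restrict UNAFFECTED to deceased dogs.  Everything else (young, or of
    unknown age) is UNEVALUABLE.
    """
    cutoff = pedigree.cutoff_age if cutoff is None else cutoff
    if cutoff <= 0:
        # degenerate but well-defined: every undiagnosed dog of known age
        # has already outlived the cutoff
        pass
    out: dict[str, Phenotype] = {}
    for rec in pedigree.dogs.values():
        if rec.diagnosed:
            out[rec.id] = Phenotype.AFFECTED
        elif rec.age_years is not None and rec.age_years >= cutoff and (
                not strict_deceased_only or not rec.alive):
            out[rec.id] = Phenotype.UNAFFECTED
        else:
            out[rec.id] = Phenotype.UNEVALUABLE
    return out


def filter_evaluable(pedigree: Pedigree,
                     phenotypes: Mapping[str, Phenotype]) -> Pedigree:
    """Drop unevaluable pups; keep unevaluable parents as structural nodes.

    Litters left with zero evaluable pups are dropped entirely (with their
    dogs, unless those dogs anchor another litter), reproducing the data loss
    the age cutoff causes in a young pedigree.
    """
    evaluable = {d for d, ph in phenotypes.items() if ph is not Phenotype.UNEVALUABLE}

    new_litters: list[Litter] = []
    for lit in pedigree.litters:
        kept = tuple(p for p in lit.pup_ids if p in evaluable)
        if kept:
            new_litters.append(replace(lit, pup_ids=kept))

    keep: set[str] = set()
    for lit in new_litters:
        keep.update((lit.sire_id, lit.dam_id))
        keep.update(lit.pup_ids)
    # evaluable dogs outside any surviving litter stay: they may be
    # free-standing relatives; ancestors of kept dogs stay as structure
    keep.update(d for d in evaluable if d in pedigree.dogs)
    changed = True
    while changed:
        changed = False
        for d in list(keep):
            rec = pedigree.dogs[d]
            for parent in (rec.sire_id, rec.dam_id):
                if parent and parent not in keep:
                    keep.add(parent)
                    changed = True

    new_dogs = {d: rec for d, rec in pedigree.dogs.items() if d in keep}
    return Pedigree(dogs=new_dogs, litters=new_litters,
                    cutoff_age=pedigree.cutoff_age)


def n_evaluable(phenotypes: Mapping[str, Phenotype]) -> int:
    """Number of dogs carrying a usable (non-censored) phenotype."""
    return sum(1 for ph in phenotypes.values() if ph is not Phenotype.UNEVALUABLE)


def classify_crosses(pedigree: Pedigree,
                     phenotypes: Mapping[str, Phenotype]) -> dict[str, CrossClass]:
    """Classify each litter by its two parental phenotypes."""
    out: dict[str, CrossClass] = {}
    for lit in pedigree.litters:
        ph_sire = phenotypes[lit.sire_id]
        ph_dam = phenotypes[lit.dam_id]
        if Phenotype.UNEVALUABLE in (ph_sire, ph_dam):
            out[lit.litter_id] = CrossClass.PARENT_UNKNOWN
        elif ph_sire is Phenotype.AFFECTED and ph_dam is Phenotype.AFFECTED:
            out[lit.litter_id] = CrossClass.AFF_X_AFF
        elif Phenotype.AFFECTED in (ph_sire, ph_dam):
            out[lit.litter_id] = CrossClass.AFF_X_UNAFF
        else:
            out[lit.litter_id] = CrossClass.UNAFF_X_UNAFF
    return out
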