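"""Pedigrees, genotype tables and per-marker descriptive statistics.

The data model mirrors what multigenerational wild-pedigree mapping studies
work with: a directed acyclic family structure of sexed individuals, and an
individual x microsatellite table of unordered allele pairs with explicit
missingness.  Validation, Mendelian-inconsistency screening and
informative-meiosis accounting live here because every downstream stage
(phasing, two-point analysis, map estimation) assumes clean input.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

#: unordered allele pair; stored sorted so a/b == b/a
Genotype = tuple


@dataclass(frozen=True)
class Individual:
    """One pedigree member; ``sire_id``/``dam_id`` are ``None`` for founders."""

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = UNKNOWN
    population: str = "pop"


class Pedigree:
    """A set of individuals linked by parent -> offspring edges.

    Parent references may point at individuals of unknown sex; referencing a
    female as sire (or male as dam), a missing individual, or creating an
    ancestry cycle is a structural violation reported by
    :func:`validate_pedigree`.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        self._offspring: dict[str, list[str]] = defaultdict(list)
        for ind in self.individuals.values():
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None:
                    self._offspring[pid].append(ind.id)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.individuals

    def __iter__(self):
        return iter(self.individuals.values())

    def offspring_of(self, parent_id: str) -> list[str]:
        return list(self._offspring.get(parent_id, []))

    @property
    def paternal_links(self) -> int:
        return sum(1 for i in self if i.sire_id is not None)

    @property
    def maternal_links(self) -> int:
        return sum(1 for i in self if i.dam_id is not None)

    def sire_offspring_counts(self) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for i in self:
            if i.sire_id is not None:
                out[i.sire_id] += 1
        return dict(out)

    def dam_offspring_counts(self) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for i in self:
            if i.dam_id is not None:
                out[i.dam_id] += 1
        return dict(out)

    def founders(self) -> list[Individual]:
        return [i for i in self if i.sire_id is None and i.dam_id is None]

    def populations(self) -> list[str]:
        return sorted({i.population for i in self})


class GenotypeTable:
    """Unordered allele-pair calls for (individual, marker) cells.

    Missing calls are simply absent from ``calls`` — no sentinel alleles.
    Alleles may be any hashable, orderable labels (microsatellite fragment
    sizes in practice).
    """

    def __init__(self, markers: Iterable[str],
                 calls: Mapping[tuple[str, str], Genotype] | None = None):
        self.markers: list[str] = list(markers)
        self._marker_set = set(self.markers)
        if len(self._marker_set) != len(self.markers):
            raise ValueError("duplicate marker labels")
        self.calls: dict[tuple[str, str], Genotype] = {}
        if calls:
            for (ind, marker), gt in calls.items():
                self.set(ind, marker, gt)

    def set(self, ind: str, marker: str, genotype: Genotype | None) -> None:
        if marker not in self._marker_set:
            raise KeyError(f"unknown marker {marker!r}")
        key = (ind, marker)
        if genotype is None:
            self.calls.pop(key, None)
            return
        a, b = genotype
        self.calls[key] = (a, b) if not b < a else (b, a)

    def get(self, ind: str, marker: str) -> Genotype | None:
        return self.calls.get((ind, marker))

    def individuals(self) -> list[str]:
        return sorted({ind for ind, _ in self.calls})

    def alleles(self, marker: str) -> list:
        seen = set()
        for (_, m), gt in self.calls.items():
            if m == marker:
                seen.update(gt)
        return sorted(seen)

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(self.markers, dict(self.calls))


@dataclass
class MarkerSummary:
    """Descriptive statistics for one marker in one pedigree."""

    marker: str
    typing_success: float
    n_alleles: int
    obs_het: float
    info_meioses_female: int
    info_meioses_male: int
    info_meioses_total: int


@dataclass
class Violation:
    """One pedigree-invariant violation (data, not an exception)."""

    individual: str
    rule: str
    detail: str = ""


# ---------------------------------------------------------------------------
# validation & Mendelian screening


def validate_pedigree(pedigree: Pedigree) -> list[Violation]:
    """Report every structural violation: dangling or sex-conflicting parent
    references and ancestry cycles.  Empty list iff the pedigree is valid."""
    out: list[Violation] = []
    for ind in pedigree:
        for role, pid, wrong_sex in (("sire", ind.sire_id, FEMALE),
                                     ("dam", ind.dam_id, MALE)):
            if pid is None:
                continue
            if pid not in pedigree:
                out.append(Violation(ind.id, "missing-parent",
                                     f"{role} {pid} not in pedigree"))
            elif pedigree.individuals[pid].sex == wrong_sex:
                out.append(Violation(ind.id, "sex-role conflict",
                                     f"{role} {pid} is {wrong_sex}"))
    # cycle detection on parent -> offspring edges (self-ancestry included)
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(node: str, stack: list[str]) -> None:
        state[node] = 0
        stack.append(node)
        for child in pedigree.offspring_of(node):
            if child not in pedigree:
                continue
            s = state.get(child)
            if s is None:
                visit(child, stack)
            elif s == 0:
                cyc = stack[stack.index(child):] + [child]
                out.append(Violation(child, "cycle", "->".join(cyc)))
        stack.pop()
        state[node] = 1

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(pedigree) + 100))
    try:
        for ind in pedigree:
            if ind.id not in state:
                visit(ind.id, [])
    finally:
        sys.setrecursionlimit(old)
    return out


def transmitted_allele(parent_gt: Genotype,
                       other_gt: Genotype | None,
                       off_gt: Genotype):
    """Allele transmitted by ``parent`` to the offspring, or ``None``.

    The transmitted allele is determined when exactly one assignment of the
    offspring's two alleles to {this parent, other parent} is compatible with
    the parents' genotypes.  An untyped other parent constrains nothing.
    """
    x, y = off_gt
    feasible = set()
    for t, o in ((x, y), (y, x)):
        if t in parent_gt and (other_gt is None or o in other_gt):
            feasible.add(t)
    if len(feasible) == 1:
        return next(iter(feasible))
    return None


@dataclass
class MendelianRecord:
    individual: str
    marker: str
    parents: tuple[str, ...]
    kind: str  # "duo" or "trio"


def mendelian_check(pedigree: Pedigree,
                    genotypes: GenotypeTable) -> list[MendelianRecord]:
    """Level-1 Mendelian screening.

    Duo rule: a typed parent-offspring pair sharing no allele is flagged.
    Trio rule: when both parents are typed and no duo conflict exists, the
    offspring genotype must be formable from one allele of each parent.
    Missing calls never trigger records.
    """
    for (ind, _m) in genotypes.calls:
        if ind not in pedigree:
            raise ValueError(f"genotype table references unknown individual {ind!r}")
    out: list[MendelianRecord] = []
    for ind in pedigree:
        for marker in genotypes.markers:
            off = genotypes.get(ind.id, marker)
            if off is None:
                continue
            sire = genotypes.get(ind.sire_id, marker) if ind.sire_id else None
            dam = genotypes.get(ind.dam_id, marker) if ind.dam_id else None
            duo_bad = []
            for pid, pgt in ((ind.sire_id, sire), (ind.dam_id, dam)):
                if pgt is not None and not (set(off) & set(pgt)):
                    duo_bad.append(pid)
            if duo_bad:
                out.append(MendelianRecord(ind.id, marker, tuple(duo_bad), "duo"))
                continue
            if sire is not None and dam is not None:
                x, y = off
                ok = any(t in sire and o in dam for t, o in ((x, y), (y, x)))
                if not ok:
                    out.append(MendelianRecord(
                        ind.id, marker, (ind.sire_id, ind.dam_id), "trio"))
    return out


def delete_inconsistent(genotypes: GenotypeTable,
                        records: list[MendelianRecord]) -> GenotypeTable:
    """Remove every genotype involved in a flagged inconsistency (offspring
    and implicated parents).  Flag-and-delete is the only correction offered."""
    table = genotypes.copy()
    for rec in records:
        table.set(rec.individual, rec.marker, None)
        for pid in rec.parents:
            if pid is not None and table.get(pid, rec.marker) is not None:
                table.set(pid, rec.marker, None)
    return table


# ---------------------------------------------------------------------------
# marker statistics


def count_informative_meioses(pedigree: Pedigree, genotypes: GenotypeTable,
                              marker: str) -> tuple[int, int]:
    """(female, male) informative-meiosis counts for one marker.

    A parent -> offspring transmission is informative when the parent is
    typed and heterozygous and the transmitted allele is uniquely resolvable
    from the offspring genotype (using the other parent's genotype when
    needed).  Sex-unknown parents are excluded from both sex-specific counts
    (callers wanting totals add them via :func:`marker_summary`).
    """
    counts = {FEMALE: 0, MALE: 0, UNKNOWN: 0}
    for parent_id, parent_sex, other_id, off_id in _transmissions(pedigree):
        pgt = genotypes.get(parent_id, marker)
        if pgt is None or pgt[0] == pgt[1]:
            continue
        off = genotypes.get(off_id, marker)
        if off is None:
            continue
        other = genotypes.get(other_id, marker) if other_id else None
        if transmitted_allele(pgt, other, off) is not None:
            counts[parent_sex] += 1
    return counts[FEMALE], counts[MALE]


def _transmissions(pedigree: Pedigree):
    """Yield (parent_id, parent_sex, other_parent_id, offspring_id)."""
    for ind in pedigree:
        if ind.sire_id is not None:
            sex = pedigree.individuals[ind.sire_id].sex if ind.sire_id in pedigree else UNKNOWN
            yield ind.sire_id, sex, ind.dam_id, ind.id
        if ind.dam_id is not None:
            sex = pedigree.individuals[ind.dam_id].sex if ind.dam_id in pedigree else UNKNOWN
            yield ind.dam_id, sex, ind.sire_id, ind.id


def marker_summary(pedigree: Pedigree, genotypes: GenotypeTable,
                   marker: str) -> MarkerSummary:
    """Typing success, allele count, observed heterozygosity and
    informative-meiosis counts for ``marker`` over all pedigree members."""
    if marker not in genotypes._marker_set:
        raise KeyError(f"marker {marker!r} not in genotype table")
    n_total = len(pedigree)
    typed = [genotypes.get(i.id, marker) for i in pedigree]
    typed = [g for g in typed if g is not None]
    n_typed = len(typed)
    het = sum(1 for g in typed if g[0] != g[1])
    alleles = {a for g in typed for a in g}
    fem, mal = count_informative_meioses(pedigree, genotypes, marker)
    # sex-unknown parents count toward the total only
    unk = 0
    for parent_id, parent_sex, other_id, off_id in _transmissions(pedigree):
        if parent_sex != UNKNOWN:
            continue
        pgt = genotypes.get(parent_id, marker)
        off = genotypes.get(off_id, marker)
        if pgt is None or off is None or pgt[0] == pgt[1]:
            continue
        other = genotypes.get(other_id, marker) if other_id else None
        if transmitted_allele(pgt, other, off) is not None:
            unk += 1
    return MarkerSummary(
        marker=marker,
        typing_success=n_typed / n_total if n_total else 0.0,
        n_alleles=len(alleles),
        obs_het=het / n_typed if n_typed else 0.0,
        info_meioses_female=fem,
        info_meioses_male=mal,
        info_meioses_total=fem + mal + unk,
    )


def summarize_markers(pedigree: Pedigree,
                      genotypes: GenotypeTable) -> list[MarkerSummary]:
    return [marker_summary(pedigree, genotypes, m) for m in genotypes.markers]
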