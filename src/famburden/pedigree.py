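"""Pedigree data model, generation assignment, and Mendelian consistency checks.

A pedigree is a small directed acyclic graph of individuals linked by
parent-child edges.  Founders (no in-pedigree parents) sit at generation 1;
every child sits one generation below its deepest in-pedigree parent.
Marry-ins — spouses without a consanguineous path to the probands — carry no
shared genetic material and are excluded from burden scoring via
:func:`blood_relatives`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .panel import GenotypeMatrix


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


# PLINK PED/FAM dialect codes
_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree file or object."""


@dataclass(frozen=True)
class Individual:
    id: str
    sex: Sex = Sex.UNKNOWN
    father_id: str | None = None
    mother_id: str | None = None
    affected: bool = False
    notes: str = ""

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def partial_parentage(self) -> bool:
        """Exactly one parent link present (the other parent is unrecorded)."""
        return (self.father_id is None) != (self.mother_id is None)


@dataclass
class Pedigree:
    """Ordered collection of :class:`Individual` sharing one family id."""

    family_id: str
    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        self._check_links()
        self._check_acyclic()

    def _check_links(self) -> None:
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeError(
                        f"{ind.id}: parent {pid!r} referenced but not present "
                        "(use '0' for an unknown parent or declare it external)"
                    )

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 = in progress, 1 = done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(
                    f"cycle detected in pedigree: {' -> '.join(stack + [iid])}"
                )
            state[iid] = 0
            ind = self._by_id[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid, stack + [iid])
            state[iid] = 1

        for ind in self.individuals:
            visit(ind.id, [])

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        ind = self._by_id[iid]
        return ind.father_id, ind.mother_id

    def ancestors(self, iid: str) -> frozenset[str]:
        """All in-pedigree ancestors of ``iid``, including ``iid`` itself."""
        out: set[str] = set()
        stack = [iid]
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            ind = self._by_id[cur]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    stack.append(pid)
        return frozenset(out)

    def full_sib_pairs(self) -> list[tuple[str, str]]:
        """Pairs of individuals sharing both in-pedigree parents."""
        by_parents: dict[tuple[str, str], list[str]] = {}
        for ind in self.individuals:
            if ind.father_id is not None and ind.mother_id is not None:
                by_parents.setdefault((ind.father_id, ind.mother_id), []).append(ind.id)
        pairs = []
        for sibs in by_parents.values():
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    pairs.append((sibs[i], sibs[j]))
        return pairs

    def write_ped(self, path: str | Path) -> None:
        lines = []
        for ind in self.individuals:
            pheno = "2" if ind.affected else "1"
            lines.append(
                "\t".join(
                    [
                        self.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_OUT[ind.sex],
                        pheno,
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")


def load_pedigree(path: str | Path, family_id: str | None = None) -> Pedigree:
    """Read a whitespace-delimited PED/FAM-dialect file.

    Columns: family id, individual id, father id, mother id, sex code,
    phenotype code.  ``0`` marks an unknown parent; sex codes are 1=male,
    2=female, 0=unknown; phenotype 2=affected, 1=unaffected, 0/-9=unknown.
    """
    individuals: list[Individual] = []
    fam: str | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
        fid, iid, fat, mot, sex, pheno = fields[:6]
        if family_id is not None and fid != family_id:
            continue
        if fam is None:
            fam = fid
        elif fid != fam:
            raise PedigreeError(
                f"{path}:{lineno}: multiple family ids ({fam!r}, {fid!r}); "
                "pass family_id= to select one"
            )
        if fat == iid or mot == iid:
            raise PedigreeError(f"{path}:{lineno}: {iid} listed as its own parent")
        individuals.append(
            Individual(
                id=iid,
                sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                father_id=None if fat == "0" else fat,
                mother_id=None if mot == "0" else mot,
                affected=pheno == "2",
            )
        )
    if not individuals:
        raise PedigreeError(f"{path}: no pedigree rows found")
    return Pedigree(family_id=fam or "FAM", individuals=individuals)


def assign_generations(ped: Pedigree) -> dict[str, int]:
    """Ordinal generation per individual: founders = 1, child = max(parents) + 1.

    A child with a single in-pedigree parent sits one generation below that
    parent.  Deterministic and independent of input row order.
    """
    memo: dict[str, int] = {}

    def gen(iid: str) -> int:
        if iid in memo:
            return memo[iid]
        ind = ped[iid]
        parents = [p for p in (ind.father_id, ind.mother_id) if p is not None]
        g = 1 if not parents else max(gen(p) for p in parents) + 1
        memo[iid] = g
        return g

    for ind in ped:
        gen(ind.id)
    return {iid: memo[iid] for iid in ped.ids}


def blood_relatives(ped: Pedigree, proband_set: Iterable[str]) -> Pedigree:
    """Subset of ``ped`` consanguineous with at least one proband.

    An individual is retained iff it shares an in-pedigree common ancestor
    (counting itself) with some proband — the standard consanguinity
    criterion.  It keeps ancestors, descendants and collateral relatives while
    excluding marry-ins, whose ancestor sets are disjoint from the probands'.
    A spouse who also has a blood path to a proband (e.g. a cousin marriage)
    is retained.  Parent links pointing outside the subset are cleared.
    """
    probands = list(proband_set)
    if not probands:
        raise PedigreeError("proband set must be non-empty")
    for p in probands:
        if p not in ped:
            raise PedigreeError(f"unknown proband id {p!r}")
    proband_anc: set[str] = set()
    for p in probands:
        proband_anc |= ped.ancestors(p)
    keep = {ind.id for ind in ped if ped.ancestors(ind.id) & proband_anc}
    subset = []
    for ind in ped:
        if ind.id not in keep:
            continue
        fat = ind.father_id if ind.father_id in keep else None
        mot = ind.mother_id if ind.mother_id in keep else None
        if fat != ind.father_id or mot != ind.mother_id:
            ind = replace(ind, father_id=fat, mother_id=mot)
        subset.append(ind)
    return Pedigree(family_id=ped.family_id, individuals=subset)


@dataclass(frozen=True)
class MendelianViolation:
    individual_id: str
    rsid: str
    child_gt: str
    father_gt: str
    mother_gt: str
    reason: str = "child genotype incompatible with parental genotypes"


def _gt_str(call: tuple[str, str] | None) -> str:
    return "./." if call is None else "/".join(call)


def _compatible(
    child: tuple[str, str],
    father: tuple[str, str] | None,
    mother: tuple[str, str] | None,
) -> bool:
    """True iff one allele from each (known) parent can produce the child."""
    a, b = child
    for x, y in ((a, b), (b, a)):
        ok_f = father is None or x in father
        ok_m = mother is None or y in mother
        if ok_f and ok_m:
            return True
    return False


def check_mendelian(ped: Pedigree, gm: "GenotypeMatrix") -> list[MendelianViolation]:
    """Flag (child, snp) pairs where no parental gamete pair yields the child.

    Each snp is treated independently (no linkage phasing).  Missing
    genotypes — in the child or a parent — are never flagged; an absent
    parent constrains nothing.
    """
    for sample in gm.samples:
        if sample not in ped:
            raise PedigreeError(f"genotyped sample {sample!r} absent from pedigree")
    violations: list[MendelianViolation] = []
    for ind in ped:
        if ind.id not in gm.sample_index:
            continue
        fat = ind.father_id if ind.father_id in gm.sample_index else None
        mot = ind.mother_id if ind.mother_id in gm.sample_index else None
        if fat is None and mot is None:
            continue
        for rsid in gm.rsids:
            child = gm.call(ind.id, rsid)
            if child is None:
                continue
            f = gm.call(fat, rsid) if fat else None
            m = gm.call(mot, rsid) if mot else None
            if f is None and m is None:
                continue
            if not _compatible(child, f, m):
                violations.append(
                    MendelianViolation(
                        individual_id=ind.id,
                        rsid=rsid,
                        child_gt=_gt_str(child),
                        father_gt=_gt_str(f),
                        mother_gt=_gt_str(m),
                    )
                )
    return violations


def violations_to_tsv(violations: Sequence[MendelianViolation], path: str | Path) -> None:
    header = "individual_id\trsid\tchild_gt\tfather_gt\tmother_gt\treason"
    rows = [
        f"{v.individual_id}\t{v.rsid}\t{v.child_gt}\t{v.father_gt}\t{v.mother_gt}\t{v.reason}"
        for v in violations
    ]
    Path(path).write_text("\n".join([header] + rows) + "\n")
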