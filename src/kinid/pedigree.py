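"""Pedigree data model and exact relationship arithmetic.

A :class:`Pedigree` is a directed acyclic graph of individuals with sexed
parent links.  On top of it this module provides the classical quantities of
relationship testing:

* the kinship coefficient phi(a, b) — the probability that one allele drawn
  at random from each of *a* and *b* is identical by descent — computed by
  the standard founder recursion in exact rational arithmetic;
* meiosis-path counting (optionally restricted to patrilineal or
  matrilineal transmissions), the quantity that governs lineage-marker
  mutation opportunity;
* the forensic degree-of-relatedness label of the closest connecting path;
* canonical non-inbred Cotterman IBD coefficient triples (k0, k1, k2) for
  the eight relationship categories used in pairwise kinship prediction.

Pedigrees with multiple connecting paths (pedigree collapse, e.g. through a
cross-cousin marriage) are fully supported: phi automatically accumulates
every path, while degree labels deliberately reflect only the closest one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, Iterator, Optional, Tuple

from .errors import DisconnectedError, UnknownIdentifierError

__all__ = [
    "Individual",
    "Pedigree",
    "RelationshipCategory",
    "CATEGORY_LABELS",
    "CATEGORIES",
    "category_ibd_coefficients",
    "kinship_coefficient",
    "meiosis_path_count",
    "degree_of_relatedness",
    "read_ped",
    "write_ped",
]

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_CODE = {1: MALE, 2: FEMALE, 0: UNKNOWN}
_CODE_SEX = {MALE: 1, FEMALE: 2, UNKNOWN: 0}


@dataclass(frozen=True)
class Individual:
    """One pedigree member with optional parent links."""

    id: str
    sex: str = UNKNOWN
    father: Optional[str] = None
    mother: Optional[str] = None

    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class Pedigree:
    """A named, validated collection of :class:`Individual` records.

    Validation enforces referential integrity, parental sexes and
    acyclicity on construction and after every :meth:`add`.
    """

    def __init__(self, members: Iterable[Individual] = (), name: str = "pedigree"):
        self.name = name
        self._members: Dict[str, Individual] = {}
        for ind in members:
            self._members[ind.id] = ind
        self._validate()

    # -- container protocol -------------------------------------------------

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self._members[iid]
        except KeyError:
            raise UnknownIdentifierError(iid) from None

    @property
    def ids(self):
        return list(self._members)

    def add(self, ind: Individual) -> None:
        self._members[ind.id] = ind
        self._validate()

    # -- structure ----------------------------------------------------------

    def parents(self, iid: str) -> Tuple[Optional[str], Optional[str]]:
        ind = self[iid]
        return ind.father, ind.mother

    def founders(self):
        return [i.id for i in self if i.is_founder()]

    def members_with_sex(self, sex: str):
        return [i.id for i in self if i.sex == sex]

    def depth(self, iid: str) -> int:
        """Generation index: 0 for founders, 1 + max(parent depths) otherwise."""
        ind = self[iid]
        if ind.is_founder():
            return 0
        return 1 + max(
            self.depth(p) for p in (ind.father, ind.mother) if p is not None
        )

    def topological_order(self):
        """Members ordered so that parents precede children."""
        return sorted(self.ids, key=self.depth)

    def ancestors(self, iid: str) -> set:
        """All strict ancestors of ``iid``."""
        out: set = set()
        stack = [p for p in self.parents(iid) if p is not None]
        while stack:
            a = stack.pop()
            if a in out:
                continue
            out.add(a)
            stack.extend(p for p in self.parents(a) if p is not None)
        return out

    def couples(self) -> set:
        """Unordered (father, mother) pairs that have a common child."""
        out = set()
        for ind in self:
            if ind.father is not None and ind.mother is not None:
                out.add((ind.father, ind.mother))
        return out

    def subset_to_ancestors_of(self, ids: Iterable[str]) -> "Pedigree":
        """Restriction to ``ids`` and their ancestors (closed under parents)."""
        keep: set = set()
        for iid in ids:
            self[iid]  # raise on unknown
            keep.add(iid)
            keep |= self.ancestors(iid)
        # preserve the parent pedigree's member order so downstream seeded
        # simulations are reproducible across processes
        return Pedigree(
            [m for m in self if m.id in keep], name=self.name
        )

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        for ind in self:
            for parent, want in ((ind.father, MALE), (ind.mother, FEMALE)):
                if parent is None:
                    continue
                if parent not in self._members:
                    raise UnknownIdentifierError(
                        f"{ind.id}: parent {parent!r} not in pedigree"
                    )
                psex = self._members[parent].sex
                if psex != UNKNOWN and psex != want:
                    raise ValueError(
                        f"{ind.id}: parent {parent!r} has sex {psex}, expected {want}"
                    )
        # acyclicity: an individual may never be its own ancestor
        for ind in self:
            if ind.id in self.ancestors(ind.id):
                raise ValueError(f"cycle through {ind.id!r}")


# ---------------------------------------------------------------------------
# relationship categories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelationshipCategory:
    """A relationship label with its canonical IBD coefficient triple."""

    label: str
    k: Tuple[float, float, float]

    def __post_init__(self):
        if abs(sum(self.k) - 1.0) > 1e-12:
            raise ValueError(f"k-triple must sum to 1: {self.k}")

    @property
    def expected_ibd_share(self) -> float:
        """k1/2 + k2 — the expected genome fraction shared, equal to 2*phi."""
        return self.k[1] / 2 + self.k[2]


# the eight categories of pairwise kinship prediction, closest first
_K_TRIPLES = {
    "self": (0.0, 0.0, 1.0),
    "parent-child": (0.0, 1.0, 0.0),
    "full-siblings": (0.25, 0.5, 0.25),
    "degree2": (0.5, 0.5, 0.0),
    "degree3": (0.75, 0.25, 0.0),
    "degree4": (0.875, 0.125, 0.0),
    "degree5": (0.9375, 0.0625, 0.0),
    "unrelated": (1.0, 0.0, 0.0),
}

CATEGORY_LABELS = list(_K_TRIPLES)
CATEGORIES = [RelationshipCategory(lbl, k) for lbl, k in _K_TRIPLES.items()]


def category_ibd_coefficients(label: str) -> Tuple[float, float, float]:
    """Canonical non-inbred Cotterman (k0, k1, k2) for a category label."""
    try:
        return _K_TRIPLES[label]
    except KeyError:
        raise ValueError(f"unknown relationship category {label!r}") from None


# ---------------------------------------------------------------------------
# kinship coefficient
# ---------------------------------------------------------------------------

# Above this size exact rationals get slow; fall back to floats.
_EXACT_LIMIT = 64


def kinship_coefficient(ped: Pedigree, a: str, b: str):
    """Kinship coefficient phi(a, b) by the founder recursion.

    phi(x, x) = (1 + F_x) / 2 with F_x = phi(father_x, mother_x); for a != b
    the individual of greater generation depth is replaced by the average
    over its parents.  Returns a :class:`fractions.Fraction` for pedigrees
    of at most 64 members, a float above that.
    """
    ped[a], ped[b]  # raise on unknown ids
    exact = len(ped) <= _EXACT_LIMIT
    zero = Fraction(0) if exact else 0.0
    half = Fraction(1, 2) if exact else 0.5
    depth = {i: ped.depth(i) for i in ped.ids}
    cache: Dict[Tuple[str, str], object] = {}

    def phi(x: Optional[str], y: Optional[str]):
        if x is None or y is None:
            return zero
        key = (x, y) if x <= y else (y, x)
        if key in cache:
            return cache[key]
        if x == y:
            f, m = ped.parents(x)
            val = half * (1 + phi(f, m))
        else:
            # recurse through the parents of the deeper individual
            if depth[x] < depth[y]:
                x, y = y, x
            f, m = ped.parents(x)
            if f is None and m is None:
                val = zero
            else:
                val = half * (phi(f, y) + phi(m, y))
        cache[key] = val
        return val

    return phi(a, b)


# ---------------------------------------------------------------------------
# meiosis paths and degrees
# ---------------------------------------------------------------------------


def _ancestor_distances(ped: Pedigree, iid: str, lineage: str) -> Dict[str, int]:
    """Minimal meiosis counts from ``iid`` up to each of its ancestors.

    ``lineage`` restricts which parental edges may be traversed:
    ``"patrilineal"`` climbs only father links, ``"matrilineal"`` only
    mother links, ``"any"`` both.  The individual itself appears at 0.
    """
    dist = {iid: 0}
    frontier = [iid]
    while frontier:
        nxt = []
        for x in frontier:
            f, m = ped.parents(x)
            ups = []
            if lineage in ("any", "patrilineal") and f is not None:
                ups.append(f)
            if lineage in ("any", "matrilineal") and m is not None:
                ups.append(m)
            for p in ups:
                d = dist[x] + 1
                if p not in dist or d < dist[p]:
                    dist[p] = d
                    nxt.append(p)
        frontier = nxt
    return dist


def meiosis_path_count(ped: Pedigree, a: str, b: str, lineage: str = "any") -> int:
    """Meiosis count of the shortest path connecting ``a`` and ``b``.

    The path climbs from each individual to a common ancestor (respecting
    the lineage filter: for ``patrilineal`` every edge on the path is a
    father-child transmission) and its length is the total number of
    parent-to-child transmissions it crosses.
    """
    if lineage not in ("any", "patrilineal", "matrilineal"):
        raise ValueError(f"unknown lineage filter {lineage!r}")
    da = _ancestor_distances(ped, a, lineage)
    db = _ancestor_distances(ped, b, lineage)
    common = set(da) & set(db)
    if not common:
        raise DisconnectedError(
            f"no {lineage} path connects {a!r} and {b!r} in {ped.name}"
        )
    return min(da[c] + db[c] for c in common)


def degree_of_relatedness(ped: Pedigree, a: str, b: str) -> str:
    """Forensic degree label of the *closest* connecting path.

    Degree equals the meiosis count of the shortest path; a relationship
    running through both members of a mated couple (a "full" relationship,
    e.g. full siblings or a full uncle) counts one degree less than its
    meioses, per the standard forensic degree tables.  Parent-child and
    full siblings receive their dedicated labels.  Secondary paths created
    by pedigree collapse are deliberately ignored here — they raise phi,
    not the genealogical degree.
    """
    if a == b:
        ped[a]
        return "self"
    da = _ancestor_distances(ped, a, "any")
    db = _ancestor_distances(ped, b, "any")
    common = set(da) & set(db)
    if not common:
        return "unrelated"
    m = min(da[c] + db[c] for c in common)
    minimal = {c: (da[c], db[c]) for c in common if da[c] + db[c] == m}
    # full relationship: both members of a couple sit at the same minimal
    # (up, down) split, giving two parallel closest paths
    full = any(
        f in minimal and mo in minimal and minimal[f] == minimal[mo]
        for f, mo in ped.couples()
    )
    if m == 1:
        return "parent-child"
    if m == 2 and full and a not in db and b not in da:
        return "full-siblings"
    degree = m - 1 if full else m
    return f"degree{degree}"


# ---------------------------------------------------------------------------
# PED-like file IO
# ---------------------------------------------------------------------------


def read_ped(path) -> Pedigree:
    """Read a tab-separated PED-like file.

    Columns: family, id, father (0 = missing), mother (0), sex
    (1 = male, 2 = female, 0 = unknown).  Lines starting with ``#`` are
    comments.  The family column of the first record names the pedigree.
    """
    members = []
    name = "pedigree"
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fam, iid, father, mother, sex = line.split("\t")[:5]
        name = fam
        members.append(
            Individual(
                id=iid,
                sex=_SEX_CODE[int(sex)],
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
            )
        )
    return Pedigree(members, name=name)


def write_ped(ped: Pedigree, path) -> None:
    """Write a pedigree in the tab-separated PED-like format of :func:`read_ped`."""
    lines = []
    for iid in ped.topological_order():
        ind = ped[iid]
        lines.append(
            "\t".join(
                [
                    ped.name,
                    ind.id,
                    ind.father or "0",
                    ind.mother or "0",
                    str(_CODE_SEX[ind.sex]),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
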