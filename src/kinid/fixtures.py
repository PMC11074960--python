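"""Bundled study pedigrees.

The Washington pedigree encodes the genealogy connecting the living
reference donor S.W.W. to the three Harewood Cemetery burials, restricted
to documented edges:

* Samuel Washington and John Augustine Washington are full brothers, sons
  of one founder couple;
* burial B (Dr. Samuel Walter Washington) is a patrilineal grandson of
  Samuel via George Steptoe Washington Sr.; burial 3 (George Steptoe
  Washington Jr.) is his full brother; burial 4 (Lucy Payne) is their
  mother;
* Christian Maria Washington, a daughter of burial B, married Richard
  Scott Blackburn Washington, a patrilineal great-grandson of John
  Augustine — the cross-cousin marriage that collapses the pedigree;
* S.W.W. descends from that union through a three-generation patriline,
  placing him six patrilineal generations below John Augustine.

Consequences built into the fixture: the closest path makes burial B
S.W.W.'s great-great-grandfather (4th degree), burial 3 his
great-great-great-uncle (5th degree) and Lucy Payne his
great-great-great-grandmother (5th degree); the patrilineal path between
S.W.W. and burial B crosses 10 meioses; the secondary path through the
founder couple raises phi for both male burials but not for Lucy Payne.
Unstated spouses are distinct founders.
"""

from __future__ import annotations

from importlib import resources

from .pedigree import FEMALE, MALE, Individual, Pedigree, read_ped

__all__ = [
    "washington_pedigree",
    "washington_ped_path",
    "lineal_pedigree",
    "avuncular_pedigree",
    "sibling_pedigree",
    "BURIAL_B",
    "BURIAL_3",
    "BURIAL_4",
    "SWW",
]

BURIAL_B = "BurialB"   # Dr. Samuel Walter Washington
BURIAL_3 = "Burial3"   # George Steptoe Washington Jr.
BURIAL_4 = "LucyPayne" # burial 4
SWW = "SWW"            # living reference donor


def washington_pedigree() -> Pedigree:
    """The collapsed Washington fixture pedigree (see module docstring)."""

    def m(iid, father=None, mother=None):
        return Individual(iid, MALE, father, mother)

    def f(iid, father=None, mother=None):
        return Individual(iid, FEMALE, father, mother)

    members = [
        # founder couple at the top of both Washington branches
        m("Augustine"),
        f("AugustineWife"),
        m("Samuel", "Augustine", "AugustineWife"),
        m("JohnAugustine", "Augustine", "AugustineWife"),
        # Samuel's branch down to the burials
        f("SamuelWife"),
        m("GeorgeSteptoeSr", "Samuel", "SamuelWife"),
        f(BURIAL_4),
        m(BURIAL_3, "GeorgeSteptoeSr", BURIAL_4),
        m(BURIAL_B, "GeorgeSteptoeSr", BURIAL_4),
        f("BurialBWife"),
        f("ChristianMaria", BURIAL_B, "BurialBWife"),
        # John Augustine's patriline down to Richard Scott Blackburn W.
        f("JohnAugustineWife"),
        m("JA2", "JohnAugustine", "JohnAugustineWife"),
        f("JA2Wife"),
        m("JA3", "JA2", "JA2Wife"),
        f("JA3Wife"),
        m("RichardScottBlackburn", "JA3", "JA3Wife"),
        # the cross-cousin union and the patriline to S.W.W.
        m("SWWGrandfather", "RichardScottBlackburn", "ChristianMaria"),
        f("SWWGrandmother"),
        m("SWWFather", "SWWGrandfather", "SWWGrandmother"),
        f("SWWMother"),
        m(SWW, "SWWFather", "SWWMother"),
    ]
    return Pedigree(members, name="Washington")


def washington_ped_path():
    """Path to the bundled PED-format copy of the Washington fixture."""
    return resources.files("kinid.data") / "washington.ped"


def lineal_pedigree(degree: int, ancestor_sex: str = MALE,
                    descendant_id: str = "proband") -> Pedigree:
    """A plain single-path lineal pedigree of the given degree.

    ``degree`` meioses separate ``"ancestor"`` from ``descendant_id``
    (degree 1 = parent, 4 = great-great-grandparent, ...).  Intermediate
    links are male so the chain is patrilineal when the ancestor is male;
    unnamed spouses are founders.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    members = []
    if ancestor_sex == MALE:
        members.append(Individual("ancestor", MALE))
        members.append(Individual("spouse0", FEMALE))
        father, mother = "ancestor", "spouse0"
    else:
        members.append(Individual("ancestor", FEMALE))
        members.append(Individual("spouse0", MALE))
        father, mother = "spouse0", "ancestor"
    for g in range(1, degree + 1):
        iid = descendant_id if g == degree else f"gen{g}"
        members.append(Individual(iid, MALE, father, mother))
        if g < degree:
            members.append(Individual(f"spouse{g}", FEMALE))
            father, mother = iid, f"spouse{g}"
    return Pedigree(members, name=f"lineal-degree{degree}")


def avuncular_pedigree(degree: int) -> Pedigree:
    """A plain full-avuncular pedigree: ``"uncle"`` is the proband's
    (great-)^(degree-2) uncle, e.g. degree 5 = great-great-great-uncle.

    The proband sits ``degree - 1`` generations below the uncle's full
    sibling, so the closest path crosses ``degree + 1`` meioses through the
    shared grandparent couple.
    """
    if degree < 2:
        raise ValueError("avuncular degree must be >= 2")
    members = [
        Individual("gf", MALE),
        Individual("gm", FEMALE),
        Individual("uncle", MALE, "gf", "gm"),
        Individual("sib", MALE, "gf", "gm"),
        Individual("sibwife", FEMALE),
    ]
    father, mother = "sib", "sibwife"
    n_below = degree - 1
    for g in range(1, n_below + 1):
        iid = "proband" if g == n_below else f"gen{g}"
        members.append(Individual(iid, MALE, father, mother))
        if g < n_below:
            members.append(Individual(f"wife{g}", FEMALE))
            father, mother = iid, f"wife{g}"
    return Pedigree(members, name=f"avuncular-degree{degree}")


def sibling_pedigree(n_children: int = 2, child_sexes=None) -> Pedigree:
    """Two founder parents with ``n_children`` full siblings child1..childN."""
    sexes = child_sexes or [MALE] * n_children
    members = [Individual("father", MALE), Individual("mother", FEMALE)]
    for i in range(n_children):
        members.append(Individual(f"child{i + 1}", sexes[i], "father", "mother"))
    return Pedigree(members, name="siblings")
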