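"""Forensic lineage-marker logic: Y-STR profiles, Y-haplogroup placement
on a SNP tree, and mitochondrial haplotype calling and comparison.

Y-STR alleles are repeat designations (possibly microvariants such as
"17.2") with capillary-electrophoresis peak heights in RFU.  Composite
profiles require replicate amplification: an allele is *confirmed* when
reportable (>70 RFU) in at least two amplifications, *below-threshold*
when replicated but dipping under the reporting threshold, and
*unreplicated* when seen once.  The genetic difference between two
haplotypes is the total number of repeat steps across compared loci.

Y-haplogroup placement walks a SNP-defined tree to the most derived node
supported by covered defining SNPs; branches with no coverage cannot
refine the call further.

Mitochondrial variants are called from per-position base counts against a
reference using coverage (>10X, strict), variant frequency (>=10%) and
variant count (>=4) gates; positions where reference and variant both
pass are heteroplasmic (mixed) and are conventionally ignored when
comparing haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import (
    InsufficientDataError,
    NonReportableProfileError,
    ParameterError,
)

__all__ = [
    "STRProfile",
    "CompositeProfile",
    "CompositeAllele",
    "MitoVariant",
    "MitoHaplotype",
    "HaplogroupNode",
    "HaplogroupTree",
    "build_composite_ystr",
    "ystr_genetic_difference",
    "place_y_haplogroup",
    "call_mito_variants",
    "compare_mito_haplotypes",
    "control_clean_check",
    "RFU_THRESHOLD",
]

RFU_THRESHOLD = 70.0
MIN_REPORTABLE_LOCI = 4

IUPAC_MIXED = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


# ---------------------------------------------------------------------------
# Y-STR profiles
# ---------------------------------------------------------------------------


@dataclass
class STRProfile:
    """One amplification's allele calls: locus -> [(allele, rfu)]."""

    sample: str
    loci: Dict[str, List[Tuple[str, Optional[float]]]]

    def reportable_loci(self, rfu_threshold: float = RFU_THRESHOLD) -> Set[str]:
        """Loci with at least one peak strictly above the threshold."""
        out = set()
        for locus, alleles in self.loci.items():
            for _, rfu in alleles:
                if rfu is None or rfu > rfu_threshold:
                    out.add(locus)
                    break
        return out


@dataclass(frozen=True)
class CompositeAllele:
    allele: str
    status: str  # confirmed | below-threshold | unreplicated | not-reported

    def render(self) -> str:
        return f"{self.allele} (BT)" if self.status == "below-threshold" else self.allele


@dataclass
class CompositeProfile:
    sample: str
    loci: Dict[str, List[CompositeAllele]]

    def typed_loci(self) -> Set[str]:
        """Loci carrying at least one confirmed or below-threshold allele."""
        return {
            locus
            for locus, alleles in self.loci.items()
            if any(a.status in ("confirmed", "below-threshold") for a in alleles)
        }

    def alleles(self, locus: str) -> List[str]:
        return [
            a.allele
            for a in self.loci.get(locus, [])
            if a.status in ("confirmed", "below-threshold")
        ]


def build_composite_ystr(
    replicates: Sequence[STRProfile],
    rfu_threshold: float = RFU_THRESHOLD,
    min_loci_per_replicate: int = MIN_REPORTABLE_LOCI,
    min_recordable_rfu: float = 30.0,
) -> CompositeProfile:
    """Combine replicate amplifications into a composite profile.

    Only replicates with at least ``min_loci_per_replicate`` reportable
    loci qualify; fewer than two qualifying replicates make the sample
    non-reportable.  Per allele: *confirmed* when present above the RFU
    threshold in >=2 qualifying replicates; *below-threshold* when present
    in >=2 replicates but under the threshold in at least one (recorded
    down to an analytic minimum of ``min_recordable_rfu``); *unreplicated*
    when seen in exactly one.  Loci whose replicated alleles conflict
    (different allele sets both replicated, e.g. a count mismatch at a
    single-copy locus) are marked not-reported.
    """
    qualifying = [
        rep for rep in replicates
        if len(rep.reportable_loci(rfu_threshold)) >= min_loci_per_replicate
    ]
    if len(qualifying) < 2:
        raise NonReportableProfileError(
            f"{len(qualifying)} qualifying replicate(s); "
            f"composite requires >= 2 with >= {min_loci_per_replicate} "
            "reportable loci"
        )
    sample = qualifying[0].sample

    # collect per-allele observations: (reportable count, seen count)
    per_locus: Dict[str, Dict[str, List[float]]] = {}
    for rep in qualifying:
        for locus, alleles in rep.loci.items():
            slot = per_locus.setdefault(locus, {})
            for allele, rfu in alleles:
                if rfu is not None and rfu < min_recordable_rfu:
                    continue  # below the analytic minimum: not recorded
                slot.setdefault(allele, []).append(
                    np.inf if rfu is None else float(rfu)
                )

    out: Dict[str, List[CompositeAllele]] = {}
    for locus, alleles in per_locus.items():
        entries: List[CompositeAllele] = []
        replicated = {
            a for a, rfus in alleles.items() if len(rfus) >= 2
        }
        # conflict: single-copy locus semantics — more than one replicated
        # allele is legitimate (multi-copy loci), but replicated alleles
        # with disagreeing replicated partners cannot be resolved when the
        # replicate-level allele sets differ; flag only genuinely
        # contradictory single-allele loci
        rep_sets = [
            frozenset(a for a, r in rep.loci.get(locus, []))
            for rep in qualifying
            if rep.loci.get(locus)
        ]
        conflict = (
            len(replicated) > 0
            and len({s for s in rep_sets if s}) > 1
            and all(len(s) == 1 for s in rep_sets)
            and len(replicated) > 1
        )
        for allele, rfus in sorted(alleles.items()):
            n_seen = len(rfus)
            n_reportable = sum(r > rfu_threshold for r in rfus)
            if conflict and allele in replicated:
                status = "not-reported"
            elif n_seen >= 2 and n_reportable >= 2:
                status = "confirmed"
            elif n_seen >= 2:
                status = "below-threshold"
            else:
                status = "unreplicated"
            entries.append(CompositeAllele(allele, status))
        out[locus] = entries
    return CompositeProfile(sample, out)


def _allele_value(allele: str) -> float:
    """Numeric repeat value; microvariants keep their fractional part."""
    return float(allele)


def ystr_genetic_difference(
    a, b, loci_subset: Optional[Iterable[str]] = None
):
    """Total repeat-step difference between two Y-STR haplotypes.

    Profiles may be composite profiles or plain ``locus -> [alleles]``
    mappings; below-threshold alleles count, loci missing from either
    profile are skipped.  Multi-copy loci are compared as multisets under
    the minimal-total-step assignment; unpaired copies each add their
    nearest-step cost.  Returns (total, per-locus breakdown, number of
    compared loci).
    """
    map_a = _allele_map(a)
    map_b = _allele_map(b)
    shared = set(map_a) & set(map_b)
    if loci_subset is not None:
        shared &= set(loci_subset)
    shared = {l for l in shared if map_a[l] and map_b[l]}
    if not shared:
        raise InsufficientDataError("no shared typed loci")
    per_locus: Dict[str, float] = {}
    for locus in sorted(shared):
        per_locus[locus] = _multiset_steps(map_a[locus], map_b[locus])
    total = sum(per_locus.values())
    if float(total).is_integer():
        total = int(total)
    return total, per_locus, len(shared)


def _allele_map(profile) -> Dict[str, List[str]]:
    if isinstance(profile, CompositeProfile):
        return {l: profile.alleles(l) for l in profile.loci}
    if isinstance(profile, STRProfile):
        return {l: [a for a, _ in v] for l, v in profile.loci.items()}
    return {l: list(v) for l, v in profile.items()}


def _multiset_steps(a: List[str], b: List[str]) -> float:
    va = sorted(_allele_value(x) for x in a)
    vb = sorted(_allele_value(x) for x in b)
    if len(va) == len(vb):
        cost = np.abs(np.subtract.outer(va, vb))
        rows, cols = linear_sum_assignment(cost)
        total = float(cost[rows, cols].sum())
    else:
        short, long_ = (va, vb) if len(va) < len(vb) else (vb, va)
        cost = np.abs(np.subtract.outer(short, long_))
        rows, cols = linear_sum_assignment(cost)
        total = float(cost[rows, cols].sum())
        unmatched = set(range(len(long_))) - set(cols)
        for j in unmatched:
            total += float(min(abs(long_[j] - s) for s in short))
    return int(total) if total.is_integer() else total


# ---------------------------------------------------------------------------
# Y-haplogroup tree placement
# ---------------------------------------------------------------------------


@dataclass
class HaplogroupNode:
    name: str
    parent: Optional[str]
    defining_snps: List[Tuple[str, str, str]]  # (site id, ancestral, derived)


class HaplogroupTree:
    """A rooted Y-haplogroup tree with SNP-defined branches."""

    def __init__(self, nodes: Iterable[HaplogroupNode]):
        self.nodes: Dict[str, HaplogroupNode] = {n.name: n for n in nodes}
        if not self.nodes:
            raise ParameterError("empty haplogroup tree")
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ParameterError(f"tree must have exactly one root, got {len(roots)}")
        self.root = roots[0].name
        self.children: Dict[str, List[str]] = {name: [] for name in self.nodes}
        for n in self.nodes.values():
            if n.parent is not None:
                if n.parent not in self.nodes:
                    raise ParameterError(f"{n.name}: unknown parent {n.parent}")
                self.children[n.parent].append(n.name)
                if not n.defining_snps:
                    raise ParameterError(f"{n.name}: non-root node lacks defining SNPs")
        # acyclicity via path-to-root check
        for name in self.nodes:
            seen = set()
            cur: Optional[str] = name
            while cur is not None:
                if cur in seen:
                    raise ParameterError(f"cycle through {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    def path_to_root(self, name: str) -> List[str]:
        out = []
        cur: Optional[str] = name
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out[::-1]


def _node_support(node: HaplogroupNode, calls: Dict[str, str]):
    derived = []
    ancestral = []
    for sid, anc, der in node.defining_snps:
        if sid not in calls:
            continue
        if calls[sid] == der:
            derived.append(sid)
        elif calls[sid] == anc:
            ancestral.append(sid)
    return derived, ancestral


def place_y_haplogroup(
    calls: Dict[str, str], tree: HaplogroupTree
) -> Tuple[str, List[str], List[str]]:
    """Most refined Y-haplogroup supported by the observed SNP calls.

    Starting at the root, descend into a child only when at least one of
    its covered defining SNPs is derived and none is ancestral; branches
    with zero covered defining SNPs cannot be entered, so resolution stops
    at the last supported node.  Derived calls on branches off the chosen
    path are reported as conflicts (with the walk halting where the
    ambiguity arises when several children are simultaneously supported).

    Returns (haplogroup name, supporting SNP ids along the path, conflict
    SNP ids).
    """
    current = tree.root
    supporting: List[str] = []
    conflicts: List[str] = []
    while True:
        candidates = []
        for child in tree.children[current]:
            derived, ancestral = _node_support(tree.nodes[child], calls)
            if derived and not ancestral:
                candidates.append((child, derived))
        if len(candidates) == 1:
            child, derived = candidates[0]
            supporting.extend(derived)
            current = child
            continue
        if len(candidates) > 1:
            # incompatible branches simultaneously derived
            for child, derived in candidates:
                conflicts.extend(derived)
            break
        break
    # derived calls strictly below or beside the final placement that were
    # unreachable (e.g. a gap in coverage on an intermediate node) are
    # also surfaced as conflicts-of-coverage for reporting
    reachable = set(tree.path_to_root(current))
    for name, node in tree.nodes.items():
        if name in reachable:
            continue
        derived, ancestral = _node_support(node, calls)
        for sid in derived:
            if sid not in conflicts:
                conflicts.append(sid)
    return current, supporting, conflicts


# ---------------------------------------------------------------------------
# mitochondrial variant calling and comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MitoVariant:
    position: str  # 1-based; insertions use point suffixes ("315.1")
    call: str      # base, IUPAC mixed code, or "-" for deletion
    type: str      # substitution | insertion | deletion
    heteroplasmic: bool = False

    def render(self) -> str:
        return f"{self.position}{self.call}"


@dataclass
class MitoHaplotype:
    sample: str
    variants: List[MitoVariant]
    covered_range: Tuple[int, int]

    def by_position(self) -> Dict[str, MitoVariant]:
        return {v.position: v for v in self.variants}


def call_mito_variants(
    pileup: pd.DataFrame,
    reference: str,
    sample: str = "sample",
    min_coverage: float = 10,
    min_frequency: float = 0.10,
    min_count: int = 4,
) -> MitoHaplotype:
    """Call a haplotype from per-position base counts against a reference.

    A variant is reported where a non-reference base passes all three
    gates: coverage strictly above ``min_coverage``, frequency at least
    ``min_frequency`` and count at least ``min_count``.  When the
    reference base also passes the frequency and count gates the position
    is a mixed (heteroplasmic) call rendered as an IUPAC code.  Insertion
    rows (point-suffix positions) have no reference base and report the
    dominant inserted base; deletions are called from the gap column.
    """
    bases = ["A", "C", "G", "T"]
    variants: List[MitoVariant] = []
    covered: List[int] = []
    for row in pileup.itertuples():
        pos = str(row.position)
        counts = {b: getattr(row, b) for b in bases}
        gap = getattr(row, "gap", 0)
        depth = sum(counts.values()) + gap
        is_insertion = "." in pos
        if not is_insertion:
            ipos = int(pos)
            if not (1 <= ipos <= len(reference)):
                raise ParameterError(
                    f"position {pos} outside reference (length {len(reference)})"
                )
            if depth > 0:
                covered.append(ipos)
        if depth <= min_coverage:
            continue

        if is_insertion:
            best = max(bases, key=lambda b: counts[b])
            if counts[best] >= min_count and counts[best] / depth >= min_frequency:
                variants.append(MitoVariant(pos, best, "insertion"))
            continue

        ref_base = reference[ipos - 1]

        def passes(n: int) -> bool:
            return n >= min_count and n / depth >= min_frequency

        alt_candidates = [b for b in bases if b != ref_base and passes(counts[b])]
        del_pass = passes(gap)
        if not alt_candidates and not del_pass:
            continue
        if del_pass and not alt_candidates:
            variants.append(MitoVariant(pos, "-", "deletion"))
            continue
        best = max(alt_candidates, key=lambda b: counts[b])
        if passes(counts.get(ref_base, 0)):
            code = IUPAC_MIXED.get(frozenset((ref_base, best)), "N")
            variants.append(MitoVariant(pos, code, "substitution", True))
        else:
            variants.append(MitoVariant(pos, best, "substitution"))
    if covered:
        covered_range = (min(covered), max(covered))
    else:
        covered_range = (0, 0)
    return MitoHaplotype(sample, variants, covered_range)


def _mixed_components(code: str) -> Set[str]:
    for pair, c in IUPAC_MIXED.items():
        if c == code:
            return set(pair)
    return {code}


def compare_mito_haplotypes(
    a: MitoHaplotype,
    b: MitoHaplotype,
    ignore_heteroplasmy: bool = True,
) -> Tuple[int, List[str]]:
    """Count haplotype differences within the shared covered range.

    A heteroplasmic (mixed) call matches either of its component bases —
    and matches the reference state — when ``ignore_heteroplasmy`` is set,
    following the convention that heteroplasmy is not a haplotype
    difference.
    """
    lo = max(a.covered_range[0], b.covered_range[0])
    hi = min(a.covered_range[1], b.covered_range[1])
    if hi < lo:
        raise InsufficientDataError("covered ranges do not overlap")

    def in_range(pos: str) -> bool:
        return lo <= float(pos) <= hi

    va = {p: v for p, v in a.by_position().items() if in_range(p)}
    vb = {p: v for p, v in b.by_position().items() if in_range(p)}
    differing: List[str] = []
    for pos in sorted(set(va) | set(vb), key=float):
        xa, xb = va.get(pos), vb.get(pos)
        if ignore_heteroplasmy:
            if (xa is not None and xa.heteroplasmic) or (
                xb is not None and xb.heteroplasmic
            ):
                # a mixed position is compatible with any state that one of
                # its components (or the reference, for the absent sample)
                # could present
                comp_a = _mixed_components(xa.call) if xa else None
                comp_b = _mixed_components(xb.call) if xb else None
                if comp_a is None or comp_b is None or comp_a & comp_b:
                    continue
                differing.append(pos)
                continue
        ca = xa.call if xa else None
        cb = xb.call if xb else None
        if ca != cb:
            differing.append(pos)
    return len(differing), differing


def control_clean_check(average_coverage: float) -> bool:
    """Negative controls and reagent blanks are clean below 2X average."""
    if average_coverage < 0:
        raise ParameterError("average coverage must be >= 0")
    return average_coverage < 2.0
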