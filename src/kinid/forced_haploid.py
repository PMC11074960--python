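"""Pseudo-haploid allele-mismatch test for very low-coverage pairs.

When both samples are too shallow for genotype likelihoods, each is forced
into a pseudo-haploid genome — one randomly sampled read allele per
covered site — and the proportion of mismatching alleles over the jointly
called sites is compared against simulated expectations per relationship.

For two random alleles, one from each individual, the mismatch chance at
a site of alternate frequency p is 2p(1-p)(1 - phi): identical-by-descent
alleles (probability phi, the kinship coefficient) always agree, and
independent ones disagree at the heterozygosity rate.  Parent-child and
full siblings share phi = 1/4 and therefore coincide on autosomes; the
X chromosome separates them because a father transmits his X to every
daughter and to no son, making the comparison sex-aware.

A simplistic error model (independent symmetric flip of the final
pseudo-haploid call with probability epsilon) absorbs deamination, PCR,
sequencing and mapping error; rates 0 and 0.005 are conventional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConsistencyError, InsufficientDataError, ParameterError
from .synthetic import SiteObservation

__all__ = [
    "HaploidCallSet",
    "MismatchResult",
    "MismatchDistribution",
    "ClassificationResult",
    "pseudo_haploidize",
    "mismatch_proportion",
    "expected_mismatch",
    "simulate_mismatch_distribution",
    "classify_mismatch",
    "AUTOSOMAL_RELATIONSHIPS",
    "X_RELATIONSHIPS",
]

AUTOSOMAL_RELATIONSHIPS = ("self", "parent-child", "full-siblings", "unrelated")
# "self" is excluded on X: hemizygous males make it degenerate with the
# listed hypotheses and it is not part of the conventional X comparison set
X_RELATIONSHIPS = ("parent-child", "full-siblings", "unrelated")

_PHI = {
    "self": 0.5,
    "parent-child": 0.25,
    "full-siblings": 0.25,
    "unrelated": 0.0,
}


@dataclass
class HaploidCallSet:
    """One randomly drawn allele per covered site for one sample."""

    sample: str
    calls: Dict[str, int]  # site id -> 0 (ref) / 1 (alt)
    chrom_class: str = "autosomal"

    def __len__(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class MismatchResult:
    pair: Tuple[str, str]
    n_overlap: int
    mismatch_proportion: float


@dataclass
class MismatchDistribution:
    """Simulated mismatch proportions for one relationship hypothesis."""

    relationship: str
    chrom_class: str
    sexes: Optional[Tuple[str, str]]
    error_rate: float
    samples: np.ndarray
    n_sites: int

    @property
    def reps(self) -> int:
        return len(self.samples)

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    def quantile(self, q) -> float:
        return float(np.quantile(self.samples, q))

    def summary(self) -> Dict[str, float]:
        return {
            "mean": self.mean,
            "q025": self.quantile(0.025),
            "median": self.quantile(0.5),
            "q975": self.quantile(0.975),
        }


@dataclass
class ClassificationResult:
    """Relationships ranked by empirical two-sided tail probability."""

    ranked: List[Tuple[str, float]]  # (relationship, p-value), best first
    hard_call: Optional[str]

    @property
    def top(self) -> str:
        return self.ranked[0][0]


# ---------------------------------------------------------------------------
# observed side
# ---------------------------------------------------------------------------


def pseudo_haploidize(
    observations: Iterable[SiteObservation],
    seed: int = 0,
    sample: str = "sample",
    chrom_class: str = "autosomal",
) -> HaploidCallSet:
    """Force observations into a pseudo-haploid genome.

    For every site with at least one read, one read is chosen uniformly at
    random (seeded) and its allele becomes the call; uncovered sites are
    absent from the call set.
    """
    rng = np.random.default_rng(seed)
    calls: Dict[str, int] = {}
    for obs in observations:
        if obs.coverage == 0:
            continue
        calls[obs.site_id] = int(obs.alleles[rng.integers(obs.coverage)])
    return HaploidCallSet(sample, calls, chrom_class)


def mismatch_proportion(a: HaploidCallSet, b: HaploidCallSet) -> MismatchResult:
    """Proportion of jointly called sites whose alleles differ."""
    shared = sorted(set(a.calls) & set(b.calls))
    if not shared:
        raise InsufficientDataError(
            f"no jointly called sites between {a.sample} and {b.sample}"
        )
    mism = sum(a.calls[s] != b.calls[s] for s in shared)
    return MismatchResult(
        pair=(a.sample, b.sample),
        n_overlap=len(shared),
        mismatch_proportion=mism / len(shared),
    )


# ---------------------------------------------------------------------------
# expectations and simulated null distributions
# ---------------------------------------------------------------------------


def expected_mismatch(relationship: str, frequencies: np.ndarray) -> float:
    """Closed-form expected mismatch proportion over a site set.

    Mean over sites of 2p(1-p)(1 - phi); the same-individual comparison
    uses phi = 1/2 (two independent allele draws from one genotype).
    """
    if relationship not in _PHI:
        raise ParameterError(f"unknown relationship {relationship!r}")
    p = np.asarray(frequencies, dtype=float)
    return float(np.mean(2 * p * (1 - p)) * (1 - _PHI[relationship]))


def _draw_autosomal_pair(rel: str, p: np.ndarray, rng) -> Tuple[np.ndarray, np.ndarray]:
    """One pseudo-haploid call per site for each member of the pair."""
    n = len(p)

    def bern(shape=n):
        return (rng.random(shape) < p).astype(np.int8)

    if rel == "unrelated":
        return bern(), bern()
    if rel == "self":
        g = np.stack([bern(), bern()])  # one genotype, two allele draws
        pick = rng.integers(2, size=(2, n))
        return g[pick[0], np.arange(n)], g[pick[1], np.arange(n)]
    if rel == "parent-child":
        pa, pb = bern(), bern()  # parent's two alleles
        transmitted = np.where(rng.integers(2, size=n) == 0, pa, pb)
        child = np.stack([transmitted, bern()])
        parent = np.stack([pa, pb])
        return (
            parent[rng.integers(2, size=n), np.arange(n)],
            child[rng.integers(2, size=n), np.arange(n)],
        )
    if rel == "full-siblings":
        f = np.stack([bern(), bern()])
        m = np.stack([bern(), bern()])
        idx = np.arange(n)
        sib1 = np.stack([f[rng.integers(2, size=n), idx],
                         m[rng.integers(2, size=n), idx]])
        sib2 = np.stack([f[rng.integers(2, size=n), idx],
                         m[rng.integers(2, size=n), idx]])
        return (
            sib1[rng.integers(2, size=n), idx],
            sib2[rng.integers(2, size=n), idx],
        )
    raise ParameterError(f"unknown relationship {rel!r}")


def _draw_x_pair(rel: str, sexes: Tuple[str, str], p: np.ndarray,
                 rng) -> Tuple[np.ndarray, np.ndarray]:
    """Sex-aware X-chromosome pseudo-haploid calls for the pair.

    Females carry two X copies (one from each parent), males one
    (maternal); a pseudo-haploid call draws evenly among the carried
    copies.  Unlinked sites suffice because only the per-site mismatch
    rate matters.
    """
    n = len(p)
    idx = np.arange(n)

    def bern():
        return (rng.random(n) < p).astype(np.int8)

    def call(copies: List[np.ndarray]) -> np.ndarray:
        if len(copies) == 1:
            return copies[0]
        stack = np.stack(copies)
        return stack[rng.integers(len(copies), size=n), idx]

    sa, sb = (s.upper()[0] for s in sexes)
    if rel == "unrelated":
        a = [bern()] if sa == "M" else [bern(), bern()]
        b = [bern()] if sb == "M" else [bern(), bern()]
        return call(a), call(b)

    if rel == "parent-child":
        # orient as (parent, child); X transmission depends on both sexes
        if sa == "F":  # mother-child
            mother = [bern(), bern()]
            maternal = np.where(rng.integers(2, size=n) == 0,
                                mother[0], mother[1])
            child = [maternal] if sb == "M" else [bern(), maternal]
            return call(mother), call(child)
        # father-child: father's single X goes to daughters only
        father = [bern()]
        if sb == "M":
            child = [bern()]  # son's X is maternal: unrelated to father's
        else:
            child = [father[0], bern()]
        return call(father), call(child)

    if rel == "full-siblings":
        mother = [bern(), bern()]
        father_x = bern()

        def sib(sex):
            maternal = np.where(rng.integers(2, size=n) == 0,
                                mother[0], mother[1])
            return [maternal] if sex == "M" else [father_x, maternal]

        return call(sib(sa)), call(sib(sb))
    raise ParameterError(f"unknown relationship {rel!r}")


def simulate_mismatch_distribution(
    relationship: str,
    site_frequencies: np.ndarray,
    chrom_class: str = "autosomal",
    sexes: Optional[Tuple[str, str]] = None,
    error_rate: float = 0.0,
    reps: int = 1000,
    seed: int = 0,
) -> MismatchDistribution:
    """Simulate the pseudo-haploid mismatch distribution for a hypothesis.

    Each replicate simulates the pair's genotypes under the relationship
    over exactly the provided site set, forces pseudo-haploid calls, flips
    each call independently with probability ``error_rate`` and records
    the mismatch proportion.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    if not (0 <= error_rate <= 1):
        raise ParameterError("error_rate must lie in [0, 1]")
    p = np.asarray(site_frequencies, dtype=float)
    if chrom_class == "autosomal":
        if relationship not in AUTOSOMAL_RELATIONSHIPS:
            raise ParameterError(
                f"{relationship!r} not an autosomal hypothesis"
            )
    elif chrom_class == "X":
        if relationship not in X_RELATIONSHIPS:
            raise ParameterError(f"{relationship!r} not an X hypothesis")
        if sexes is None or any(
            s.upper()[0] not in ("M", "F") for s in sexes
        ):
            raise ParameterError("X simulation requires the pair's sexes")
    else:
        raise ParameterError(f"unknown chrom_class {chrom_class!r}")

    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    for r in range(reps):
        if chrom_class == "autosomal":
            ca, cb = _draw_autosomal_pair(relationship, p, rng)
        else:
            ca, cb = _draw_x_pair(relationship, sexes, p, rng)
        if error_rate > 0:
            ca = np.where(rng.random(len(p)) < error_rate, 1 - ca, ca)
            cb = np.where(rng.random(len(p)) < error_rate, 1 - cb, cb)
        out[r] = np.mean(ca != cb)
    return MismatchDistribution(
        relationship=relationship,
        chrom_class=chrom_class,
        sexes=tuple(sexes) if sexes else None,
        error_rate=error_rate,
        samples=out,
        n_sites=len(p),
    )


def classify_mismatch(
    observed: MismatchResult,
    distributions: Sequence[MismatchDistribution],
    ambiguity_level: float = 0.05,
) -> ClassificationResult:
    """Rank relationship hypotheses by empirical tail probability.

    Each hypothesis receives a two-sided empirical p-value of the observed
    proportion within its simulated distribution (rank-based, with the
    (r+1)/(n+1) correction).  No hard call is made when the runner-up also
    remains plausible at the ``ambiguity_level``.
    """
    if not distributions:
        raise ParameterError("no distributions supplied")
    for dist in distributions:
        if dist.n_sites != observed.n_overlap:
            raise ConsistencyError(
                f"{dist.relationship}: simulated on {dist.n_sites} sites, "
                f"observed pair has {observed.n_overlap}"
            )
    x = observed.mismatch_proportion
    ranked = []
    for dist in distributions:
        n = dist.reps
        lo = (np.sum(dist.samples <= x) + 1) / (n + 1)
        hi = (np.sum(dist.samples >= x) + 1) / (n + 1)
        ranked.append((dist.relationship, float(min(1.0, 2 * min(lo, hi)))))
    ranked.sort(key=lambda t: -t[1])
    hard_call = ranked[0][0]
    if len(ranked) > 1 and ranked[1][1] > ambiguity_level:
        hard_call = None
    return ClassificationResult(ranked=ranked, hard_call=hard_call)
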