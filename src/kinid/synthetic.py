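"""Synthetic data generation for every input of the identification pipeline.

The generator emulates the structure of a 95K-style forensic SNP capture
experiment on degraded remains:

* a frequency panel of autosomal, X and Y SNP targets with per-population
  alternate-allele frequencies and genetic-map positions;
* Mendelian gene-dropping through arbitrary pedigrees with crossover
  interference (chi2/gamma renewal model) on autosomes and the X, with
  exact true-IBD bookkeeping via founder-allele labels;
* sparse read observations with per-read base error and terminal cytosine
  deamination damage decaying exponentially with distance from the
  fragment end;
* stepwise Y-STR mutation along patrilines;
* mitochondrial per-position base-count pileups with deamination-induced
  mixed positions.

Every function is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .genetic_map import AUTOSOMES, GeneticMap
from .pedigree import FEMALE, MALE, Pedigree

__all__ = [
    "FrequencySpec",
    "FrequencyPanel",
    "DamageModel",
    "FragmentLengthSpec",
    "SiteObservation",
    "TrueIBDSegment",
    "GeneDropResult",
    "generate_frequency_panel",
    "gene_drop",
    "simulate_reads",
    "reference_genotypes",
    "simulate_ystr_profiles",
    "simulate_mito_pileup",
    "random_reference",
]

SIDE_5P = 0
SIDE_3P = 1

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencySpec:
    """Distribution of per-population alternate-allele frequencies.

    Frequencies are drawn uniform(low, high) independently per population;
    ``missing_fraction`` of autosomal sites are flagged as lacking
    reference-database frequencies (and are excluded from kinship).
    """

    low: float = 0.05
    high: float = 0.95
    missing_fraction: float = 0.0

    def __post_init__(self):
        if not (0 <= self.low < self.high <= 1):
            raise ParameterError("need 0 <= low < high <= 1")
        if not (0 <= self.missing_fraction <= 1):
            raise ParameterError("missing_fraction outside [0, 1]")


@dataclass
class FrequencyPanel:
    """An ordered SNP target manifest with population allele frequencies.

    ``df`` columns: id, chrom_class (autosomal/X/Y), chrom, cm (NaN on Y),
    ref, alt, has_frequency, and one ``freq_<POP>`` column per population.
    """

    df: pd.DataFrame
    populations: List[str]

    def __post_init__(self):
        if self.df["id"].duplicated().any():
            raise ValueError("panel site ids must be unique")

    def __len__(self) -> int:
        return len(self.df)

    def counts_by_class(self) -> Dict[str, int]:
        c = self.df["chrom_class"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("autosomal", "X", "Y")}

    def freq(self, population: str) -> np.ndarray:
        return self.df[f"freq_{population}"].to_numpy()

    def class_mask(self, chrom_class: str) -> np.ndarray:
        return (self.df["chrom_class"] == chrom_class).to_numpy()

    def subset(self, mask) -> "FrequencyPanel":
        return FrequencyPanel(self.df.loc[mask].reset_index(drop=True),
                              list(self.populations))


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of ``total`` items by ``weights``."""
    if total == 0:
        return np.zeros(len(weights), dtype=int)
    raw = weights / weights.sum() * total
    out = np.floor(raw).astype(int)
    rem = total - out.sum()
    order = np.argsort(raw - out)[::-1]
    out[order[:rem]] += 1
    return out


# allele pairs: transition (damage-prone) pairs are common on SNP panels
_PAIR_CHOICES = [("C", "T"), ("T", "C"), ("G", "A"), ("A", "G"),
                 ("A", "C"), ("C", "G"), ("G", "T"), ("A", "T")]
_PAIR_WEIGHTS = np.array([0.17, 0.17, 0.17, 0.17, 0.08, 0.08, 0.08, 0.08])


def generate_frequency_panel(
    n_auto: int,
    n_x: int,
    n_y: int,
    populations: Sequence[str] = ("EUR",),
    freq_spec: Optional[FrequencySpec] = None,
    seed: int = 0,
    gmap: Optional[GeneticMap] = None,
) -> FrequencyPanel:
    """Generate a synthetic SNP target manifest.

    Autosomal sites are spread over chromosomes 1-22 proportionally to
    genetic length and evenly spaced within each chromosome; X sites
    likewise on the X scale; Y sites carry no map position.
    """
    if min(n_auto, n_x, n_y) < 0:
        raise ParameterError("site counts must be >= 0")
    spec = freq_spec or FrequencySpec()
    gmap = gmap or GeneticMap()
    rng = np.random.default_rng(seed)

    chroms: List[str] = []
    cms: List[float] = []
    classes: List[str] = []
    lengths = np.array([gmap.length(c) for c in AUTOSOMES])
    for chrom, n_c in zip(AUTOSOMES, _allocate(n_auto, lengths)):
        L = gmap.length(chrom)
        pos = (np.arange(n_c) + 0.5) * L / max(n_c, 1)
        chroms += [chrom] * n_c
        cms += list(pos)
        classes += ["autosomal"] * n_c
    if n_x:
        L = gmap.length("X")
        chroms += ["X"] * n_x
        cms += list((np.arange(n_x) + 0.5) * L / n_x)
        classes += ["X"] * n_x
    chroms += ["Y"] * n_y
    cms += [np.nan] * n_y
    classes += ["Y"] * n_y

    n = len(chroms)
    pair_idx = rng.choice(len(_PAIR_CHOICES), size=n, p=_PAIR_WEIGHTS)
    ref = [_PAIR_CHOICES[i][0] for i in pair_idx]
    alt = [_PAIR_CHOICES[i][1] for i in pair_idx]

    df = pd.DataFrame(
        {
            "id": [f"rs{i:08d}" for i in range(n)],
            "chrom_class": classes,
            "chrom": chroms,
            "cm": cms,
            "ref": ref,
            "alt": alt,
        }
    )
    has_freq = np.ones(n, dtype=bool)
    auto_idx = np.flatnonzero(df["chrom_class"] == "autosomal")
    n_missing = int(round(spec.missing_fraction * len(auto_idx)))
    if n_missing:
        miss = rng.choice(auto_idx, size=n_missing, replace=False)
        has_freq[miss] = False
    df["has_frequency"] = has_freq
    for pop in populations:
        df[f"freq_{pop}"] = rng.uniform(spec.low, spec.high, size=n)
    return FrequencyPanel(df, list(populations))


def reference_genotypes(panel: FrequencyPanel, n_ref: int,
                        population: str, seed: int = 0) -> np.ndarray:
    """HWE reference genotype dosages (n_ref x n_sites), for LD pruning."""
    rng = np.random.default_rng(seed)
    p = panel.freq(population)
    return (rng.random((n_ref, len(panel))) < p).astype(np.int8) + (
        rng.random((n_ref, len(panel))) < p
    ).astype(np.int8)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

Mosaic = Tuple[np.ndarray, np.ndarray]  # (segment start cM, founder hap label)


@dataclass(frozen=True)
class TrueIBDSegment:
    chrom: str
    start_cm: float
    end_cm: float
    state: int  # 0, 1 or 2 shared allele copies

    def __post_init__(self):
        if self.end_cm <= self.start_cm:
            raise ValueError("segment end must exceed start")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


def _crossovers(length_cm: float, model: str, shape: int,
                rng: np.random.Generator) -> np.ndarray:
    """Crossover positions for one meiosis on a chromosome of given length.

    ``poisson`` is the no-interference (Haldane) baseline at 1 event per
    Morgan.  ``chi2`` draws chiasmata from the stationary gamma renewal
    process of integer shape m at rate 2m per Morgan (generated as every
    m-th point of a Poisson process with random phase) and thins each
    chiasma onto the sampled chromatid with probability 1/2.
    """
    if model == "poisson":
        n = rng.poisson(length_cm / 100.0)
        return np.sort(rng.uniform(0.0, length_cm, n))
    if model != "chi2":
        raise ParameterError(f"unknown recombination model {model!r}")
    rate = 2.0 * shape / 100.0  # per cM
    n = rng.poisson(rate * length_cm)
    pts = np.sort(rng.uniform(0.0, length_cm, n))
    phase = int(rng.integers(shape))
    chiasmata = pts[phase::shape]
    keep = rng.random(chiasmata.size) < 0.5
    return chiasmata[keep]


def _meiosis(h0: Mosaic, h1: Mosaic, length_cm: float, model: str,
             shape: int, rng: np.random.Generator) -> Mosaic:
    """One transmitted haplotype: alternate between the parent's two
    mosaics at sampled crossover points, starting from a random phase."""
    xs = _crossovers(length_cm, model, shape, rng)
    cur = int(rng.integers(2))
    haps = (h0, h1)
    bounds = np.concatenate([[0.0], xs, [length_cm]])
    starts: List[float] = []
    labels: List[int] = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        if b <= a:
            cur ^= 1
            continue
        s, lab = haps[cur]
        j0 = int(np.searchsorted(s, a, side="right")) - 1
        j1 = int(np.searchsorted(s, b, side="left"))
        for j in range(j0, j1):
            seg_start = max(float(s[j]), a)
            if labels and labels[-1] == lab[j] and starts[-1] <= seg_start:
                continue  # merged with previous identical-label segment
            starts.append(seg_start)
            labels.append(int(lab[j]))
        cur ^= 1
    # collapse adjacent duplicates created across phase switches
    st, lb = [starts[0]], [labels[0]]
    for s_, l_ in zip(starts[1:], labels[1:]):
        if l_ == lb[-1]:
            continue
        st.append(s_)
        lb.append(l_)
    return np.asarray(st), np.asarray(lb, dtype=np.int64)


def _single(label: int) -> Mosaic:
    return np.array([0.0]), np.array([label], dtype=np.int64)


def _labels_at(mosaic: Mosaic, pos: np.ndarray) -> np.ndarray:
    starts, labels = mosaic
    idx = np.searchsorted(starts, pos, side="right") - 1
    return labels[idx]


def _pair_ibd_intervals(haps_a: List[Mosaic], haps_b: List[Mosaic],
                        length_cm: float):
    """(start, end, state) intervals over [0, L] for one chromosome."""
    cuts = np.unique(np.concatenate(
        [m[0] for m in haps_a + haps_b] + [np.array([0.0, length_cm])]
    ))
    cuts = cuts[(cuts >= 0) & (cuts <= length_cm)]
    mids = (cuts[:-1] + cuts[1:]) / 2
    la = np.stack([_labels_at(m, mids) for m in haps_a])  # (na, k)
    lb = np.stack([_labels_at(m, mids) for m in haps_b])
    out = []
    for i in range(len(mids)):
        a = list(la[:, i])
        b = list(lb[:, i])
        # maximum bipartite matching on <=2 vs <=2 label lists
        if len(a) == 2 and len(b) == 2:
            if (a[0] == b[0] and a[1] == b[1]) or (a[0] == b[1] and a[1] == b[0]):
                state = 2
            elif a[0] in b or a[1] in b:
                state = 1
            else:
                state = 0
        else:
            state = 1 if (set(a) & set(b)) else 0
        out.append((float(cuts[i]), float(cuts[i + 1]), state))
    # merge adjacent runs of equal state
    merged = [out[0]]
    for s_, e_, st_ in out[1:]:
        ps, pe, pst = merged[-1]
        if st_ == pst:
            merged[-1] = (ps, e_, pst)
        else:
            merged.append((s_, e_, st_))
    return merged


class GeneDropResult:
    """Phased gene-drop outcome: founder-label mosaics, genotypes and
    exact IBD segments for any pair of pedigree members."""

    def __init__(self, ped: Pedigree, gmap: GeneticMap,
                 auto_mosaics, x_mosaics, y_labels,
                 genotypes: Optional[Dict[str, np.ndarray]],
                 panel: Optional[FrequencyPanel]):
        self.ped = ped
        self.gmap = gmap
        self._auto = auto_mosaics  # ind -> chrom -> [mosaic, mosaic]
        self._x = x_mosaics        # ind -> [mosaic(s)]
        self._y = y_labels         # ind -> founder label (males only)
        self.genotypes = genotypes
        self.panel = panel

    # -- IBD ----------------------------------------------------------------

    def ibd_segments(self, a: str, b: str,
                     chrom_class: str = "autosomal") -> List[TrueIBDSegment]:
        segs: List[TrueIBDSegment] = []
        if chrom_class == "autosomal":
            for chrom in self.gmap.autosomes:
                L = self.gmap.length(chrom)
                for s, e, st in _pair_ibd_intervals(
                    self._auto[a][chrom], self._auto[b][chrom], L
                ):
                    segs.append(TrueIBDSegment(chrom, s, e, st))
        elif chrom_class == "X":
            L = self.gmap.length("X")
            for s, e, st in _pair_ibd_intervals(self._x[a], self._x[b], L):
                segs.append(TrueIBDSegment("X", s, e, st))
        else:
            raise ParameterError("IBD segments defined for autosomal or X")
        return segs

    def ibd_proportions(self, a: str, b: str,
                        chrom_class: str = "autosomal") -> Dict[int, float]:
        """Genome-length fractions spent in IBD states 0/1/2."""
        tot = {0: 0.0, 1: 0.0, 2: 0.0}
        for seg in self.ibd_segments(a, b, chrom_class):
            tot[seg.state] += seg.length_cm
        total = sum(tot.values())
        return {k: v / total for k, v in tot.items()}

    def pair_summary(self, a: str, b: str) -> Dict[str, float]:
        """Autosomal sharing summary for one pair.

        ``total_shared_cm`` sums maximal IBD>=1 runs (state-agnostic, the
        quantity plotted in pedigree-hypothesis comparisons) and
        ``segment_count`` counts them; ``weighted_shared_cm`` is the
        kinship-weighted length (IBD1/2 + IBD2) whose expectation is
        2*phi times the map length.
        """
        total = 0.0
        weighted = 0.0
        longest = 0.0
        count = 0
        for chrom in self.gmap.autosomes:
            L = self.gmap.length(chrom)
            run = 0.0
            for s, e, st in _pair_ibd_intervals(
                self._auto[a][chrom], self._auto[b][chrom], L
            ):
                seg = e - s
                if st >= 1:
                    total += seg
                    weighted += seg * (0.5 if st == 1 else 1.0)
                    if run == 0.0:
                        count += 1
                    run += seg
                    longest = max(longest, run)
                else:
                    run = 0.0
        return {
            "total_shared_cm": total,
            "segment_count": count,
            "longest_cm": longest,
            "weighted_shared_cm": weighted,
        }


def gene_drop(
    ped: Pedigree,
    panel: Optional[FrequencyPanel] = None,
    gmap: Optional[GeneticMap] = None,
    recomb_model: str = "chi2",
    shape: int = 4,
    seed: int = 0,
    population: Optional[str] = None,
) -> GeneDropResult:
    """Drop founder genomes through the pedigree.

    Founders receive uniquely labelled haplotypes; every non-founder
    inherits one recombinant haplotype from each parent.  X transmission
    is sex-aware (males hemizygous; a father passes his X intact to
    daughters and nothing to sons); the Y follows the patriline without
    recombination.  When a ``panel`` is supplied, founder labels are
    translated to alleles drawn under HWE at the panel's frequencies for
    ``population`` and per-individual genotype arrays are produced.
    """
    gmap = gmap or GeneticMap()
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    founders = [i for i in order if ped[i].is_founder()]
    lab = {f: (2 * k, 2 * k + 1) for k, f in enumerate(founders)}

    auto: Dict[str, Dict[str, List[Mosaic]]] = {}
    for iid in order:
        ind = ped[iid]
        auto[iid] = {}
        for chrom in gmap.autosomes:
            L = gmap.length(chrom)
            if ind.is_founder():
                auto[iid][chrom] = [_single(lab[iid][0]), _single(lab[iid][1])]
            else:
                fh = auto[ind.father][chrom]
                mh = auto[ind.mother][chrom]
                auto[iid][chrom] = [
                    _meiosis(fh[0], fh[1], L, recomb_model, shape, rng),
                    _meiosis(mh[0], mh[1], L, recomb_model, shape, rng),
                ]

    # X: females carry [paternal X (intact), maternal recombinant];
    # males carry [maternal recombinant] only
    x: Dict[str, List[Mosaic]] = {}
    if "X" in gmap.lengths:
        LX = gmap.length("X")
        for iid in order:
            ind = ped[iid]
            if ind.is_founder():
                if ind.sex == MALE:
                    x[iid] = [_single(lab[iid][0])]
                else:
                    x[iid] = [_single(lab[iid][0]), _single(lab[iid][1])]
            else:
                mx = x[ind.mother]
                maternal = (
                    _meiosis(mx[0], mx[1], LX, recomb_model, shape, rng)
                    if len(mx) == 2 else mx[0]
                )
                if ind.sex == FEMALE:
                    fx = x[ind.father]
                    x[iid] = [fx[0], maternal]
                else:
                    x[iid] = [maternal]

    # Y: single label down the patriline; patriline heads get fresh labels
    y: Dict[str, int] = {}
    next_label = 2 * len(founders)
    for iid in order:
        ind = ped[iid]
        if ind.sex != MALE:
            continue
        if ind.father is not None and ind.father in y:
            y[iid] = y[ind.father]
        elif ind.is_founder():
            y[iid] = lab[iid][0]
        else:
            y[iid] = next_label
            next_label += 1

    genotypes = None
    if panel is not None:
        if population is None:
            population = panel.populations[0]
        genotypes = _mosaics_to_genotypes(
            ped, panel, gmap, auto, x, y, next_label, population, rng
        )
    return GeneDropResult(ped, gmap, auto, x, y, genotypes, panel)


def _mosaics_to_genotypes(ped, panel, gmap, auto, x, y, n_labels,
                          population, rng):
    df = panel.df
    p = panel.freq(population)
    n_sites = len(df)
    # founder haplotype alleles under HWE: one Bernoulli(p) draw per label
    founder_alleles = (rng.random((n_labels, n_sites)) < p).astype(np.int8)

    genotypes = {
        iid: np.full((n_sites, 2), -1, dtype=np.int8) for iid in ped.ids
    }
    cc = df["chrom_class"].to_numpy()
    chrom_col = df["chrom"].to_numpy()
    cm = df["cm"].to_numpy()

    for chrom in gmap.autosomes:
        mask = (cc == "autosomal") & (chrom_col == chrom)
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        pos = cm[idx]
        for iid in ped.ids:
            for copy in (0, 1):
                labels = _labels_at(auto[iid][chrom][copy], pos)
                genotypes[iid][idx, copy] = founder_alleles[labels, idx]

    xmask = cc == "X"
    if xmask.any() and "X" in gmap.lengths:
        idx = np.flatnonzero(xmask)
        pos = cm[idx]
        for iid in ped.ids:
            for copy, mosaic in enumerate(x.get(iid, [])):
                labels = _labels_at(mosaic, pos)
                genotypes[iid][idx, copy] = founder_alleles[labels, idx]

    ymask = cc == "Y"
    if ymask.any():
        idx = np.flatnonzero(ymask)
        for iid, label in y.items():
            genotypes[iid][idx, 0] = founder_alleles[label, idx]
    return genotypes


# ---------------------------------------------------------------------------
# read simulation with damage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DamageModel:
    """Terminal deamination damage plus a per-read base error rate.

    ``amplitude5`` is the probability of C->T conversion at the 5' terminal
    base (``amplitude3`` likewise for G->A at 3'), decaying as
    exp(-distance / decay_length) into the read.
    """

    amplitude5: float = 0.2
    amplitude3: float = 0.2
    decay_length: float = 3.0
    base_error: float = 0.001

    def __post_init__(self):
        for p in (self.amplitude5, self.amplitude3, self.base_error):
            if not (0 <= p <= 1):
                raise ParameterError("damage probabilities must lie in [0, 1]")
        if self.decay_length <= 0:
            raise ParameterError("decay_length must be positive")


@dataclass(frozen=True)
class FragmentLengthSpec:
    """Normal fragment length model, truncated below at ``minimum`` bases."""

    mean: float = 60.0
    sd: float = 15.0
    minimum: int = 30


@dataclass
class SiteObservation:
    """Per-site read-level observations for one sample.

    ``alleles`` holds 0 (ref) / 1 (alt) calls; ``dists`` the distance of
    the site from the read's nearest fragment end; ``sides`` which end
    that is (0 = 5', 1 = 3').
    """

    site_id: str
    alleles: np.ndarray
    dists: np.ndarray
    sides: np.ndarray

    @property
    def coverage(self) -> int:
        return len(self.alleles)


def damage_prone_side(ref: str, alt: str) -> int:
    """-1 if the allele pair is not deamination-prone, else the fragment
    end (0 = 5' for C/T pairs, 1 = 3' for G/A pairs) where damage acts."""
    pair = {ref, alt}
    if pair == {"C", "T"}:
        return SIDE_5P
    if pair == {"G", "A"}:
        return SIDE_3P
    return -1


def _damage_source_product(ref: str, alt: str) -> Tuple[int, int]:
    """Indices (0=ref, 1=alt) of the damage source base (C or G) and the
    product base (T or A) for a damage-prone pair."""
    if ref in ("C", "G"):
        return 0, 1
    return 1, 0


def simulate_reads(
    genotypes: Dict[str, np.ndarray],
    panel: FrequencyPanel,
    mean_depth: float,
    depth_model: str = "poisson",
    damage: Optional[DamageModel] = None,
    fragment_spec: Optional[FragmentLengthSpec] = None,
    seed: int = 0,
    negbin_dispersion: float = 2.0,
) -> Dict[str, List[SiteObservation]]:
    """Simulate sparse allele-count observations for each sample.

    Per-site coverage is Poisson (or negative-binomial) around
    ``mean_depth``; each read carries a uniformly chosen chromosome copy,
    is flipped with probability ``base_error`` and, when the true base is
    deamination-susceptible on the read's fragment end, converted with
    probability amplitude * exp(-distance / decay_length).
    """
    if mean_depth < 0:
        raise ParameterError("mean_depth must be >= 0")
    if depth_model not in ("poisson", "negbin"):
        raise ParameterError(f"unknown depth model {depth_model!r}")
    dm = damage or DamageModel(0.0, 0.0, 3.0, 0.0)
    fs = fragment_spec or FragmentLengthSpec()
    rng = np.random.default_rng(seed)

    df = panel.df
    site_ids = df["id"].tolist()
    refs = df["ref"].tolist()
    alts = df["alt"].tolist()
    dmg_side = np.array([damage_prone_side(r, a) for r, a in zip(refs, alts)])
    src_prod = [_damage_source_product(r, a) if s >= 0 else (-1, -1)
                for r, a, s in zip(refs, alts, dmg_side)]

    out: Dict[str, List[SiteObservation]] = {}
    for sample, geno in genotypes.items():
        obs_list: List[SiteObservation] = []
        if mean_depth == 0:
            depths = np.zeros(len(df), dtype=int)
        elif depth_model == "poisson":
            depths = rng.poisson(mean_depth, len(df))
        else:
            r = negbin_dispersion
            depths = rng.negative_binomial(r, r / (r + mean_depth), len(df))
        for i, sid in enumerate(site_ids):
            d = int(depths[i])
            copies = geno[i][geno[i] >= 0]
            if d == 0 or copies.size == 0:
                obs_list.append(SiteObservation(
                    sid, np.empty(0, np.int8), np.empty(0, np.int16),
                    np.empty(0, np.int8)))
                continue
            true = copies[rng.integers(copies.size, size=d)]
            obs = np.where(rng.random(d) < dm.base_error, 1 - true, true)
            frag = np.maximum(
                rng.normal(fs.mean, fs.sd, d), fs.minimum
            ).astype(int)
            pos = (rng.random(d) * frag).astype(int)
            d5 = pos
            d3 = frag - 1 - pos
            sides = (d3 < d5).astype(np.int8)
            dists = np.minimum(d5, d3).astype(np.int16)
            if dmg_side[i] >= 0:
                src, prod = src_prod[i]
                amp = dm.amplitude5 if dmg_side[i] == SIDE_5P else dm.amplitude3
                prob = amp * np.exp(-dists / dm.decay_length)
                hit = (
                    (true == src)
                    & (sides == dmg_side[i])
                    & (rng.random(d) < prob)
                )
                obs = np.where(hit, prod, obs)
            obs_list.append(SiteObservation(
                sid, obs.astype(np.int8), dists, sides))
        out[sample] = obs_list
    return out


# ---------------------------------------------------------------------------
# Y-STR patriline simulation
# ---------------------------------------------------------------------------


def simulate_ystr_profiles(
    ped: Pedigree,
    loci_rates: Dict[str, float],
    founder_profile: Dict[str, float],
    step_dist=None,
    seed: int = 0,
) -> Dict[str, Dict[str, float]]:
    """Drop a Y-STR haplotype down every patriline of the pedigree.

    Each father-to-son transmission mutates each locus independently with
    its per-meiosis rate; the default step distribution is a symmetric
    +-1 repeat change.  Male founders all start from ``founder_profile``.
    """
    for locus, rate in loci_rates.items():
        if not (0 <= rate <= 1):
            raise ParameterError(f"{locus}: mutation rate outside [0, 1]")
    missing = set(loci_rates) - set(founder_profile)
    if missing:
        raise ParameterError(f"founder profile missing loci: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    step = step_dist or (lambda r: 1 if r.random() < 0.5 else -1)

    profiles: Dict[str, Dict[str, float]] = {}
    for iid in ped.topological_order():
        ind = ped[iid]
        if ind.sex != MALE:
            continue
        if ind.father is not None and ind.father in profiles:
            prof = dict(profiles[ind.father])
            for locus, rate in loci_rates.items():
                if rng.random() < rate:
                    prof[locus] = prof[locus] + step(rng)
        else:
            prof = {loc: founder_profile[loc] for loc in loci_rates}
        profiles[iid] = prof
    return profiles


# ---------------------------------------------------------------------------
# mitochondrial pileup simulation
# ---------------------------------------------------------------------------


def random_reference(length: int, seed: int = 0, gc: float = 0.44) -> str:
    """A random reference sequence with the given GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def simulate_mito_pileup(
    variants: Dict[object, str],
    reference: str,
    depth: float,
    error_rate: float = 0.0,
    deamination_rate: float = 0.0,
    affected_fraction: float = 0.0,
    deaminated_positions: Optional[Iterable[int]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-position base counts for a haplotype carrying ``variants``.

    ``variants`` maps 1-based positions to the sample's base (insertion
    positions use point-suffix strings such as ``"315.1"``).  Deamination
    converts C->T (G->A) reads with probability ``deamination_rate`` at
    ``deaminated_positions`` (or at a random ``affected_fraction`` of C/G
    positions).  ``depth`` of 0 yields an empty pileup.
    """
    if depth < 0:
        raise ParameterError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    cols = ["A", "C", "G", "T", "gap"]
    if depth == 0:
        return pd.DataFrame(columns=["position"] + cols)

    true: Dict[str, str] = {}
    for i, base in enumerate(reference, start=1):
        true[str(i)] = base
    for pos, base in variants.items():
        true[str(pos)] = base

    if deaminated_positions is not None:
        affected = {str(p) for p in deaminated_positions}
    elif affected_fraction > 0:
        cg = [p for p, b in true.items() if b in "CG"]
        n_aff = int(round(affected_fraction * len(cg)))
        affected = set(rng.choice(cg, size=n_aff, replace=False)) if n_aff else set()
    else:
        affected = set()

    def poskey(p):
        return tuple(int(x) for x in p.split("."))

    rows = []
    for pos in sorted(true, key=poskey):
        base = true[pos]
        d = int(rng.poisson(depth))
        counts = dict.fromkeys(cols, 0)
        if base == "-":
            counts["gap"] = d
        else:
            reads = np.full(d, base, dtype="U1")
            if pos in affected and base in "CG":
                product = "T" if base == "C" else "A"
                hit = rng.random(d) < deamination_rate
                reads[hit] = product
            err = rng.random(d) < error_rate
            for j in np.flatnonzero(err):
                others = [b for b in "ACGT" if b != reads[j]]
                reads[j] = others[rng.integers(3)]
            for b in reads:
                counts[b] += 1
        rows.append({"position": pos, **counts})
    return pd.DataFrame(rows)
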