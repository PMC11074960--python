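"""Pairwise relationship-category inference from genotype likelihoods.

For two samples, the per-site likelihood of each relationship category is
the genotype-likelihood-weighted probability of the ordered genotype pair
under the category's Cotterman triple (k0, k1, k2): with probability k0
the genotypes are independent HWE draws, with k1 they share one allele
identical by descent, with k2 both.  Per-site log-likelihoods are summed
over LD-pruned overlapping autosomal sites; the most likely category, its
likelihood ratio versus unrelated, and flat-prior posteriors are
reported, with strong support declared when LR >= 1e4 and the posterior
reaches 99.99%.

Likelihood ratios routinely exceed 1e300 at realistic site counts, so
every accumulation and every reported magnitude stays in log10 space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError
from .pedigree import CATEGORIES, RelationshipCategory
from .synthetic import FrequencyPanel

__all__ = [
    "KinshipResult",
    "AncestryResult",
    "prune_ld",
    "predict_ancestry",
    "pairwise_kinship",
    "LR_STRONG_SUPPORT",
    "POSTERIOR_STRONG_SUPPORT",
]

LR_STRONG_SUPPORT = 1e4
POSTERIOR_STRONG_SUPPORT = 0.9999

# categories ordered from most distant to closest: argmax ties break
# toward the more distant relationship (conservative identification)
_DISTANT_FIRST = [
    "unrelated", "degree5", "degree4", "degree3", "degree2",
    "full-siblings", "parent-child", "self",
]


@dataclass
class KinshipResult:
    pair: Tuple[str, str]
    n_overlap_snps: int
    log10_likelihood: Dict[str, float]
    max_category: str
    log10_lr_vs_unrelated: float
    posterior: Dict[str, float]
    strong_support: bool


@dataclass
class AncestryResult:
    sample: str
    proportions: Dict[str, float]
    selected_population: str


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def prune_ld(
    sites: pd.DataFrame,
    reference_genotypes: np.ndarray,
    r2_threshold: float = 0.2,
    window: int = 50,
) -> np.ndarray:
    """Greedy left-to-right LD pruning within chromosomes.

    ``sites`` must carry ``chrom`` in panel order; ``reference_genotypes``
    is an (n_ref, n_sites) dosage matrix over the same columns.  A site is
    dropped iff its squared genotype correlation with an already-kept site
    among the previous ``window`` kept sites of the same chromosome
    strictly exceeds ``r2_threshold`` (a pair at exactly the threshold is
    retained).  Monomorphic reference sites have undefined r² and are kept
    with a warning.  Returns a boolean keep-mask.
    """
    if not (0 <= r2_threshold <= 1):
        raise ParameterError("r2_threshold must lie in [0, 1]")
    g = np.asarray(reference_genotypes, dtype=float)
    if g.shape[1] != len(sites):
        raise ParameterError("reference genotype matrix does not cover sites")
    chrom = sites["chrom"].to_numpy()
    keep = np.zeros(len(sites), dtype=bool)
    centered = g - g.mean(axis=0)
    ss = (centered ** 2).sum(axis=0)

    kept_by_chrom: Dict[str, List[int]] = {}
    for j in range(len(sites)):
        kept = kept_by_chrom.setdefault(chrom[j], [])
        if ss[j] == 0:
            warnings.warn(
                f"monomorphic reference at site index {j}; r2 undefined, kept"
            )
            keep[j] = True
            kept.append(j)
            continue
        drop = False
        for i in kept[-window:]:
            if ss[i] == 0:
                continue
            r = (centered[:, i] @ centered[:, j]) / np.sqrt(ss[i] * ss[j])
            # boundary pairs (r2 equal to the threshold at working
            # precision) are retained under the strict-inequality rule
            if round(r * r, 12) > r2_threshold:
                drop = True
                break
        if not drop:
            keep[j] = True
            kept.append(j)
    return keep


# ---------------------------------------------------------------------------
# ancestry
# ---------------------------------------------------------------------------


def _linear_gl(gl: pd.DataFrame) -> np.ndarray:
    """Per-site linear likelihood triples normalised to sum 1."""
    logs = gl[["log_rr", "log_ra", "log_aa"]].to_numpy()
    logs = logs - logs.max(axis=1, keepdims=True)
    lin = np.exp(logs)
    return lin / lin.sum(axis=1, keepdims=True)


def _hwe(p: np.ndarray) -> np.ndarray:
    """(n_sites, 3) HWE genotype priors for alternate frequency p."""
    q = 1.0 - p
    return np.stack([q * q, 2 * p * q, p * p], axis=1)


def predict_ancestry(
    gl: pd.DataFrame,
    panel: FrequencyPanel,
    max_iter: int = 200,
    tol: float = 1e-8,
    sample: str = "sample",
) -> AncestryResult:
    """Maximum-likelihood global ancestry proportions by EM.

    Each site's ancestry is modelled as a latent draw from mixture weights
    over the panel's populations; the site likelihood under population k
    integrates the genotype likelihoods against HWE at that population's
    frequencies.  The selected population (argmax weight) supplies the
    frequency column for kinship.
    """
    if len(gl) == 0:
        raise InsufficientDataError("empty genotype-likelihood profile")
    pops = panel.populations
    sub = panel.df.set_index("id").loc[gl.index]
    lin = _linear_gl(gl)
    # site-by-population marginal likelihoods
    lik = np.stack(
        [(lin * _hwe(sub[f"freq_{p}"].to_numpy())).sum(axis=1) for p in pops],
        axis=1,
    )
    w = np.full(len(pops), 1.0 / len(pops))
    for _ in range(max_iter):
        resp = lik * w
        resp /= resp.sum(axis=1, keepdims=True)
        w_new = resp.mean(axis=0)
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    proportions = {p: float(v) for p, v in zip(pops, w)}
    selected = max(proportions, key=proportions.get)
    return AncestryResult(sample, proportions, selected)


# ---------------------------------------------------------------------------
# pairwise kinship
# ---------------------------------------------------------------------------


def _pair_tables(p: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint genotype-pair probability tables (n_sites, 3, 3) for IBD 0/1/2.

    IBD1 is built from the shared-allele construction: the second genotype
    contains one allele drawn evenly from the first plus an independent
    HWE draw.
    """
    q = 1.0 - p
    h = _hwe(p)  # (n, 3)
    m0 = h[:, :, None] * h[:, None, :]
    eye = np.eye(3)
    m2 = h[:, :, None] * eye[None, :, :]
    # transition T[g1, g2] of sharing one allele
    n = len(p)
    t = np.zeros((n, 3, 3))
    t[:, 0, 0] = q
    t[:, 0, 1] = p
    t[:, 1, 0] = 0.5 * q
    t[:, 1, 1] = 0.5
    t[:, 1, 2] = 0.5 * p
    t[:, 2, 1] = q
    t[:, 2, 2] = p
    m1 = h[:, :, None] * t
    return m0, m1, m2


def pairwise_kinship(
    gl_a: pd.DataFrame,
    gl_b: pd.DataFrame,
    panel: FrequencyPanel,
    population: Optional[str] = None,
    categories: Sequence[RelationshipCategory] = tuple(CATEGORIES),
    pair: Tuple[str, str] = ("A", "B"),
    reference_genotypes: Optional[np.ndarray] = None,
    r2_threshold: float = 0.2,
    ld_window: int = 50,
) -> KinshipResult:
    """Relationship-category likelihoods for a pair of GL profiles.

    Overlapping sites are those with coverage >= 1 in both samples that
    are autosomal with reference frequencies available; when
    ``reference_genotypes`` (dosage matrix over panel columns) is given
    they are additionally LD-pruned at ``r2_threshold``.
    """
    population = population or panel.populations[0]
    df = panel.df
    usable = df[(df["chrom_class"] == "autosomal") & df["has_frequency"]]
    ids = usable["id"]
    in_both = ids.isin(gl_a.index[gl_a["coverage"] >= 1]) & ids.isin(
        gl_b.index[gl_b["coverage"] >= 1]
    )
    sites = usable[in_both.to_numpy()]
    if reference_genotypes is not None and len(sites):
        cols = sites.index.to_numpy()
        keep = prune_ld(
            sites, np.asarray(reference_genotypes)[:, cols],
            r2_threshold, ld_window,
        )
        sites = sites[keep]
    n_overlap = len(sites)
    if n_overlap == 0:
        raise InsufficientDataError(
            f"zero overlapping sites for pair {pair}; n_overlap_snps=0"
        )

    site_ids = sites["id"].to_numpy()
    p = sites[f"freq_{population}"].to_numpy()
    if np.any((p <= 0) | (p >= 1)):
        raise ParameterError("allele frequencies must lie strictly in (0, 1)")
    la = _linear_gl(gl_a.loc[site_ids])
    lb = _linear_gl(gl_b.loc[site_ids])
    m0, m1, m2 = _pair_tables(p)

    log10_l: Dict[str, float] = {}
    for cat in categories:
        k0, k1, k2 = cat.k
        m = k0 * m0 + k1 * m1 + k2 * m2
        per_site = np.einsum("si,sij,sj->s", la, m, lb)
        # a structurally impossible genotype pair (e.g. discordant
        # homozygotes under "self") gives 0; floor to keep logs finite
        per_site = np.maximum(per_site, 1e-300)
        log10_l[cat.label] = float(np.log10(per_site).sum())

    order = [c for c in _DISTANT_FIRST if c in log10_l]
    max_cat = order[0]
    for label in order[1:]:
        if log10_l[label] > log10_l[max_cat]:
            max_cat = label
    log10_lr = log10_l[max_cat] - log10_l["unrelated"]

    logs = np.array([log10_l[c] for c in order])
    post = np.power(10.0, logs - logs.max())
    post /= post.sum()
    posterior = {c: float(v) for c, v in zip(order, post)}

    strong = bool(
        log10_lr >= np.log10(LR_STRONG_SUPPORT)
        and posterior[max_cat] >= POSTERIOR_STRONG_SUPPORT
    )
    return KinshipResult(
        pair=pair,
        n_overlap_snps=n_overlap,
        log10_likelihood=log10_l,
        max_category=max_cat,
        log10_lr_vs_unrelated=log10_lr,
        posterior=posterior,
        strong_support=strong,
    )
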