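"""Genotype likelihoods from sparse, damage-bearing allele counts.

Low-coverage data from degraded remains cannot support hard genotype
calls, so every downstream comparison works from per-site likelihood
triples L(RR), L(RA), L(AA).  Post-mortem cytosine deamination inflates
the apparent alternate (or reference) allele at C/T and G/A sites near
fragment ends; its positional profile is estimated from the data and
folded into the per-read error model asymmetrically — a true C may be
read as T, never the reverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .errors import DamageEstimationError, ParameterError
from .synthetic import (
    SIDE_3P,
    SIDE_5P,
    FrequencyPanel,
    SiteObservation,
    _damage_source_product,
    damage_prone_side,
)

__all__ = [
    "DamageProfile",
    "GenotypeLikelihood",
    "estimate_damage_profile",
    "genotype_likelihoods",
    "gl_profile",
]

DEFAULT_MAX_DISTANCE = 15


@dataclass
class DamageProfile:
    """Positional deamination profile with a fitted exponential decay.

    ``rate5[d]`` is the empirical C->T mismatch rate at distance ``d``
    from the 5' end (``rate3`` for G->A at 3'); the fitted model is
    amplitude * exp(-d / scale) per end, used inside the likelihood and
    taken as zero beyond ``max_distance``.
    """

    rate5: np.ndarray
    rate3: np.ndarray
    amplitude5: float
    scale5: float
    amplitude3: float
    scale3: float
    max_distance: int = DEFAULT_MAX_DISTANCE
    warning: bool = False

    def rate(self, side: int, dist: np.ndarray) -> np.ndarray:
        """Fitted damage probability for reads at the given end distances."""
        amp, scale = (
            (self.amplitude5, self.scale5)
            if side == SIDE_5P
            else (self.amplitude3, self.scale3)
        )
        d = np.asarray(dist, dtype=float)
        out = amp * np.exp(-d / scale) if scale > 0 else np.zeros_like(d)
        return np.where(d <= self.max_distance, out, 0.0)

    @classmethod
    def zero(cls, max_distance: int = DEFAULT_MAX_DISTANCE,
             warning: bool = False) -> "DamageProfile":
        z = np.zeros(max_distance + 1)
        return cls(z, z.copy(), 0.0, 1.0, 0.0, 1.0, max_distance, warning)


@dataclass
class GenotypeLikelihood:
    """Log-likelihood triple (RR, RA, AA) for one site of one sample."""

    site_id: str
    log_l: np.ndarray  # shape (3,)
    coverage: int


def _fit_decay(dists: np.ndarray, rates: np.ndarray,
               weights: np.ndarray) -> Tuple[float, float]:
    """Weighted least-squares fit of amplitude * exp(-d / scale)."""
    mask = weights > 0
    if mask.sum() < 2 or not (rates[mask] > 0).any():
        return 0.0, 1.0
    d, r, w = dists[mask], rates[mask], weights[mask]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda x, a, s: a * np.exp(-x / s),
                d, r,
                p0=[max(r[0], 1e-3), 3.0],
                sigma=1.0 / np.sqrt(w),
                bounds=([0.0, 0.1], [1.0, 100.0]),
                maxfev=10000,
            )
        return float(popt[0]), float(popt[1])
    except RuntimeError:
        return float(max(r[0], 0.0)), 3.0


def estimate_damage_profile(
    observations: Iterable[SiteObservation],
    panel: FrequencyPanel,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    population: Optional[str] = None,
) -> DamageProfile:
    """Estimate the positional deamination profile from read observations.

    Only transition (C/T and G/A) sites are informative.  At a C/T site the
    expected T-allele read fraction without damage equals the population
    alternate frequency; the pooled excess over that expectation at each
    end distance estimates the per-read conversion probability, which is
    then summarised by a least-squares exponential-decay fit per end.
    """
    obs_list = list(observations)
    if not obs_list or all(o.coverage == 0 for o in obs_list):
        raise DamageEstimationError("no reads supplied")
    population = population or panel.populations[0]
    df = panel.df
    meta = {
        row.id: (damage_prone_side(row.ref, row.alt), row.ref, row.alt,
                 getattr(row, f"freq_{population}"))
        for row in df.itertuples()
    }

    n_bins = max_distance + 1
    # per end: reads, damage-product reads, expected product reads, 1-p mass
    stats = {SIDE_5P: np.zeros((n_bins, 3)), SIDE_3P: np.zeros((n_bins, 3))}
    any_prone = False
    for obs in obs_list:
        side, ref, alt, p_alt = meta.get(obs.site_id, (-1, "", "", np.nan))
        if side < 0 or obs.coverage == 0:
            continue
        any_prone = True
        src, prod = _damage_source_product(ref, alt)
        # the site's true product-allele fraction is estimated from reads on
        # the opposite (undamaged) fragment end, lightly shrunk toward the
        # population frequency; this avoids biasing the excess by the
        # sample's own genotype draws
        p_prod = p_alt if prod == 1 else 1.0 - p_alt
        clean = obs.sides != side
        n_clean = int(clean.sum())
        prod_clean = int((obs.alleles[clean] == prod).sum())
        f_site = (prod_clean + p_prod) / (n_clean + 1)
        sel = (obs.sides == side) & (obs.dists <= max_distance)
        if not sel.any():
            continue
        d = obs.dists[sel]
        is_prod = (obs.alleles[sel] == prod).astype(float)
        np.add.at(stats[side][:, 0], d, 1.0)
        np.add.at(stats[side][:, 1], d, is_prod)
        np.add.at(stats[side][:, 2], d, f_site)

    if not any_prone:
        return DamageProfile.zero(max_distance, warning=True)

    rates = {}
    for side, s in stats.items():
        n, prod_obs, prod_exp = s[:, 0], s[:, 1], s[:, 2]
        denom = n - prod_exp  # reads expected to be the source allele
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (prod_obs - prod_exp) / denom, 0.0)
        rates[side] = (np.clip(r, 0.0, 1.0), n)

    dists = np.arange(n_bins, dtype=float)
    amp5, sc5 = _fit_decay(dists, rates[SIDE_5P][0], rates[SIDE_5P][1])
    amp3, sc3 = _fit_decay(dists, rates[SIDE_3P][0], rates[SIDE_3P][1])
    return DamageProfile(
        rate5=rates[SIDE_5P][0],
        rate3=rates[SIDE_3P][0],
        amplitude5=amp5,
        scale5=sc5,
        amplitude3=amp3,
        scale3=sc3,
        max_distance=max_distance,
    )


def _read_probs(obs: SiteObservation, ref: str, alt: str, base_error: float,
                damage: Optional[DamageProfile]) -> np.ndarray:
    """P(observed allele | true allele) per read: shape (coverage, 2)."""
    n = obs.coverage
    eps = base_error
    # columns: true allele 0 (ref), true allele 1 (alt)
    probs = np.empty((n, 2))
    for true_allele in (0, 1):
        match = obs.alleles == true_allele
        probs[:, true_allele] = np.where(match, 1.0 - eps, eps)
    side = damage_prone_side(ref, alt)
    if damage is not None and side >= 0:
        src, prod = _damage_source_product(ref, alt)
        on_end = obs.sides == side
        delta = np.where(on_end, damage.rate(side, obs.dists), 0.0)
        # true source base: observed as product with delta + (1-delta)*eps,
        # retained with (1-delta)*(1-eps); other observations unaffected
        obs_is_prod = obs.alleles == prod
        obs_is_src = obs.alleles == src
        probs[:, src] = np.where(
            obs_is_prod, delta + (1 - delta) * eps,
            np.where(obs_is_src, (1 - delta) * (1 - eps), eps),
        )
    return probs


def genotype_likelihoods(
    obs: SiteObservation,
    ref: str,
    alt: str,
    base_error: float = 0.001,
    damage: Optional[DamageProfile] = None,
) -> GenotypeLikelihood:
    """Log-likelihood triple for one site from its read observations.

    Each read contributes a genotype-conditional mixture: under a
    heterozygote its true allele is an even draw between the two copies.
    Computation is in log space and safe for very deep sites.  Zero
    coverage yields the uninformative equal triple.
    """
    if not (0 < base_error < 0.5):
        raise ParameterError("base_error must lie in (0, 0.5)")
    if np.any((obs.alleles != 0) & (obs.alleles != 1)):
        raise ValueError(f"{obs.site_id}: alleles must be 0 (ref) or 1 (alt)")
    if obs.coverage == 0:
        return GenotypeLikelihood(obs.site_id, np.zeros(3), 0)
    probs = _read_probs(obs, ref, alt, base_error, damage)
    with np.errstate(divide="ignore"):
        log_l = np.array([
            np.sum(np.log(probs[:, 0])),
            np.sum(np.log(0.5 * (probs[:, 0] + probs[:, 1]))),
            np.sum(np.log(probs[:, 1])),
        ])
    return GenotypeLikelihood(obs.site_id, log_l, obs.coverage)


def gl_profile(
    observations: Iterable[SiteObservation],
    panel: FrequencyPanel,
    base_error: float = 0.001,
    damage: Optional[DamageProfile] = None,
):
    """Genotype-likelihood profile for one sample as a DataFrame.

    Rows align with covered panel sites; columns log_rr, log_ra, log_aa,
    coverage, indexed by site id.
    """
    import pandas as pd

    meta = {row.id: (row.ref, row.alt) for row in panel.df.itertuples()}
    rows = []
    for obs in observations:
        ref, alt = meta[obs.site_id]
        gl = genotype_likelihoods(obs, ref, alt, base_error, damage)
        rows.append((obs.site_id, *gl.log_l, gl.coverage))
    df = pd.DataFrame(
        rows, columns=["site_id", "log_rr", "log_ra", "log_aa", "coverage"]
    ).set_index("site_id")
    return df
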