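"""Promoter-interacting-region (PIR) calling against a distance-decay background.

Contact frequency between a bait and a genomic bin falls off with linear
separation.  This module estimates that decay empirically: cis counts are
pooled across baits into log-spaced distance strata (counting unobserved
bait–bin pairs as zeros), per-stratum means are made monotone non-increasing
by isotonic regression, and a single negative-binomial dispersion is
estimated by the method of moments.  A bait–bin observation is scored by the
upper-tail probability of its count under that background:
``score = -log10 P(X >= N)``.

Bins with score >= 5 that are not themselves bait bins and lie within 1 Mb
of the bait are called PIRs.  This is a deliberately simple background —
no convolution of biological and technical noise components and no
distance-dependent p-value reweighting, as in the full established caller —
but it exposes the same decision semantics (score scale, threshold 5,
non-bait bins, 1-Mb filter), and externally computed scores can be attached
via :func:`attach_external_scores` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.stats import nbinom, poisson

#: default score threshold for PIR calls (established-caller convention)
DEFAULT_SCORE_THRESHOLD = 5.0
#: default maximum bait–bin distance for PIR calls (bases)
DEFAULT_MAX_DISTANCE = 1_000_000
#: score assigned when the tail probability underflows
MAX_SCORE = 350.0

CALL_COLUMNS = ["bait_id", "other_end_id", "N", "dist", "expected", "score", "is_pir"]


@dataclass
class DecayProfile:
    """Expected count per bait–bin pair as a function of distance.

    ``edges`` are log-spaced distance-stratum boundaries (length k+1);
    ``mean`` holds the isotonic (monotone non-increasing) per-pair mean in
    each stratum; ``dispersion`` is the pooled negative-binomial dispersion
    alpha (variance = mu + alpha*mu^2; 0 means Poisson).
    """

    edges: np.ndarray
    mean: np.ndarray
    dispersion: float
    raw_mean: np.ndarray = field(default=None, repr=False)
    n_candidates: np.ndarray = field(default=None, repr=False)
    #: per-bait multiplicative scaling of the expected count (capture
    #: efficiency differs between baits); baits absent from the index get 1.
    bait_scaling: pd.Series = field(default=None, repr=False)

    @property
    def midpoints(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def total_candidates(self) -> int:
        return int(self.n_candidates.sum()) if self.n_candidates is not None else 0

    def expected_at(self, dist, bait_id=None) -> np.ndarray:
        """Stratum mean at each |distance| (step function, flat extrapolation).

        With ``bait_id`` given (scalar or array aligned with ``dist``), the
        mean is multiplied by that bait's scaling factor.
        """
        d = np.abs(np.atleast_1d(np.asarray(dist, dtype=float)))
        # log-log interpolation between stratum midpoints (flat beyond);
        # a step function would under-estimate the mean at the near edge of
        # each stratum and mis-calibrate the tail test there
        mid = self.midpoints
        positive = self.mean > 0
        if positive.sum() >= 2:
            log_mu = np.interp(
                np.log10(np.clip(d, 1.0, None)),
                np.log10(mid[positive]),
                np.log10(self.mean[positive]),
            )
            mu = 10.0**log_mu
        else:
            idx = np.clip(np.searchsorted(self.edges, d, side="right") - 1, 0, len(self.mean) - 1)
            mu = self.mean[idx]
        if bait_id is not None and self.bait_scaling is not None:
            scale = self.bait_scaling.reindex(np.atleast_1d(bait_id)).fillna(1.0).to_numpy()
            mu = mu * scale
        return mu


def distance_strata(
    min_distance: float, max_distance: float, n_strata: int = 20
) -> np.ndarray:
    """Log-spaced distance-stratum edges shared by the caller and the
    distance-matched randomisation in loop annotation."""
    return np.geomspace(min_distance, max_distance, n_strata + 1)


def candidate_pair_distances(
    bins: pd.DataFrame, baits: pd.DataFrame, max_distance: float
) -> pd.DataFrame:
    """All cis (bait, bin) pairs within ``max_distance``, with distances.

    Returns columns ``bait_id, other_end_id, dist, is_bait_bin``; this is
    the universe the background is estimated over and random bin sets are
    drawn from.
    """
    from capcraft.chinput import bin_to_bait_map

    b2b = bin_to_bait_map(bins, baits)
    frames = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        bsub = baits[baits["chrom"] == chrom]
        if bsub.empty:
            continue
        bin_mid = ((sub["start"] + sub["end"]) / 2.0).to_numpy()
        bin_ids = sub["id"].to_numpy()
        is_bait_bin = np.array([int(b) in b2b for b in bin_ids])
        for bait in bsub.itertuples(index=False):
            bait_mid = (bait.start + bait.end) / 2.0
            dist = np.abs(bin_mid - bait_mid)
            keep = (dist <= max_distance) & (dist > 0)
            frames.append(
                pd.DataFrame(
                    {
                        "bait_id": bait.id,
                        "other_end_id": bin_ids[keep],
                        "dist": dist[keep],
                        "is_bait_bin": is_bait_bin[keep],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["bait_id", "other_end_id", "dist", "is_bait_bin"])
    return pd.concat(frames, ignore_index=True)


def estimate_distance_decay(
    chinput: pd.DataFrame,
    bins: pd.DataFrame,
    baits: pd.DataFrame,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    n_strata: int = 20,
) -> DecayProfile:
    """Estimate the distance-decay background from a chinput table.

    Cis counts are pooled across baits into log-spaced distance strata;
    bait–bin pairs with no observed products contribute zeros.  The
    per-stratum mean is smoothed by isotonic regression (monotone
    non-increasing in distance, weighted by the number of candidate pairs);
    dispersion is a pooled method-of-moments estimate.
    """
    cis = chinput.dropna(subset=["dist"])
    if cis.empty:
        raise ValueError("chinput table has no cis rows: cannot estimate distance decay")
    candidates = candidate_pair_distances(bins, baits, max_distance)
    if candidates.empty:
        raise ValueError("no candidate bait-bin pairs within the distance range")
    min_dist = max(candidates["dist"].min(), 1.0)
    edges = distance_strata(min_dist * 0.999, max_distance, n_strata)
    cand_stratum = np.clip(
        np.searchsorted(edges, candidates["dist"].to_numpy(), side="right") - 1, 0, n_strata - 1
    )
    n_cand = np.bincount(cand_stratum, minlength=n_strata).astype(float)

    obs = cis[np.abs(cis["dist"]) <= max_distance]
    obs_stratum = np.clip(
        np.searchsorted(edges, np.abs(obs["dist"].to_numpy()), side="right") - 1, 0, n_strata - 1
    )

    # per-bait scaling: baits are captured with different efficiencies, so
    # the expected count of a (bait, bin) pair is s_bait * mu(distance)
    cand_per_bait = candidates.groupby("bait_id").size()
    obs_per_bait = obs.groupby("bait_id")["N"].sum().reindex(cand_per_bait.index).fillna(0.0)
    overall_rate = obs_per_bait.sum() / cand_per_bait.sum()
    if overall_rate <= 0:
        raise ValueError("no cis counts within the distance range")
    scaling = (obs_per_bait / cand_per_bait / overall_rate).clip(lower=0.05, upper=20.0)
    s_cand = scaling.reindex(candidates["bait_id"]).to_numpy()
    s_obs = scaling.reindex(obs["bait_id"]).fillna(1.0).to_numpy()

    # stratum mean: sum(N) / sum(s) over candidate pairs (zeros included)
    sum_s = np.bincount(cand_stratum, weights=s_cand, minlength=n_strata)
    sum_n = np.bincount(obs_stratum, weights=obs["N"].to_numpy(), minlength=n_strata)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw_mean = np.where(sum_s > 0, sum_n / sum_s, 0.0)

    # robust pooled NB dispersion from scale-normalised counts y = N / s:
    # Var(y) = mu/s + alpha*mu^2, so per stratum
    # alpha = (var_y - mu * E[1/s]) / mu^2; median across strata resists
    # inflation by genuine loops concentrated at a few distances
    y = obs["N"].to_numpy() / s_obs
    sum_y = np.bincount(obs_stratum, weights=y, minlength=n_strata)
    sum_y2 = np.bincount(obs_stratum, weights=y**2, minlength=n_strata)
    sum_inv_s = np.bincount(cand_stratum, weights=1.0 / s_cand, minlength=n_strata)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_y = np.where(n_cand > 0, sum_y / n_cand, 0.0)
        var_y = np.where(n_cand > 0, sum_y2 / n_cand, 0.0) - mean_y**2
        mean_inv_s = np.where(n_cand > 0, sum_inv_s / n_cand, 1.0)
    valid = (n_cand > 0) & (mean_y > 0)
    if valid.any():
        alphas = (var_y[valid] - mean_y[valid] * mean_inv_s[valid]) / mean_y[valid] ** 2
        alpha = float(np.clip(np.median(alphas), 0.0, None))
    else:
        alpha = 0.0
    weights = np.where(n_cand > 0, n_cand, 1e-9)
    iso = isotonic_regression(raw_mean, weights=weights, increasing=False)
    mean = np.maximum(np.asarray(iso.x), 0.0)
    return DecayProfile(
        edges=edges,
        mean=mean,
        dispersion=alpha,
        raw_mean=raw_mean,
        n_candidates=n_cand,
        bait_scaling=scaling,
    )


def fit_decay_exponent(profile: DecayProfile, min_distance: float = 0.0) -> float:
    """Log-log slope of the decay profile (the contact-law exponent, signed).

    Fits ``log10(mean) ~ log10(distance)`` over strata with positive mean
    and midpoint above ``min_distance``, weighted by candidate-pair counts.
    """
    mid = profile.midpoints
    mask = (profile.mean > 0) & (mid >= min_distance)
    if mask.sum() < 2:
        raise ValueError("too few informative strata to fit a decay exponent")
    # np.polyfit multiplies residuals by w, so sqrt gives candidate-count weights
    w = np.sqrt(profile.n_candidates[mask]) if profile.n_candidates is not None else None
    slope = np.polyfit(np.log10(mid[mask]), np.log10(profile.mean[mask]), 1, w=w)[0]
    return float(slope)


def _upper_tail_pvalue(n: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """P(X >= n) under NB(mean mu, dispersion alpha); Poisson when alpha ~ 0."""
    mu = np.clip(mu, 1e-12, None)
    if alpha < 1e-9:
        return poisson.sf(n - 1, mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return nbinom.sf(n - 1, size, p)


def call_pirs(
    chinput: pd.DataFrame,
    profile: DecayProfile,
    bins: pd.DataFrame,
    baits: pd.DataFrame,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> pd.DataFrame:
    """Score every observed cis bait–bin pair and flag PIRs.

    ``is_pir`` is true when score >= ``score_threshold``, the other end is
    not itself a bait bin, and the bait–bin distance is below
    ``max_distance``.  Trans rows are excluded (the distance filter makes
    them ineligible).
    """
    from capcraft.chinput import bin_to_bait_map

    cis = chinput.dropna(subset=["dist"]).copy()
    if cis.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    dist = np.abs(cis["dist"].to_numpy())
    mu = profile.expected_at(dist, bait_id=cis["bait_id"].to_numpy())
    pvals = _upper_tail_pvalue(cis["N"].to_numpy(), mu, profile.dispersion)
    with np.errstate(divide="ignore"):
        score = np.where(pvals > 0, -np.log10(pvals), MAX_SCORE)
    score = np.minimum(score, MAX_SCORE)
    b2b = bin_to_bait_map(bins, baits)
    non_bait = ~cis["other_end_id"].isin(b2b.keys()).to_numpy()
    out = pd.DataFrame(
        {
            "bait_id": cis["bait_id"].to_numpy(),
            "other_end_id": cis["other_end_id"].to_numpy(),
            "N": cis["N"].to_numpy(),
            "dist": cis["dist"].to_numpy(),
            "expected": mu,
            "score": score,
            "is_pir": (score >= score_threshold) & non_bait & (dist < max_distance),
        }
    )
    return out


def attach_external_scores(
    chinput: pd.DataFrame,
    scores: pd.DataFrame,
    bins: pd.DataFrame,
    baits: pd.DataFrame,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> pd.DataFrame:
    """Import per-pair scores from an external caller.

    ``scores`` must have columns ``bait_id, other_end_id, score``.  The PIR
    decision semantics (threshold, non-bait other end, distance filter) are
    identical to :func:`call_pirs`; pairs without an external score get
    score 0.
    """
    from capcraft.chinput import bin_to_bait_map

    cis = chinput.dropna(subset=["dist"]).copy()
    merged = cis.merge(scores[["bait_id", "other_end_id", "score"]], how="left")
    merged["score"] = merged["score"].fillna(0.0)
    merged["expected"] = np.nan
    dist = np.abs(merged["dist"].to_numpy())
    b2b = bin_to_bait_map(bins, baits)
    non_bait = ~merged["other_end_id"].isin(b2b.keys()).to_numpy()
    merged["is_pir"] = (merged["score"] >= score_threshold) & non_bait & (dist < max_distance)
    return merged[CALL_COLUMNS]


def pir_bins(calls: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """PIR rows joined with their bin coordinates (for BED export / annotation)."""
    pirs = calls[calls["is_pir"]]
    bin_ix = bins.set_index("id")
    out = pirs.copy()
    out["chrom"] = bin_ix["chrom"].reindex(pirs["other_end_id"]).to_numpy()
    out["start"] = bin_ix["start"].reindex(pirs["other_end_id"]).to_numpy()
    out["end"] = bin_ix["end"].reindex(pirs["other_end_id"]).to_numpy()
    return out.reset_index(drop=True)
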