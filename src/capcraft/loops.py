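"""Functional annotation of PIRs and loop-level statistics.

PIR bins are intersected with regulatory-element tracks (enhancers, CTCF
sites, DHSs, user-defined classes) to produce promoter–element loops, with
duplicate (bait, element) pairs collapsed.  Three statistics accompany the
annotation:

* enrichment of each element class in PIRs versus distance-matched random
  bin sets (default 100 sets),
* the expected number of TAD-boundary-crossing loops under random loop
  orientation (default 100 randomisations, median reported),
* the CTCF motif-convergence exact binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import binom

from capcraft.calling import distance_strata

LOOP_COLUMNS = [
    "bait_id",
    "other_end_id",
    "element_id",
    "feature_class",
    "chrom",
    "bait_mid",
    "pir_mid",
    "element_start",
    "element_end",
    "dist",
]

FEATURE_COLUMNS = ["chrom", "start", "end", "element_id", "feature_class"]


def annotate_pirs(
    pirs: pd.DataFrame,
    features: pd.DataFrame,
    bins: pd.DataFrame,
    baits: pd.DataFrame,
) -> pd.DataFrame:
    """Intersect PIR bins with regulatory features to form loops.

    ``pirs`` needs columns ``bait_id, other_end_id`` (e.g. the ``is_pir``
    rows of a call table); ``features`` needs ``chrom, start, end,
    element_id, feature_class``.  Every >= 1 bp overlap between a PIR bin
    and a feature yields a candidate loop; duplicates — the same
    (bait, element) reached through different PIR bins — are collapsed to
    one record (the first in genomic order).  PIRs overlapping nothing
    produce no loop.  The operation is idempotent at the loop level.
    """
    if pirs.empty or features.empty:
        return pd.DataFrame(columns=LOOP_COLUMNS)
    bin_ix = bins.set_index("id")
    bait_ix = baits.set_index("id")
    rows = []
    for chrom, fsub in features.groupby("chrom", sort=False):
        fstart = fsub["start"].to_numpy()
        fend = fsub["end"].to_numpy()
        psub = pirs[bin_ix["chrom"].reindex(pirs["other_end_id"]).to_numpy() == chrom]
        if psub.empty:
            continue
        pstart = bin_ix["start"].reindex(psub["other_end_id"]).to_numpy()
        pend = bin_ix["end"].reindex(psub["other_end_id"]).to_numpy()
        hit_p, hit_f = np.nonzero(
            (pstart[:, None] < fend[None, :]) & (fstart[None, :] < pend[:, None])
        )
        for pi, fi in zip(hit_p, hit_f):
            prow = psub.iloc[pi]
            frow = fsub.iloc[fi]
            bait = bait_ix.loc[int(prow["bait_id"])]
            bait_mid = (bait["start"] + bait["end"]) / 2.0
            pir_mid = (pstart[pi] + pend[pi]) / 2.0
            rows.append(
                (
                    int(prow["bait_id"]),
                    int(prow["other_end_id"]),
                    frow["element_id"],
                    frow["feature_class"],
                    chrom,
                    bait_mid,
                    pir_mid,
                    int(frow["start"]),
                    int(frow["end"]),
                    abs(pir_mid - bait_mid),
                )
            )
    loops = pd.DataFrame(rows, columns=LOOP_COLUMNS)
    if loops.empty:
        return loops
    loops = loops.sort_values(["chrom", "bait_mid", "pir_mid"], kind="stable")
    loops = loops.drop_duplicates(subset=["bait_id", "element_id"], keep="first")
    return loops.reset_index(drop=True)


@dataclass
class EnrichmentResult:
    feature_class: str
    observed: int
    expected: float
    sd: float
    log2_ratio: float
    n_sets: int


def enrichment_vs_random(
    pirs: pd.DataFrame,
    features: pd.DataFrame,
    bins: pd.DataFrame,
    baits: pd.DataFrame,
    n_sets: int = 100,
    max_distance: float = 1_000_000,
    n_strata: int = 20,
    rng=None,
) -> pd.DataFrame:
    """Enrichment of feature classes in PIRs vs distance-matched random bins.

    For each of ``n_sets`` draws, a random set of non-bait candidate
    bait–bin pairs is sampled with the same per-distance-stratum
    multiplicities as the observed PIR set (strata are the same log-spaced
    bins the decay profile uses).  The observed count is the number of PIRs
    overlapping at least one feature of the class; expected is the mean over
    random sets, with its s.d. and log2(observed/expected).

    A stratum with too few candidates is widened to its neighbours (with a
    warning); sampling is without replacement within a stratum.
    """
    import warnings

    from capcraft.calling import candidate_pair_distances

    rng = np.random.default_rng(rng)
    candidates = candidate_pair_distances(bins, baits, max_distance)
    candidates = candidates[~candidates["is_bait_bin"]].reset_index(drop=True)
    if candidates.empty:
        raise ValueError("no non-bait candidate bins available for randomisation")
    edges = distance_strata(max(candidates["dist"].min() * 0.999, 1.0), max_distance, n_strata)
    cand_stratum = np.clip(
        np.searchsorted(edges, candidates["dist"].to_numpy(), side="right") - 1, 0, n_strata - 1
    )
    bin_ix = bins.set_index("id")
    bait_ix = baits.set_index("id")
    bait_mid = (
        bait_ix["start"].reindex(pirs["bait_id"]).to_numpy()
        + bait_ix["end"].reindex(pirs["bait_id"]).to_numpy()
    ) / 2.0
    pir_mid = (
        bin_ix["start"].reindex(pirs["other_end_id"]).to_numpy()
        + bin_ix["end"].reindex(pirs["other_end_id"]).to_numpy()
    ) / 2.0
    pir_dist = np.abs(pir_mid - bait_mid)
    pir_stratum = np.clip(np.searchsorted(edges, pir_dist, side="right") - 1, 0, n_strata - 1)
    need = np.bincount(pir_stratum, minlength=n_strata)

    # per-class overlap flag for every bin (vectorised, reused across draws)
    classes = list(dict.fromkeys(features["feature_class"]))
    bin_flags = _bin_overlap_flags(bins, features, classes)

    pir_bin_ids = pirs["other_end_id"].to_numpy()
    results = []
    # pre-draw random sets once, shared across classes
    draws = []
    for _ in range(n_sets):
        chosen = []
        for s in range(n_strata):
            if need[s] == 0:
                continue
            pool = np.nonzero(cand_stratum == s)[0]
            lo, hi = s, s
            while len(pool) < need[s] and (lo > 0 or hi < n_strata - 1):
                lo, hi = max(lo - 1, 0), min(hi + 1, n_strata - 1)
                pool = np.nonzero((cand_stratum >= lo) & (cand_stratum <= hi))[0]
                warnings.warn(
                    f"distance stratum {s} has too few candidates; widened to [{lo}, {hi}]",
                    stacklevel=2,
                )
            replace = len(pool) < need[s]
            chosen.append(rng.choice(pool, size=need[s], replace=replace))
        draws.append(candidates["other_end_id"].to_numpy()[np.concatenate(chosen)])

    for cls in classes:
        flags = bin_flags[cls]
        observed = int(flags.reindex(pir_bin_ids).fillna(False).to_numpy().sum())
        rand_counts = np.array(
            [flags.reindex(drawn).fillna(False).to_numpy().sum() for drawn in draws], dtype=float
        )
        expected = float(rand_counts.mean())
        sd = float(rand_counts.std(ddof=1)) if n_sets > 1 else 0.0
        log2_ratio = float(np.log2(observed / expected)) if expected > 0 and observed > 0 else np.nan
        results.append(
            (cls, observed, expected, sd, log2_ratio, n_sets)
        )
    return pd.DataFrame(
        results, columns=["feature_class", "observed", "expected", "sd", "log2_ratio", "n_sets"]
    )


def _bin_overlap_flags(bins, features, classes) -> Mapping[str, pd.Series]:
    out = {}
    for cls in classes:
        fsub = features[features["feature_class"] == cls]
        flag = np.zeros(len(bins), dtype=bool)
        for chrom, csub in fsub.groupby("chrom", sort=False):
            mask = (bins["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            bstart = bins["start"].to_numpy()[mask]
            bend = bins["end"].to_numpy()[mask]
            fs = csub["start"].to_numpy()
            fe = csub["end"].to_numpy()
            hit = ((bstart[:, None] < fe[None, :]) & (fs[None, :] < bend[:, None])).any(axis=1)
            flag[np.nonzero(mask)[0]] = hit
        out[cls] = pd.Series(flag, index=bins["id"].to_numpy())
    return out


def classify_tad_crossing(loops: pd.DataFrame, boundaries: pd.DataFrame) -> pd.DataFrame:
    """Label each intra-chromosomal loop inter-TAD or intra-TAD.

    A loop is inter-TAD iff at least one boundary position lies strictly
    between its bait midpoint and PIR midpoint.  ``boundaries`` has columns
    ``chrom, pos`` (intervals should be collapsed to midpoints upstream).
    Trans loops are excluded from the output.
    """
    out = loops.dropna(subset=["bait_mid", "pir_mid"]).copy()
    inter = np.zeros(len(out), dtype=bool)
    for chrom, bsub in boundaries.groupby("chrom", sort=False):
        pos = np.sort(bsub["pos"].to_numpy())
        mask = (out["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        lo = np.minimum(out["bait_mid"].to_numpy()[mask], out["pir_mid"].to_numpy()[mask])
        hi = np.maximum(out["bait_mid"].to_numpy()[mask], out["pir_mid"].to_numpy()[mask])
        # boundaries strictly inside (lo, hi)
        n_inside = np.searchsorted(pos, hi, side="left") - np.searchsorted(pos, lo, side="right")
        inter[np.nonzero(mask)[0]] = n_inside > 0
    out["inter_tad"] = inter
    return out


def _place_oriented(bait_mid, dist, sign, size):
    return np.clip(bait_mid + sign * dist, 0, size - 1)


def simulate_expected_intertad(
    loops: pd.DataFrame,
    boundaries: pd.DataFrame,
    sizes: Mapping[str, int],
    reps: int = 100,
    rng=None,
) -> tuple[float, np.ndarray]:
    """Expected inter-TAD loop count under random loop orientation.

    Each randomisation keeps every loop's bait and distance but re-places
    the PIR at bait ± distance with equal probability (positions clipped to
    the chromosome).  Returns the median inter-TAD count over ``reps``
    randomisations and the full distribution.
    """
    rng = np.random.default_rng(rng)
    loops = loops.dropna(subset=["bait_mid", "pir_mid"]).reset_index(drop=True)
    n = len(loops)
    if n == 0:
        return 0.0, np.zeros(reps)
    chrom_size = loops["chrom"].map(sizes).to_numpy(dtype=float)
    bait_mid = loops["bait_mid"].to_numpy(dtype=float)
    dist = np.abs(loops["pir_mid"].to_numpy() - bait_mid)
    # precompute crossing outcome for both orientations of each loop
    cross = np.zeros((n, 2), dtype=bool)
    for j, sign in enumerate((+1, -1)):
        placed = _place_oriented(bait_mid, dist, sign, chrom_size)
        labelled = classify_tad_crossing(
            loops.assign(pir_mid=placed), boundaries
        )
        cross[:, j] = labelled["inter_tad"].to_numpy()
    signs = rng.integers(0, 2, size=(reps, n))  # 0 -> +, 1 -> -
    counts = np.where(signs == 0, cross[:, 0][None, :], cross[:, 1][None, :]).sum(axis=1)
    return float(np.median(counts)), counts.astype(float)


@dataclass
class ConvergenceResult:
    n_convergent: int
    n_total: int
    null_p: float
    pvalue: float


def convergence_pvalue(n_convergent: int, n_total: int, null_p: float = 0.25) -> float:
    """One-sided upper-tail exact binomial probability of >= n_convergent
    convergent pairs among n_total under the null probability ``null_p``
    (one of the four equiprobable strand configurations is convergent)."""
    if not 0 <= n_convergent <= n_total:
        raise ValueError("n_convergent must be between 0 and n_total")
    return float(binom.sf(n_convergent - 1, n_total, null_p))


def ctcf_convergence_test(
    loops: pd.DataFrame,
    motifs: pd.DataFrame,
    baits: pd.DataFrame,
    bins: pd.DataFrame,
    null_p: float = 0.25,
) -> ConvergenceResult:
    """CTCF motif-convergence test on loop anchors.

    ``loops`` should already be restricted to loops whose two anchors both
    carry CTCF binding evidence; ``motifs`` has columns ``chrom, pos,
    strand, score`` (genomic motif hits).  For each loop, the best-scoring
    motif inside the bait interval and inside the PIR bin is selected; loops
    lacking a motif on either anchor are discarded.  With anchors in genomic
    order, a pair is convergent iff the left anchor's motif is on the + and
    the right anchor's on the - strand.  The p-value is the one-sided exact
    binomial upper tail under ``null_p``.
    """
    bait_ix = baits.set_index("id")
    bin_ix = bins.set_index("id")
    n_total = 0
    n_convergent = 0
    for loop in loops.itertuples(index=False):
        bait = bait_ix.loc[int(loop.bait_id)]
        pbin = bin_ix.loc[int(loop.other_end_id)]
        if bait["chrom"] != pbin["chrom"]:
            continue
        m_bait = _best_motif(motifs, bait["chrom"], bait["start"], bait["end"])
        m_pir = _best_motif(motifs, pbin["chrom"], pbin["start"], pbin["end"])
        if m_bait is None or m_pir is None:
            continue
        if bait["start"] <= pbin["start"]:
            left, right = m_bait, m_pir
        else:
            left, right = m_pir, m_bait
        n_total += 1
        if left[1] == "+" and right[1] == "-":
            n_convergent += 1
    pvalue = convergence_pvalue(n_convergent, n_total, null_p) if n_total else float("nan")
    return ConvergenceResult(n_convergent, n_total, null_p, pvalue)


def _best_motif(motifs: pd.DataFrame, chrom, start, end):
    sub = motifs[(motifs["chrom"] == chrom) & (motifs["pos"] >= start) & (motifs["pos"] < end)]
    if sub.empty:
        return None
    best = sub.loc[sub["score"].idxmax()]
    return float(best["score"]), str(best["strand"])


def read_features_bed(path, default_class: Optional[str] = None) -> pd.DataFrame:
    """Read a feature BED: chrom, start, end[, name].

    The name field supplies ``feature_class``; with 3 columns (or
    ``default_class`` set) all rows get one class.  Element ids are
    ``class:serial``.
    """
    raw = pd.read_csv(path, sep="\t", header=None)
    raw = raw.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if 3 in raw.columns and default_class is None:
        cls = raw[3].astype(str)
    else:
        cls = pd.Series([default_class or "feature"] * len(raw))
    out = pd.DataFrame(
        {
            "chrom": raw["chrom"].astype(str),
            "start": raw["start"].astype(int),
            "end": raw["end"].astype(int),
            "feature_class": cls,
        }
    )
    out["element_id"] = out["feature_class"] + ":" + out.groupby("feature_class").cumcount().astype(str)
    return out[FEATURE_COLUMNS]


def read_tad_boundaries_bed(path) -> pd.DataFrame:
    """TAD boundaries from BED; intervals are collapsed to their midpoints."""
    raw = pd.read_csv(path, sep="\t", header=None)
    return pd.DataFrame(
        {
            "chrom": raw[0].astype(str),
            "pos": ((raw[1].astype(int) + raw[2].astype(int)) // 2),
        }
    )


def read_motifs_tsv(path) -> pd.DataFrame:
    """Motif-hit table: chrom, pos, strand, score (tab-delimited with header)."""
    return pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "pos": int, "strand": str, "score": float}
    )
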