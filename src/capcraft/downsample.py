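"""Coverage-saturation analysis by per-bait downsampling.

Starting from chinput tables, per-bait coverage is stepwise reduced by
drawing unique ligation products uniformly without replacement; loops are
re-called at every level and compared with a *standard pool* — the loops
found both in the full data and in the top (start-level) downsample.  The
retained fraction per loop class, averaged over independent repetitions,
forms a retention curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from capcraft.calling import (
    DEFAULT_MAX_DISTANCE,
    DEFAULT_SCORE_THRESHOLD,
    call_pirs,
    estimate_distance_decay,
)
from capcraft.chinput import bait_coverage
from capcraft.loops import annotate_pirs


@dataclass(frozen=True)
class SubsampleSchedule:
    """A stepwise per-bait subsampling schedule.

    ``start`` is the products-per-bait level everything is first downsampled
    to; each of ``rounds`` subsequent levels removes ``decrement`` products
    per bait.  ``per_replicate`` schedules apply the level to each replicate
    separately (replicates are combined after subsampling); combined
    schedules treat the level as the total across replicates.
    """

    start: int
    decrement: int
    rounds: int
    per_replicate: bool = True
    name: str = "custom"

    def __post_init__(self):
        if self.start - self.rounds * self.decrement < 0:
            raise ValueError("schedule would go below zero products per bait")

    @property
    def levels(self) -> list[int]:
        """All coverage levels, the start level first."""
        return [self.start - i * self.decrement for i in range(self.rounds + 1)]


# blood-cell preset: 10,000 per replicate, 29 rounds of 333 fewer products.
# Described equivalently as 30,000 combined across the 3 replicates stepping
# by ~1,000; note 3 x 333 = 999, a 1-in-1,000 discrepancy between the two
# phrasings that the per-replicate form resolves.
assert 3 * 333 == 999
SCHEDULE_PRESETS = {
    "blood": SubsampleSchedule(start=10_000, decrement=333, rounds=29, per_replicate=True, name="blood"),
    "hela": SubsampleSchedule(start=15_000, decrement=1_000, rounds=14, per_replicate=True, name="hela"),
    "chesi": SubsampleSchedule(
        start=20_000, decrement=1_000, rounds=19, per_replicate=False, name="chesi"
    ),
}


def select_covered_baits(
    coverages: Sequence[pd.Series],
    min_coverage: Optional[float] = None,
    top_n: Optional[int] = None,
    n_choose: Optional[int] = None,
    rng=None,
) -> list[int]:
    """Select baits by coverage across experiments.

    ``coverages`` is one per-bait coverage Series per experiment.  With
    ``min_coverage``, baits whose coverage strictly exceeds it in *every*
    experiment are eligible; with ``top_n``, the best-covered baits by
    minimum coverage across experiments are taken.  ``n_choose`` draws a
    seeded uniform random subset of the eligible baits.
    """
    if min_coverage is None and top_n is None:
        raise ValueError("one of min_coverage or top_n is required")
    table = pd.concat(coverages, axis=1).fillna(0)
    floor = table.min(axis=1)
    if min_coverage is not None:
        eligible = floor[floor > min_coverage].index.to_list()
    else:
        eligible = floor.sort_values(ascending=False).index[:top_n].to_list()
    if n_choose is not None:
        if len(eligible) < n_choose:
            raise ValueError(
                f"only {len(eligible)} eligible baits, cannot choose {n_choose}"
            )
        rng = np.random.default_rng(rng)
        eligible = list(rng.choice(np.array(eligible), size=n_choose, replace=False))
    return [int(b) for b in eligible]


def subsample_chinput(
    chinput: pd.DataFrame,
    target_per_bait: int,
    rng=None,
    baits: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Downsample each bait to exactly ``target_per_bait`` unique products.

    Products are drawn uniformly without replacement from the multiset
    expansion of the bait's rows (a multivariate hypergeometric draw over
    the row counts).  With ``baits`` given, only those baits are kept (and
    subsampled); otherwise every bait in the table is subsampled.
    A bait with fewer products than the target raises an error naming it.
    """
    rng = np.random.default_rng(rng)
    if baits is not None:
        chinput = chinput[chinput["bait_id"].isin(set(baits))]
    pieces = []
    for bait_id, group in chinput.groupby("bait_id", sort=True):
        counts = group["N"].to_numpy(dtype=np.int64)
        total = int(counts.sum())
        if total < target_per_bait:
            raise ValueError(
                f"bait {bait_id} has only {total} unique products, cannot subsample to {target_per_bait}"
            )
        if total == target_per_bait:
            pieces.append(group)
            continue
        new_counts = rng.multivariate_hypergeometric(counts, target_per_bait)
        kept = new_counts > 0
        sub = group.loc[kept].copy()
        sub["N"] = new_counts[kept]
        pieces.append(sub)
    if not pieces:
        return chinput.iloc[0:0]
    return pd.concat(pieces, ignore_index=True)


def combine_chinputs(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum counts of several chinput tables (replicate pooling)."""
    cat = pd.concat(tables, ignore_index=True)
    out = (
        cat.groupby(["bait_id", "other_end_id"], sort=True)
        .agg(N=("N", "sum"), dist=("dist", "first"))
        .reset_index()
    )
    return out[["bait_id", "other_end_id", "N", "dist"]]


def build_standard_pool(loops_full: pd.DataFrame, loops_top: pd.DataFrame) -> pd.DataFrame:
    """Loops conserved between the full data and the top downsample.

    Identity is the (bait, element) pair; the feature class is carried
    along.  Loops gained by subsampling (present only in the downsample)
    are excluded — they behave as apparent false positives.
    """
    key = ["bait_id", "element_id"]
    pool = loops_full.merge(loops_top[key].drop_duplicates(), on=key, how="inner")
    return pool.reset_index(drop=True)


def call_and_annotate(
    chinput: pd.DataFrame,
    bins: pd.DataFrame,
    baits: pd.DataFrame,
    features: pd.DataFrame,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> pd.DataFrame:
    """Convenience pipeline: decay background -> PIR calls -> annotated loops."""
    profile = estimate_distance_decay(chinput, bins, baits, max_distance=max_distance)
    calls = call_pirs(
        chinput, profile, bins, baits, score_threshold=score_threshold, max_distance=max_distance
    )
    return annotate_pirs(calls[calls["is_pir"]], features, bins, baits)


def retention_fraction(loops: pd.DataFrame, pool: pd.DataFrame) -> pd.Series:
    """Fraction of standard-pool loops recovered, per feature class."""
    key = ["bait_id", "element_id"]
    out = {}
    for cls, psub in pool.groupby("feature_class"):
        lsub = loops[loops["feature_class"] == cls]
        hit = psub.merge(lsub[key].drop_duplicates(), on=key, how="inner")
        out[cls] = len(hit) / len(psub)
    return pd.Series(out, name="retained_fraction")


def retention_curve(
    replicates: Sequence[pd.DataFrame],
    schedule: SubsampleSchedule,
    bins: pd.DataFrame,
    baits: pd.DataFrame,
    features: pd.DataFrame,
    seed: int,
    n_repetitions: int = 3,
    bait_ids: Optional[Sequence[int]] = None,
    n_choose: Optional[int] = None,
    min_coverage: Optional[float] = None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retention of standard-pool loops across a downsampling schedule.

    For each of ``n_repetitions`` independent repetitions (separate random
    bait subsets when ``n_choose`` is given, always separate subsampling
    randomness): the replicate chinputs are restricted to the selected
    baits; the *full* combined data and the start-level downsample define
    the standard pool; every schedule level is then subsampled from the
    start-level tables, replicates are combined, loops are called and
    annotated, and the retained fraction per loop class is recorded.

    One master ``seed`` deterministically spawns per-repetition,
    per-level, per-replicate randomness, so any round is reproducible in
    isolation.

    Returns ``(tidy, summary)``: per-repetition values and the
    across-repetition mean and s.d. per level and class.
    """
    master = np.random.SeedSequence(seed)
    rep_seqs = master.spawn(n_repetitions)
    records = []
    for r, rep_seq in enumerate(rep_seqs):
        sel_rng, sub_seq = np.random.default_rng(rep_seq.spawn(1)[0]), rep_seq
        if bait_ids is not None:
            chosen = list(bait_ids)
        elif min_coverage is not None or n_choose is not None:
            covs = [bait_coverage(t) for t in replicates]
            chosen = select_covered_baits(
                covs,
                min_coverage=min_coverage if min_coverage is not None else schedule.start,
                n_choose=n_choose,
                rng=sel_rng,
            )
        else:
            # default: baits covered above the schedule start in every replicate
            covs = [bait_coverage(t) for t in replicates]
            chosen = select_covered_baits(covs, min_coverage=schedule.start)
        scoped = [t[t["bait_id"].isin(set(chosen))] for t in replicates]
        full = combine_chinputs(scoped)
        loops_full = call_and_annotate(
            full, bins, baits, features, score_threshold, max_distance
        )
        # start-level downsample, per replicate or combined
        level_seqs = sub_seq.spawn(len(schedule.levels))
        start_tables = _subsample_level(scoped, schedule, schedule.start, level_seqs[0])
        start_combined = combine_chinputs(start_tables)
        loops_top = call_and_annotate(
            start_combined, bins, baits, features, score_threshold, max_distance
        )
        pool = build_standard_pool(loops_full, loops_top)
        if pool.empty:
            raise ValueError("standard pool is empty: nothing to measure retention against")
        for li, level in enumerate(schedule.levels):
            if li == 0:
                loops_level = loops_top
            else:
                tables = _subsample_level(start_tables, schedule, level, level_seqs[li])
                combined = combine_chinputs(tables)
                loops_level = call_and_annotate(
                    combined, bins, baits, features, score_threshold, max_distance
                )
            retained = retention_fraction(loops_level, pool)
            for cls, frac in retained.items():
                records.append(
                    {
                        "repetition": r,
                        "level": level,
                        "feature_class": cls,
                        "retained_fraction": frac,
                        "pool_size": int((pool["feature_class"] == cls).sum()),
                    }
                )
    tidy = pd.DataFrame(records)
    summary = (
        tidy.groupby(["level", "feature_class"])["retained_fraction"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
        .sort_values(["feature_class", "level"], ascending=[True, False])
        .reset_index(drop=True)
    )
    return tidy, summary


def _subsample_level(from_tables, schedule, level, seq):
    """Subsample every replicate table to ``level`` (per-replicate or combined)."""
    child = seq.spawn(len(from_tables))
    if schedule.per_replicate:
        targets = [level] * len(from_tables)
    else:
        # combined schedule: split the total as evenly as possible
        base, extra = divmod(level, len(from_tables))
        targets = [base + (1 if i < extra else 0) for i in range(len(from_tables))]
    return [
        subsample_chinput(t, target, rng=np.random.default_rng(c))
        for t, target, c in zip(from_tables, targets, child)
    ]
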