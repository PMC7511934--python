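"""Genomic binning, bait definition and chinput count tables.

The genome is tiled with fixed-size bins (default 2 kb).  Bins containing at
least one hybridisation probe become baits; runs of adjacent probe-bearing
bins are merged into a single bait.  Valid proximity-ligation pairs are then
converted into a chinput table: one row per (bait, other-end bin) with the
number of unique ligation products joining them.

File dialects: chinput is tab-delimited with a ``baitID/otherEndID/N/distSign``
header; rmap and baitmap are emitted 1-based inclusive (the established
design-file convention) while everything in memory stays 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

BIN_COLUMNS = ["chrom", "start", "end", "id"]
BAIT_COLUMNS = ["chrom", "start", "end", "id", "name", "n_probes"]
PAIR_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
CHINPUT_COLUMNS = ["bait_id", "other_end_id", "N", "dist"]

#: unique-ligation-product count that per-bait coverage is normalised to
COVERAGE_NORMALISATION = 10_000_000


def build_bin_map(sizes: Mapping[str, int], bin_size: int = 2000) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping bins of ``bin_size`` bases.

    The final bin of a chromosome may be shorter.  Ids are global, ascending
    in genomic order with chromosomes in input order.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    next_id = 0
    for chrom, length in sizes.items():
        starts = np.arange(0, length, bin_size)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + bin_size, length)), next_id))
            next_id += 1
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def merge_bait_bins(bins: pd.DataFrame, probes: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent probe-bearing bins into baits.

    A bin is probe-bearing when at least one probe overlaps it (a probe
    straddling a bin boundary targets both bins).  Maximal runs of adjacent
    probe-bearing bins on the same chromosome become one bait; the bait id
    is the id of its first bin, and the bait name joins the promoters of all
    probes it contains.  ``n_probes`` counts distinct probes overlapping the
    bait.
    """
    if probes.empty:
        return pd.DataFrame(columns=BAIT_COLUMNS)
    known = set(bins["chrom"])
    unknown = set(probes["chrom"]) - known
    if unknown:
        raise ValueError(f"probes on chromosomes absent from the bin map: {sorted(unknown)}")
    bin_flags = {}
    bin_probes: dict[int, list[int]] = {}
    for chrom, sub in bins.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["id"].to_numpy()
        psub = probes[probes["chrom"] == chrom]
        for pi, prow in zip(psub.index, psub.itertuples(index=False)):
            if prow.start < 0 or prow.end > ends[-1]:
                raise ValueError(f"probe {prow.start}-{prow.end} outside chromosome {chrom}")
            lo = np.searchsorted(ends, prow.start, side="right")
            hi = np.searchsorted(starts, prow.end, side="left")
            for b in range(lo, hi):
                bin_probes.setdefault(int(ids[b]), []).append(pi)
                bin_flags[int(ids[b])] = True
    flagged = bins[bins["id"].isin(bin_flags)].sort_values("id")
    rows = []
    run: list = []
    prev = None
    for b in flagged.itertuples(index=False):
        if prev is not None and b.chrom == prev.chrom and b.start == prev.end and b.id == prev.id + 1:
            run.append(b)
        else:
            if run:
                rows.append(_finish_bait(run, bin_probes, probes))
            run = [b]
        prev = b
    if run:
        rows.append(_finish_bait(run, bin_probes, probes))
    return pd.DataFrame(rows, columns=BAIT_COLUMNS)


def _finish_bait(run, bin_probes, probes):
    probe_idx = sorted({i for b in run for i in bin_probes.get(int(b.id), [])})
    names = sorted(set(probes.loc[probe_idx, "promoter"].astype(str)))
    return (
        run[0].chrom,
        run[0].start,
        run[-1].end,
        int(run[0].id),
        ",".join(names),
        len(probe_idx),
    )


def deduplicate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Remove PCR duplicates: identical anchor-coordinate pairs.

    Anchors are canonically ordered by (chrom, pos) before comparison, so
    the two read orientations of the same ligation product collapse;
    strands are ignored.
    """
    a = pairs[["chrom1", "pos1"]].to_numpy()
    b = pairs[["chrom2", "pos2"]].to_numpy()
    swap = (pairs["chrom2"] < pairs["chrom1"]) | (
        (pairs["chrom1"] == pairs["chrom2"]) & (pairs["pos2"] < pairs["pos1"])
    )
    swap = swap.to_numpy()
    first = np.where(swap[:, None], b, a)
    second = np.where(swap[:, None], a, b)
    key = pd.DataFrame(
        {
            "c1": first[:, 0],
            "p1": first[:, 1].astype(np.int64),
            "c2": second[:, 0],
            "p2": second[:, 1].astype(np.int64),
        }
    )
    keep = ~key.duplicated()
    return pairs.loc[keep.to_numpy()].reset_index(drop=True)


def assign_bins(chroms, positions, bins: pd.DataFrame) -> np.ndarray:
    """Bin id for each (chrom, position); raises on off-genome anchors."""
    out = np.full(len(chroms), -1, dtype=np.int64)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    for chrom, sub in bins.groupby("chrom", sort=False):
        mask = chroms == chrom
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["id"].to_numpy()
        pos = positions[mask]
        if (pos < 0).any() or (pos >= ends[-1]).any():
            bad = pos[(pos < 0) | (pos >= ends[-1])][0]
            raise ValueError(f"anchor position {bad} outside chromosome {chrom}")
        idx = np.searchsorted(starts, pos, side="right") - 1
        out[mask] = ids[idx]
    unknown = out < 0
    if unknown.any():
        raise ValueError(f"anchors on chromosomes absent from the bin map: {set(chroms[unknown])}")
    return out


def bin_to_bait_map(bins: pd.DataFrame, baits: pd.DataFrame) -> dict[int, int]:
    """``{bin id: bait id}`` for every bin inside a bait interval."""
    mapping: dict[int, int] = {}
    for bait in baits.itertuples(index=False):
        sub = bins[
            (bins["chrom"] == bait.chrom) & (bins["start"] >= bait.start) & (bins["end"] <= bait.end)
        ]
        for b in sub["id"]:
            mapping[int(b)] = int(bait.id)
    return mapping


def pairs_to_chinput(
    pairs: pd.DataFrame,
    bins: pd.DataFrame,
    baits: pd.DataFrame,
    dedup: bool = True,
) -> pd.DataFrame:
    """Aggregate valid pairs into a bait × other-end count table.

    Every unique pair with at least one anchor inside a bait contributes:
    one row keyed by that bait and the other anchor's bin.  Bait–bait pairs
    contribute one row per bait anchor (two rows).  Pairs touching no bait
    are dropped.  ``dist`` is the signed distance from the bait midpoint to
    the other-end bin midpoint for cis rows, NaN for trans rows.

    Anchors are assigned to bins by their mapped position.
    """
    if dedup:
        pairs = deduplicate_pairs(pairs)
    if pairs.empty:
        return pd.DataFrame(columns=CHINPUT_COLUMNS)
    bin1 = assign_bins(pairs["chrom1"].to_numpy(), pairs["pos1"].to_numpy(), bins)
    bin2 = assign_bins(pairs["chrom2"].to_numpy(), pairs["pos2"].to_numpy(), bins)
    b2b = bin_to_bait_map(bins, baits)
    bait1 = np.array([b2b.get(int(b), -1) for b in bin1])
    bait2 = np.array([b2b.get(int(b), -1) for b in bin2])
    rows = []
    for anchor_bait, other_bin in ((bait1, bin2), (bait2, bin1)):
        mask = anchor_bait >= 0
        rows.append(pd.DataFrame({"bait_id": anchor_bait[mask], "other_end_id": other_bin[mask]}))
    long = pd.concat(rows, ignore_index=True)
    if long.empty:
        return pd.DataFrame(columns=CHINPUT_COLUMNS)
    table = long.groupby(["bait_id", "other_end_id"], sort=True).size().reset_index(name="N")
    table["dist"] = chinput_distances(table, bins, baits)
    return table[CHINPUT_COLUMNS]


def chinput_distances(table: pd.DataFrame, bins: pd.DataFrame, baits: pd.DataFrame) -> np.ndarray:
    """Signed midpoint distance (other end − bait) per row; NaN for trans."""
    bait_ix = baits.set_index("id")
    bin_ix = bins.set_index("id")
    bait_mid = (bait_ix["start"] + bait_ix["end"]) / 2.0
    bin_mid = (bin_ix["start"] + bin_ix["end"]) / 2.0
    bm = bait_mid.reindex(table["bait_id"]).to_numpy()
    om = bin_mid.reindex(table["other_end_id"]).to_numpy()
    same = (
        bait_ix["chrom"].reindex(table["bait_id"]).to_numpy()
        == bin_ix["chrom"].reindex(table["other_end_id"]).to_numpy()
    )
    return np.where(same, om - bm, np.nan)


@dataclass
class QcReport:
    """Library-level quality metrics for a capture experiment."""

    total_pairs: int
    unique_pairs: int
    trans_fraction: float
    bait_fraction: float
    per_bait: pd.DataFrame  # bait_id, raw, normalized

    def summary(self) -> dict:
        return {
            "total_pairs": self.total_pairs,
            "unique_pairs": self.unique_pairs,
            "duplicate_fraction": 1 - self.unique_pairs / self.total_pairs
            if self.total_pairs
            else float("nan"),
            "trans_percent": 100 * self.trans_fraction,
            "bait_percent": 100 * self.bait_fraction,
        }


def percentage(part: float, whole: float, ndigits: int = 1) -> float:
    """``part/whole`` as a percentage rounded to ``ndigits`` decimals."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty denominator is undefined")
    return round(100.0 * part / whole, ndigits)


def qc_metrics(pairs: pd.DataFrame, bins: pd.DataFrame, baits: pd.DataFrame) -> QcReport:
    """Compute trans fraction, bait fraction and per-bait coverage.

    Coverage counts unique ligation products per bait (bait–bait products
    count toward both baits) and is additionally normalised to a library of
    10,000,000 unique ligation products.
    """
    total = len(pairs)
    unique = deduplicate_pairs(pairs)
    n_unique = len(unique)
    if n_unique == 0:
        raise ValueError("no unique pairs: QC fractions are undefined")
    trans = (unique["chrom1"] != unique["chrom2"]).sum()
    bin1 = assign_bins(unique["chrom1"].to_numpy(), unique["pos1"].to_numpy(), bins)
    bin2 = assign_bins(unique["chrom2"].to_numpy(), unique["pos2"].to_numpy(), bins)
    b2b = bin_to_bait_map(bins, baits)
    bait1 = np.array([b2b.get(int(b), -1) for b in bin1])
    bait2 = np.array([b2b.get(int(b), -1) for b in bin2])
    touching = ((bait1 >= 0) | (bait2 >= 0)).sum()
    raw = pd.Series(np.concatenate([bait1[bait1 >= 0], bait2[bait2 >= 0]])).value_counts()
    per_bait = pd.DataFrame({"bait_id": raw.index.astype(int), "raw": raw.to_numpy()})
    per_bait = per_bait.sort_values("bait_id").reset_index(drop=True)
    per_bait["normalized"] = per_bait["raw"] * COVERAGE_NORMALISATION / n_unique
    return QcReport(
        total_pairs=total,
        unique_pairs=n_unique,
        trans_fraction=trans / n_unique,
        bait_fraction=touching / n_unique,
        per_bait=per_bait,
    )


def bait_coverage(chinput: pd.DataFrame) -> pd.Series:
    """Raw per-bait coverage: sum of chinput counts per bait."""
    return chinput.groupby("bait_id")["N"].sum()


def probe_gc_vs_coverage(
    baits: pd.DataFrame,
    probes: pd.DataFrame,
    coverage: pd.Series,
    bins: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, float, float]:
    """Mean probe GC vs coverage for baits targeted by exactly two probes.

    ``coverage`` is indexed by bait id (raw or normalised).  Returns the
    (bait_id, mean_gc, coverage) table and the Spearman rank correlation
    with its p-value (NaN when fewer than 3 baits qualify).
    """
    probe_bait = _probes_per_bait(baits, probes)
    rows = []
    for bait_id, idx in probe_bait.items():
        if len(idx) != 2:
            continue
        mean_gc = probes.loc[idx, "gc"].mean()
        rows.append((bait_id, mean_gc, float(coverage.get(bait_id, 0.0))))
    table = pd.DataFrame(rows, columns=["bait_id", "mean_gc", "coverage"])
    if len(table) >= 3:
        rho, pval = spearmanr(table["mean_gc"], table["coverage"])
    else:
        rho, pval = float("nan"), float("nan")
    return table, float(rho), float(pval)


def _probes_per_bait(baits: pd.DataFrame, probes: pd.DataFrame) -> dict[int, list]:
    out: dict[int, list] = {}
    for bait in baits.itertuples(index=False):
        sub = probes[
            (probes["chrom"] == bait.chrom)
            & (probes["end"] > bait.start)
            & (probes["start"] < bait.end)
        ]
        out[int(bait.id)] = list(sub.index)
    return out


# ---------------------------------------------------------------------------
# file dialects


def write_chinput(table: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "baitID": table["bait_id"].astype(int),
            "otherEndID": table["other_end_id"].astype(int),
            "N": table["N"].astype(int),
            "distSign": [
                "NA" if pd.isna(d) else str(int(d)) if float(d).is_integer() else repr(float(d))
                for d in table["dist"]
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_chinput(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype={"baitID": int, "otherEndID": int, "N": int})
    dist = pd.to_numeric(raw["distSign"], errors="coerce")
    return pd.DataFrame(
        {"bait_id": raw["baitID"], "other_end_id": raw["otherEndID"], "N": raw["N"], "dist": dist}
    )


def write_rmap(bins: pd.DataFrame, path) -> None:
    """rmap: tab-delimited chrom, start, end, id — 1-based inclusive coordinates."""
    out = pd.DataFrame(
        {
            "chrom": bins["chrom"],
            "start": bins["start"] + 1,
            "end": bins["end"],
            "id": bins["id"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_rmap(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "id"])
    raw["start"] = raw["start"] - 1
    return raw


def write_baitmap(baits: pd.DataFrame, path) -> None:
    """baitmap: chrom, start, end, id, name — 1-based inclusive coordinates."""
    out = pd.DataFrame(
        {
            "chrom": baits["chrom"],
            "start": baits["start"] + 1,
            "end": baits["end"],
            "id": baits["id"],
            "name": baits["name"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_baitmap(path) -> pd.DataFrame:
    raw = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "id", "name"]
    )
    raw["start"] = raw["start"] - 1
    return raw
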