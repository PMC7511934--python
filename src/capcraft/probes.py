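"""Hybridisation-probe selection at restriction-fragment ends.

Each probe is a 140-bp genomic window anchored near one end of a DpnII
fragment that overlaps a promoter window.  Selection applies six rules:

1. each fragment end carries at most one probe;
2. probe length is 140 bp;
3. the host fragment is at least 300 bp long;
4. at most 30 probe bases are repeat-masked;
5. GC content is within [0.25, 0.65] (inclusive);
6. the probe's outer end lies within 40 bp of the targeted fragment end.

Probes for synthesis are flanked by two constant 15-nt adapters, giving
170-nt oligos; PCR with 21-nt primers that extend each adapter by 6 nt
yields 182-bp double-stranded probes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from capcraft.genome import rank_fragments_for_promoter

ADAPTER_5 = "TCGCGCCCATAACTC"
ADAPTER_3 = "CTGAGGGTCCGCCTT"
FORWARD_PRIMER = "CTGGGATCGCGCCCATAACTC"
REVERSE_PRIMER = "CGTGGAAAGGCGGACCCTCAG"

PROBE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "fragment_id",
    "fragment_end",
    "sequence",
    "gc",
    "repeat_bases",
    "promoter",
]


@dataclass(frozen=True)
class ProbeRules:
    """Tunable probe-selection thresholds (defaults are the protocol's)."""

    probe_len: int = 140
    min_frag_len: int = 300
    gc_min: float = 0.25
    gc_max: float = 0.65
    max_repeat: int = 30
    max_end_dist: int = 40
    probes_per_promoter: int = 2


def gc_content(sequence: str) -> float:
    """Fraction of G/C bases (case-insensitive; N counts as non-GC)."""
    if not sequence:
        raise ValueError("cannot compute GC content of an empty sequence")
    seq = sequence.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def count_repeat_bases(
    sequence: str,
    mask_intervals: Optional[Iterable[tuple]] = None,
    probe_interval: Optional[tuple] = None,
) -> int:
    """Number of repeat-masked bases in a probe window.

    With no ``mask_intervals``, soft masking is used: every lowercase base
    counts.  With explicit RepeatMasker-style intervals, ``probe_interval``
    must give the probe's genomic location ``(chrom, start, end)`` and the
    count is the number of probe bases covered by any interval
    ``(chrom, start, end)`` of the mask.
    """
    if mask_intervals is None:
        return sum(1 for b in sequence if b.islower())
    if probe_interval is None:
        raise ValueError("probe_interval is required when mask_intervals are given")
    chrom, pstart, pend = probe_interval
    covered = np.zeros(pend - pstart, dtype=bool)
    for mchrom, mstart, mend in mask_intervals:
        if mchrom != chrom:
            continue
        lo = max(mstart, pstart) - pstart
        hi = min(mend, pend) - pstart
        if hi > lo:
            covered[lo:hi] = True
    return int(covered.sum())


def _mask_lookup(mask_intervals, chrom):
    if mask_intervals is None:
        return None
    return [iv for iv in mask_intervals if iv[0] == chrom]


def place_probe(
    fragment,
    fragment_end: str,
    genome: Mapping[str, str],
    rules: ProbeRules = ProbeRules(),
    mask_intervals: Optional[Sequence[tuple]] = None,
) -> tuple[Optional[dict], Optional[str]]:
    """Try to place one probe at a fragment end.

    The probe's outer end may retreat 0..``max_end_dist`` bases inward from
    the targeted fragment end; offsets are scanned in ascending order and
    the first 140-bp window satisfying the GC and repeat rules wins.
    Sequences are reported on the forward strand (dsDNA hybridisation is
    strand-agnostic).

    Returns ``(probe_dict, None)`` on success, or ``(None, reason)`` where
    ``reason`` names the rule(s) that blocked every candidate window.
    """
    chrom = fragment["chrom"] if isinstance(fragment, dict) else fragment.chrom
    fstart = fragment["start"] if isinstance(fragment, dict) else fragment.start
    fend = fragment["end"] if isinstance(fragment, dict) else fragment.end
    fid = fragment["id"] if isinstance(fragment, dict) else fragment.id
    if fragment_end not in ("left", "right"):
        raise ValueError(f"fragment_end must be 'left' or 'right', got {fragment_end!r}")
    if fend - fstart < rules.min_frag_len:
        return None, "fragment_too_short"
    seq = genome[chrom]
    local_mask = _mask_lookup(mask_intervals, chrom)
    failed: set[str] = set()
    for offset in range(rules.max_end_dist + 1):
        if fragment_end == "left":
            start = fstart + offset
            end = start + rules.probe_len
        else:
            end = fend - offset
            start = end - rules.probe_len
        if start < fstart or end > fend:
            break  # window would leave the fragment
        window = seq[start:end]
        gc = gc_content(window)
        if local_mask is None:
            repeats = count_repeat_bases(window)
        else:
            repeats = count_repeat_bases(window, local_mask, (chrom, start, end))
        ok = True
        if not (rules.gc_min <= gc <= rules.gc_max):
            failed.add("gc_out_of_range")
            ok = False
        if repeats > rules.max_repeat:
            failed.add("repeat_bases_exceeded")
            ok = False
        if ok:
            return (
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "fragment_id": fid,
                    "fragment_end": fragment_end,
                    "sequence": window.upper(),
                    "gc": gc,
                    "repeat_bases": repeats,
                },
                None,
            )
    return None, "+".join(sorted(failed)) if failed else "no_candidate_window"


@dataclass
class DesignReport:
    """Bookkeeping for a probe-design run."""

    probes_per_promoter: dict = field(default_factory=dict)
    failure_tallies: Counter = field(default_factory=Counter)

    @property
    def n_promoters(self) -> int:
        return len(self.probes_per_promoter)

    def count_with(self, predicate) -> int:
        return sum(1 for v in self.probes_per_promoter.values() if predicate(v))

    def summary(self) -> dict:
        return {
            "n_promoters": self.n_promoters,
            "n_probes": sum(self.probes_per_promoter.values()),
            "promoters_ge2": self.count_with(lambda v: v >= 2),
            "promoters_eq1": self.count_with(lambda v: v == 1),
            "promoters_eq0": self.count_with(lambda v: v == 0),
            "failures": dict(self.failure_tallies),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "promoter": list(self.probes_per_promoter),
                "n_probes": list(self.probes_per_promoter.values()),
            }
        )


def design_probe_set(
    promoters: pd.DataFrame,
    fragments: pd.DataFrame,
    genome: Mapping[str, str],
    rules: ProbeRules = ProbeRules(),
    mask_intervals: Optional[Sequence[tuple]] = None,
) -> tuple[pd.DataFrame, DesignReport]:
    """Design probes for every promoter window.

    Per promoter, fragments are visited in decreasing order of promoter
    overlap; both ends of each untested fragment are tried; the loop stops
    once at least ``rules.probes_per_promoter`` probes have accumulated or
    the fragment list is exhausted.  Probes accumulate across fragments.
    A fragment end already claimed by an earlier promoter is never reused
    (one probe per fragment end, genome-wide).
    """
    taken: set[tuple[int, str]] = set()
    report = DesignReport()
    rows = []
    for prom in promoters.itertuples(index=False):
        ranked = rank_fragments_for_promoter(fragments, prom)
        n_found = 0
        if ranked.empty:
            report.failure_tallies["no_overlapping_fragment"] += 1
        for frag in ranked.itertuples(index=False):
            if n_found >= rules.probes_per_promoter:
                break
            for end_side in ("left", "right"):
                key = (frag.id, end_side)
                if key in taken:
                    report.failure_tallies["fragment_end_already_used"] += 1
                    continue
                probe, reason = place_probe(frag, end_side, genome, rules, mask_intervals)
                if probe is None:
                    report.failure_tallies[reason] += 1
                    continue
                taken.add(key)
                probe["promoter"] = prom.gene
                rows.append(probe)
                n_found += 1
        report.probes_per_promoter[prom.gene] = n_found
    probes = pd.DataFrame(rows, columns=PROBE_COLUMNS)
    return probes, report


def emit_synthesis_sequences(probes: pd.DataFrame) -> pd.DataFrame:
    """Adapter-flanked 170-nt synthesis oligos and the resulting amplicon size.

    The oligo is 5'-adapter + 140 specific bases + 3'-adapter.  Each PCR
    primer is 21 nt and extends its 15-nt adapter by 6 nt, so the
    double-stranded amplicon is 170 + 6 + 6 = 182 bp.
    """
    if probes.empty:
        return pd.DataFrame(columns=list(probes.columns) + ["oligo_sequence", "amplicon_length"])
    bad = probes["sequence"].str.len() != 140
    if bad.any():
        raise ValueError(f"{int(bad.sum())} probe sequence(s) are not 140 nt")
    # primers each add (21 - 15) = 6 nt of new sequence beyond the adapters
    oligo_len = len(ADAPTER_5) + 140 + len(ADAPTER_3)
    amplicon = oligo_len + (len(FORWARD_PRIMER) - len(ADAPTER_5)) + (len(REVERSE_PRIMER) - len(ADAPTER_3))
    out = probes.copy()
    out["oligo_sequence"] = ADAPTER_5 + out["sequence"] + ADAPTER_3
    out["amplicon_length"] = amplicon
    return out


def write_probes_bed(probes: pd.DataFrame, path) -> None:
    """Probes as BED6: name = promoter|fragment_id|end, score = GC*1000."""
    name = (
        probes["promoter"].astype(str)
        + "|"
        + probes["fragment_id"].astype(str)
        + "|"
        + probes["fragment_end"]
    )
    out = pd.DataFrame(
        {
            "chrom": probes["chrom"],
            "start": probes["start"],
            "end": probes["end"],
            "name": name,
            "score": (probes["gc"] * 1000).round().astype(int),
            "strand": "+",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_oligo_fasta(oligos: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in oligos.itertuples(index=False):
            fh.write(f">{row.promoter}|{row.fragment_id}|{row.fragment_end}\n{row.oligo_sequence}\n")
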