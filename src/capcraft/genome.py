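"""Restriction-fragment maps and promoter windows.

A genome is a mapping ``{chrom: sequence}``; lowercase bases mark
repeat-masked positions (soft masking), which probe design consumes.
All coordinates in the package are 0-based half-open.  Fragment maps and
promoter tables are plain :class:`pandas.DataFrame` objects with documented
columns, so they compose with the rest of the scientific Python stack.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: bases a promoter window extends upstream of the TSS (against the gene)
PROMOTER_UPSTREAM = 1000
#: bases a promoter window extends downstream of the TSS (into the gene)
PROMOTER_DOWNSTREAM = 500

FRAGMENT_COLUMNS = ["chrom", "start", "end", "id"]
PROMOTER_COLUMNS = ["gene", "chrom", "tss", "strand", "start", "end"]


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly soft-masked) FASTA into ``{chrom: sequence}``, case preserved."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def chrom_sizes(genome: Mapping[str, str]) -> dict[str, int]:
    return {chrom: len(seq) for chrom, seq in genome.items()}


def find_sites(sequence: str, site: str) -> list[int]:
    """Start indices of every occurrence of ``site`` (overlaps allowed, case-insensitive).

    Matching is strict A/C/G/T: an N in the sequence never matches.
    """
    if not site:
        raise ValueError("recognition site must be non-empty")
    seq = sequence.upper()
    site = site.upper()
    hits = []
    pos = seq.find(site)
    while pos != -1:
        hits.append(pos)
        pos = seq.find(site, pos + 1)
    return hits


def digest_genome(genome: Mapping[str, str], site: str = "GATC") -> pd.DataFrame:
    """In-silico digestion of a genome with a restriction enzyme.

    Cuts are placed at the first base of every recognition-site occurrence
    (DpnII cuts ^GATC, leaving the site on the downstream fragment).
    Fragment boundaries are ``{0} ∪ cuts ∪ {chrom length}`` with zero-length
    fragments suppressed; ids are assigned genome-wide in genomic order,
    chromosomes in input order.

    Parameters
    ----------
    genome
        ``{chrom: sequence}``; soft masking is irrelevant here (scan is
        case-insensitive).
    site
        Recognition sequence, e.g. ``"GATC"`` for DpnII.

    Returns
    -------
    DataFrame with columns ``chrom, start, end, id`` tiling each chromosome.
    """
    if not genome:
        raise ValueError("genome must contain at least one chromosome")
    if not site:
        raise ValueError("recognition site must be non-empty")
    rows = []
    next_id = 0
    for chrom, seq in genome.items():
        length = len(seq)
        if length == 0:
            continue
        cuts = find_sites(seq, site)
        bounds = sorted({0, *cuts, length})
        for start, end in zip(bounds[:-1], bounds[1:]):
            if end > start:  # zero-length suppression (cut at index 0)
                rows.append((chrom, start, end, next_id))
                next_id += 1
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def define_promoter_windows(
    genes: pd.DataFrame,
    sizes: Mapping[str, int],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> pd.DataFrame:
    """Strand-aware promoter windows around transcription start sites.

    The TSS is ``txStart`` for plus-strand genes and ``txEnd`` for
    minus-strand genes (UCSC convention: txStart/txEnd are 0-based
    half-open, so the minus-strand TSS base is ``txEnd - 1`` but the window
    is anchored at the half-open boundary).  The window runs ``downstream``
    bases into the gene and ``upstream`` bases the other way, clipped to
    chromosome bounds.

    Parameters
    ----------
    genes
        DataFrame with columns ``gene, chrom, txStart, txEnd, strand``.
        One window is produced per input row; TSS deduplication is the
        caller's responsibility.
    sizes
        ``{chrom: length}`` for clipping and chromosome validation.
    """
    required = {"gene", "chrom", "txStart", "txEnd", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    rows = []
    for rec in genes.itertuples(index=False):
        if rec.chrom not in sizes:
            raise ValueError(f"unknown chromosome {rec.chrom!r} for gene {rec.gene!r}")
        if rec.strand not in ("+", "-"):
            raise ValueError(f"gene {rec.gene!r} has invalid strand {rec.strand!r}")
        if rec.txStart > rec.txEnd:
            raise ValueError(f"gene {rec.gene!r} has txStart > txEnd")
        length = sizes[rec.chrom]
        if rec.strand == "+":
            tss = rec.txStart
            start, end = tss - upstream, tss + downstream
        else:
            tss = rec.txEnd
            start, end = tss - downstream, tss + upstream
        start = max(0, start)
        end = min(length, end)
        rows.append((rec.gene, rec.chrom, min(max(tss, 0), length - 1), rec.strand, start, end))
    return pd.DataFrame(rows, columns=PROMOTER_COLUMNS)


def rank_fragments_for_promoter(fragments: pd.DataFrame, window) -> pd.DataFrame:
    """Fragments overlapping a promoter window, best-covered first.

    Sorted by the length of promoter sequence inside the fragment
    (descending); ties broken by genomic order (leftmost first).  ``window``
    is any object with ``chrom``, ``start`` and ``end`` attributes or keys.

    Returns the overlapping fragment rows with an extra ``overlap`` column;
    empty when nothing overlaps.
    """
    if isinstance(window, dict):
        chrom, wstart, wend = window["chrom"], window["start"], window["end"]
    else:
        chrom, wstart, wend = window.chrom, window.start, window.end
    sub = fragments[fragments["chrom"] == chrom]
    if sub.empty:
        return fragments.iloc[0:0].assign(overlap=pd.Series(dtype=int))
    overlap = sub["end"].clip(upper=wend) - sub["start"].clip(lower=wstart)
    sub = sub.assign(overlap=overlap)
    sub = sub[sub["overlap"] > 0]
    return sub.sort_values(["overlap", "start"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )


def read_genes_table(path) -> pd.DataFrame:
    """Read a BED-like gene table (tab-delimited: gene, chrom, txStart, txEnd, strand)."""
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"gene": str, "chrom": str, "txStart": int, "txEnd": int, "strand": str},
    )


def write_bed(df: pd.DataFrame, path, columns: Iterable[str]) -> None:
    """Write selected columns as tab-delimited BED (no header)."""
    df.loc[:, list(columns)].to_csv(path, sep="\t", header=False, index=False)


def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    """Fragment map as BED4: chrom, start, end, id."""
    write_bed(fragments, path, FRAGMENT_COLUMNS)


def write_promoters_bed(promoters: pd.DataFrame, path) -> None:
    """Promoter windows as BED6: chrom, start, end, gene, 0, strand."""
    out = promoters.assign(score=0)
    write_bed(out, path, ["chrom", "start", "end", "gene", "score", "strand"])


def read_promoters_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "gene": str, "strand": str},
    )
    # TSS is recoverable from the window and strand: the window runs
    # PROMOTER_DOWNSTREAM into the gene and PROMOTER_UPSTREAM the other way,
    # but after edge clipping only the unclipped side is reliable; windows in
    # BED round-trips therefore carry tss = start + upstream (plus) or
    # end - upstream (minus), valid for unclipped windows.
    tss = [
        row.start + PROMOTER_UPSTREAM if row.strand == "+" else row.end - PROMOTER_UPSTREAM
        for row in bed.itertuples(index=False)
    ]
    return pd.DataFrame(
        {
            "gene": bed["gene"],
            "chrom": bed["chrom"],
            "tss": tss,
            "strand": bed["strand"],
            "start": bed["start"],
            "end": bed["end"],
        }
    )
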