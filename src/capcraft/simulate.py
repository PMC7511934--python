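"""Seeded synthetic data with known ground truth.

The generator emulates the statistical structure a promoter Capture-C
analysis assumes, at desk scale:

* a small multi-chromosome genome of uniform random sequence (so GATC
  occurs roughly every 256 bp) with extra GATC sites planted to a target
  spacing, soft-masked repeat stretches, promoters, TAD boundaries and
  regulatory-element tracks;
* planted promoter–element loops, a subset of which carry convergently
  oriented CTCF motifs;
* proximity-ligation products whose cis partner distances follow a
  power-law contact decay P(d) ∝ (d + d0)^(−α), with multiplicative
  enrichment at planted loop positions, a trans-contact fraction, and PCR
  duplicates;
* a capture step whose per-bait retention is a logistic function of mean
  probe GC, emulating GC-dependent hybridisation efficiency (either sign).

Everything is driven by one :class:`SyntheticScenario` and a seed; the same
seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from capcraft.chinput import PAIR_COLUMNS
from capcraft.loops import FEATURE_COLUMNS

BASES = np.array(list("ACGT"))


@dataclass
class SyntheticScenario:
    """Study conditions for the synthetic generator (defaults are the
    package's reference scenario used throughout the test-suite)."""

    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000})
    gatc_spacing: int = 256          # target mean spacing of planted GATC sites (bp)
    repeat_fraction: float = 0.05    # fraction of the genome soft-masked
    repeat_length: int = 400         # mean masked-stretch length (bp)
    n_promoters: int = 50            # split evenly across chromosomes
    promoter_margin: int = 100_000   # keep promoters away from chromosome edges
    promoter_spacing: int = 25_000   # minimum distance between planted TSSs
    tad_spacing: int = 250_000       # boundary every this many bases
    n_enhancer_loops: int = 40       # planted promoter-enhancer loops
    n_ctcf_loops: int = 30           # planted promoter-CTCF loops
    n_background_enhancers: int = 40
    n_background_ctcf: int = 30
    n_background_dhs: int = 40
    element_length: int = 800        # regulatory-element width (bp)
    loop_dist_min: int = 50_000
    loop_dist_max: int = 300_000
    convergent_fraction: float = 0.65  # planted CTCF loops with convergent motifs
    alpha: float = 1.0               # contact-decay exponent
    d0: float = 5_000.0              # decay offset preventing divergence at d -> 0
    trans_fraction: float = 0.10     # fraction of interchromosomal products
    products_per_bait: int = 10_000  # unique ligation products per promoter
    loop_enrichment: float = 10.0    # fold enrichment at planted loop bins
    duplicate_rate: float = 0.10     # PCR-duplicate fraction of total products
    capture_a: float = 3.0           # logistic intercept of capture efficiency
    capture_b: float = -3.0          # logistic GC coefficient (sign selects protocol variant)
    off_target_rate: float = 0.02    # retention of pairs touching no bait
    bin_size: int = 2_000

    def __post_init__(self):
        for name in ("repeat_fraction", "trans_fraction", "duplicate_rate",
                     "off_target_rate", "convergent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SyntheticGenome:
    """Generator output bundle: genome plus ground-truth annotations."""

    genome: dict                    # {chrom: soft-masked sequence}
    genes: pd.DataFrame             # gene, chrom, txStart, txEnd, strand
    tad_boundaries: pd.DataFrame    # chrom, pos
    features: pd.DataFrame          # chrom, start, end, element_id, feature_class
    motifs: pd.DataFrame            # chrom, pos, strand, score
    planted_loops: pd.DataFrame     # gene, element_id, feature_class, chrom, tss, element_mid, convergent

    @property
    def chrom_sizes(self) -> dict:
        return {c: len(s) for c, s in self.genome.items()}


def _random_sequence(rng, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def generate_genome(scenario: SyntheticScenario, seed: int) -> SyntheticGenome:
    """Generate a toy genome with promoters, TADs, elements and planted loops.

    Promoters are placed on a jittered grid away from chromosome edges;
    loop partner elements are placed at 50–300 kb from their promoter, at
    least 5 kb from every TSS (so they never fall inside a bait) and fully
    inside one 2-kb bin (clean ground truth for recovery tests).  CTCF
    elements carry strand-annotated motifs; a configurable fraction of
    planted CTCF loops is convergent.  Background (unlooped) elements are
    scattered uniformly under the same TSS-clearance rule.
    """
    rng = np.random.default_rng(seed)
    chroms = list(scenario.chrom_sizes)
    n_per_chrom = _split_evenly(scenario.n_promoters, len(chroms))

    genome: dict[str, str] = {}
    gene_rows = []
    tad_rows = []
    tss_by_chrom: dict[str, list[int]] = {}
    gi = 0
    for chrom, n_prom in zip(chroms, n_per_chrom):
        size = scenario.chrom_sizes[chrom]
        codes = _random_sequence(rng, size)
        # uniform random sequence already yields GATC every ~256 bp; plant
        # only the shortfall towards the requested spacing
        natural = size // 256
        n_sites = max(size // scenario.gatc_spacing - natural, 0)
        if n_sites:
            site_pos = rng.choice(size - 4, size=n_sites, replace=False)
            for p in site_pos:
                codes[p : p + 4] = [2, 0, 3, 1]  # G A T C
        seq = BASES[codes]
        # soft-mask repeat stretches
        mask = np.zeros(size, dtype=bool)
        n_rep = int(scenario.repeat_fraction * size / max(scenario.repeat_length, 1))
        if n_rep:
            starts = rng.integers(0, max(size - scenario.repeat_length, 1), size=n_rep)
            lens = rng.poisson(scenario.repeat_length, size=n_rep)
            for s, l in zip(starts, lens):
                mask[s : min(s + max(l, 1), size)] = True
        chars = seq.copy()
        chars[mask] = np.char.lower(chars[mask])
        genome[chrom] = "".join(chars)

        # promoters on a jittered grid
        lo, hi = scenario.promoter_margin, size - scenario.promoter_margin
        grid = np.arange(lo, hi, scenario.promoter_spacing)
        tss = np.sort(rng.choice(grid, size=min(n_prom, len(grid)), replace=False))
        tss = tss + rng.integers(0, scenario.promoter_spacing // 4, size=len(tss))
        tss_by_chrom[chrom] = [int(t) for t in tss]
        for t in tss:
            strand = rng.choice(["+", "-"])
            glen = int(rng.integers(5_000, 50_000))
            if strand == "+":
                tx_start, tx_end = int(t), min(int(t) + glen, size)
            else:
                tx_start, tx_end = max(int(t) - glen, 0), int(t)
            gene_rows.append((f"gene{gi:03d}", chrom, tx_start, tx_end, strand))
            gi += 1
        for pos in range(scenario.tad_spacing, size, scenario.tad_spacing):
            tad_rows.append((chrom, pos))

    genes = pd.DataFrame(gene_rows, columns=["gene", "chrom", "txStart", "txEnd", "strand"])
    tads = pd.DataFrame(tad_rows, columns=["chrom", "pos"])

    features, motifs, planted = _plant_elements(scenario, rng, genes, tss_by_chrom)
    return SyntheticGenome(
        genome=genome,
        genes=genes,
        tad_boundaries=tads,
        features=features,
        motifs=motifs,
        planted_loops=planted,
    )


def _split_evenly(n, k):
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _tss_of(gene_row):
    return gene_row.txStart if gene_row.strand == "+" else gene_row.txEnd


def _plant_elements(scenario, rng, genes, tss_by_chrom):
    feature_rows = []
    motif_rows = []
    planted_rows = []
    counters = {"enhancer": 0, "CTCF": 0, "DHS": 0}
    elen = scenario.element_length
    b = scenario.bin_size

    def element_ok(chrom, mid):
        size = scenario.chrom_sizes[chrom]
        if mid < elen or mid > size - elen:
            return False
        return all(abs(mid - t) >= 5_000 for t in tss_by_chrom[chrom])

    def place_element(chrom, mid, cls):
        # snap inside a single bin for clean ground truth
        bin_start = (int(mid) // b) * b
        start = bin_start + (b - elen) // 2
        end = start + elen
        eid = f"{cls}:{counters[cls]}"
        counters[cls] += 1
        feature_rows.append((chrom, start, end, eid, cls))
        return eid, (start + end) // 2

    # planted loops: cycle through promoters
    loop_specs = [("enhancer", scenario.n_enhancer_loops), ("CTCF", scenario.n_ctcf_loops)]
    prom_cycle = list(genes.itertuples(index=False))
    ci = 0
    for cls, n_loops in loop_specs:
        placed = 0
        attempts = 0
        while placed < n_loops and attempts < 50 * n_loops:
            attempts += 1
            prom = prom_cycle[ci % len(prom_cycle)]
            ci += 1
            tss = _tss_of(prom)
            d = int(rng.integers(scenario.loop_dist_min, scenario.loop_dist_max))
            side = rng.choice([-1, 1])
            mid = tss + side * d
            if not element_ok(prom.chrom, mid):
                continue
            eid, emid = place_element(prom.chrom, mid, cls)
            convergent = False
            if cls == "CTCF":
                convergent = bool(rng.random() < scenario.convergent_fraction)
                left_is_prom = tss < emid
                if convergent:
                    left_strand, right_strand = "+", "-"
                else:
                    # any non-convergent configuration, uniformly
                    left_strand, right_strand = [("+", "+"), ("-", "-"), ("-", "+")][
                        rng.integers(0, 3)
                    ]
                prom_strand = left_strand if left_is_prom else right_strand
                elem_strand = right_strand if left_is_prom else left_strand
                motif_rows.append((prom.chrom, tss, prom_strand, float(rng.uniform(8, 15))))
                motif_rows.append((prom.chrom, emid, elem_strand, float(rng.uniform(8, 15))))
            planted_rows.append(
                (prom.gene, eid, cls, prom.chrom, tss, emid, convergent)
            )
            placed += 1

    # background elements, independent of loops
    for cls, n_bg in (
        ("enhancer", scenario.n_background_enhancers),
        ("CTCF", scenario.n_background_ctcf),
        ("DHS", scenario.n_background_dhs),
    ):
        placed = 0
        attempts = 0
        chroms = list(scenario.chrom_sizes)
        while placed < n_bg and attempts < 100 * n_bg:
            attempts += 1
            chrom = chroms[rng.integers(0, len(chroms))]
            mid = int(rng.integers(elen, scenario.chrom_sizes[chrom] - elen))
            if not element_ok(chrom, mid):
                continue
            eid, emid = place_element(chrom, mid, cls)
            if cls == "CTCF":
                motif_rows.append(
                    (chrom, emid, str(rng.choice(["+", "-"])), float(rng.uniform(8, 15)))
                )
            placed += 1

    features = pd.DataFrame(feature_rows, columns=FEATURE_COLUMNS)
    motifs = pd.DataFrame(motif_rows, columns=["chrom", "pos", "strand", "score"])
    planted = pd.DataFrame(
        planted_rows,
        columns=["gene", "element_id", "feature_class", "chrom", "tss", "element_mid", "convergent"],
    )
    return features, motifs, planted


def simulate_ligation_products(
    gen: SyntheticGenome,
    scenario: SyntheticScenario,
    seed: int,
    n_products: Optional[int] = None,
) -> pd.DataFrame:
    """Draw valid ligation pairs anchored at the planted promoters.

    Per promoter, cis partner bins are drawn with probability proportional
    to (distance + d0)^(−α); bins hosting a planted partner element of that
    promoter get ``loop_enrichment``-fold extra weight.  A fraction
    ``trans_fraction`` of products is interchromosomal (uniform position on
    a uniformly chosen other chromosome).  PCR duplicates are appended so
    that unique/total ≈ 1 − duplicate_rate.  The first anchor is uniform in
    ±500 bp around the TSS.
    """
    rng = np.random.default_rng(seed)
    b = scenario.bin_size
    sizes = gen.chrom_sizes
    genes = gen.genes
    if n_products is None:
        n_products = scenario.products_per_bait * len(genes)
    per_prom = rng.multinomial(n_products, np.full(len(genes), 1.0 / len(genes)))
    loops_by_gene = gen.planted_loops.groupby("gene") if not gen.planted_loops.empty else None

    # cis partners are never drawn from bins proximal to *another* baited
    # promoter: products joining two baited promoters are not simulated
    # (bait-bait rows are excluded from PIR calling anyway, and partially
    # baited anchor bins would otherwise carry concentrated reciprocal
    # signal that does not follow the local decay law)
    proximal_bins: dict[str, dict[str, set]] = {c: {} for c in sizes}
    for prom in genes.itertuples(index=False):
        t = _tss_of(prom)
        proximal_bins[prom.chrom][prom.gene] = {
            int(i) for i in range(max((t - 5_000) // b, 0), (t + 5_000) // b + 1)
        }

    chunks = []
    for (prom, n_prom) in zip(genes.itertuples(index=False), per_prom):
        if n_prom == 0:
            continue
        size = sizes[prom.chrom]
        tss = _tss_of(prom)
        n_bins = int(np.ceil(size / b))
        mids = np.arange(n_bins) * b + b / 2.0
        dist = np.abs(mids - tss)
        weights = np.power(dist + scenario.d0, -scenario.alpha)
        weights[int(tss // b)] = 0.0  # self-bin products are uninformative upstream
        for gene, bset in proximal_bins[prom.chrom].items():
            if gene == prom.gene:
                continue
            for bin_i in bset:
                if bin_i < n_bins:
                    weights[bin_i] = 0.0
        if loops_by_gene is not None and prom.gene in loops_by_gene.groups:
            for em in loops_by_gene.get_group(prom.gene)["element_mid"]:
                weights[int(em) // b] *= scenario.loop_enrichment
        weights /= weights.sum()

        n_trans = rng.binomial(n_prom, scenario.trans_fraction)
        n_cis = n_prom - n_trans
        counts = rng.multinomial(n_cis, weights)
        nz = np.nonzero(counts)[0]
        partner_pos = np.concatenate(
            [
                rng.integers(i * b, min((i + 1) * b, size), size=counts[i])
                for i in nz
            ]
        ) if len(nz) else np.empty(0, dtype=np.int64)
        anchor_pos = rng.integers(max(tss - 500, 0), min(tss + 500, size), size=n_cis)
        chunk = pd.DataFrame(
            {
                "chrom1": prom.chrom,
                "pos1": anchor_pos,
                "strand1": rng.choice(["+", "-"], size=n_cis),
                "chrom2": prom.chrom,
                "pos2": partner_pos,
                "strand2": rng.choice(["+", "-"], size=n_cis),
            }
        )
        chunks.append(chunk)
        if n_trans:
            others = [c for c in sizes if c != prom.chrom]
            tchrom = np.array(others)[rng.integers(0, len(others), size=n_trans)]
            tpos = np.array([rng.integers(0, sizes[c]) for c in tchrom])
            chunks.append(
                pd.DataFrame(
                    {
                        "chrom1": prom.chrom,
                        "pos1": rng.integers(max(tss - 500, 0), min(tss + 500, size), size=n_trans),
                        "strand1": rng.choice(["+", "-"], size=n_trans),
                        "chrom2": tchrom,
                        "pos2": tpos,
                        "strand2": rng.choice(["+", "-"], size=n_trans),
                    }
                )
            )
    pairs = pd.concat(chunks, ignore_index=True)[PAIR_COLUMNS]
    # inject PCR duplicates: total = unique / (1 - rate)
    if scenario.duplicate_rate > 0:
        n_dup = int(round(len(pairs) * scenario.duplicate_rate / (1 - scenario.duplicate_rate)))
        if n_dup:
            dup_idx = rng.integers(0, len(pairs), size=n_dup)
            pairs = pd.concat([pairs, pairs.iloc[dup_idx]], ignore_index=True)
    # shuffle so duplicates are interspersed
    pairs = pairs.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)
    return pairs


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_capture(
    pairs: pd.DataFrame,
    bins: pd.DataFrame,
    baits: pd.DataFrame,
    probes: pd.DataFrame,
    scenario: SyntheticScenario,
    seed: int,
) -> pd.DataFrame:
    """Hybridisation-capture filter over a ligation-product pool.

    A pair touching at least one bait is retained with probability
    logistic(a + b·meanGC) of the best (highest-efficiency) touched bait,
    where meanGC is the mean GC of the bait's probes; pairs touching no
    bait are retained at ``off_target_rate``.
    """
    from capcraft.chinput import _probes_per_bait, assign_bins, bin_to_bait_map

    rng = np.random.default_rng(seed)
    bin1 = assign_bins(pairs["chrom1"].to_numpy(), pairs["pos1"].to_numpy(), bins)
    bin2 = assign_bins(pairs["chrom2"].to_numpy(), pairs["pos2"].to_numpy(), bins)
    b2b = bin_to_bait_map(bins, baits)
    probe_map = _probes_per_bait(baits, probes)
    eff = {
        bait_id: float(_logistic(scenario.capture_a + scenario.capture_b * probes.loc[idx, "gc"].mean()))
        if idx
        else scenario.off_target_rate
        for bait_id, idx in probe_map.items()
    }
    bait1 = np.array([b2b.get(int(x), -1) for x in bin1])
    bait2 = np.array([b2b.get(int(x), -1) for x in bin2])
    p_keep = np.full(len(pairs), scenario.off_target_rate)
    for i in range(len(pairs)):
        cands = [eff[x] for x in (bait1[i], bait2[i]) if x >= 0]
        if cands:
            p_keep[i] = max(cands)
    keep = rng.random(len(pairs)) < p_keep
    return pairs.loc[keep].reset_index(drop=True)


def evaluate_loop_recovery(
    called_loops: pd.DataFrame,
    planted_loops: pd.DataFrame,
    baits: pd.DataFrame,
    classes: Optional[list] = None,
) -> tuple[float, float]:
    """Recall and precision of called loops against the planted ground truth.

    A planted (gene, element) loop counts as recovered when some called loop
    pairs a bait whose name contains the gene with the same element.  Only
    planted loops whose promoter actually received a bait enter the recall
    denominator universe — a promoter that could not be baited is invisible
    to the assay by construction — and precision is the fraction of called
    loops (in the planted classes) that correspond to a planted pair.
    """
    if classes is None:
        classes = sorted(set(planted_loops["feature_class"]))
    gene_to_baits: dict[str, set] = {}
    for bait in baits.itertuples(index=False):
        for gene in str(bait.name).split(","):
            gene_to_baits.setdefault(gene, set()).add(int(bait.id))
    planted = planted_loops[planted_loops["feature_class"].isin(classes)]
    called = called_loops[called_loops["feature_class"].isin(classes)]
    called_keys = set(zip(called["bait_id"].astype(int), called["element_id"]))
    truth_keys = set()
    n_recovered = 0
    n_eligible = 0
    for row in planted.itertuples(index=False):
        bait_ids = gene_to_baits.get(row.gene, set())
        if not bait_ids:
            continue  # promoter got no probes; unrecoverable by construction
        n_eligible += 1
        keys = {(b, row.element_id) for b in bait_ids}
        truth_keys |= keys
        if keys & called_keys:
            n_recovered += 1
    recall = n_recovered / n_eligible if n_eligible else float("nan")
    n_called = len(called_keys)
    n_true_called = len(called_keys & truth_keys)
    precision = n_true_called / n_called if n_called else float("nan")
    return recall, precision


def scenario_from_yaml(path) -> SyntheticScenario:
    """Load a scenario from a flat key-value YAML file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SyntheticScenario(**data)
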