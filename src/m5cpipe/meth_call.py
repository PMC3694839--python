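"""Per-cytosine methylation quantification.

For every reference cytosine, in both orientations, the reads in which the C
was converted to T (unmethylated) and those in which it was retained
(methylated) are counted.  Three artifact filters precede the counting:

1. PCR duplicates — reads with an identical full sequence string collapse to
   a single representative (genome mode only; in transcriptome mode identical
   reads from highly expressed structural RNAs are genuine coverage);
2. conversion failures — reads with >= 3 unconverted cytosines are dropped,
   as they likely come from molecules insufficiently exposed to bisulfite;
3. base quality — only bases with Phred quality > 20 are counted.

Each site receives a methylation level, 100*k/n with k the unconverted and n
the qualifying read count, and a p-value from a two-sided Fisher's exact test
of the observed counts against an all-converted pseudo-sample of equal depth
(table [[k, n-k], [0, n]]).  Significant sites within 10 nt of one another
are discarded (both members), and sites sharing an identical 31-nt flanking
context — typically identical multi-copy genes — are collapsed, with level
and p recomputed from summed counts.

Levels are reported to one decimal place and p-values to three significant
figures.  Sites with n = 0 are never emitted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .bs_align import BisulfiteAligner, BsAlignment, map_reads
from .reference_prep import (
    GENOME,
    TRANSCRIPTOME,
    ReferenceSet,
    convert_reference,
    reverse_complement,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_QUALITY = 20
DEFAULT_UNCONVERTED_CUTOFF = 3
DEFAULT_SPACING = 10
DEFAULT_CONTEXT_WINDOW = 31
DEFAULT_ALPHA = 0.01
DEFAULT_BANDS = (10.0, 20.0, 50.0)


@dataclass(frozen=True)
class SiteCount:
    """Tally at one reference cytosine: n covering reads, k unconverted."""

    ref_id: str
    pos: int  # 0-based original coordinate of the C (G base when strand '-')
    strand: str
    n: int
    k: int

    def __post_init__(self):
        if not 0 <= self.k <= self.n:
            raise ValueError(f"invalid counts k={self.k}, n={self.n}")


@dataclass
class MethylationCall:
    """A site with level, exact-test p-value and collapse-group identity."""

    site: SiteCount
    level: float  # percent, one decimal
    p: float
    context: str = ""  # 31-nt strand-oriented flank, site at index 15 (0-based)
    truncated: bool = False  # context clipped by a sequence edge
    group_id: str | None = None
    members: tuple[tuple[str, int, str], ...] = ()
    classification: str | None = None

    def __post_init__(self):
        if not self.members:
            self.members = ((self.site.ref_id, self.site.pos, self.site.strand),)

    @property
    def position_1based(self) -> int:
        return self.site.pos + 1


@dataclass
class LibrarySummary:
    """Library-level QC mirroring the coverage/conversion summary tables."""

    conversion_rate: float | None  # percent of sequenced reference Cs converted
    gene_mean_coverage: dict[str, float] = field(default_factory=dict)
    n_genes: int = 0
    n_genes_covered: int = 0  # mean coverage > 5, strictly
    pct_genes_covered: float = 0.0  # rounded to the nearest integer percent


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_duplicates(alignments: list[BsAlignment], mode: str = GENOME) -> list[BsAlignment]:
    """Collapse reads with identical full sequence strings (PCR artifacts).

    Keyed on the read sequence as sequenced, not on coordinates; the
    representative is the first read by (reference coordinate, read id).
    Disabled in transcriptome mode, where identical reads reflect coverage of
    highly expressed genes rather than amplification.
    """
    if mode == TRANSCRIPTOME:
        return list(alignments)
    by_seq: dict[str, BsAlignment] = {}
    for aln in sorted(alignments, key=lambda a: (a.ref_id, a.start, a.read_id)):
        by_seq.setdefault(aln.seq, aln)
    kept = sorted(by_seq.values(), key=lambda a: (a.ref_id, a.start, a.read_id))
    removed = len(alignments) - len(kept)
    if removed:
        logger.info("duplicate filter removed %d of %d reads", removed, len(alignments))
    return kept


def filter_unconverted_reads(
    alignments: list[BsAlignment],
    cutoff: int = DEFAULT_UNCONVERTED_CUTOFF,
    min_quality: int = DEFAULT_MIN_QUALITY,
) -> list[BsAlignment]:
    """Drop reads with >= ``cutoff`` unconverted cytosines (conversion
    failures).  States are counted on the read's resolved strand and only at
    bases passing the quality gate, so quality-failed bases cannot mask a
    molecule-level failure signal they never contribute to."""
    kept = [a for a in alignments if a.n_unconverted(min_quality) < cutoff]
    removed = len(alignments) - len(kept)
    if removed:
        logger.info("unconverted-read filter removed %d of %d reads", removed, len(alignments))
    return kept


# ---------------------------------------------------------------------------
# Counting and testing
# ---------------------------------------------------------------------------

def pileup(
    alignments: list[BsAlignment],
    refs: ReferenceSet | None = None,
    min_quality: int = DEFAULT_MIN_QUALITY,
) -> list[SiteCount]:
    """Tally n/k per covered reference cytosine over quality-passing bases.

    Every reference C (plus strand) and G (a minus-strand transcript C)
    covered by at least one qualifying base is emitted; the strand comes from
    each read's resolved transcript strand.
    """
    counts: dict[tuple[str, str, int], list[int]] = {}
    for aln in alignments:
        for ev in aln.events:
            if ev.qual > min_quality:
                c = counts.setdefault((aln.ref_id, aln.strand, ev.pos), [0, 0])
                c[0] += 1
                if ev.unconverted:
                    c[1] += 1
    return [
        SiteCount(rid, pos, strand, n, k)
        for (rid, strand, pos), (n, k) in sorted(counts.items())
    ]


def methylation_level(k: int, n: int) -> float:
    """Percent of covering reads in which the C was not converted."""
    if n < 1:
        raise ValueError("methylation level undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    return round(100.0 * k / n, 1)


def fisher_conversion_test(k: int, n: int, alternative: str = "two-sided") -> float:
    """Exact test of k unconverted out of n against full conversion.

    The observed column (k unconverted, n-k converted) is compared with an
    all-converted pseudo-sample of equal depth, i.e. the 2x2 table
    [[k, n-k], [0, n]], under the minimum-likelihood two-sided rule (the sum
    of hypergeometric probabilities no larger than the observed table's).
    A one-sided variant is available via ``alternative='greater'``.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    return float(stats.fisher_exact([[k, n - k], [0, n]], alternative=alternative).pvalue)


def extract_context(
    refs: ReferenceSet, ref_id: str, pos: int, strand: str,
    window: int = DEFAULT_CONTEXT_WINDOW,
) -> tuple[str, bool]:
    """Strand-oriented flanking sequence with the site at the center.

    Returns (context, truncated); near a sequence edge the available shorter
    context is returned and flagged.
    """
    half = window // 2
    seq = refs.seq(ref_id)
    lo, hi = max(0, pos - half), min(len(seq), pos + half + 1)
    ctx = seq[lo:hi]
    if strand == "-":
        ctx = reverse_complement(ctx)
    return ctx, len(ctx) < window


def call_sites(
    sites: list[SiteCount],
    refs: ReferenceSet | None = None,
    window: int = DEFAULT_CONTEXT_WINDOW,
) -> list[MethylationCall]:
    """Attach level, p-value and flanking context to every counted site."""
    calls = []
    for s in sites:
        ctx, trunc = extract_context(refs, s.ref_id, s.pos, s.strand, window) if refs else ("", False)
        calls.append(
            MethylationCall(
                site=s,
                level=methylation_level(s.k, s.n),
                p=fisher_conversion_test(s.k, s.n),
                context=ctx,
                truncated=trunc,
            )
        )
    return calls


def significant_calls(calls: list[MethylationCall], alpha: float = DEFAULT_ALPHA) -> list[MethylationCall]:
    return [c for c in calls if c.p < alpha]


def spacing_filter(calls: list[MethylationCall], spacing: int = DEFAULT_SPACING) -> list[MethylationCall]:
    """Discard every call with another call within ``spacing`` nt on the same
    reference — both members of a close pair are removed (clustered calls are
    a hallmark of local conversion artifacts)."""
    order = sorted(calls, key=lambda c: (c.site.ref_id, c.site.pos))
    drop: set[int] = set()
    for i in range(len(order) - 1):
        j = i + 1
        while j < len(order) and (
            order[j].site.ref_id == order[i].site.ref_id
            and order[j].site.pos - order[i].site.pos <= spacing
        ):
            drop.add(id(order[i]))
            drop.add(id(order[j]))
            j += 1
    return [c for c in calls if id(c) not in drop]


def collapse_by_context(calls: list[MethylationCall]) -> list[MethylationCall]:
    """Collapse calls sharing an identical flanking context into one call.

    Multi-copy genes produce several genomic positions with the same local
    sequence; their counts are summed and level/p recomputed from the sums so
    the collapsed call reflects the cumulative evidence.
    """
    groups: dict[str, list[MethylationCall]] = {}
    for c in sorted(calls, key=lambda c: (c.site.ref_id, c.site.pos, c.site.strand)):
        groups.setdefault(c.context, []).append(c)
    out = []
    for gi, (ctx, members) in enumerate(sorted(groups.items(), key=lambda kv: kv[1][0].site.pos)):
        rep = members[0]
        if len(members) == 1:
            rep.group_id = f"ctx{gi:04d}"
            out.append(rep)
            continue
        n = sum(m.site.n for m in members)
        k = sum(m.site.k for m in members)
        site = replace(rep.site, n=n, k=k)
        out.append(
            MethylationCall(
                site=site,
                level=methylation_level(k, n),
                p=fisher_conversion_test(k, n),
                context=ctx,
                truncated=rep.truncated,
                group_id=f"ctx{gi:04d}",
                members=tuple(m for mm in members for m in mm.members),
            )
        )
    return sorted(out, key=lambda c: (c.site.ref_id, c.site.pos, c.site.strand))


def classify_calls(
    calls: list[MethylationCall], bands: tuple[float, ...] = DEFAULT_BANDS
) -> list[MethylationCall]:
    """Label each call by its methylation-level band (edges inclusive upward).

    Default bands {10, 20, 50} give <10%, 10-20%, 20-50% and >=50%.
    """
    lo, mid, hi = bands
    for c in calls:
        if c.level >= hi:
            c.classification = f">={hi:g}%"
        elif c.level >= mid:
            c.classification = f"{mid:g}-{hi:g}%"
        elif c.level >= lo:
            c.classification = f"{lo:g}-{mid:g}%"
        else:
            c.classification = f"<{lo:g}%"
    return calls


# ---------------------------------------------------------------------------
# Library summaries and spike-in QC
# ---------------------------------------------------------------------------

def conversion_rate(alignments: list[BsAlignment]) -> float | None:
    """Percent of sequenced reference-C positions converted, over raw
    (pre-filter) alignments; all aligned bases contribute."""
    total = unconv = 0
    for aln in alignments:
        total += len(aln.events)
        unconv += sum(1 for ev in aln.events if ev.unconverted)
    if total == 0:
        return None
    return 100.0 * (total - unconv) / total


def coverage_summary(
    alignments: list[BsAlignment],
    refs: ReferenceSet,
    min_mean_coverage: float = 5.0,
    biotypes: tuple[str, ...] | None = None,
) -> LibrarySummary:
    """Per-gene mean per-base coverage and the count of genes above the
    (strict) mean-coverage threshold."""
    depth: dict[str, np.ndarray] = {}
    for rec in refs:
        depth[rec.id] = np.zeros(len(rec.seq) + 1, dtype=np.int64)
    for aln in alignments:
        d = depth.get(aln.ref_id)
        if d is not None:
            d[aln.start] += 1
            d[aln.end] -= 1
    cum = {rid: np.cumsum(d[:-1]) for rid, d in depth.items()}
    means: dict[str, float] = {}
    for rid, feat in refs.all_features():
        if biotypes is not None and feat.biotype not in biotypes:
            continue
        means[feat.feature_id] = float(cum[rid][feat.start : feat.end].mean())
    n_cov = sum(1 for m in means.values() if m > min_mean_coverage)
    return LibrarySummary(
        conversion_rate=conversion_rate(alignments),
        gene_mean_coverage=means,
        n_genes=len(means),
        n_genes_covered=n_cov,
        pct_genes_covered=float(round(100.0 * n_cov / len(means))) if means else 0.0,
    )


@dataclass
class SpikeReport:
    """Non-conversion QC for one unmethylated spike-in template."""

    spike_id: str
    n_reads: int
    overall_nonconversion_pct: float | None
    motif_c: dict[int, dict] = field(default_factory=dict)  # anchor pos -> {n,k,pct}


def spike_qc(
    reads,
    spike_refs: ReferenceSet,
    motif_pattern: str = "ATCGANGT",
    motif_anchor: int = 2,
    anchors: dict[str, int] | None = None,
    min_quality: int = DEFAULT_MIN_QUALITY,
    unconverted_cutoff: int = DEFAULT_UNCONVERTED_CUTOFF,
    seed: int = 0,
) -> list[SpikeReport]:
    """Align a library against the spike templates alone and quantify
    non-conversion per spike, overall and at the embedded consensus C.

    Spike templates form their own synthetic reference, so spike reads are
    never counted toward genomic sites and vice versa.  Templates are
    unmethylated by construction: non-conversion at the consensus C near the
    global rate shows the motif itself is not bisulfite-resistant.

    The interrogated consensus C per template is either given explicitly via
    ``anchors`` (template id -> position of the C) or located by scanning
    with ``motif_pattern``; an explicit anchor is needed for consensus
    variants that deviate from the scanning pattern.
    """
    from .motif_analysis import iupac_regex  # local import to avoid a cycle

    conv = convert_reference(spike_refs, mode=TRANSCRIPTOME)
    aligner = BisulfiteAligner(conv)
    alignments, stats_ = map_reads(reads, aligner, seed=seed)
    alignments = filter_unconverted_reads(alignments, unconverted_cutoff, min_quality)
    sites = {(s.ref_id, s.strand, s.pos): s for s in pileup(alignments, min_quality=min_quality)}
    pat = re.compile(f"(?=({iupac_regex(motif_pattern)}))")
    reports = []
    for rec in spike_refs:
        hits = [a for a in alignments if a.ref_id == rec.id]
        n_tot = sum(s.n for (rid, strand, _), s in sites.items() if rid == rec.id and strand == "+")
        k_tot = sum(s.k for (rid, strand, _), s in sites.items() if rid == rec.id and strand == "+")
        rep = SpikeReport(
            spike_id=rec.id,
            n_reads=len(hits),
            overall_nonconversion_pct=(100.0 * k_tot / n_tot) if n_tot else None,
        )
        if anchors and rec.id in anchors:
            anchor_positions = [anchors[rec.id]]
        else:
            anchor_positions = [m.start() + motif_anchor for m in pat.finditer(rec.seq)]
        for anchor in anchor_positions:
            s = sites.get((rec.id, "+", anchor))
            rep.motif_c[anchor] = {
                "n": s.n if s else 0,
                "k": s.k if s else 0,
                "pct": (100.0 * s.k / s.n) if s and s.n else None,
            }
        if not hits:
            logger.warning("no reads mapped to spike %s", rec.id)
        reports.append(rep)
    return reports
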