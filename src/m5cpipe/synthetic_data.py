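"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates an RNA bisulfite-sequencing experiment on a microbial
genome: annotated genes on both strands (protein-coding plus rRNA/tRNA-like
features), planted m5C sites with chosen stoichiometry — optionally embedded
in the ATCGANGT consensus — and 40-nt reads from a non-directional
double-stranded cDNA library with

* per-C conversion of unmethylated cytosines (default probability 0.985,
  matching the >98% conversion of real libraries),
* whole-molecule conversion failures (a small fraction of molecules sees a
  much lower conversion probability, the artifact motivating the
  >=3-unconverted-C read filter),
* sequencing errors, a Phred-quality model with a configurable fraction of
  sub-20 bases, and PCR duplicates with identical sequence strings.

Unmethylated ~200-nt spike templates carrying one consensus variant each, and
RIP fragment libraries (IP enriched at planted sites proportionally to
stoichiometry; control-IP and input uniform), cover the QC and validation
stages.  Every stochastic outcome is logged to a TruthTable so filters and
calls can be audited read by read.  All randomness flows from one mandatory
seed; independent streams are spawned per stage so the genome, the reads, the
spikes and the RIP libraries are individually reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .bs_align import BsRead
from .reference_prep import (
    GeneFeature,
    ReferenceSet,
    RefRecord,
    reverse_complement,
)
from .rip_coverage import Fragment

BASES = np.array(list("ACGT"))
CONSENSUS = "ATCGANGT"
CONSENSUS_ANCHOR = 2
SPIKE_VARIANTS = ("ATCGAGGT", "ATCGAAGG")


@dataclass
class SimConfig:
    """Study conditions for the simulator.  ``seed`` is mandatory."""

    seed: int
    genome_length: int = 50_000
    n_genes: int = 30
    gene_length: tuple[int, int] = (600, 1500)
    n_rrna: int = 2
    rrna_length: int = 1500
    n_trna: int = 6
    trna_length: int = 75
    # planted m5C sites: (stoichiometry in [0,1], embed consensus motif?)
    planted: tuple[tuple[float, bool], ...] = ()
    conversion_prob: float = 0.985
    failure_fraction: float = 0.02
    failure_conversion_prob: float = 0.2
    read_length: int = 40
    coverage: float = 50.0
    error_rate: float = 0.002
    pcr_duplicate_rate: float = 0.05
    quality_mean: float = 38.0
    low_quality_fraction: float = 0.02

    def __post_init__(self):
        for name in (
            "conversion_prob", "failure_fraction", "failure_conversion_prob",
            "error_rate", "pcr_duplicate_rate", "low_quality_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for stoich, _ in self.planted:
            if not 0.0 <= stoich <= 1.0:
                raise ValueError(f"stoichiometry {stoich} outside [0, 1]")
        if self.coverage < 0:
            raise ValueError("coverage must be non-negative")

    def stream(self, label: int) -> np.random.Generator:
        """Independent, reproducible RNG stream for one stage."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, label)))


@dataclass(frozen=True)
class PlantedSite:
    ref_id: str
    pos: int  # genomic, 0-based; a C on the designated strand
    strand: str
    stoichiometry: float
    motif_embedded: bool
    gene_id: str
    context: str = ""  # coding-strand flank


@dataclass
class ReadTruth:
    gene_id: str
    ref_id: str
    start: int  # genomic start of the fragment
    strand: str  # transcript strand
    reverse: bool  # read emitted as the second cDNA strand
    conversion_failure: bool
    duplicate_of: str | None
    n_cytosines: int  # reference Cs in the fragment (transcript strand)
    n_unconverted: int  # retained Cs (pre sequencing error)
    planted_outcomes: dict[int, bool] = field(default_factory=dict)  # gpos -> methylated


@dataclass
class TruthTable:
    sites: list[PlantedSite] = field(default_factory=list)
    reads: dict[str, ReadTruth] = field(default_factory=dict)

    def site_map(self) -> dict[tuple[str, int, str], PlantedSite]:
        return {(s.ref_id, s.pos, s.strand): s for s in self.sites}

    def realized_levels(self) -> dict[tuple[str, int, str], tuple[int, int]]:
        """(k, n) per planted site over non-failure, non-duplicate molecules —
        the realized methylation truth a perfect pipeline would estimate."""
        site_strand = {(s.ref_id, s.pos): s.strand for s in self.sites}
        out: dict[tuple[str, int, str], list[int]] = {}
        for rt in self.reads.values():
            if rt.conversion_failure or rt.duplicate_of is not None:
                continue
            for gpos, methylated in rt.planted_outcomes.items():
                strand = site_strand[(rt.ref_id, gpos)]
                c = out.setdefault((rt.ref_id, gpos, strand), [0, 0])
                c[1] += 1
                if methylated:
                    c[0] += 1
        return {key: (k, n) for key, (k, n) in out.items()}


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _write_coding(genome: list[str], feat: GeneFeature, offset: int, text: str) -> None:
    """Write ``text`` at coding-strand offset ``offset`` of a feature."""
    if feat.strand == "+":
        start = feat.start + offset
        genome[start : start + len(text)] = list(text)
    else:
        start = feat.end - offset - len(text)
        genome[start : start + len(text)] = list(reverse_complement(text))


def _coding_base(genome: list[str], feat: GeneFeature, offset: int) -> str:
    if feat.strand == "+":
        return genome[feat.start + offset]
    return reverse_complement(genome[feat.end - 1 - offset])


def simulate_genome(cfg: SimConfig) -> tuple[ReferenceSet, TruthTable]:
    """Random annotated genome with planted m5C sites.

    Features are laid out non-overlapping with random intergenic gaps;
    motif-embedded sites get the full consensus written on the coding strand,
    other planted sites get a C whose context deliberately breaks the
    consensus.  Fails if the requested sites do not fit.
    """
    rng = cfg.stream(0)
    genome = list(rng.choice(BASES, size=cfg.genome_length))
    features: list[GeneFeature] = []
    cursor = int(rng.integers(40, 120))
    plan = (
        [("rRNA", cfg.rrna_length)] * cfg.n_rrna
        + [("tRNA", cfg.trna_length)] * cfg.n_trna
        + [("CDS", None)] * cfg.n_genes
    )
    for i, (biotype, length) in enumerate(plan):
        if length is None:
            length = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
        if cursor + length + 40 > cfg.genome_length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(GeneFeature(f"{biotype.lower()}{i:03d}", cursor, cursor + length, strand, biotype))
        cursor += length + int(rng.integers(40, 160))

    truth = TruthTable()
    cds = [f for f in features if f.biotype == "CDS" and f.length >= 120]
    if cfg.planted and not cds:
        raise ValueError("no genes large enough to plant sites in")
    occupied: list[int] = []
    gene_cycle = list(rng.permutation(len(cds))) if cds else []
    for si, (stoich, motif) in enumerate(cfg.planted):
        placed = False
        for attempt in range(200):
            feat = cds[gene_cycle[(si + attempt) % len(gene_cycle)]]
            j = int(rng.integers(30, feat.length - 30))
            gpos = feat.start + j if feat.strand == "+" else feat.end - 1 - j
            if any(abs(gpos - p) < 80 for p in occupied):
                continue
            if motif:
                n_base = str(rng.choice(BASES))
                _write_coding(genome, feat, j - CONSENSUS_ANCHOR, CONSENSUS.replace("N", n_base))
            else:
                _write_coding(genome, feat, j, "C")
                # break the consensus so the site cannot double as a motif hit
                if _coding_base(genome, feat, j - 2) == "A":
                    _write_coding(genome, feat, j - 2, "G")
            occupied.append(gpos)
            ctx_lo = max(0, j - 15)
            coding = "".join(
                _coding_base(genome, feat, jj) for jj in range(ctx_lo, min(feat.length, j + 16))
            )
            truth.sites.append(
                PlantedSite("chr1", gpos, feat.strand, stoich, motif, feat.feature_id, coding)
            )
            placed = True
            break
        if not placed:
            raise ValueError("could not place all planted sites (genome too crowded)")

    refs = ReferenceSet([RefRecord("chr1", "".join(genome), tuple(features))])
    return refs, truth


# ---------------------------------------------------------------------------
# Bisulfite reads
# ---------------------------------------------------------------------------

def simulate_bisulfite_reads(
    refs: ReferenceSet, truth: TruthTable, cfg: SimConfig
) -> tuple[list[BsRead], TruthTable]:
    """Transcript fragments through the bisulfite/sequencing noise model.

    Molecules are drawn length-weighted from annotated genes; each molecule
    is flagged a conversion failure with the configured fraction, converting
    its unmethylated Cs with the (much lower) failure probability instead.
    Planted-site Cs stay unconverted with probability equal to the site's
    stoichiometry.  Reads are emitted in either cDNA orientation
    (non-directional library), sequencing errors and qualities applied, and
    PCR duplicates appended with identical sequence and qualities.
    """
    if cfg.coverage <= 0:
        raise ValueError("coverage must be positive to simulate reads")
    rng = cfg.stream(1)
    rl = cfg.read_length
    site_map = {(s.ref_id, s.pos): s for s in truth.sites}

    genes = []
    for rec in refs:
        feats = rec.features or (GeneFeature(rec.id, 0, len(rec.seq), "+", "gene"),)
        for feat in feats:
            if feat.length < rl:
                continue
            coding = rec.seq[feat.start : feat.end]
            if feat.strand == "-":
                coding = reverse_complement(coding)
            c_offsets = np.array([i for i, b in enumerate(coding) if b == "C"], dtype=np.int64)
            genes.append((rec.id, feat, coding, c_offsets))
    if not genes:
        raise ValueError("no features long enough to draw reads from")

    lengths = np.array([f.length for _, f, _, _ in genes], dtype=float)
    weights = lengths / lengths.sum()
    n_mol = int(round(cfg.coverage * lengths.sum() / rl))
    gene_idx = rng.choice(len(genes), size=n_mol, p=weights)
    u_off = rng.random(n_mol)
    failure = rng.random(n_mol) < cfg.failure_fraction
    reverse = rng.random(n_mol) < 0.5
    duplicate = rng.random(n_mol) < cfg.pcr_duplicate_rate

    reads: list[BsRead] = []
    for i in range(n_mol):
        rid, feat, coding, c_offsets = genes[gene_idx[i]]
        off = int(u_off[i] * (feat.length - rl + 1))
        lo, hi = np.searchsorted(c_offsets, (off, off + rl))
        cs = c_offsets[lo:hi]
        conv_p = cfg.failure_conversion_prob if failure[i] else cfg.conversion_prob
        frag = list(coding[off : off + rl])
        u_meth = rng.random(len(cs))
        u_conv = rng.random(len(cs))
        n_unconv = 0
        outcomes: dict[int, bool] = {}
        for c_off, um, uc in zip(cs, u_meth, u_conv):
            gpos = feat.start + c_off if feat.strand == "+" else feat.end - 1 - c_off
            site = site_map.get((rid, int(gpos)))
            if site is not None:
                methylated = um < site.stoichiometry
                retained = methylated or uc >= conv_p
                outcomes[int(gpos)] = bool(methylated)
            else:
                retained = um >= conv_p
            if retained:
                n_unconv += 1
            else:
                frag[c_off - off] = "T"

        err = np.flatnonzero(rng.random(rl) < cfg.error_rate)
        for e in err:
            frag[e] = str(rng.choice(BASES[BASES != frag[e]]))
        lowq = rng.random(rl) < cfg.low_quality_fraction
        quals = np.clip(np.rint(rng.normal(cfg.quality_mean, 2.0, rl)), 2, 41).astype(int)
        quals[lowq] = rng.integers(8, 20, int(lowq.sum()))

        seq = "".join(frag)
        qlist = quals.tolist()
        if reverse[i]:
            seq = reverse_complement(seq)
            qlist = qlist[::-1]
        name = f"r{i:07d}"
        gstart = feat.start + off if feat.strand == "+" else feat.end - off - rl
        reads.append(BsRead(name, seq, qlist))
        truth.reads[name] = ReadTruth(
            gene_id=feat.feature_id, ref_id=rid, start=int(gstart), strand=feat.strand,
            reverse=bool(reverse[i]), conversion_failure=bool(failure[i]),
            duplicate_of=None, n_cytosines=len(cs), n_unconverted=n_unconv,
            planted_outcomes=outcomes,
        )
        if duplicate[i]:
            dname = f"{name}.dup"
            reads.append(BsRead(dname, seq, qlist))
            truth.reads[dname] = ReadTruth(
                gene_id=feat.feature_id, ref_id=rid, start=int(gstart), strand=feat.strand,
                reverse=bool(reverse[i]), conversion_failure=bool(failure[i]),
                duplicate_of=name, n_cytosines=len(cs), n_unconverted=n_unconv,
                planted_outcomes=dict(outcomes),
            )
    return reads, truth


# ---------------------------------------------------------------------------
# Spike-in templates and RIP libraries
# ---------------------------------------------------------------------------

def simulate_spikes(
    cfg: SimConfig, template_length: int = 200, n_reads_per_spike: int | None = None
) -> tuple[ReferenceSet, list[BsRead], TruthTable, dict[str, int]]:
    """Two unmethylated spike templates, each embedding one consensus variant,
    plus a bisulfite read library over them.

    Returns (templates, reads, truth, anchor positions of the embedded
    consensus C per template).  Backgrounds are redrawn until each variant
    occurs exactly once in its template.
    """
    rng = cfg.stream(2)
    records = []
    anchors: dict[str, int] = {}
    for i, variant in enumerate(SPIKE_VARIANTS):
        insert_at = template_length // 2 - len(variant) // 2
        for _ in range(50):
            tpl = list(rng.choice(BASES, size=template_length))
            tpl[insert_at : insert_at + len(variant)] = list(variant)
            seq = "".join(tpl)
            if len(re.findall(f"(?={variant})", seq)) == 1:
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not build a clean spike template")
        sid = f"spike{i + 1}"
        records.append(
            RefRecord(sid, seq, (GeneFeature(f"{sid}_t", 0, template_length, "+", "spike"),))
        )
        anchors[sid] = insert_at + CONSENSUS_ANCHOR
    spikes = ReferenceSet(records)

    read_cfg = cfg
    if n_reads_per_spike is not None:
        cov = n_reads_per_spike * len(SPIKE_VARIANTS) * cfg.read_length / (
            template_length * len(SPIKE_VARIANTS)
        )
        from dataclasses import replace as _replace

        read_cfg = _replace(cfg, coverage=cov)
    truth = TruthTable()  # no planted sites: templates are unmethylated
    reads, truth = simulate_bisulfite_reads(spikes, truth, read_cfg)
    return spikes, reads, truth, anchors


def simulate_rip_library(
    refs: ReferenceSet,
    truth: TruthTable,
    enrichment_factor: float,
    cfg: SimConfig,
    fragment_length: int = 100,
    n_fragments: int | None = None,
) -> dict[str, list[Fragment]]:
    """IP, control-IP and input fragment libraries (~100-nt fragments).

    IP fragments overlapping a planted site are over-sampled by a factor
    1 + (enrichment_factor - 1) * stoichiometry (rejection sampling against a
    uniform proposal); control-IP and input are sampled uniformly.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    rng = cfg.stream(3)
    genes = [
        (rec.id, feat)
        for rec in refs
        for feat in rec.features
        if feat.length >= fragment_length
    ]
    if not genes:
        raise ValueError("no features long enough for RIP fragments")
    lengths = np.array([f.length for _, f in genes], dtype=float)
    weights = lengths / lengths.sum()
    if n_fragments is None:
        n_fragments = int(round(cfg.coverage * lengths.sum() / fragment_length))
    sites = [(s.ref_id, s.pos, s.stoichiometry) for s in truth.sites]

    def draw(n: int) -> list[Fragment]:
        idx = rng.choice(len(genes), size=n, p=weights)
        flen = np.clip(np.rint(rng.normal(fragment_length, 10, n)), 60, 150).astype(int)
        out = []
        for g, fl in zip(idx, flen):
            rid, feat = genes[g]
            fl = min(int(fl), feat.length)
            off = int(rng.integers(0, feat.length - fl + 1))
            out.append(Fragment(rid, feat.start + off, fl))
        return out

    def ip_weight(frag: Fragment) -> float:
        w = 1.0
        for rid, pos, stoich in sites:
            if rid == frag.ref_id and frag.start <= pos < frag.end:
                w = max(w, 1.0 + (enrichment_factor - 1.0) * stoich)
        return w

    ip: list[Fragment] = []
    while len(ip) < n_fragments:
        batch = draw(max(1024, n_fragments))
        accept = rng.random(len(batch))
        for frag, u in zip(batch, accept):
            if u < ip_weight(frag) / enrichment_factor:
                ip.append(frag)
                if len(ip) == n_fragments:
                    break
    return {
        "IP": ip,
        "control-IP": draw(n_fragments),
        "input": draw(n_fragments),
    }


# ---------------------------------------------------------------------------
# FASTQ / truth I/O
# ---------------------------------------------------------------------------

def write_fastq(reads: list[BsRead], path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.quals)
            desc = f" {header_comment}" if header_comment else ""
            fh.write(f"@{r.id}{desc}\n{r.seq}\n+\n{quals}\n")


def read_fastq(path) -> list[BsRead]:
    from Bio import SeqIO

    return [
        BsRead(rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_truth_tsv(truth: TruthTable, sites_path, reads_path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "ref": s.ref_id, "position": s.pos + 1, "strand": s.strand,
                "stoichiometry": s.stoichiometry, "motif_embedded": s.motif_embedded,
                "gene": s.gene_id, "context": s.context,
            }
            for s in truth.sites
        ]
    ).to_csv(sites_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "read": name, "gene": rt.gene_id, "ref": rt.ref_id,
                "start": rt.start + 1, "strand": rt.strand, "reverse": rt.reverse,
                "conversion_failure": rt.conversion_failure,
                "duplicate_of": rt.duplicate_of or "",
                "n_cytosines": rt.n_cytosines, "n_unconverted": rt.n_unconverted,
            }
            for name, rt in truth.reads.items()
        ]
    ).to_csv(reads_path, sep="\t", index=False)
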