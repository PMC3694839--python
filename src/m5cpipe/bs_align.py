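"""Bisulfite-aware short-read alignment.

Three-letter matching: both the read and the reference are collapsed so that
the bisulfite conversion (C read as T on the transcript strand) can never
penalize a placement.  The library is non-directional (double-stranded cDNA),
so every read is tried in four states,

    {C->T, G->A read conversion} x {as sequenced, reverse complement},

each against the matching strand-conversion of the reference: C->T states are
matched on the plus-converted reference and report transcript strand '+';
G->A states on the minus-converted reference report strand '-'.  The winning
state fixes the strand on which per-cytosine conversion states are read out.

The mapping contract further implements:

* exact k-mer seeding (default k=12, three seed offsets so that up to two
  mismatches can never knock out every seed) followed by ungapped extension;
* iterative 2-nt trimming from the 3' end of unaligned reads, stopping before
  any attempt below a 35-nt floor;
* seeded uniform random assignment of reads whose best score is shared by
  several placements (multi-copy genes).

Alignments can also be imported from SAM, with conversion states
reconstructed against the original (unconverted) reference.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import NamedTuple

import pysam

from .reference_prep import (
    ConvertedReference,
    ReferenceSet,
    bisulfite_minus,
    bisulfite_plus,
    reverse_complement,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentParams:
    """Tunables of the mapping contract."""

    seed_k: int = 12
    max_mismatches: int = 2
    min_length: int = 35
    trim_step: int = 2


@dataclass
class BsRead:
    """A sequenced bisulfite read (post-conversion alphabet)."""

    id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self):
        self.seq = self.seq.upper()
        self.quals = tuple(self.quals)
        if len(self.quals) != len(self.seq):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.seq)

    def trimmed(self, length: int) -> "BsRead":
        """Trim from the 3' end, qualities in lockstep."""
        return BsRead(self.id, self.seq[:length], self.quals[:length])


class ConvEvent(NamedTuple):
    """Conversion state at one reference cytosine covered by a read.

    ``pos`` is the original reference coordinate of the cytosine (the C base
    itself on strand '+', the G base whose complement is the transcript C on
    strand '-').  ``unconverted`` True means the read retained the C
    (evidence of methylation); False means it was read as converted.
    Reference cytosines covered by any other read base (sequencing error) are
    neutral and carry no event.
    """

    pos: int
    unconverted: bool
    qual: int


@dataclass
class BsAlignment:
    """A read placed on the original reference with per-cytosine states."""

    read_id: str
    ref_id: str
    start: int  # 0-based on the original reference
    strand: str  # strand of the originating transcript
    length: int
    n_mismatch: int
    reverse: bool  # read is stored reverse-complemented relative to the reference
    seq: str  # read sequence as sequenced (after any trimming)
    events: tuple[ConvEvent, ...]
    multiplicity: int = 1

    @property
    def end(self) -> int:
        return self.start + self.length

    def n_unconverted(self, min_quality: int | None = None) -> int:
        if min_quality is None:
            return sum(1 for ev in self.events if ev.unconverted)
        return sum(1 for ev in self.events if ev.unconverted and ev.qual > min_quality)

    def sort_key(self):
        return (self.ref_id, self.start, self.strand)


@dataclass
class AlignmentResult:
    """Outcome of aligning one read, including the trimming trail."""

    read_id: str
    candidates: list[BsAlignment]
    attempted_lengths: list[int] = field(default_factory=list)
    reason: str | None = None

    @property
    def mapped(self) -> bool:
        return bool(self.candidates)

    @property
    def final_length(self) -> int | None:
        return self.attempted_lengths[-1] if self.attempted_lengths else None


def _hamming(a: str, b: str) -> int:
    if a == b:
        return 0
    return sum(1 for x, y in zip(a, b) if x != y)


class _KmerIndex:
    """Exact k-mer dictionary over a set of (converted) sequences."""

    def __init__(self, seqs: dict[str, str], k: int):
        self.k = k
        index: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in seqs.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((rid, i))
        self._index = index

    def lookup(self, kmer: str):
        return self._index.get(kmer, ())


# Alignment states for a non-directional library.  Each entry is
# (read orientation, read conversion, transcript strand).
_STATES = (
    ("fwd", "CT", "+"),  # sense read of a forward-strand transcript
    ("rev", "CT", "+"),  # second-strand cDNA read of a forward transcript
    ("rev", "GA", "-"),  # sense read of a reverse-strand transcript
    ("fwd", "GA", "-"),  # second-strand cDNA read of a reverse transcript
)


class BisulfiteAligner:
    """Three-letter seeded aligner over a converted reference."""

    def __init__(self, conv_ref: ConvertedReference, params: AlignmentParams | None = None):
        self.conv_ref = conv_ref
        self.params = params or AlignmentParams()
        k = self.params.seed_k
        self._conv_seqs = {"CT": conv_ref.plus, "GA": conv_ref.minus}
        self._indexes = {
            "CT": _KmerIndex(conv_ref.plus, k),
            "GA": _KmerIndex(conv_ref.minus, k),
        }

    # -- core matching -----------------------------------------------------

    def _seed_offsets(self, length: int) -> list[int]:
        k = self.params.seed_k
        if length < k:
            return []
        # three spread seeds: with <=2 mismatches at least one seed is exact
        return sorted({0, (length - k) // 2, length - k})

    def _candidates_for_state(self, genome_read: str, conversion: str):
        """Yield (ref_id, start, mismatches) for one read state."""
        query = bisulfite_plus(genome_read) if conversion == "CT" else bisulfite_minus(genome_read)
        L = len(query)
        index = self._indexes[conversion]
        conv_seqs = self._conv_seqs[conversion]
        max_mm = self.params.max_mismatches
        seen: set[tuple[str, int]] = set()
        for off in self._seed_offsets(L):
            for rid, pos in index.lookup(query[off : off + self.params.seed_k]):
                start = pos - off
                key = (rid, start)
                if key in seen:
                    continue
                seen.add(key)
                ref = conv_seqs[rid]
                if start < 0 or start + L > len(ref):
                    continue
                mm = _hamming(query, ref[start : start + L])
                if mm <= max_mm:
                    yield rid, start, mm

    def _events(self, rid: str, start: int, length: int, strand: str,
                genome_read: str, genome_quals: tuple[int, ...]) -> tuple[ConvEvent, ...]:
        ref = self.conv_ref.source.seq(rid)[start : start + length]
        events = []
        if strand == "+":
            retained, converted, target = "C", "T", "C"
        else:
            retained, converted, target = "G", "A", "G"
        for i, base in enumerate(ref):
            if base == target:
                b = genome_read[i]
                if b == retained:
                    events.append(ConvEvent(start + i, True, genome_quals[i]))
                elif b == converted:
                    events.append(ConvEvent(start + i, False, genome_quals[i]))
        return tuple(events)

    def align_read(self, read: BsRead) -> list[BsAlignment]:
        """All equal-best placements of a read at its current length."""
        if len(read) < self.params.min_length:
            return []
        fwd = read.seq
        rev = reverse_complement(fwd)
        quals_rev = read.quals[::-1]
        raw: dict[tuple[str, int, str], tuple[int, str, bool]] = {}
        for orient, conversion, strand in _STATES:
            genome_read = fwd if orient == "fwd" else rev
            for rid, start, mm in self._candidates_for_state(genome_read, conversion):
                key = (rid, start, strand)
                prev = raw.get(key)
                if prev is None or mm < prev[0]:
                    raw[key] = (mm, conversion, orient == "rev")
        if not raw:
            return []
        best = min(mm for mm, _, _ in raw.values())
        out = []
        for (rid, start, strand), (mm, _conversion, is_rev) in sorted(raw.items()):
            if mm != best:
                continue
            genome_read = rev if is_rev else fwd
            genome_quals = quals_rev if is_rev else read.quals
            out.append(
                BsAlignment(
                    read_id=read.id,
                    ref_id=rid,
                    start=start,
                    strand=strand,
                    length=len(read),
                    n_mismatch=mm,
                    reverse=is_rev,
                    seq=read.seq,
                    events=self._events(rid, start, len(read), strand,
                                        genome_read, genome_quals),
                )
            )
        for aln in out:
            aln.multiplicity = len(out)
        return out

    def iterative_trim_align(self, read: BsRead) -> AlignmentResult:
        """Align, trimming 2 nt from the 3' end after each failure.

        No attempt is made below the 35-nt floor; the last attempted length
        is recorded for unmapped reads.
        """
        attempted = []
        length = len(read)
        if length < self.params.min_length:
            return AlignmentResult(read.id, [], [length], reason="too_short")
        current = read
        while length >= self.params.min_length:
            attempted.append(length)
            cands = self.align_read(current)
            if cands:
                return AlignmentResult(read.id, cands, attempted)
            length -= self.params.trim_step
            current = read.trimmed(length)
        return AlignmentResult(read.id, [], attempted, reason="unaligned")


def assign_multimappers(cands: list[BsAlignment], seed: int | random.Random) -> BsAlignment:
    """Pick one placement uniformly at random among equal-best candidates.

    Candidates are pre-sorted by (reference id, coordinate, strand) so the
    choice is deterministic for a fixed seed regardless of input order.
    """
    if not cands:
        raise ValueError("no candidate alignments to assign")
    best = min(a.n_mismatch for a in cands)
    if any(a.n_mismatch != best for a in cands):
        raise ValueError("assign_multimappers requires equal-best candidates")
    ordered = sorted(cands, key=BsAlignment.sort_key)
    rng = random.Random(seed) if isinstance(seed, int) else seed
    chosen = ordered[rng.randrange(len(ordered))]
    chosen.multiplicity = len(ordered)
    return chosen


@dataclass
class MappingStats:
    total: int = 0
    mapped: int = 0
    unmapped: int = 0
    multimapped: int = 0
    trimmed: int = 0


def map_reads(reads, aligner: BisulfiteAligner, seed: int = 0) -> tuple[list[BsAlignment], MappingStats]:
    """Map a read set end to end: trim-align then resolve multi-mappers."""
    rng = random.Random(seed)
    stats = MappingStats()
    out = []
    for read in reads:
        stats.total += 1
        res = aligner.iterative_trim_align(read)
        if not res.mapped:
            stats.unmapped += 1
            continue
        stats.mapped += 1
        if len(res.attempted_lengths) > 1:
            stats.trimmed += 1
        if len(res.candidates) > 1:
            stats.multimapped += 1
        out.append(assign_multimappers(res.candidates, rng))
    return out, stats


# ---------------------------------------------------------------------------
# SAM import/export
# ---------------------------------------------------------------------------

def _sam_header(refs: ReferenceSet) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": rec.id, "LN": len(rec.seq)} for rec in refs],
    }


def write_sam(alignments, refs: ReferenceSet, path) -> None:
    """Emit minimal valid SAM; XG carries the conversion strand, XE the
    conversion-state vector (pos:state, U=unconverted, c=converted)."""
    header = _sam_header(refs)
    tid = {rec.id: i for i, rec in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = aln.read_id
            rec.flag = 16 if aln.reverse else 0
            rec.reference_id = tid[aln.ref_id]
            rec.reference_start = aln.start
            rec.mapping_quality = 255
            rec.cigartuples = [(0, aln.length)]
            seq = reverse_complement(aln.seq) if aln.reverse else aln.seq
            rec.query_sequence = seq
            rec.query_qualities = None
            rec.set_tag("NM", aln.n_mismatch)
            rec.set_tag("XG", "CT" if aln.strand == "+" else "GA")
            rec.set_tag("XM", aln.multiplicity)
            rec.set_tag(
                "XE",
                ",".join(f"{ev.pos}:{'U' if ev.unconverted else 'c'}" for ev in aln.events),
            )
            fh.write(rec)


def _infer_strand(pairs, ref: str, seq: str) -> str:
    ct = ga = 0
    for qpos, rpos in pairs:
        rb = ref[rpos]
        qb = seq[qpos]
        if rb == "C" and qb == "T":
            ct += 1
        elif rb == "G" and qb == "A":
            ga += 1
    return "+" if ct >= ga else "-"


def import_sam(path, refs: ReferenceSet, default_qual: int = 40) -> list[BsAlignment]:
    """Import external alignments; conversion states are rebuilt from the
    original reference.  Unmapped/secondary/supplementary records are skipped
    and counted."""
    out = []
    skipped = {"unmapped": 0, "secondary": 0}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                skipped["secondary"] += 1
                continue
            if rec.reference_name not in refs:
                raise ValueError(
                    f"SAM reference {rec.reference_name!r} not present in the reference set"
                )
            ref = refs.seq(rec.reference_name)
            seq = rec.query_sequence.upper()
            quals = rec.query_qualities
            if quals is None:
                quals = [default_qual] * len(seq)
            pairs = rec.get_aligned_pairs(matches_only=True)
            xg = rec.get_tag("XG") if rec.has_tag("XG") else None
            strand = {"CT": "+", "GA": "-"}.get(xg) or _infer_strand(pairs, ref, seq)
            retained, converted, target = ("C", "T", "C") if strand == "+" else ("G", "A", "G")
            events = []
            mm = 0
            for qpos, rpos in pairs:
                rb = ref[rpos]
                qb = seq[qpos]
                if rb == target:
                    if qb == retained:
                        events.append(ConvEvent(rpos, True, quals[qpos]))
                    elif qb == converted:
                        events.append(ConvEvent(rpos, False, quals[qpos]))
                    else:
                        mm += 1
                elif qb != rb:
                    mm += 1
            as_sequenced = reverse_complement(seq) if rec.is_reverse else seq
            out.append(
                BsAlignment(
                    read_id=rec.query_name,
                    ref_id=rec.reference_name,
                    start=rec.reference_start,
                    strand=strand,
                    length=rec.query_alignment_length,
                    n_mismatch=mm,
                    reverse=rec.is_reverse,
                    seq=as_sequenced,
                    events=tuple(events),
                    multiplicity=rec.get_tag("XM") if rec.has_tag("XM") else 1,
                )
            )
    if skipped["unmapped"] or skipped["secondary"]:
        logger.info(
            "import_sam skipped %d unmapped and %d secondary/supplementary records",
            skipped["unmapped"], skipped["secondary"],
        )
    return out


def brute_force_align(read: BsRead, conv_ref: ConvertedReference,
                      params: AlignmentParams | None = None) -> list[tuple[str, int, str, int]]:
    """Reference oracle: all offsets, all four states, Hamming distance on the
    converted alphabet.  Returns equal-best (ref_id, start, strand, mm).
    Exhaustive; intended for small references and tests."""
    import numpy as np

    params = params or AlignmentParams()
    fwd = read.seq
    rev = reverse_complement(fwd)
    found: dict[tuple[str, int, str], int] = {}
    for orient, conversion, strand in _STATES:
        genome_read = fwd if orient == "fwd" else rev
        query = bisulfite_plus(genome_read) if conversion == "CT" else bisulfite_minus(genome_read)
        conv_seqs = conv_ref.plus if conversion == "CT" else conv_ref.minus
        L = len(query)
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        for rid, ref in conv_seqs.items():
            if len(ref) < L:
                continue
            r = np.frombuffer(ref.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(r, L)
            mms = (windows != q).sum(axis=1)
            for start in np.flatnonzero(mms <= params.max_mismatches):
                key = (rid, int(start), strand)
                mm = int(mms[start])
                if key not in found or mm < found[key]:
                    found[key] = mm
    if not found:
        return []
    best = min(found.values())
    return sorted((rid, start, strand, mm) for (rid, start, strand), mm in found.items() if mm == best)
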