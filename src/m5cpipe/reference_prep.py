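"""Bisulfite-converted reference preparation.

Bisulfite treatment deaminates unmethylated cytosine to uracil, which is read
as T after reverse transcription.  Reads are therefore mapped against
*converted* references in which the conversion has been applied in silico:
a plus conversion (every C -> T, for transcripts read off the forward strand)
and a minus conversion (every G -> A, the same chemistry seen from the
reverse strand).  Two reference modes are supported:

``genome``
    whole chromosomes, both strand conversions; used for mRNA analysis.
``transcriptome``
    a database of unique mature tRNA/rRNA sequences, so that reads from
    multi-copy structural RNAs are not diluted across identical gene copies
    and intron-containing genomic copies do not lose reads.

Conversion is position-preserving, so converted coordinates map one-to-one
onto original coordinates; the provenance map is kept explicit anyway so that
downstream code never assumes this.

Coordinates are 0-based half-open internally; all user-facing reports are
1-based inclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GENOME = "genome"
TRANSCRIPTOME = "transcriptome"
MODES = (GENOME, TRANSCRIPTOME)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def bisulfite_plus(seq: str) -> str:
    """In-silico conversion of the forward strand: every C becomes T."""
    return seq.replace("C", "T")


def bisulfite_minus(seq: str) -> str:
    """Conversion as seen from the reverse strand: every G becomes A."""
    return seq.replace("G", "A")


@dataclass(frozen=True)
class GeneFeature:
    """A strand-aware gene annotation on a reference record.

    ``start``/``end`` are 0-based half-open positions on the record.
    """

    feature_id: str
    start: int
    end: int
    strand: str = "+"
    biotype: str = "gene"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r} for {self.feature_id}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval for feature {self.feature_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RefRecord:
    """One reference sequence plus its annotation.

    ``members`` lists the identifiers of all source gene copies this record
    represents; it is (id,) for ordinary records and grows when identical
    copies are collapsed into a transcript database.
    """

    id: str
    seq: str
    features: tuple[GeneFeature, ...] = ()
    members: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.members:
            object.__setattr__(self, "members", (self.id,))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceSet:
    """A validated collection of reference records."""

    records: list[RefRecord] = field(default_factory=list)

    def __post_init__(self):
        seen_feat: set[str] = set()
        for rec in self.records:
            if not rec.seq:
                raise ValueError(f"record {rec.id!r} has an empty sequence")
            bad = set(rec.seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"record {rec.id!r} contains non-nucleotide characters: "
                    f"{sorted(bad)}"
                )
            for feat in rec.features:
                if feat.end > len(rec.seq):
                    raise ValueError(
                        f"feature {feat.feature_id!r} extends past the end of "
                        f"record {rec.id!r}"
                    )
                if feat.feature_id in seen_feat:
                    raise ValueError(f"duplicate feature id {feat.feature_id!r}")
                seen_feat.add(feat.feature_id)
        self._by_id = {rec.id: rec for rec in self.records}
        if len(self._by_id) != len(self.records):
            raise ValueError("duplicate record ids in reference set")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def get(self, rid: str) -> RefRecord:
        try:
            return self._by_id[rid]
        except KeyError:
            raise KeyError(f"reference {rid!r} not in reference set") from None

    def seq(self, rid: str) -> str:
        return self.get(rid).seq

    def __contains__(self, rid: str) -> bool:
        return rid in self._by_id

    def all_features(self):
        for rec in self.records:
            for feat in rec.features:
                yield rec.id, feat


@dataclass
class ConvertedReference:
    """Both strand conversions of a reference set plus the coordinate back-map.

    Conversion preserves sequence length, so the provenance map from a
    converted coordinate back to the original coordinate is the identity on
    position; the conversion used ("plus" vs "minus") determines which
    original strand the placement reports.
    """

    source: ReferenceSet
    mode: str
    plus: dict[str, str]
    minus: dict[str, str]

    def to_original(self, rid: str, pos: int, conversion: str) -> tuple[int, str]:
        """Map a converted-reference coordinate back to (position, strand)."""
        if conversion not in ("plus", "minus"):
            raise ValueError(f"unknown conversion {conversion!r}")
        n = len(self.source.seq(rid))
        if not 0 <= pos < n:
            raise IndexError(f"position {pos} outside {rid!r} (length {n})")
        return pos, "+" if conversion == "plus" else "-"

    def provenance_table(self) -> pd.DataFrame:
        """Summary provenance map, one row per (record, conversion)."""
        rows = []
        for rec in self.source:
            for conv, strand in (("plus", "+"), ("minus", "-")):
                rows.append(
                    {
                        "record": rec.id,
                        "conversion": conv,
                        "original_strand": strand,
                        "length": len(rec.seq),
                        "coordinate_map": "identity",
                    }
                )
        return pd.DataFrame(rows)


def convert_reference(refs: ReferenceSet, mode: str = GENOME) -> ConvertedReference:
    """Build the in-silico bisulfite-converted reference for both strands."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if len(refs) == 0:
        raise ValueError("reference set is empty")
    plus = {rec.id: bisulfite_plus(rec.seq) for rec in refs}
    minus = {rec.id: bisulfite_minus(rec.seq) for rec in refs}
    return ConvertedReference(source=refs, mode=mode, plus=plus, minus=minus)


def build_transcript_db(tRNAs: ReferenceSet | None, rRNAs: ReferenceSet | None) -> ReferenceSet:
    """Collapse exact-duplicate mature transcript sequences into unique records.

    Multi-copy tRNA/rRNA genes are frequently sequence-identical; aligning
    against one representative per unique sequence prevents dilution of reads
    across identical copies.  Membership of every collapsed source copy is
    recorded so a call on the representative can be attributed to all copies.
    """
    sources = [r for rs in (tRNAs, rRNAs) if rs is not None for r in rs]
    by_seq: dict[str, RefRecord] = {}
    order: list[str] = []
    for rec in sources:
        if rec.seq in by_seq:
            rep = by_seq[rec.seq]
            by_seq[rec.seq] = replace(rep, members=rep.members + rec.members)
        else:
            by_seq[rec.seq] = rec
            order.append(rec.seq)
    return ReferenceSet([by_seq[s] for s in order])


# ---------------------------------------------------------------------------
# File formats: FASTA in/out, GFF3 / BED6 features, provenance sidecar TSV.
# ---------------------------------------------------------------------------

def read_fasta(path, features: dict[str, list[GeneFeature]] | None = None) -> ReferenceSet:
    features = features or {}
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            RefRecord(
                id=rec.id,
                seq=str(rec.seq).upper(),
                features=tuple(features.get(rec.id, ())),
            )
        )
    return ReferenceSet(records)


def write_fasta(refs: ReferenceSet, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(rec.seq), id=rec.id, description="") for rec in refs),
        str(path),
        "fasta",
    )


def write_converted_fasta(conv: ConvertedReference, fasta_path, provenance_path) -> None:
    """Converted sequences as FASTA with a sidecar provenance TSV."""
    recs = []
    for rec in conv.source:
        recs.append(SeqRecord(Seq(conv.plus[rec.id]), id=f"{rec.id}|plusC2T", description=""))
        recs.append(SeqRecord(Seq(conv.minus[rec.id]), id=f"{rec.id}|minusG2A", description=""))
    SeqIO.write(recs, str(fasta_path), "fasta")
    conv.provenance_table().to_csv(provenance_path, sep="\t", index=False)


def _gff_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_gff3(path) -> dict[str, list[GeneFeature]]:
    """Read gene features from GFF3 (1-based inclusive on disk)."""
    out: dict[str, list[GeneFeature]] = {}
    counter = itertools.count(1)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols[:9]
            fid = _gff_attribute(attrs, "ID") or f"feature{next(counter)}"
            out.setdefault(seqid, []).append(
                GeneFeature(fid, int(start) - 1, int(end), strand, biotype=ftype)
            )
    return out


def write_gff3(refs: ReferenceSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, feat in refs.all_features():
            fh.write(
                f"{rid}\tm5cpipe\t{feat.biotype}\t{feat.start + 1}\t{feat.end}\t."
                f"\t{feat.strand}\t.\tID={feat.feature_id}\n"
            )


def read_bed6(path) -> dict[str, list[GeneFeature]]:
    """Read gene features from BED6 (0-based half-open on disk)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    out: dict[str, list[GeneFeature]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.chrom, []).append(
            GeneFeature(str(row.name), int(row.start), int(row.end), str(row.strand))
        )
    return out
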