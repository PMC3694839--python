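"""Consensus-motif scanning and methylation-stratified enrichment.

The methylated mRNA positions in *S. solfataricus* share an 8-nt consensus,
AUCGANGU (DNA: ATCGANGT), with the interrogated C at offset 2.  This module
scans coding genes for the motif, annotates every occurrence whose anchor C
is covered in the pileup, builds the mismatch-constrained control set of
covered cytosines (no A at -2, no T at -1, no G at +1 relative to the C), and
compares the fraction of methylated sites between motif and control sets.  A
position frequency matrix and IUPAC consensus can be derived from site
flanks.

Scanning is coding-strand only by default — the motif is defined on the
mRNA — with an optional strand-agnostic genome-wide mode.  Occurrences are
deduplicated by genomic anchor position, so overlapping gene annotations do
not double-count a site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .meth_call import SiteCount, methylation_level
from .reference_prep import ReferenceSet, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_FOR_PAIR = {frozenset(v): k for k, v in IUPAC.items() if len(v) == 2}

DEFAULT_PATTERN = "ATCGANGT"
# variant spelling of the consensus with degenerate alternatives spelled out
ALT_PATTERN = "ATCGWKGK"
DEFAULT_MIN_COVERAGE = 5


def iupac_regex(pattern: str) -> str:
    parts = []
    for ch in pattern.upper():
        try:
            opts = IUPAC[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in pattern") from None
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def iupac_match(pattern: str, seq: str) -> bool:
    return len(pattern) == len(seq) and re.fullmatch(iupac_regex(pattern), seq.upper()) is not None


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC consensus with the interrogated C at a declared offset."""

    pattern: str = DEFAULT_PATTERN
    anchor: int = 2  # 0-based offset of the methylated C

    def __post_init__(self):
        pat = self.pattern.upper().replace("U", "T")
        object.__setattr__(self, "pattern", pat)
        if not 0 <= self.anchor < len(pat):
            raise ValueError("anchor offset outside pattern")
        if pat[self.anchor] != "C":
            raise ValueError("pattern must have its anchor C at the declared offset")
        iupac_regex(pat)  # validates symbols

    @property
    def regex(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all found
        return re.compile(f"(?=({iupac_regex(self.pattern)}))")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifOccurrence:
    """One motif hit with its anchor-C pileup annotation."""

    gene_id: str
    ref_id: str
    pos: int  # genomic position of the anchor C (0-based)
    strand: str
    flank: str  # coding-strand sequence matching the pattern
    n: int
    k: int

    @property
    def level(self) -> float:
        return methylation_level(self.k, self.n)


def _pileup_index(sites) -> dict[tuple[str, str, int], SiteCount]:
    if isinstance(sites, dict):
        return sites
    return {(s.ref_id, s.strand, s.pos): s for s in sites}


def scan_motif(
    genes: ReferenceSet,
    sites,
    pattern: MotifPattern | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    biotypes: tuple[str, ...] | None = None,
    coding_strand_only: bool = True,
) -> list[MotifOccurrence]:
    """All motif matches on the coding strand of annotated genes whose anchor
    C is covered by at least ``min_coverage`` reads, regardless of p-value."""
    pattern = pattern or MotifPattern()
    index = _pileup_index(sites)
    rx = pattern.regex
    seen: set[tuple[str, int, str]] = set()
    out: list[MotifOccurrence] = []
    for rec in genes:
        for feat in rec.features:
            if biotypes is not None and feat.biotype not in biotypes:
                continue
            strands = (feat.strand,) if coding_strand_only else ("+", "-")
            for strand in strands:
                coding = rec.seq[feat.start : feat.end]
                if strand == "-":
                    coding = reverse_complement(coding)
                for m in rx.finditer(coding):
                    j = m.start() + pattern.anchor
                    gpos = feat.start + j if strand == "+" else feat.end - 1 - j
                    key = (rec.id, gpos, strand)
                    if key in seen:
                        continue
                    sc = index.get((rec.id, strand, gpos))
                    if sc is None or sc.n < min_coverage:
                        continue
                    seen.add(key)
                    out.append(
                        MotifOccurrence(
                            gene_id=feat.feature_id,
                            ref_id=rec.id,
                            pos=gpos,
                            strand=strand,
                            flank=m.group(1),
                            n=sc.n,
                            k=sc.k,
                        )
                    )
    return sorted(out, key=lambda o: (o.ref_id, o.pos, o.strand))


def build_control_set(
    genes: ReferenceSet,
    sites,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    biotypes: tuple[str, ...] | None = None,
) -> list[MotifOccurrence]:
    """Covered cytosines whose coding-strand context violates the consensus at
    all three constrained offsets: a C at 0, but -2 not A, -1 not T and +1 not
    G.  By construction this background set is disjoint from any motif hit."""
    index = _pileup_index(sites)
    out: list[MotifOccurrence] = []
    seen: set[tuple[str, int, str]] = set()
    for rec in genes:
        for feat in rec.features:
            if biotypes is not None and feat.biotype not in biotypes:
                continue
            strand = feat.strand
            coding = rec.seq[feat.start : feat.end]
            if strand == "-":
                coding = reverse_complement(coding)
            for j in range(2, len(coding) - 1):
                if coding[j] != "C":
                    continue
                if coding[j - 2] == "A" or coding[j - 1] == "T" or coding[j + 1] == "G":
                    continue
                gpos = feat.start + j if strand == "+" else feat.end - 1 - j
                key = (rec.id, gpos, strand)
                if key in seen:
                    continue
                sc = index.get((rec.id, strand, gpos))
                if sc is None or sc.n < min_coverage:
                    continue
                seen.add(key)
                out.append(
                    MotifOccurrence(
                        gene_id=feat.feature_id,
                        ref_id=rec.id,
                        pos=gpos,
                        strand=strand,
                        flank=coding[j - 2 : j + 2],
                        n=sc.n,
                        k=sc.k,
                    )
                )
    return sorted(out, key=lambda o: (o.ref_id, o.pos, o.strand))


def enrichment_summary(
    occurrences: list[MotifOccurrence],
    controls: list[MotifOccurrence],
    level_cuts: tuple[float, ...] = (10.0, 20.0),
) -> pd.DataFrame:
    """Fraction of sites methylated above each level cut, motif vs control,
    with a two-sided Fisher comparison of the two fractions.

    Percentages are rounded to the nearest integer, matching how such
    fractions are conventionally reported (e.g. 31/75 -> 41%).
    """
    if not occurrences or not controls:
        raise ValueError("both the motif and the control set must be nonempty")
    rows = []
    for cut in level_cuts:
        m_above = sum(1 for o in occurrences if o.level > cut)
        c_above = sum(1 for o in controls if o.level > cut)
        p = stats.fisher_exact(
            [[m_above, len(occurrences) - m_above], [c_above, len(controls) - c_above]]
        ).pvalue
        rows.append(
            {
                "level_cut_pct": cut,
                "motif_n": len(occurrences),
                "motif_above": m_above,
                "motif_pct": round(100.0 * m_above / len(occurrences)),
                "control_n": len(controls),
                "control_above": c_above,
                "control_pct": round(100.0 * c_above / len(controls)),
                "fisher_p": float(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PositionFrequencyMatrix:
    counts: pd.DataFrame  # rows A/C/G/T, one column per position
    consensus: str
    n_sequences: int = 0

    def frequencies(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)


def build_pfm(flanks: list[str], fixed_threshold: float = 0.9) -> PositionFrequencyMatrix:
    """Position frequency matrix over equal-length flanks aligned on the
    anchor C, plus an IUPAC consensus: a fixed base at >= 90% frequency, a
    two-base degenerate symbol when the top two jointly reach 90%, else N."""
    if not flanks:
        raise ValueError("no flanking sequences given")
    L = len(flanks[0])
    if any(len(f) != L for f in flanks):
        raise ValueError("flanking sequences must have equal lengths")
    bases = "ACGT"
    counts = np.zeros((4, L), dtype=np.int64)
    for f in flanks:
        for j, ch in enumerate(f.upper().replace("U", "T")):
            if ch in bases:
                counts[bases.index(ch), j] += 1
    df = pd.DataFrame(counts, index=list(bases), columns=range(L))
    consensus = []
    for j in range(L):
        col = counts[:, j]
        tot = col.sum()
        if tot == 0:
            consensus.append("N")
            continue
        order = np.argsort(col)[::-1]
        if col[order[0]] / tot >= fixed_threshold:
            consensus.append(bases[order[0]])
        elif (col[order[0]] + col[order[1]]) / tot >= fixed_threshold:
            pair = frozenset((bases[order[0]], bases[order[1]]))
            consensus.append(_IUPAC_FOR_PAIR[pair])
        else:
            consensus.append("N")
    return PositionFrequencyMatrix(df, "".join(consensus), n_sequences=len(flanks))


def occurrences_table(occurrences: list[MotifOccurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": o.gene_id,
                "ref": o.ref_id,
                "position": o.pos + 1,
                "strand": o.strand,
                "flank": o.flank,
                "n": o.n,
                "k": o.k,
                "level_pct": o.level,
            }
            for o in occurrences
        ]
    )
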