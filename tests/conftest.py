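"""Shared fixtures: small simulated datasets reused across module tests."""

import pytest

from m5cpipe import (
    BisulfiteAligner,
    BsRead,
    ReferenceSet,
    RefRecord,
    GeneFeature,
    convert_reference,
    map_reads,
)
from m5cpipe.synthetic_data import SimConfig, simulate_bisulfite_reads, simulate_genome


def make_read(seq: str, rid: str = "r1", qual: int = 40) -> BsRead:
    return BsRead(rid, seq, [qual] * len(seq))


@pytest.fixture(scope="session")
def small_sim():
    """A 12 kb genome with four planted sites and a matching read library."""
    cfg = SimConfig(
        seed=11,
        genome_length=12_000,
        n_genes=8,
        coverage=40.0,
        planted=((0.25, True), (0.5, True), (0.9, True), (1.0, False)),
    )
    refs, truth = simulate_genome(cfg)
    reads, truth = simulate_bisulfite_reads(refs, truth, cfg)
    return cfg, refs, truth, reads


@pytest.fixture(scope="session")
def small_alignments(small_sim):
    cfg, refs, truth, reads = small_sim
    aligner = BisulfiteAligner(convert_reference(refs))
    alignments, stats = map_reads(reads, aligner, seed=3)
    return refs, truth, alignments, stats


@pytest.fixture()
def tiny_refs():
    """A 120-nt hand-checkable reference with one plus and one minus gene."""
    seq = (
        "AGATTACCGGATAGCATCGAGGTATTTACCAGTGCAAGGA"
        "TTCAGGCATCCTAGGATTACAGGATGCCTGAATCCTTGCA"
        "CTGGTAAATACCTCGATGCTATCCGGTAATCTTTTTTTTT"
    )
    feats = (
        GeneFeature("geneA", 0, 60, "+", "CDS"),
        GeneFeature("geneB", 60, 120, "-", "CDS"),
    )
    return ReferenceSet([RefRecord("chrT", seq, feats)])
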