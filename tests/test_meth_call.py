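"""Filters, pileup, exact conversion test, spacing/collapse and summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import m5cpipe.meth_call as mc
from m5cpipe import (
    GeneFeature,
    ReferenceSet,
    RefRecord,
    SiteCount,
    classify_calls,
    collapse_by_context,
    conversion_rate,
    coverage_summary,
    fisher_conversion_test,
    methylation_level,
    pileup,
    spacing_filter,
)
from m5cpipe.bs_align import BsAlignment, ConvEvent
from m5cpipe.meth_call import MethylationCall, call_sites, filter_duplicates, filter_unconverted_reads


def aln(read_id="r", seq="ACGT" * 10, start=0, events=(), strand="+", ref_id="chr1"):
    return BsAlignment(
        read_id=read_id, ref_id=ref_id, start=start, strand=strand,
        length=len(seq), n_mismatch=0, reverse=False, seq=seq,
        events=tuple(ConvEvent(*e) for e in events),
    )


# ---------------------------------------------------------------------------
# read filters
# ---------------------------------------------------------------------------

def test_duplicate_filter_keeps_one_representative_per_sequence():
    reads = [aln(read_id=f"r{i}", seq="AAAA", start=5) for i in range(5)]
    reads.append(aln(read_id="r9", seq="TTTT", start=50))
    kept = filter_duplicates(reads)
    assert len(kept) == 2
    assert {a.seq for a in kept} == {"AAAA", "TTTT"}
    # representative is first by coordinate then read id
    assert min(a.read_id for a in kept if a.seq == "AAAA") == "r0"


def test_duplicate_filter_disabled_in_transcriptome_mode():
    reads = [aln(read_id=f"r{i}", seq="AAAA") for i in range(4)]
    assert len(filter_duplicates(reads, mode="transcriptome")) == 4


def test_duplicate_filter_matches_hash_set_oracle():
    rng = np.random.default_rng(8)
    seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(66)]
    seqs = seqs + seqs[:17] + ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(17)]
    rng.shuffle(seqs)
    reads = [aln(read_id=f"r{i}", seq=s, start=i) for i, s in enumerate(seqs)]
    assert len(filter_duplicates(reads)) == len(set(seqs))


@pytest.mark.parametrize("n_unconv,kept", [(0, True), (2, True), (3, False), (5, False)])
def test_unconverted_read_filter_threshold(n_unconv, kept):
    events = [(i, i < n_unconv, 40) for i in range(6)]
    result = filter_unconverted_reads([aln(events=events)])
    assert bool(result) is kept


def test_unconverted_filter_ignores_quality_failed_bases():
    # 3 unconverted Cs but one below the quality gate: read survives
    events = [(0, True, 40), (5, True, 40), (9, True, 15)]
    assert len(filter_unconverted_reads([aln(events=events)])) == 1


def test_filters_commute_on_final_pileup():
    rng = np.random.default_rng(3)
    reads = []
    for i in range(200):
        # unique sequence per template read (base-4 encoding of the index)
        seq = "".join("ACGT"[(i >> (2 * j)) & 3] for j in range(6))
        events = [(int(p), bool(rng.random() < 0.3), 40) for p in rng.integers(0, 50, size=5)]
        reads.append(aln(read_id=f"r{i}", seq=seq, start=int(rng.integers(0, 40)), events=events))
    # PCR duplicates: identical sequence, placement and conversion states
    for i, a in enumerate(reads[:40]):
        reads.append(
            aln(read_id=f"d{i}", seq=a.seq, start=a.start,
                events=[(e.pos, e.unconverted, e.qual) for e in a.events])
        )
    a = pileup(filter_unconverted_reads(filter_duplicates(reads)))
    b = pileup(filter_duplicates(filter_unconverted_reads(reads)))
    assert a == b


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def test_pileup_counts_match_worked_example():
    # 10 reads over one C, 7 retained, all Q40 -> n=10, k=7
    reads = [
        aln(read_id=f"r{i}", events=[(100, i < 7, 40)]) for i in range(10)
    ]
    (site,) = pileup(reads)
    assert (site.n, site.k) == (10, 7)
    assert methylation_level(site.k, site.n) == 70.0

    # 3 of the unconverted bases at Q15 -> n=7, k=4
    reads_q = [
        aln(read_id=f"r{i}", events=[(100, i < 7, 15 if i < 3 else 40)]) for i in range(10)
    ]
    (site_q,) = pileup(reads_q)
    assert (site_q.n, site_q.k) == (7, 4)


def test_pileup_equals_columnwise_oracle():
    rng = np.random.default_rng(12)
    reads = []
    for i in range(300):
        events = [
            (int(p), bool(rng.random() < 0.2), int(rng.choice([15, 40])))
            for p in rng.choice(80, size=4, replace=False)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(aln(read_id=f"r{i}", events=events, strand=strand))
    sites = pileup(reads)
    # brute-force recount per column
    oracle = {}
    for a in reads:
        for ev in a.events:
            if ev.qual > 20:
                n, k = oracle.get((a.strand, ev.pos), (0, 0))
                oracle[(a.strand, ev.pos)] = (n + 1, k + ev.unconverted)
    assert {(s.strand, s.pos): (s.n, s.k) for s in sites} == oracle
    assert all(s.n >= 1 for s in sites)


# ---------------------------------------------------------------------------
# level and exact test
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "k,n,expected",
    [(17, 30, 56.7), (179, 500, 35.8), (12, 13, 92.3), (7, 10, 70.0), (0, 50, 0.0)],
)
def test_methylation_level_worked_examples(k, n, expected):
    assert methylation_level(k, n) == expected


def test_methylation_level_rejects_empty_or_invalid():
    with pytest.raises(ValueError):
        methylation_level(0, 0)
    with pytest.raises(ValueError):
        methylation_level(5, 3)


def _fisher_oracle(k, n):
    """Independent enumeration: hypergeometric two-sided by minimum likelihood."""
    N, K, draws = 2 * n, k, n
    def pmf(x):
        return math.comb(K, x) * math.comb(N - K, draws - x) / math.comb(N, draws)
    obs = pmf(k)
    lo = max(0, K - (N - draws))
    return sum(pmf(x) for x in range(lo, min(K, draws) + 1) if pmf(x) <= obs * (1 + 1e-9))


@pytest.mark.parametrize(
    "k,n,printed",
    [(7, 10, 0.003096), (17, 30, 6.19e-07), (31, 65, 8.06e-12), (12, 13, 2.69e-06)],
)
def test_fisher_conversion_test_reproduces_printed_p_values(k, n, printed):
    p = fisher_conversion_test(k, n)
    assert p == pytest.approx(printed, rel=5e-3)
    assert p == pytest.approx(_fisher_oracle(k, n), rel=1e-9)


def test_fisher_null_table_gives_one():
    for n in (1, 5, 50):
        assert fisher_conversion_test(0, n) == 1.0


def test_fisher_one_sided_variant_available():
    two = fisher_conversion_test(7, 10)
    one = fisher_conversion_test(7, 10, alternative="greater")
    assert 0 < one <= two


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=60), st.data())
def test_fisher_matches_enumeration_and_decreases_in_k(n, data):
    k = data.draw(st.integers(min_value=1, max_value=n))
    p = fisher_conversion_test(k, n)
    assert p == pytest.approx(_fisher_oracle(k, n), rel=1e-9)
    assert 0 < p <= 1
    if k > 1:
        assert p < fisher_conversion_test(k - 1, n)


# ---------------------------------------------------------------------------
# spacing, collapse, classify
# ---------------------------------------------------------------------------

def _call(pos, k=8, n=10, ref="chr1", strand="+", context=""):
    return MethylationCall(
        site=SiteCount(ref, pos, strand, n, k),
        level=methylation_level(k, n),
        p=fisher_conversion_test(k, n),
        context=context or f"ctx{pos}",
    )


def test_spacing_filter_removes_both_members_of_close_pairs():
    close = spacing_filter([_call(100), _call(105)])
    assert close == []
    apart = spacing_filter([_call(100), _call(111)])
    assert len(apart) == 2  # distance 11: boundary retained
    boundary = spacing_filter([_call(100), _call(110)])
    assert boundary == []  # distance 10: removed


def test_spacing_filter_matches_all_pairs_oracle():
    rng = np.random.default_rng(23)
    for _ in range(20):
        positions = sorted(set(rng.integers(0, 400, size=30).tolist()))
        calls = [_call(p) for p in positions]
        got = {c.site.pos for c in spacing_filter(calls)}
        oracle = {
            p for p in positions
            if not any(q != p and abs(q - p) <= 10 for q in positions)
        }
        assert got == oracle


def test_collapse_merges_identical_contexts_and_sums_counts():
    # two gene copies each k=26/n=28 with the same 31-nt context -> 52/56
    ctx = "A" * 15 + "C" + "G" * 15
    c1 = _call(100, k=26, n=28, context=ctx)
    c2 = _call(5000, k=26, n=28, context=ctx)
    other = _call(900, k=5, n=9)
    out = collapse_by_context([c1, c2, other])
    assert len(out) == 2
    merged = next(c for c in out if c.context == ctx)
    assert (merged.site.k, merged.site.n) == (52, 56)
    assert merged.level == methylation_level(52, 56)
    assert merged.p == fisher_conversion_test(52, 56)
    assert len(merged.members) == 2


def test_collapse_with_unique_contexts_is_identity_on_counts():
    calls = [_call(p) for p in (10, 50, 90)]
    out = collapse_by_context(calls)
    assert [(c.site.pos, c.site.n, c.site.k) for c in out] == [
        (10, 10, 8), (50, 10, 8), (90, 10, 8)
    ]


def test_collapse_conserves_total_reads():
    rng = np.random.default_rng(44)
    contexts = ["CTX%d" % i for i in range(5)]
    calls = [
        _call(int(p), k=int(rng.integers(0, 9)), n=10,
              context=contexts[int(rng.integers(0, 5))])
        for p in rng.choice(10_000, size=40, replace=False)
    ]
    out = collapse_by_context(calls)
    assert sum(c.site.n for c in out) == sum(c.site.n for c in calls)
    assert sum(c.site.k for c in out) == sum(c.site.k for c in calls)


@pytest.mark.parametrize(
    "k,n,expected",
    [
        (17, 30, ">=50%"),     # 56.7%
        (179, 500, "20-50%"),  # 35.8%
        (5, 10, ">=50%"),      # exactly 50: inclusive upward
        (3, 20, "10-20%"),     # 15%
        (2, 20, "10-20%"),     # exactly 10
        (1, 20, "<10%"),       # 5%
    ],
)
def test_classification_bands(k, n, expected):
    (call,) = classify_calls([_call(1, k=k, n=n)])
    assert call.classification == expected


def test_call_sites_extracts_centered_context(tiny_refs):
    seq = tiny_refs.seq("chrT")
    pos = 40
    assert seq[pos] in "ACGT"
    sites = [SiteCount("chrT", pos, "+", 10, 5)]
    (call,) = call_sites(sites, tiny_refs)
    assert len(call.context) == 31
    assert call.context[15] == seq[pos]
    assert not call.truncated
    # near the edge the context is shorter and flagged
    (edge,) = call_sites([SiteCount("chrT", 3, "+", 10, 5)], tiny_refs)
    assert edge.truncated and len(edge.context) < 31


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_conversion_rate_trivial_extremes():
    all_conv = [aln(events=[(i, False, 40) for i in range(5)])]
    all_kept = [aln(events=[(i, True, 40) for i in range(5)])]
    assert conversion_rate(all_conv) == 100.0
    assert conversion_rate(all_kept) == 0.0
    assert conversion_rate([aln(events=[])]) is None


def test_conversion_rate_matches_simulator_probability():
    # no planted sites, no failure molecules: the observed global conversion
    # rate is the per-C binomial probability (98.5% within sampling error)
    from m5cpipe import BisulfiteAligner, convert_reference, map_reads
    from m5cpipe.synthetic_data import SimConfig, simulate_bisulfite_reads, simulate_genome

    cfg = SimConfig(seed=29, genome_length=10_000, n_genes=6, coverage=25.0,
                    failure_fraction=0.0)
    refs, truth = simulate_genome(cfg)
    reads, _ = simulate_bisulfite_reads(refs, truth, cfg)
    alignments, _ = map_reads(reads, BisulfiteAligner(convert_reference(refs)), seed=1)
    assert conversion_rate(alignments) == pytest.approx(98.5, abs=0.2)


def test_coverage_summary_boundary_and_oracle():
    refs = ReferenceSet(
        [RefRecord("chr1", "A" * 400, (GeneFeature("g1", 0, 100, "+", "CDS"),
                                       GeneFeature("g2", 200, 300, "+", "CDS")))]
    )
    # ten 50-nt reads inside g1 -> mean coverage exactly 5.0: NOT counted (>5 strict)
    reads = [aln(read_id=f"r{i}", seq="A" * 50, start=0) for i in range(5)]
    reads += [aln(read_id=f"s{i}", seq="A" * 50, start=50) for i in range(5)]
    # six full-length reads on g2 -> mean 6.0: counted
    reads += [aln(read_id=f"t{i}", seq="A" * 100, start=200) for i in range(6)]
    summary = coverage_summary(reads, refs)
    assert summary.gene_mean_coverage["g1"] == 5.0
    assert summary.gene_mean_coverage["g2"] == 6.0
    assert summary.n_genes_covered == 1
    assert summary.pct_genes_covered == 50.0


def test_spike_qc_methylated_and_unmethylated_templates():
    from m5cpipe import spike_qc
    from m5cpipe.synthetic_data import SimConfig, simulate_spikes

    # unmethylated spikes: motif-C non-conversion tracks 1 - conversion_prob
    cfg = SimConfig(seed=51, conversion_prob=0.97, coverage=25.0,
                    failure_fraction=0.0, error_rate=0.0)
    spikes, reads, _, anchors = simulate_spikes(cfg, n_reads_per_spike=4000)
    reports = spike_qc(reads, spikes, anchors=anchors, seed=2)
    for rep in reports:
        stats = rep.motif_c[anchors[rep.spike_id]]
        assert stats["n"] > 300
        assert stats["pct"] == pytest.approx(3.0, abs=1.0)
        assert rep.overall_nonconversion_pct == pytest.approx(3.0, abs=0.5)

    # a fully methylated site on a template: ~100% non-conversion there.
    # build it by planting a full-stoichiometry site at the spike anchor
    from m5cpipe.synthetic_data import TruthTable, PlantedSite, simulate_bisulfite_reads

    sid = "spike1"
    truth = TruthTable(sites=[PlantedSite(sid, anchors[sid], "+", 1.0, True, f"{sid}_t")])
    reads_m, _ = simulate_bisulfite_reads(spikes, truth, cfg)
    reads_m = [r for r in reads_m]
    (rep1,) = [r for r in spike_qc(reads_m, spikes, anchors=anchors, seed=2)
               if r.spike_id == sid]
    assert rep1.motif_c[anchors[sid]]["pct"] == pytest.approx(100.0, abs=0.5)


def test_spike_reads_align_to_spike_reference_only(small_sim):
    # spike reads are quantified against their own synthetic reference and are
    # never attributed to genomic sites: genomic reads do not map to spikes
    from m5cpipe import BisulfiteAligner, convert_reference, map_reads
    from m5cpipe.synthetic_data import SimConfig, simulate_spikes

    cfg, refs, truth, genomic_reads = small_sim
    spike_cfg = SimConfig(seed=53, coverage=10.0)
    spikes, _, _, _ = simulate_spikes(spike_cfg)
    aligner = BisulfiteAligner(convert_reference(spikes, "transcriptome"))
    alignments, stats = map_reads(genomic_reads[:2000], aligner, seed=1)
    assert stats.mapped / stats.total < 0.01


def test_coverage_summary_means_match_per_base_oracle():
    rng = np.random.default_rng(77)
    feats = tuple(
        GeneFeature(f"g{i}", int(s), int(s) + 80, "+", "CDS")
        for i, s in enumerate(range(0, 800, 100))
    )
    refs = ReferenceSet([RefRecord("chr1", "A" * 1000, feats)])
    reads = [
        aln(read_id=f"r{i}", seq="A" * 40, start=int(rng.integers(0, 960)))
        for i in range(200)
    ]
    summary = coverage_summary(reads, refs)
    depth = np.zeros(1000)
    for a in reads:
        depth[a.start : a.end] += 1
    for f in feats:
        assert summary.gene_mean_coverage[f.feature_id] == pytest.approx(
            depth[f.start : f.end].mean()
        )
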