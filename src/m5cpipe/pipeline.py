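"""End-to-end orchestration: configuration, stage flow, reports, audit log.

The stage flow mirrors the analysis design: reference conversion ->
bisulfite alignment (with iterative trimming and seeded multi-mapper
assignment) -> artifact filters -> per-cytosine pileup -> exact conversion
test -> spacing filter -> context collapsing -> classification, optionally
followed by motif enrichment.  Two presets cover the two experimental
designs: ``structural-rna`` (transcriptome mode, duplicate filter off) for
tRNA/rRNA work and ``mrna`` (genome mode, duplicate filter on).

Every filter's removal count is logged in the run ledger — the only audit
trail for reads that silently disappear between input and calls — and the
ledger is checked to account for every input read exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bs_align, meth_call, motif_analysis
from .reference_prep import GENOME, MODES, ReferenceSet, convert_reference

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mode: str = GENOME
    # alignment
    seed_k: int = 12
    max_mismatches: int = 2
    min_read_length: int = 35
    trim_step: int = 2
    # filters and calling
    dedup: bool | None = None  # None -> on in genome mode, off in transcriptome
    unconverted_cutoff: int = 3
    min_quality: int = 20
    spacing: int = 10
    context_window: int = 31
    alpha: float = 0.01
    bands: tuple[float, float, float] = (10.0, 20.0, 50.0)
    # motif
    motif_pattern: str = motif_analysis.DEFAULT_PATTERN
    motif_min_coverage: int = 5
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        for name in ("unconverted_cutoff", "min_quality", "spacing", "context_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.bands = tuple(self.bands)

    @property
    def dedup_enabled(self) -> bool:
        return self.mode == GENOME if self.dedup is None else self.dedup

    def alignment_params(self) -> bs_align.AlignmentParams:
        return bs_align.AlignmentParams(
            seed_k=self.seed_k,
            max_mismatches=self.max_mismatches,
            min_length=self.min_read_length,
            trim_step=self.trim_step,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "bands" in data and data["bands"] is not None:
            data["bands"] = tuple(data["bands"])
        return cls(**data)


PRESETS = {
    # transcriptome mode against unique mature tRNA/rRNA sequences; identical
    # reads are genuine coverage there, so the duplicate filter is off
    "structural-rna": PipelineConfig(mode="transcriptome", dedup=False),
    # genome mode for mRNA work, duplicate filter on
    "mrna": PipelineConfig(mode=GENOME, dedup=True),
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    config: PipelineConfig
    calls: list = field(default_factory=list)  # final classified MethylationCalls
    raw_alignments_n: int = 0
    conversion_rate: float | None = None
    library_summary: meth_call.LibrarySummary | None = None
    motif_table: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    ledger: dict = field(default_factory=dict)

    def check_ledger(self) -> None:
        lg = self.ledger
        if lg["mapped"] + lg["unmapped"] != lg["input_reads"]:
            raise AssertionError("read ledger does not sum: mapping")
        kept = lg["mapped"] - lg["duplicates_removed"] - lg["unconverted_removed"]
        if kept != lg["reads_counted"]:
            raise AssertionError("read ledger does not sum: filters")


def run_pipeline(
    refs: ReferenceSet,
    reads,
    cfg: PipelineConfig,
    run_motif: bool = True,
) -> RunReport:
    """Execute the full calling pipeline on in-memory inputs."""
    report = RunReport(config=cfg)
    ledger = report.ledger
    try:
        conv = convert_reference(refs, mode=cfg.mode)
    except Exception as exc:
        raise PipelineError("reference_prep", str(exc)) from exc

    reads = list(reads)
    if not reads:
        raise PipelineError("alignment", "no input reads")
    try:
        aligner = bs_align.BisulfiteAligner(conv, cfg.alignment_params())
        alignments, mstats = bs_align.map_reads(reads, aligner, seed=cfg.seed)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("alignment", str(exc)) from exc
    ledger.update(
        input_reads=mstats.total, mapped=mstats.mapped, unmapped=mstats.unmapped,
        multimapped=mstats.multimapped, trimmed=mstats.trimmed,
    )
    logger.info("mapped %d/%d reads (%d multi-mapped, %d after trimming)",
                mstats.mapped, mstats.total, mstats.multimapped, mstats.trimmed)

    report.raw_alignments_n = len(alignments)
    # conversion rate comes from the raw data, before any filtering
    report.conversion_rate = meth_call.conversion_rate(alignments)

    if cfg.dedup_enabled:
        deduped = meth_call.filter_duplicates(alignments, mode=cfg.mode)
    else:
        deduped = alignments
    ledger["duplicates_removed"] = len(alignments) - len(deduped)

    filtered = meth_call.filter_unconverted_reads(
        deduped, cfg.unconverted_cutoff, cfg.min_quality
    )
    ledger["unconverted_removed"] = len(deduped) - len(filtered)
    ledger["reads_counted"] = len(filtered)

    sites = meth_call.pileup(filtered, min_quality=cfg.min_quality)
    ledger["sites_covered"] = len(sites)
    calls = meth_call.call_sites(sites, refs, window=cfg.context_window)
    sig = meth_call.significant_calls(calls, cfg.alpha)
    ledger["significant_sites"] = len(sig)
    spaced = meth_call.spacing_filter(sig, cfg.spacing)
    ledger["after_spacing"] = len(spaced)
    collapsed = meth_call.collapse_by_context(spaced)
    ledger["after_collapse"] = len(collapsed)
    report.calls = meth_call.classify_calls(collapsed, cfg.bands)

    report.library_summary = meth_call.coverage_summary(alignments, refs)

    if run_motif:
        try:
            pattern = motif_analysis.MotifPattern(cfg.motif_pattern)
            occurrences = motif_analysis.scan_motif(
                refs, sites, pattern, cfg.motif_min_coverage
            )
            report.motif_table = motif_analysis.occurrences_table(occurrences)
            controls = motif_analysis.build_control_set(refs, sites, cfg.motif_min_coverage)
            if occurrences and controls:
                report.enrichment = motif_analysis.enrichment_summary(occurrences, controls)
        except Exception as exc:
            raise PipelineError("motif", str(exc)) from exc

    ledger["seed"] = cfg.seed
    report.check_ledger()
    return report


def run_pipeline_files(
    fasta, fastq, cfg: PipelineConfig, outdir, gff=None, run_motif: bool = True
) -> RunReport:
    """File-based wrapper: read inputs, run, write the report bundle.

    Any stage failure removes partial outputs before re-raising.
    """
    from .reference_prep import read_fasta, read_gff3
    from .synthetic_data import read_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        features = read_gff3(gff) if gff else None
        refs = read_fasta(fasta, features)
        reads = read_fastq(fastq)
        report = run_pipeline(refs, reads, cfg, run_motif=run_motif)
        calls_tsv = outdir / "calls.tsv"
        written.append(calls_tsv)
        calls_table(report.calls, refs).to_csv(calls_tsv, sep="\t", index=False)
        bed = outdir / "calls.bed"
        written.append(bed)
        write_calls_bed(report.calls, bed)
        summary_tsv = outdir / "summary.tsv"
        written.append(summary_tsv)
        summary_table(report).to_csv(summary_tsv, sep="\t", index=False)
        if report.motif_table is not None:
            motif_tsv = outdir / "motif.tsv"
            written.append(motif_tsv)
            report.motif_table.to_csv(motif_tsv, sep="\t", index=False)
        log_path = outdir / "run_log.yaml"
        written.append(log_path)
        with open(log_path, "w") as fh:
            yaml.safe_dump(report.ledger, fh, sort_keys=False)
        return report
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _sig3(p: float) -> str:
    return f"{p:.3g}"


def _locus(call, refs: ReferenceSet | None) -> str:
    if refs is not None and call.site.ref_id in refs:
        for feat in refs.get(call.site.ref_id).features:
            if feat.start <= call.site.pos < feat.end and feat.strand == call.site.strand:
                return feat.feature_id
    return call.site.ref_id


def calls_table(calls, refs: ReferenceSet | None = None) -> pd.DataFrame:
    rows = [
        {
            "locus": _locus(c, refs),
            "ref": c.site.ref_id,
            "position": c.position_1based,
            "strand": c.site.strand,
            "p_value": _sig3(c.p),
            "n": c.site.n,
            "k": c.site.k,
            "level_pct": c.level,
            "class": c.classification or "",
            "group": c.group_id or "",
            "n_collapsed": len(c.members),
        }
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=["locus", "ref", "position", "strand", "p_value", "n", "k",
                 "level_pct", "class", "group", "n_collapsed"],
    )
    return df.sort_values("level_pct", ascending=False, ignore_index=True) if rows else df


def report_table3_style(
    calls, replicate_calls=None, refs: ReferenceSet | None = None
) -> pd.DataFrame:
    """Worked-example call report: one row per site, sorted by level
    descending, with optional second-replicate counts ('NA' when absent)."""
    rep_index = {}
    if replicate_calls:
        rep_index = {
            (c.site.ref_id, c.site.pos, c.site.strand): c for c in replicate_calls
        }
    rows = []
    for c in calls:
        rep = rep_index.get((c.site.ref_id, c.site.pos, c.site.strand))
        rows.append(
            {
                "locus": _locus(c, refs),
                "position": c.position_1based,
                "strand": c.site.strand,
                "p_value": _sig3(c.p),
                "n_rep1": c.site.n,
                "k_rep1": c.site.k,
                "level_rep1_pct": c.level,
                "n_rep2": rep.site.n if rep else "NA",
                "k_rep2": rep.site.k if rep else "NA",
                "level_rep2_pct": rep.level if rep else "NA",
                "description": c.classification or "",
            }
        )
    cols = ["locus", "position", "strand", "p_value", "n_rep1", "k_rep1",
            "level_rep1_pct", "n_rep2", "k_rep2", "level_rep2_pct", "description"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("level_rep1_pct", ascending=False, ignore_index=True) if rows else df


def write_calls_bed(calls, path) -> None:
    """BED6 with the methylation level in the score field."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.site.ref_id}\t{c.site.pos}\t{c.site.pos + 1}\t"
                f"{c.group_id or 'site'}\t{c.level:g}\t{c.site.strand}\n"
            )


def summary_table(report: RunReport) -> pd.DataFrame:
    ls = report.library_summary
    row = {
        "reads_input": report.ledger.get("input_reads"),
        "reads_mapped": report.ledger.get("mapped"),
        "pct_cytosines_converted": (
            round(report.conversion_rate, 1) if report.conversion_rate is not None else None
        ),
        "n_genes": ls.n_genes if ls else None,
        "n_genes_mean_cov_gt5": ls.n_genes_covered if ls else None,
        "pct_genes_covered": ls.pct_genes_covered if ls else None,
        "n_calls": len(report.calls),
    }
    return pd.DataFrame([row])
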