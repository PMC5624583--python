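"""Table I/O, read trimming, contig filtering, QC checks and the pipeline.

Tables travel as UTF-8, tab-separated files with a header row and '.'
decimals.  Sequence formats go through Bio.SeqIO (4-line FASTQ, plain
FASTA).  The read trimmer applies the fixed positional cleaning rules of
the sequencing protocol — remove the first ``head_trim`` bases, cap at
``max_length``, then drop reads shorter than ``min_length`` — and the
contig filter keeps assembly contigs of at least a minimum length.
``run_pipeline`` ties the qPCR-normalization and differential-expression
stages together from a configuration mapping and writes a reproducible run
log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from . import deg as deg_mod
from . import profiles as profiles_mod
from .qpcr import (
    NormalizationFactors,
    apply_normalization,
    divergence_summary,
    normalization_factors,
    validate_quantity_table,
)

logger = logging.getLogger("embex")

TSV_KWARGS = dict(sep="\t", encoding="utf-8")


# ---------------------------------------------------------------------------
# TSV readers / writers

def read_quantity_table(path) -> pd.DataFrame:
    """Read and validate a quantity table TSV."""
    table = pd.read_csv(path, **TSV_KWARGS)
    return validate_quantity_table(table)


def write_quantity_table(table: pd.DataFrame, path) -> None:
    validate_quantity_table(table)
    table.to_csv(path, index=False, **TSV_KWARGS)


def read_counts(path) -> pd.DataFrame:
    """Genes × samples integer count matrix; first column is the gene id."""
    counts = pd.read_csv(path, index_col=0, **TSV_KWARGS)
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, index_label="gene", **TSV_KWARGS)


def read_annotation(path) -> pd.Series:
    """Gene length annotation TSV with columns ``gene, length``."""
    ann = pd.read_csv(path, **TSV_KWARGS)
    for col in ("gene", "length"):
        if col not in ann.columns:
            raise ValueError(f"annotation missing column: {col!r}")
    lengths = ann.set_index("gene")["length"]
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    return lengths


def write_annotation(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_csv(path, index_label="gene", **TSV_KWARGS)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, **TSV_KWARGS)
    missing = [c for c in deg_mod.SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False, **TSV_KWARGS)


def write_factors(factors: NormalizationFactors, path) -> None:
    """Write factors plus per-reference fractional diagnostics."""
    out = factors.fractions.copy()
    out.insert(0, "series", factors.series)
    out["factor"] = factors.factors
    out.to_csv(path, index_label="sample_id", **TSV_KWARGS)


# ---------------------------------------------------------------------------
# Read trimming and sequence filters

@dataclass(frozen=True)
class TrimPolicy:
    """Positional read-cleaning rules.

    ``head_trim`` bases are removed from the 5' end, the remainder is capped
    at ``max_length`` bases, and reads left shorter than ``min_length`` are
    dropped.  The cap is batch-dependent in the original protocol (205 bases
    for one sequencing batch, 170 for the other).
    """

    min_length: int = 20
    head_trim: int = 15
    max_length: int = 205

    def __post_init__(self):
        if self.min_length < 1:
            raise ValueError(f"min_length must be >= 1, got {self.min_length}")
        if self.head_trim < 0:
            raise ValueError(f"head_trim must be >= 0, got {self.head_trim}")
        if self.max_length <= self.min_length:
            raise ValueError(
                f"max_length ({self.max_length}) must exceed "
                f"min_length ({self.min_length})"
            )


@dataclass(frozen=True)
class GdnaCheck:
    """Genomic-DNA contamination check on an RNA preparation.

    Passes when the measured genome copies per 10 ng RNA fall strictly
    below the threshold (default 5).
    """

    genomes_per_10ng: float
    threshold: float = 5.0

    @property
    def passed(self) -> bool:
        return self.genomes_per_10ng < self.threshold


def gdna_check(genomes_per_10ng: float, threshold: float = 5.0) -> GdnaCheck:
    """Strict-inequality gDNA check; negative measurements are an error."""
    if genomes_per_10ng < 0:
        raise ValueError(f"genome count must be >= 0, got {genomes_per_10ng}")
    return GdnaCheck(genomes_per_10ng=genomes_per_10ng, threshold=threshold)


def trim_reads(
    records: Iterable[SeqRecord], policy: TrimPolicy = TrimPolicy()
) -> Iterator[SeqRecord]:
    """Apply head-trim → length-cap → minimum-length drop to FASTQ records.

    Quality strings are sliced together with the sequence; a record whose
    quality and sequence lengths disagree is malformed and reported with
    its position in the stream.
    """
    for i, rec in enumerate(records):
        qual = rec.letter_annotations.get("phred_quality")
        if qual is not None and len(qual) != len(rec.seq):
            raise ValueError(
                f"malformed FASTQ record at index {i} ({rec.id}): "
                f"sequence length {len(rec.seq)} != quality length {len(qual)}"
            )
        trimmed = rec[policy.head_trim : policy.head_trim + policy.max_length]
        if len(trimmed.seq) >= policy.min_length:
            yield trimmed


def filter_contigs(
    records: Iterable[SeqRecord], min_length: int = 500
) -> Iterator[SeqRecord]:
    """Keep FASTA records of at least ``min_length`` bases, order preserved."""
    if min_length < 0:
        raise ValueError(f"min_length must be >= 0, got {min_length}")
    for rec in records:
        if len(rec.seq) >= min_length:
            yield rec


def trim_fastq_file(in_path, out_path, policy: TrimPolicy = TrimPolicy()) -> int:
    """Trim a FASTQ file on disk; returns the number of reads written."""
    n = SeqIO.write(trim_reads(SeqIO.parse(in_path, "fastq"), policy),
                    out_path, "fastq")
    return n


def filter_fasta_file(in_path, out_path, min_length: int = 500) -> int:
    """Length-filter a FASTA file on disk; returns records written."""
    return SeqIO.write(
        filter_contigs(SeqIO.parse(in_path, "fasta"), min_length),
        out_path, "fasta",
    )


# ---------------------------------------------------------------------------
# Pipeline

class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending field."""


def _require(config: dict, stage: str, key: str):
    if key not in config:
        raise PipelineError(f"stage {stage!r}: missing config field {key!r}")
    return config[key]


def run_pipeline(config: dict, outdir) -> dict[str, str]:
    """Run the configured stages and write artifacts plus a run log.

    ``config`` holds optional ``qpcr`` and ``deg`` sections.  The qPCR
    stage reads a quantity table, computes and applies normalization
    factors, writes factors, the normalized table, a divergence report and
    per-gene association calls.  The deg stage reads counts, annotation and
    a sample sheet, then writes per-day test records, the filtered DEG
    table and the count/average-RPKM summary.  Returns a map of artifact
    names to paths; the run log records inputs, thresholds and versions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    log: dict = {"stages": {}}

    if "qpcr" in config:
        stage = config["qpcr"]
        table = read_quantity_table(_require(stage, "qpcr", "quantities"))
        try:
            factors = normalization_factors(
                table, method=stage.get("method", "arithmetic")
            )
            normalized = apply_normalization(table, factors)
        except Exception as exc:
            raise PipelineError(f"stage 'qpcr': {exc}") from exc
        div = divergence_summary(factors)
        write_factors(factors, outdir / "normalization_factors.tsv")
        write_quantity_table(normalized, outdir / "normalized_quantities.tsv")
        profs = profiles_mod.build_profiles(normalized)
        calls = profiles_mod.classify_all(
            profs,
            threshold=stage.get("threshold", 1.0),
            pseudocount=stage.get("pseudocount", 1.0),
        )
        calls.to_csv(outdir / "association_calls.tsv", index=False, **TSV_KWARGS)
        artifacts.update(
            factors=str(outdir / "normalization_factors.tsv"),
            normalized_quantities=str(outdir / "normalized_quantities.tsv"),
            association_calls=str(outdir / "association_calls.tsv"),
        )
        log["stages"]["qpcr"] = {
            "input": str(stage["quantities"]),
            "divergence_min_percent": div.min_percent,
            "divergence_max_percent": div.max_percent,
            "divergence_half_range_percent": div.half_range_percent,
        }

    if "deg" in config:
        stage = config["deg"]
        counts = read_counts(_require(stage, "deg", "counts"))
        lengths = read_annotation(_require(stage, "deg", "annotation"))
        sheet = read_sample_sheet(_require(stage, "deg", "samples"))
        p_threshold = stage.get("p_threshold", 0.05)
        fold_threshold = stage.get("fold_threshold", 2.0)
        use_fdr = not stage.get("use_raw_p", False)
        try:
            records = deg_mod.deg_test(counts, sheet, lengths)
        except Exception as exc:
            raise PipelineError(f"stage 'deg': {exc}") from exc
        filtered = deg_mod.deg_filter(
            records, p_threshold=p_threshold,
            fold_threshold=fold_threshold, use_fdr=use_fdr,
        )
        summary = deg_mod.deg_summary(filtered)
        records.to_csv(outdir / "deg_records.tsv", index=False, **TSV_KWARGS)
        filtered.to_csv(outdir / "deg_filtered.tsv", index=False, **TSV_KWARGS)
        summary.to_csv(outdir / "deg_summary.tsv", index=False, **TSV_KWARGS)
        artifacts.update(
            deg_records=str(outdir / "deg_records.tsv"),
            deg_filtered=str(outdir / "deg_filtered.tsv"),
            deg_summary=str(outdir / "deg_summary.tsv"),
        )
        log["stages"]["deg"] = {
            "counts": str(stage["counts"]),
            "p_threshold": p_threshold,
            "fold_threshold": fold_threshold,
            "use_fdr": use_fdr,
            "n_deg": int(len(filtered)),
        }

    if not log["stages"]:
        raise PipelineError("config names no stages (expected 'qpcr' and/or 'deg')")

    import embex

    log["versions"] = {"embex": embex.__version__, "pandas": pd.__version__}
    if "seed" in config:
        log["seed"] = config["seed"]
    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    artifacts["run_log"] = str(outdir / "run_log.json")
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return artifacts
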