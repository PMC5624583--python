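"""Synthetic qPCR quantity tables, RNA-seq count matrices and FASTQ reads.

Every downstream stage of the pipeline is verifiable by parameter recovery:
the generators here emit data with known ground truth shaped like the study
design — four explant series (G6 responsive, G6NR its nonresponsive clone,
G2 and G12 nonresponsive genotypes) followed over an induction time course.

The qPCR generator plants a per-sample multiplicative technical scale (the
sample-prep variance that normalization removes), flat reference genes, and
target genes with flat, late-induced (dehydrin-like: rising monotonically to
the final day) or early-transient (peaking at day 3, gone by day 15)
profiles, under multiplicative log-normal measurement error.  The RNA-seq
generator draws negative-binomial counts with a chosen fraction of truly
differentially expressed genes at known fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .qpcr import ROLE_REFERENCE, ROLE_TARGET

PROFILE_SHAPES = ("flat", "late_induced", "early_transient")
ASSOCIATIONS = ("none", "responsiveness", "genotype")


@dataclass(frozen=True)
class TargetProfile:
    """True expression shape of one target gene.

    ``baseline`` is the reference quantity level in molecules per 10 ng RNA;
    ``peak_fold`` scales the induced part of the shape.  ``association``
    plants a series-level difference: ``responsiveness`` multiplies the G6
    (responsive) series by ``assoc_fold``; ``genotype`` multiplies both G6
    clones (G6 and G6NR) by it.
    """

    shape: str = "flat"
    baseline: float = 100.0
    peak_fold: float = 10.0
    association: str = "none"
    assoc_fold: float = 1.0

    def __post_init__(self):
        if self.shape not in PROFILE_SHAPES:
            raise ValueError(f"shape must be one of {PROFILE_SHAPES}: {self.shape!r}")
        if self.baseline <= 0:
            raise ValueError(f"baseline must be > 0, got {self.baseline}")
        if self.peak_fold < 1:
            raise ValueError(f"peak_fold must be >= 1, got {self.peak_fold}")
        if self.association not in ASSOCIATIONS:
            raise ValueError(
                f"association must be one of {ASSOCIATIONS}: {self.association!r}"
            )
        if self.assoc_fold <= 0:
            raise ValueError(f"assoc_fold must be > 0, got {self.assoc_fold}")


def _default_targets() -> dict[str, TargetProfile]:
    return {
        "PCNA_like": TargetProfile(shape="flat", baseline=500.0),
        "DHN1_like": TargetProfile(
            shape="late_induced",
            baseline=100.0,
            peak_fold=18.0,
            association="responsiveness",
            assoc_fold=4.0,
        ),
        # the transcript this emulates is ~50-90x higher in responsive explants
        "C9846_like": TargetProfile(
            shape="early_transient",
            baseline=355.0,
            peak_fold=1.0,
            association="responsiveness",
            assoc_fold=50.0,
        ),
    }


@dataclass
class QpcrSimConfig:
    """Configuration of the synthetic absolute-qPCR experiment.

    Defaults follow the study design: four explant series sampled at five
    induction time points (one sample per series × day, twenty samples),
    two stable reference genes, ±25% multiplicative measurement error, and
    a log-normal technical scale whose sigma of 0.16 makes twenty sampled
    factors typically span roughly 0.67–1.35.
    """

    series_labels: tuple[str, ...] = ("G6", "G6NR", "G2", "G12")
    days: tuple[float, ...] = (0, 3, 7, 15, 21)
    n_reference_genes: int = 2
    target_profiles: Mapping[str, TargetProfile] = field(
        default_factory=_default_targets
    )
    reference_baselines: tuple[float, ...] | None = None
    tech_scale_sigma: float = 0.16
    measurement_cv: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if len(self.series_labels) == 0:
            raise ValueError("series_labels must be non-empty")
        days = np.asarray(self.days, dtype=float)
        if len(days) < 2 or not np.all(np.diff(days) > 0):
            raise ValueError(f"days must be strictly increasing, got {self.days}")
        if self.n_reference_genes < 1:
            raise ValueError(
                f"n_reference_genes must be >= 1, got {self.n_reference_genes}"
            )
        if self.tech_scale_sigma < 0:
            raise ValueError(
                f"tech_scale_sigma must be >= 0, got {self.tech_scale_sigma}"
            )
        if self.measurement_cv < 0:
            raise ValueError(
                f"measurement_cv must be >= 0, got {self.measurement_cv}"
            )
        if self.reference_baselines is not None and (
            len(self.reference_baselines) != self.n_reference_genes
            or any(b <= 0 for b in self.reference_baselines)
        ):
            raise ValueError(
                "reference_baselines must give one positive level per reference gene"
            )


@dataclass
class RnaseqSimConfig:
    """Configuration of the synthetic RNA-seq count experiment.

    Defaults follow the sequencing design: two phenotypes × four collection
    days (3, 7, 15, 21) × three biological replicates = 24 libraries, NB
    dispersion 0.1, and truly DE genes induced at folds of at least 2.
    """

    n_genes: int = 2000
    length_range: tuple[int, int] = (200, 3000)
    groups: tuple[str, str] = ("responsive", "nonresponsive")
    n_replicates: int = 3
    days: tuple[float, ...] = (3, 7, 15, 21)
    library_size_range: tuple[int, int] = (200_000, 500_000)
    de_fraction: float = 0.05
    fold_range: tuple[float, float] = (2.0, 8.0)
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        lo, hi = self.length_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid length_range: {self.length_range}")
        if len(self.groups) != 2:
            raise ValueError(f"groups must name two phenotypes, got {self.groups}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        days = np.asarray(self.days, dtype=float)
        if len(days) < 1 or not np.all(np.diff(days) > 0):
            raise ValueError(f"days must be strictly increasing, got {self.days}")
        llo, lhi = self.library_size_range
        if llo <= 0 or lhi < llo:
            raise ValueError(
                f"invalid library_size_range: {self.library_size_range}"
            )
        if not 0 <= self.de_fraction <= 1:
            raise ValueError(f"de_fraction must be in [0, 1], got {self.de_fraction}")
        flo, fhi = self.fold_range
        if flo < 1 or fhi < flo:
            raise ValueError(f"fold bounds must be >= 1, got {self.fold_range}")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``true_tech_scale`` maps sample to its planted technical factor (qPCR);
    ``true_profiles`` holds the noise-free quantity per sample × gene
    (qPCR); ``de_labels`` records per-gene DE status, fold and induced group
    (RNA-seq).  ``metadata`` carries generator flags such as the Poisson
    substitution at dispersion 0.
    """

    true_tech_scale: pd.Series | None = None
    true_profiles: pd.DataFrame | None = None
    de_labels: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)


def _shape_values(profile: TargetProfile, days: np.ndarray) -> np.ndarray:
    """Noise-free quantity of one gene over the day grid, one series at fold 1."""
    d0, dN = days[0], days[-1]
    if profile.shape == "flat":
        return np.full_like(days, profile.baseline, dtype=float)
    if profile.shape == "late_induced":
        # geometric ramp from baseline to baseline*peak_fold: monotone rise
        frac = (days - d0) / (dN - d0)
        return profile.baseline * profile.peak_fold**frac
    # early_transient: peak at day 3, half-peak at day 7, zero elsewhere
    values = np.zeros_like(days, dtype=float)
    peak = profile.baseline * profile.peak_fold
    values[days == 3] = peak
    values[days == 7] = peak / 2.0
    return values


def _series_multiplier(profile: TargetProfile, series_label: str) -> float:
    if profile.association == "responsiveness":
        return profile.assoc_fold if series_label == "G6" else 1.0
    if profile.association == "genotype":
        return profile.assoc_fold if series_label in ("G6", "G6NR") else 1.0
    return 1.0


def gen_qpcr_dataset(config: QpcrSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate an absolute-qPCR quantity table with known ground truth.

    Observed quantity = true profile × sample technical scale ×
    multiplicative measurement noise.  The technical scale is log-normal
    with zero log-mean (log-symmetric around 1); measurement noise is
    mean-one log-normal at the configured coefficient of variation.
    Reference genes have flat true profiles.  Identical seeds give
    identical tables.
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.days, dtype=float)
    samples = [
        (f"{series}_d{day:g}", series, float(day))
        for series in config.series_labels
        for day in days
    ]
    n_samples = len(samples)
    tech = np.exp(rng.normal(0.0, config.tech_scale_sigma, size=n_samples))
    sample_ids = [s[0] for s in samples]
    tech_scale = pd.Series(tech, index=sample_ids, name="true_tech_scale")

    if config.reference_baselines is not None:
        ref_levels = list(config.reference_baselines)
    else:
        # distinct stable levels per reference, e.g. EF1a-like vs UBC1-like
        ref_levels = [20000.0 / (i + 1) for i in range(config.n_reference_genes)]
    genes: dict[str, tuple[str, dict[str, np.ndarray]]] = {}
    for i, level in enumerate(ref_levels):
        per_series = {
            s: np.full_like(days, level, dtype=float) for s in config.series_labels
        }
        genes[f"REF{i + 1}"] = (ROLE_REFERENCE, per_series)
    for name, profile in config.target_profiles.items():
        base = _shape_values(profile, days)
        per_series = {
            s: base * _series_multiplier(profile, s) for s in config.series_labels
        }
        genes[name] = (ROLE_TARGET, per_series)

    sigma_m = float(np.sqrt(np.log1p(config.measurement_cv**2)))
    rows = []
    truth_rows = []
    for gene, (role, per_series) in genes.items():
        for j, (sample_id, series_label, day) in enumerate(samples):
            day_idx = int(np.flatnonzero(days == day)[0])
            true_q = float(per_series[series_label][day_idx])
            noise = (
                float(np.exp(rng.normal(-(sigma_m**2) / 2.0, sigma_m)))
                if sigma_m > 0
                else 1.0
            )
            observed = true_q * tech[j] * noise
            rows.append(
                {
                    "sample_id": sample_id,
                    "series": series_label,
                    "day": day,
                    "gene": gene,
                    "role": role,
                    "quantity": observed,
                }
            )
            truth_rows.append(
                {"sample_id": sample_id, "gene": gene, "true_quantity": true_q}
            )
    table = pd.DataFrame(rows, columns=["sample_id", "series", "day", "gene", "role", "quantity"])
    true_profiles = pd.DataFrame(truth_rows).pivot(
        index="sample_id", columns="gene", values="true_quantity"
    )
    truth = SimTruth(
        true_tech_scale=tech_scale,
        true_profiles=true_profiles,
        metadata={"measurement_cv": config.measurement_cv},
    )
    return table, truth


def gen_count_dataset(
    config: RnaseqSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, SimTruth]:
    """Simulate an RNA-seq count matrix with planted DE genes.

    Counts are NB with mean proportional to library size × relative gene
    expression, multiplied by the true fold for DE genes in their induced
    group (all days).  A dispersion of 0 substitutes Poisson sampling and
    flags it in the truth metadata.

    Returns ``(counts, sample_sheet, gene_lengths, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    lengths = pd.Series(
        rng.integers(config.length_range[0], config.length_range[1] + 1,
                     size=config.n_genes),
        index=genes,
        name="length",
    )
    sample_rows = [
        {
            "sample_id": f"{group[:4]}_d{day:g}_r{rep + 1}",
            "phenotype": group,
            "day": float(day),
            "replicate": rep + 1,
        }
        for group in config.groups
        for day in config.days
        for rep in range(config.n_replicates)
    ]
    sheet = pd.DataFrame(sample_rows)

    # relative expression: heavy-tailed, length-weighted read propensity
    rel = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_genes)
    weight = rel * lengths.to_numpy()

    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    folds = rng.uniform(config.fold_range[0], config.fold_range[1], size=n_de)
    induced = rng.choice(config.groups, size=n_de)
    is_de = np.zeros(config.n_genes, dtype=bool)
    is_de[de_idx] = True
    gene_fold = np.ones(config.n_genes)
    gene_fold[de_idx] = folds
    gene_group = np.array([""] * config.n_genes, dtype=object)
    gene_group[de_idx] = induced

    lib_sizes = rng.integers(
        config.library_size_range[0],
        config.library_size_range[1] + 1,
        size=len(sheet),
    )
    counts = np.zeros((config.n_genes, len(sheet)), dtype=np.int64)
    poisson = config.dispersion == 0
    r = None if poisson else 1.0 / config.dispersion
    for j, row in enumerate(sample_rows):
        w = weight.copy()
        boost = gene_group == row["phenotype"]
        w[boost] *= gene_fold[boost]
        mu = lib_sizes[j] * w / w.sum()
        if poisson:
            counts[:, j] = rng.poisson(mu)
        else:
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    count_df = pd.DataFrame(counts, index=genes, columns=sheet["sample_id"].tolist())
    de_labels = pd.DataFrame(
        {
            "gene": genes,
            "is_de": is_de,
            "true_fold": gene_fold,
            "induced_group": gene_group,
        }
    ).set_index("gene")
    truth = SimTruth(
        de_labels=de_labels,
        metadata={
            "poisson_substituted": poisson,
            "dispersion": config.dispersion,
            "library_sizes": pd.Series(lib_sizes, index=count_df.columns),
        },
    )
    return count_df, sheet, lengths, truth


def gen_reads(
    n_reads: int, length_bounds: tuple[int, int], seed: int = 0
) -> list[SeqRecord]:
    """Random-base FASTQ records with uniform Q40 qualities; seeded.

    Read lengths are uniform over ``length_bounds`` (inclusive).
    """
    if n_reads < 0:
        raise ValueError(f"n_reads must be >= 0, got {n_reads}")
    lo, hi = length_bounds
    if lo <= 0 or hi < lo:
        raise ValueError(f"length bounds must be positive, got {length_bounds}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records = []
    for i in range(n_reads):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(bases, size=length))
        rec = SeqRecord(
            Seq(seq),
            id=f"read{i + 1}",
            description="",
            letter_annotations={"phred_quality": [40] * length},
        )
        records.append(rec)
    return records
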