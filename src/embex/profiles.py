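"""Time-course expression profiles and responsiveness/genotype classification.

The study design crosses explant response with genotype: G6 (responsive) and
G6NR (nonresponsive) are clones of the same genotype, while G2 and G12 are
nonresponsive genotypes.  A gene whose normalized profile separates G6 from
G6NR is associated with induction responsiveness itself; one whose profile
separates the G6 clone pair from the other genotypes while G6 and G6NR agree
tracks genotype instead.  This module builds per-(gene, series) normalized
trajectories and turns that visual comparison into a reproducible call based
on a log2 profile distance and a fold threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .qpcr import NormalizationFactors, apply_normalization, validate_quantity_table

#: Series labels with their role in the response × genotype design.
RESPONSIVE_SERIES = "G6"
CLONAL_NONRESPONSIVE_SERIES = "G6NR"
OTHER_GENOTYPE_SERIES = ("G2", "G12")

CALL_RESPONSIVENESS = "responsiveness_associated"
CALL_GENOTYPE = "genotype_associated"
CALL_NONE = "none"


@dataclass(frozen=True)
class ExpressionProfile:
    """Normalized quantity trajectory of one gene in one explant series."""

    gene: str
    series: str
    days: tuple
    quantities: tuple

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        q = np.asarray(self.quantities, dtype=float)
        if len(days) != len(q):
            raise ValueError("days and quantities differ in length")
        if len(days) and not np.all(np.diff(days) > 0):
            raise ValueError("days must be strictly increasing")
        if np.any(q < 0):
            raise ValueError("quantities must be non-negative")


@dataclass(frozen=True)
class AssociationCall:
    """Classification of a gene's profile differences across the design.

    The call is determined solely by two distances and the threshold:
    ``within_genotype_distance`` (G6 vs G6NR, same genotype) and
    ``between_genotype_distance`` (mean of G6 vs G2 and G6 vs G12).
    """

    gene: str
    call: str
    within_genotype_distance: float
    between_genotype_distance: float
    threshold: float


def build_profiles(
    table: pd.DataFrame, factors: NormalizationFactors | None = None
) -> dict[tuple[str, str], ExpressionProfile]:
    """One profile per (gene, series) from a quantity table, ordered by day.

    If ``factors`` is given the table is normalized first.  Replicate
    measurements at the same (series, day) are averaged.  Every gene must be
    measured in every sample of every series it appears in; gaps are an
    error listing the missing (gene, series, day) combinations.
    """
    validate_quantity_table(table)
    if factors is not None:
        table = apply_normalization(table, factors)
    mean_q = (
        table.groupby(["gene", "series", "day"])["quantity"].mean().reset_index()
    )
    # genes must cover the full day grid of each series they occur in
    series_days = table.groupby("series")["day"].agg(lambda d: tuple(sorted(set(d))))
    gaps = []
    for (gene, series_label), sub in mean_q.groupby(["gene", "series"]):
        expected = series_days[series_label]
        got = tuple(sorted(sub["day"]))
        if got != expected:
            missing_days = sorted(set(expected) - set(got))
            gaps.extend((gene, series_label, d) for d in missing_days)
    if gaps:
        raise ValueError(f"missing (gene, series, day) entries: {gaps}")
    out: dict[tuple[str, str], ExpressionProfile] = {}
    for (gene, series_label), sub in mean_q.groupby(["gene", "series"]):
        sub = sub.sort_values("day")
        out[(gene, series_label)] = ExpressionProfile(
            gene=gene,
            series=series_label,
            days=tuple(sub["day"]),
            quantities=tuple(sub["quantity"]),
        )
    return out


def profile_distance(
    a: ExpressionProfile, b: ExpressionProfile, pseudocount: float = 1.0
) -> float:
    """Mean absolute log2 ratio between two profiles on the same day grid.

    distance = mean over days of \\|log2((qa + eps)/(qb + eps))\\| with
    pseudocount ``eps`` guarding zero quantities (an early-transient gene is
    exactly zero at late days).  Symmetric, zero iff the profiles are equal,
    and a pseudometric on profiles sharing a day grid.
    """
    if a.gene != b.gene:
        raise ValueError(f"profiles are for different genes: {a.gene!r} vs {b.gene!r}")
    if a.days != b.days:
        raise ValueError(f"day grids differ: {a.days} vs {b.days}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    qa = np.asarray(a.quantities, dtype=float) + pseudocount
    qb = np.asarray(b.quantities, dtype=float) + pseudocount
    if np.any(qa <= 0) or np.any(qb <= 0):
        raise ValueError("quantities must be positive after pseudocount")
    return float(np.mean(np.abs(np.log2(qa / qb))))


def classify_association(
    gene_profiles: Mapping[str, ExpressionProfile],
    threshold: float = 1.0,
    pseudocount: float = 1.0,
    responsive: str = RESPONSIVE_SERIES,
    clonal_nonresponsive: str = CLONAL_NONRESPONSIVE_SERIES,
    other_genotypes: Sequence[str] = OTHER_GENOTYPE_SERIES,
) -> AssociationCall:
    """Call a gene responsiveness- or genotype-associated, or neither.

    ``gene_profiles`` maps series label to that gene's profile and must cover
    the responsive series, its nonresponsive clone, and the other-genotype
    series.  The gene is responsiveness-associated when the clone pair
    (responsive vs clonal nonresponsive — same genotype, different response)
    diverge by more than ``threshold`` log2 units on average; otherwise
    genotype-associated when the responsive series diverges from the other
    genotypes by more than the threshold; otherwise ``none``.
    """
    needed = [responsive, clonal_nonresponsive, *other_genotypes]
    missing = [s for s in needed if s not in gene_profiles]
    if missing:
        raise ValueError(f"missing series for classification: {missing}")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    ref = gene_profiles[responsive]
    within = profile_distance(ref, gene_profiles[clonal_nonresponsive], pseudocount)
    between = float(
        np.mean(
            [profile_distance(ref, gene_profiles[g], pseudocount) for g in other_genotypes]
        )
    )
    if within > threshold:
        call = CALL_RESPONSIVENESS
    elif between > threshold:
        call = CALL_GENOTYPE
    else:
        call = CALL_NONE
    return AssociationCall(
        gene=ref.gene,
        call=call,
        within_genotype_distance=within,
        between_genotype_distance=between,
        threshold=threshold,
    )


def classify_all(
    profiles: Mapping[tuple[str, str], ExpressionProfile],
    threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Classify every gene with all four design series present.

    Returns a DataFrame with one row per classifiable gene: the call, the
    two distances and the threshold used.
    """
    by_gene: dict[str, dict[str, ExpressionProfile]] = {}
    for (gene, series_label), prof in profiles.items():
        by_gene.setdefault(gene, {})[series_label] = prof
    needed = {RESPONSIVE_SERIES, CLONAL_NONRESPONSIVE_SERIES, *OTHER_GENOTYPE_SERIES}
    rows = []
    for gene in sorted(by_gene):
        if needed <= set(by_gene[gene]):
            call = classify_association(
                by_gene[gene], threshold=threshold, pseudocount=pseudocount
            )
            rows.append(
                {
                    "gene": call.gene,
                    "call": call.call,
                    "within_genotype_distance": call.within_genotype_distance,
                    "between_genotype_distance": call.between_genotype_distance,
                    "threshold": call.threshold,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "call",
            "within_genotype_distance",
            "between_genotype_distance",
            "threshold",
        ],
    )


def plot_profiles(
    profiles: Mapping[tuple[str, str], ExpressionProfile],
    path: str,
    genes: Iterable[str] | None = None,
) -> None:
    """Line chart of series × day trajectories, one panel per gene."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wanted = sorted({g for g, _ in profiles} if genes is None else set(genes))
    n = max(len(wanted), 1)
    fig, axes = plt.subplots(n, 1, figsize=(6, 3 * n), squeeze=False)
    for ax, gene in zip(axes.ravel(), wanted):
        for (g, series_label), prof in sorted(profiles.items()):
            if g == gene:
                ax.plot(prof.days, prof.quantities, marker="o", label=series_label)
        ax.set_title(gene)
        ax.set_xlabel("induction day")
        ax.set_ylabel("molecules / 10 ng RNA")
        ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
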