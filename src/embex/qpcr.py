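"""Sample-specific normalization of absolute qPCR transcript quantities.

Absolute qPCR reports transcript abundance as molecule counts per fixed RNA
input (here molecules per 10 ng total RNA).  Sample-to-sample differences in
reference-gene quantity on that scale are taken to reflect technical scaling
introduced during sample preparation (RNA extraction, quantification, reverse
transcription).  This module removes that scaling with a per-sample,
dimensionless normalization factor:

1. average each reference gene's quantity across all samples of a series
   (an explant type followed over the induction time course);
2. within each sample, express each reference gene as a fraction of its
   series average;
3. average those fractions across reference genes to obtain the sample's
   normalization factor;
4. divide every quantity in the sample (targets and references alike) by the
   factor.

Because the factor is dimensionless and averages to one within each series,
normalized quantities stay on the absolute molecules-per-10-ng scale.

A quantity table is a tidy :class:`pandas.DataFrame` with columns
``sample_id, series, day, gene, role, quantity`` where ``role`` is
``"reference"`` or ``"target"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

QUANTITY_COLUMNS = ["sample_id", "series", "day", "gene", "role", "quantity"]

ROLE_REFERENCE = "reference"
ROLE_TARGET = "target"


class QuantityTableError(ValueError):
    """Raised when a quantity table violates its schema or preconditions."""


def validate_quantity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants of a quantity table; return it unchanged.

    Invariants: all required columns present, quantities non-negative and
    finite, (sample_id, gene) pairs unique, each sample in exactly one series.
    """
    missing = [c for c in QUANTITY_COLUMNS if c not in table.columns]
    if missing:
        raise QuantityTableError(f"quantity table missing columns: {missing}")
    if len(table) == 0:
        raise QuantityTableError("quantity table is empty")
    q = pd.to_numeric(table["quantity"], errors="coerce")
    if q.isna().any():
        bad = table.loc[q.isna(), "gene"].tolist()
        raise QuantityTableError(f"non-numeric quantities for genes: {bad}")
    if (q < 0).any():
        bad = table.loc[q < 0, ["sample_id", "gene"]].to_records(index=False)
        raise QuantityTableError(f"negative quantities at: {list(bad)}")
    dup = table.duplicated(subset=["sample_id", "gene"])
    if dup.any():
        pairs = table.loc[dup, ["sample_id", "gene"]].to_records(index=False)
        raise QuantityTableError(f"duplicate (sample, gene) entries: {list(pairs)}")
    n_series = table.groupby("sample_id")["series"].nunique()
    multi = n_series[n_series > 1].index.tolist()
    if multi:
        raise QuantityTableError(f"samples assigned to multiple series: {multi}")
    bad_role = set(table["role"]) - {ROLE_REFERENCE, ROLE_TARGET}
    if bad_role:
        raise QuantityTableError(f"unknown roles: {sorted(bad_role)}")
    return table


@dataclass
class NormalizationFactors:
    """Per-sample normalization factors with per-reference diagnostics.

    Attributes
    ----------
    factors
        Series mapping ``sample_id`` to a dimensionless factor > 0.  Within
        each series the factors average to exactly 1 by construction.
    fractions
        DataFrame indexed by ``sample_id`` with one column per reference
        gene: the sample's reference quantity divided by that gene's series
        mean.  Retained for diagnostics.
    series
        Series mapping ``sample_id`` to its series label.
    method
        How fractions were combined across reference genes
        (``"arithmetic"`` or ``"geometric"``).
    """

    factors: pd.Series
    fractions: pd.DataFrame = field(repr=False)
    series: pd.Series = field(repr=False)
    method: str = "arithmetic"


@dataclass(frozen=True)
class DivergenceSummary:
    """Spread of normalization factors expressed as percentages.

    ``half_range_percent`` is (max − min)/2, the "±" figure quoted when the
    factor range is reported as a symmetric variance bound.
    """

    min_percent: float
    max_percent: float
    half_range_percent: float


def series_reference_means(table: pd.DataFrame) -> pd.Series:
    """Mean reference-gene quantity per (series, reference gene).

    Every sample of a series must carry a measurement for every reference
    gene observed in that series, and each series needs at least two
    samples; a zero mean is an error because downstream division by it is
    impossible.

    Returns a Series indexed by (series, gene).
    """
    validate_quantity_table(table)
    refs = table[table["role"] == ROLE_REFERENCE]
    if refs.empty:
        raise QuantityTableError("no reference-gene rows in table")
    for series_label, sub in refs.groupby("series"):
        samples = table.loc[table["series"] == series_label, "sample_id"].unique()
        if len(samples) < 2:
            raise QuantityTableError(
                f"series {series_label!r} has fewer than 2 samples"
            )
        genes = sub["gene"].unique()
        have = {(s, g) for s, g in sub[["sample_id", "gene"]].itertuples(index=False)}
        for s in samples:
            for g in genes:
                if (s, g) not in have:
                    raise QuantityTableError(
                        f"sample {s!r} lacks reference gene {g!r} "
                        f"in series {series_label!r}"
                    )
    means = refs.groupby(["series", "gene"])["quantity"].mean()
    zero = means[means == 0]
    if not zero.empty:
        raise QuantityTableError(
            f"zero series mean for reference(s) {zero.index.tolist()}; "
            "division impossible"
        )
    return means


def normalization_factors(
    table: pd.DataFrame, method: str = "arithmetic"
) -> NormalizationFactors:
    """Compute the per-sample normalization factor from reference genes.

    For each sample and reference gene, the fraction is the observed
    quantity divided by that gene's series mean; the factor is the mean of
    the fractions across reference genes (arithmetic by default, geometric
    as an option).  Per-series factor means equal 1 up to floating error.
    """
    if method not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown averaging method: {method!r}")
    means = series_reference_means(table)
    refs = table[table["role"] == ROLE_REFERENCE].copy()
    key = pd.MultiIndex.from_frame(refs[["series", "gene"]])
    refs["fraction"] = refs["quantity"].to_numpy() / means.loc[key].to_numpy()
    if (refs["fraction"] == 0).any():
        bad = refs.loc[refs["fraction"] == 0, ["sample_id", "gene"]]
        raise QuantityTableError(
            f"zero reference quantity (factor undefined) at: "
            f"{list(bad.to_records(index=False))}"
        )
    fractions = refs.pivot(index="sample_id", columns="gene", values="fraction")
    if method == "arithmetic":
        factors = fractions.mean(axis=1)
    else:
        factors = np.exp(np.log(fractions).mean(axis=1))
    factors.name = "factor"
    series = (
        table.drop_duplicates("sample_id")
        .set_index("sample_id")["series"]
        .loc[factors.index]
    )
    return NormalizationFactors(
        factors=factors, fractions=fractions, series=series, method=method
    )


def apply_normalization(
    table: pd.DataFrame, factors: NormalizationFactors
) -> pd.DataFrame:
    """Divide every quantity by its sample's factor; schema and units kept.

    All genes in a sample, including the reference genes themselves, are
    divided by the same factor, so the output remains in molecules per
    10 ng RNA.
    """
    validate_quantity_table(table)
    missing = set(table["sample_id"]) - set(factors.factors.index)
    if missing:
        raise QuantityTableError(
            f"no normalization factor for sample(s): {sorted(missing)}"
        )
    f = factors.factors
    if (f <= 0).any():
        bad = f[f <= 0].index.tolist()
        raise QuantityTableError(f"non-positive factors for samples: {bad}")
    out = table.copy()
    out["quantity"] = (
        out["quantity"].to_numpy() / f.loc[out["sample_id"]].to_numpy()
    )
    return out


def divergence_summary(factors: NormalizationFactors) -> DivergenceSummary:
    """Summarize the factor spread as min%, max% and the ± half-range."""
    f = factors.factors
    if len(f) == 0:
        raise ValueError("no factors to summarize")
    lo = float(f.min()) * 100.0
    hi = float(f.max()) * 100.0
    return DivergenceSummary(
        min_percent=lo, max_percent=hi, half_range_percent=(hi - lo) / 2.0
    )
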