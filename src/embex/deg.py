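"""RNA-seq differential expression: RPKM, NB exact test, FDR, fold filter.

Post-mapping stage for a two-phenotype (responsive vs nonresponsive explant)
time-course count matrix.  Per collection day it computes RPKM, estimates a
per-gene ("tagwise") negative-binomial dispersion by moment matching with
shrinkage toward the all-gene median, runs a conditional NB exact test on
library-size-adjusted pseudo-counts, applies Benjamini–Hochberg FDR, and
filters on p < 0.05 with a directional ≥2-fold induction requirement — the
retained genes are the DEG reported in per-day tables and a count/average-
RPKM summary.

A count matrix is a genes × samples integer DataFrame; the sample sheet is a
DataFrame with columns ``sample_id, phenotype, day, replicate`` where
phenotype is ``responsive`` or ``nonresponsive``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom, nbinom
from statsmodels.stats.multitest import multipletests

PHENOTYPE_RESPONSIVE = "responsive"
PHENOTYPE_NONRESPONSIVE = "nonresponsive"
SAMPLE_SHEET_COLUMNS = ["sample_id", "phenotype", "day", "replicate"]

# tie tolerance when summing enumeration probabilities <= the observed one
_TIE_LOG_TOL = 1e-10


@dataclass(frozen=True)
class DegThresholds:
    """Filtering thresholds: p (or FDR) cutoff and minimum induction fold."""

    p_threshold: float = 0.05
    fold_threshold: float = 2.0
    use_fdr: bool = True


def _check_counts(counts: pd.DataFrame) -> None:
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("counts must be numeric")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")


def rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``rpkm = count / (length_kb * library_size_millions)``.  Library sizes
    default to the column sums of the count matrix; zero library size is an
    error.  Invariant to jointly rescaling counts and library sizes, linear
    in counts at fixed library size.
    """
    _check_counts(counts)
    lengths = lengths.loc[counts.index]
    if (lengths <= 0).any():
        bad = lengths[lengths <= 0].index.tolist()
        raise ValueError(f"non-positive gene lengths: {bad}")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.loc[counts.columns]
    if (library_sizes <= 0).any():
        bad = library_sizes[library_sizes <= 0].index.tolist()
        raise ValueError(f"zero or negative library size for samples: {bad}")
    kb = lengths.to_numpy()[:, None] / 1e3
    millions = library_sizes.to_numpy()[None, :] / 1e6
    return pd.DataFrame(
        counts.to_numpy() / (kb * millions),
        index=counts.index,
        columns=counts.columns,
    )


def fold_difference(mean_resp: float, mean_nonresp: float) -> float:
    """Responsive / nonresponsive expression ratio.

    Returns ``inf`` when only the denominator is zero and ``nan`` for 0/0
    (undetected in both phenotypes); negative means are an error.
    """
    if mean_resp < 0 or mean_nonresp < 0:
        raise ValueError("mean expression must be non-negative")
    if mean_nonresp == 0:
        return np.nan if mean_resp == 0 else np.inf
    return mean_resp / mean_nonresp


def estimate_tagwise_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series,
    shrink_weight: float = 0.3,
) -> pd.Series:
    """Per-gene NB dispersion by within-group moments with median shrinkage.

    For each gene the raw dispersion is the within-group method-of-moments
    estimate ``(variance - mean) / mean**2`` averaged over groups with at
    least two samples and floored at zero (a constant-replicate or Poisson
    gene gives zero).  Raw values are then shrunk toward the all-gene median
    with weight ``shrink_weight``, stabilizing the noisy per-gene moments at
    small replicate numbers.  All-zero genes get dispersion 0.
    """
    _check_counts(counts)
    if not 0 <= shrink_weight <= 1:
        raise ValueError("shrink_weight must be in [0, 1]")
    groups = groups.loc[counts.columns]
    per_group = []
    for _, cols in groups.groupby(groups).groups.items():
        if len(cols) < 2:
            continue
        sub = counts[list(cols)].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(m > 0, (v - m) / m**2, 0.0)
        per_group.append(np.maximum(phi, 0.0))
    if not per_group:
        raise ValueError("need at least one group with >=2 samples")
    raw = np.mean(per_group, axis=0)
    common = float(np.median(raw))
    shrunk = (1.0 - shrink_weight) * raw + shrink_weight * common
    return pd.Series(shrunk, index=counts.index, name="dispersion")


def _conditional_log_pmf(
    total: int, n_a: int, n_b: int, dispersion: float
) -> np.ndarray:
    """Log P(group-a sum = k | total), k = 0..total, equal per-sample means.

    The within-group sum of ``n`` iid NB(mu, dispersion) counts is NB with
    mean ``n*mu`` and size ``n/dispersion``; conditioning on the total makes
    the split distribution free of mu.  Dispersion 0 is the Poisson limit
    (binomial split).
    """
    k = np.arange(total + 1)
    if dispersion == 0:
        return binom.logpmf(k, total, n_a / (n_a + n_b))
    r_a = n_a / dispersion
    r_b = n_b / dispersion
    mu = total / (n_a + n_b)
    # success prob identical for both group sums; cancels on conditioning
    p = r_a / (r_a + n_a * max(mu, 1e-300))
    logp = nbinom.logpmf(k, r_a, p) + nbinom.logpmf(total - k, r_b, p)
    return logp - logsumexp(logp)


def nb_exact_test(
    counts_a: np.ndarray, counts_b: np.ndarray, dispersion: float
) -> float:
    """Two-sided conditional NB exact test for a two-group count split.

    Inputs are library-size-adjusted pseudo-counts (scale samples to a
    common library size before calling).  Given the total count, the test
    enumerates the probability of every split between the groups under
    equal group means and sums the probabilities of splits no more likely
    than the observed one (ties included).  Returns p in (0, 1].
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    s_a = int(round(a.sum()))
    s_b = int(round(b.sum()))
    total = s_a + s_b
    if total == 0:
        return 1.0
    logp = _conditional_log_pmf(total, len(a), len(b), dispersion)
    observed = logp[s_a]
    p = float(np.exp(logsumexp(logp[logp <= observed + _TIE_LOG_TOL])))
    return min(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_to_common_library(
    counts: pd.DataFrame, library_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """Scale each sample's counts to the geometric-mean library size.

    The conditional exact test assumes comparable library sizes; counts are
    rescaled to the geometric mean of the totals and rounded to the nearest
    integer pseudo-count.
    """
    _check_counts(counts)
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.loc[counts.columns].astype(float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    common = float(np.exp(np.mean(np.log(library_sizes))))
    scale = common / library_sizes.to_numpy()
    return pd.DataFrame(
        np.round(counts.to_numpy() * scale[None, :]).astype(np.int64),
        index=counts.index,
        columns=counts.columns,
    )


def _check_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    bad = set(samples["phenotype"]) - {PHENOTYPE_RESPONSIVE, PHENOTYPE_NONRESPONSIVE}
    if bad:
        raise ValueError(f"unknown phenotypes: {sorted(bad)}")
    return samples


def deg_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    lengths: pd.Series,
    shrink_weight: float = 0.3,
) -> pd.DataFrame:
    """Per-gene, per-day two-group test with RPKM means and fold differences.

    For each collection day, responsive and nonresponsive samples are
    compared: pseudo-counts adjusted to a common library size, tagwise
    dispersion estimated across that day's samples, NB exact test per gene,
    BH-adjusted within the day.  Returns one record per gene per day with
    columns ``gene, day, mean_rpkm_responsive, mean_rpkm_nonresponsive,
    fold_difference, dispersion, p_value, fdr``.
    """
    _check_counts(counts)
    _check_sample_sheet(samples)
    expr = rpkm(counts, lengths)
    samples = samples.set_index("sample_id", drop=False)
    records = []
    for day, day_samples in samples.groupby("day"):
        resp = day_samples.loc[
            day_samples["phenotype"] == PHENOTYPE_RESPONSIVE, "sample_id"
        ].tolist()
        nonresp = day_samples.loc[
            day_samples["phenotype"] == PHENOTYPE_NONRESPONSIVE, "sample_id"
        ].tolist()
        if len(resp) < 2 or len(nonresp) < 2:
            raise ValueError(
                f"day {day}: need >=2 samples per phenotype for testing "
                f"(got {len(resp)} responsive, {len(nonresp)} nonresponsive)"
            )
        day_counts = counts[resp + nonresp]
        pseudo = adjust_to_common_library(day_counts)
        disp = estimate_tagwise_dispersion(
            pseudo,
            samples.loc[resp + nonresp, "phenotype"],
            shrink_weight=shrink_weight,
        )
        a = pseudo[resp].to_numpy()
        b = pseudo[nonresp].to_numpy()
        pvals = np.array(
            [
                nb_exact_test(a[i], b[i], float(disp.iloc[i]))
                for i in range(len(pseudo))
            ]
        )
        fdr = bh_fdr(pvals)
        mean_r = expr.loc[:, resp].mean(axis=1)
        mean_n = expr.loc[:, nonresp].mean(axis=1)
        for i, gene in enumerate(counts.index):
            records.append(
                {
                    "gene": gene,
                    "day": day,
                    "mean_rpkm_responsive": float(mean_r.iloc[i]),
                    "mean_rpkm_nonresponsive": float(mean_n.iloc[i]),
                    "fold_difference": fold_difference(
                        float(mean_r.iloc[i]), float(mean_n.iloc[i])
                    ),
                    "dispersion": float(disp.iloc[i]),
                    "p_value": float(pvals[i]),
                    "fdr": float(fdr[i]),
                }
            )
    return pd.DataFrame.from_records(records)


def deg_filter(
    records: pd.DataFrame,
    p_threshold: float = 0.05,
    fold_threshold: float = 2.0,
    use_fdr: bool = True,
) -> pd.DataFrame:
    """Keep significant records with >= fold_threshold directional induction.

    A record passes when its (FDR-adjusted by default) p-value is below
    ``p_threshold`` and the responsive/nonresponsive fold is either
    >= ``fold_threshold`` (responsive-induced) or <= 1/``fold_threshold``
    (nonresponsive-induced); an infinite fold counts as responsive-induced.
    Adds an ``induced_phenotype`` column.
    """
    if p_threshold <= 0 or fold_threshold < 1:
        raise ValueError("need p_threshold > 0 and fold_threshold >= 1")
    needed = {"fold_difference", "fdr" if use_fdr else "p_value"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    pcol = "fdr" if use_fdr else "p_value"
    fold = records["fold_difference"]
    sig = records[pcol] < p_threshold
    up = fold >= fold_threshold  # inf compares True; nan compares False
    down = fold <= 1.0 / fold_threshold
    out = records[sig & (up | down)].copy()
    out["induced_phenotype"] = np.where(
        out["fold_difference"] >= fold_threshold,
        PHENOTYPE_RESPONSIVE,
        PHENOTYPE_NONRESPONSIVE,
    )
    return out


def deg_summary(filtered: pd.DataFrame) -> pd.DataFrame:
    """DEG count and mean induced-phenotype RPKM per (day, induced phenotype).

    The average is taken over the retained genes' mean RPKM in the phenotype
    they are induced in; an empty cell reports count 0 and NaN average.
    """
    days = sorted(filtered["day"].unique()) if len(filtered) else []
    rows = []
    for day in days:
        for phen in (PHENOTYPE_RESPONSIVE, PHENOTYPE_NONRESPONSIVE):
            sub = filtered[
                (filtered["day"] == day) & (filtered["induced_phenotype"] == phen)
            ]
            if len(sub):
                col = (
                    "mean_rpkm_responsive"
                    if phen == PHENOTYPE_RESPONSIVE
                    else "mean_rpkm_nonresponsive"
                )
                avg = float(sub[col].mean())
            else:
                avg = np.nan
            rows.append(
                {
                    "day": day,
                    "induced_phenotype": phen,
                    "n_deg": len(sub),
                    "average_rpkm": avg,
                }
            )
    return pd.DataFrame(
        rows, columns=["day", "induced_phenotype", "n_deg", "average_rpkm"]
    )
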