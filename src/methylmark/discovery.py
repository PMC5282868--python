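"""Candidate marker-locus discovery.

A cancer-specific CpG marker must be essentially unmethylated in every
non-cancer reference class (normal urothelium, blood, non-cancer urine) and
methylated in a majority of tumours.  The filter is purely threshold-based:
no differential-methylation test statistic is involved.

Default criteria: beta < 0.10 in every non-cancer sample (a cut derived from
the beta distribution of fully unmethylated control DNA) and beta > 0.50 in
at least half of the cancers.  Inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    BetaMatrix,
    NONCANCER_REFERENCE_GROUPS,
    SampleSheet,
)


class ConfigurationError(ValueError):
    """The cohort cannot support the filter as stated."""


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds defining a cancer-specific locus.

    ``normal_beta_max``: every non-cancer sample must sit strictly below
    this beta.  ``cancer_beta_min``: a cancer sample "counts" when strictly
    above this beta.  ``cancer_fraction_min``: minimum fraction of cancers
    that must count.
    """

    normal_beta_max: float = 0.10
    cancer_beta_min: float = 0.50
    cancer_fraction_min: float = 0.50

    def __post_init__(self) -> None:
        if not (0.0 <= self.normal_beta_max < self.cancer_beta_min <= 1.0):
            raise ValueError(
                "require 0 <= normal_beta_max < cancer_beta_min <= 1"
            )
        if not (0.0 < self.cancer_fraction_min <= 1.0):
            raise ValueError("require 0 < cancer_fraction_min <= 1")


@dataclass
class CandidateLocusSet:
    """Loci passing the filter, with per-locus audit summaries.

    ``summary`` is indexed by every input locus and carries
    ``noncancer_max`` (the max — or group-quantile max — over non-cancer
    samples), ``cancer_fraction`` (fraction of cancers above
    ``cancer_beta_min``), the effective sample counts, and ``selected``.
    """

    locus_ids: list[str]
    summary: pd.DataFrame
    criteria: FilterCriteria = field(default_factory=FilterCriteria)


def filter_candidate_loci(
    betas: BetaMatrix,
    sheet: SampleSheet,
    criteria: FilterCriteria | None = None,
    noncancer_quantile: float | None = None,
) -> CandidateLocusSet:
    """Apply the cancer-specificity filter to a QC'd beta matrix.

    By default the non-cancer constraint is the maximum over *every*
    non-cancer sample; ``noncancer_quantile`` switches to a per-group
    quantile (the max of the three group quantiles), tolerating outliers.
    Missing betas are excluded per locus; the effective n is reported.
    """
    criteria = criteria or FilterCriteria()
    samples = [s for s in betas.sample_ids if s in sheet.table.index]
    sub = betas.values[samples]
    groups = sheet.table.loc[samples, "group"]

    noncancer_cols: dict[str, list[str]] = {}
    for g in NONCANCER_REFERENCE_GROUPS:
        cols = list(groups.index[groups == g])
        if not cols:
            raise ConfigurationError(
                f"non-cancer group {g!r} has no samples; the filter cannot be "
                "evaluated as stated"
            )
        noncancer_cols[g] = cols
    cancer_cols = list(groups.index[groups == "cancer"])
    if len(cancer_cols) < 2:
        raise ConfigurationError("need at least two cancer samples")

    with np.errstate(all="ignore"):
        if noncancer_quantile is None:
            nc = sub[[c for cols in noncancer_cols.values() for c in cols]]
            noncancer_stat = nc.max(axis=1, skipna=True)
        else:
            per_group = [
                sub[cols].quantile(noncancer_quantile, axis=1, interpolation="linear")
                for cols in noncancer_cols.values()
            ]
            noncancer_stat = pd.concat(per_group, axis=1).max(axis=1)
        ca = sub[cancer_cols]
        n_cancer_used = ca.notna().sum(axis=1)
        cancer_fraction = (ca > criteria.cancer_beta_min).sum(axis=1) / n_cancer_used
        nc_all = sub[[c for cols in noncancer_cols.values() for c in cols]]
        n_noncancer_used = nc_all.notna().sum(axis=1)

    selected = (
        (noncancer_stat < criteria.normal_beta_max)
        & (cancer_fraction >= criteria.cancer_fraction_min)
        & (n_cancer_used > 0)
        & (n_noncancer_used > 0)
    )
    summary = pd.DataFrame(
        {
            "noncancer_max": noncancer_stat,
            "cancer_fraction": cancer_fraction,
            "n_cancer_used": n_cancer_used,
            "n_noncancer_used": n_noncancer_used,
            "selected": selected,
        }
    )
    return CandidateLocusSet(
        locus_ids=list(summary.index[selected]),
        summary=summary,
        criteria=criteria,
    )


def estimate_unmethylated_threshold(control_betas, quantile: float = 0.99) -> float:
    """High quantile of pooled betas from fully unmethylated control DNA.

    The returned value is the data-driven choice for
    :attr:`FilterCriteria.normal_beta_max` ("how high can a truly
    unmethylated locus read?").
    """
    if isinstance(control_betas, BetaMatrix):
        values = control_betas.values.to_numpy().ravel()
    else:
        values = np.asarray(control_betas, dtype=float).ravel()
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no control beta values supplied")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    return float(np.quantile(values, quantile))
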