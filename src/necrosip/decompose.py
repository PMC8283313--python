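"""Absolute abundance and necromass-decomposition statistics.

The analysis works in absolute 16S copy units: for each sample the qPCR
total copy number ``F`` (copies per g soil) is distributed over OTUs
according to their sequencing proportions ``P``, giving per-OTU absolute
abundances ``A = F x P``.  The decomposition statistic for an OTU between
day 0 and day Ti is the percentage of absolute abundance lost,

    D = 100 * (A_T0 - A_Ti) / A_T0 ,

computed on the light (unlabeled, i.e. necromass) fraction of the
heavy-water treatment.  Two filters mirror the study design: OTUs must
exceed 0.05% mean relative abundance at day 0 (strict inequality), and only
OTUs with mean D > 0 enter downstream comparisons.  Replicates are
destructive samples, so per-replicate D at Ti is taken against the day-0
replicate mean rather than paired replicates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import benjamini_hochberg, ttest_matrix, ttest_two_sample

__all__ = [
    "AbundanceTables",
    "GRAM_POSITIVE_PHYLA",
    "GRAM_NEGATIVE_PHYLA",
    "TAXONOMY_RANKS",
    "absolute_abundance",
    "filter_day0_prevalence",
    "decomposition_statistic",
    "decomposition_table",
    "gram_group_comparison",
    "phylum_range_summary",
]

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

GRAM_POSITIVE_PHYLA = frozenset({"Actinobacteria", "Firmicutes"})
GRAM_NEGATIVE_PHYLA = frozenset({"Acidobacteria", "Gemmatimonadetes", "Proteobacteria"})

_META_COLUMNS = ("timepoint_day", "replicate", "fraction_class", "treatment")


@dataclass
class AbundanceTables:
    """Paired OTU count table, sample metadata, qPCR totals and taxonomy.

    ``counts``: OTU x sample integer DataFrame; ``sample_meta``: one row per
    sample with columns timepoint_day, replicate, fraction_class, treatment;
    ``qpcr``: per-sample total 16S copies per g soil; ``taxonomy``: per-OTU
    7-rank lineage (may be empty for toy tables).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    qpcr: pd.Series
    taxonomy: pd.DataFrame = field(default_factory=pd.DataFrame)
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        samples = list(self.counts.columns)
        if list(self.sample_meta.index) != samples:
            self.sample_meta = self.sample_meta.loc[samples]
        if list(self.qpcr.index) != samples:
            self.qpcr = self.qpcr.loc[samples]
        for col in _META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing column {col!r}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.qpcr.values < 0).any():
            raise ValueError("qpcr totals must be non-negative")

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def otus(self) -> pd.Index:
        return self.counts.index

    def proportions(self) -> pd.DataFrame:
        """Column-normalized counts; all-zero columns stay zero."""
        colsum = self.counts.sum(axis=0)
        safe = colsum.replace(0, np.nan)
        return self.counts.div(safe, axis=1).fillna(0.0)

    def restrict(self, fraction_class: str | None = None, treatment: str | None = None,
                 timepoint_day: int | None = None) -> "AbundanceTables":
        """Subset samples by metadata fields."""
        keep = pd.Series(True, index=self.sample_meta.index)
        if fraction_class is not None:
            keep &= self.sample_meta["fraction_class"] == fraction_class
        if treatment is not None:
            keep &= self.sample_meta["treatment"] == treatment
        if timepoint_day is not None:
            keep &= self.sample_meta["timepoint_day"] == timepoint_day
        cols = self.sample_meta.index[keep]
        return AbundanceTables(
            counts=self.counts[cols],
            sample_meta=self.sample_meta.loc[cols],
            qpcr=self.qpcr.loc[cols],
            taxonomy=self.taxonomy,
            flags=list(self.flags),
        )


def absolute_abundance(tables: AbundanceTables) -> pd.DataFrame:
    """Per-OTU absolute abundance A = F x P (copies per g soil).

    Columns whose count total is zero yield all-zero abundances and are
    listed in ``result.attrs['zero_count_samples']``.
    """
    if (tables.qpcr.values < 0).any():
        raise ValueError("negative qPCR total")
    colsum = tables.counts.sum(axis=0)
    zero = list(colsum.index[colsum == 0])
    scale = tables.qpcr / colsum.replace(0, np.nan)
    a = tables.counts.mul(scale, axis=1).fillna(0.0)
    a.attrs["zero_count_samples"] = zero
    return a


def decomposition_statistic(a_t0_mean, a_ti):
    """D = 100 * (A_T0 - A_Ti) / A_T0 in percent.

    ``a_t0_mean`` is the day-0 (replicate-mean) absolute abundance and must
    be positive; ``a_ti`` a scalar or array of later-timepoint abundances.
    Negative D (abundance gain) is returned as-is and handled by the
    positive filter downstream.
    """
    a0 = np.asarray(a_t0_mean, dtype=float)
    if np.any(a0 <= 0):
        raise ValueError("A_T0 mean must be positive for the decomposition statistic")
    d = 100.0 * (a0 - np.asarray(a_ti, dtype=float)) / a0
    return float(d) if np.ndim(d) == 0 else d


def filter_day0_prevalence(tables: AbundanceTables, threshold: float = 0.0005) -> pd.Index:
    """OTUs whose mean day-0 proportion strictly exceeds ``threshold``.

    The threshold default 0.0005 is the "more than 0.05% of sequences at
    day 0" rule; the boundary value itself is excluded.
    """
    day0 = tables.sample_meta.index[tables.sample_meta["timepoint_day"] == 0]
    if len(day0) == 0:
        raise ValueError("no day-0 samples present")
    mean_p = tables.proportions()[day0].mean(axis=1)
    return tables.otus[mean_p > threshold]


def decomposition_table(
    tables: AbundanceTables,
    timepoints: list[int] | None = None,
    *,
    alpha: float = 0.05,
    day0_threshold: float = 0.0005,
    ttest: str = "welch",
    restrict: bool = True,
) -> pd.DataFrame:
    """Per-OTU, per-timepoint decomposition table.

    By default the input is restricted to light-fraction samples of the
    H2_18O treatment (necromass DNA).  For each later timepoint Ti:

    * per-replicate D_i against the day-0 replicate-mean A,
    * D_mean and its standard error over replicates,
    * two-sided t-test (Welch by default) of per-replicate A at T0 vs Ti,
      with BH q-values reported alongside raw p,
    * filter flags: day-0 prevalence and positive mean D.

    ``significant`` is a nullable boolean: defined (p < alpha) only where
    both filters pass, <NA> elsewhere or when p could not be computed.
    """
    if ttest not in ("welch", "student"):
        raise ValueError("ttest must be 'welch' or 'student'")
    equal_var = ttest == "student"
    sub = tables.restrict(fraction_class="light", treatment="H2_18O") if restrict else tables
    meta = sub.sample_meta
    day0_cols = meta.index[meta["timepoint_day"] == 0]
    if len(day0_cols) == 0:
        raise ValueError("no day-0 light-fraction samples for the labeled treatment")
    if timepoints is None:
        timepoints = sorted(set(meta["timepoint_day"]) - {0})
    a = absolute_abundance(sub)
    passing = set(filter_day0_prevalence(sub, threshold=day0_threshold))
    a0 = a[day0_cols]
    a0_mean = a0.mean(axis=1)

    rows = []
    for t in timepoints:
        cols = meta.index[meta["timepoint_day"] == t]
        if len(cols) == 0:
            raise ValueError(f"no samples at timepoint {t}")
        at = a[cols]
        with np.errstate(divide="ignore", invalid="ignore"):
            d = 100.0 * (1.0 - at.div(a0_mean.replace(0, np.nan), axis=0))
        d_mean = d.mean(axis=1)
        nrep = len(cols)
        d_se = d.std(axis=1, ddof=1) / np.sqrt(nrep) if nrep >= 2 else pd.Series(np.nan, index=d.index)
        p = ttest_matrix(a0.values, at.values, equal_var=equal_var)
        p = pd.Series(p, index=a.index)
        pass0 = a.index.isin(passing)
        q = pd.Series(np.nan, index=a.index)
        q[pass0] = benjamini_hochberg(p[pass0].values)
        for i, otu in enumerate(a.index):
            dm = d_mean[otu]
            pos = bool(np.isfinite(dm) and dm > 0)
            if pass0[i] and pos and np.isfinite(p[otu]):
                sig: object = bool(p[otu] < alpha)
            else:
                sig = pd.NA
            rows.append(
                {
                    "otu_id": otu,
                    "timepoint_day": int(t),
                    "d_mean": float(dm) if np.isfinite(dm) else np.nan,
                    "d_se": float(d_se[otu]) if np.isfinite(d_se[otu]) else np.nan,
                    "d_reps": [float(x) for x in d.loc[otu]] if np.isfinite(d.loc[otu]).all() else [],
                    "p_value": float(p[otu]) if np.isfinite(p[otu]) else np.nan,
                    "q_value": float(q[otu]) if np.isfinite(q[otu]) else np.nan,
                    "significant": sig,
                    "passed_day0_filter": bool(pass0[i]),
                    "passed_positive_filter": pos,
                }
            )
    out = pd.DataFrame(rows)
    out["significant"] = out["significant"].astype("boolean")
    return out


def _retained(dtable: pd.DataFrame) -> pd.DataFrame:
    return dtable[dtable["passed_day0_filter"] & dtable["passed_positive_filter"]]


def gram_group_comparison(
    dtable: pd.DataFrame,
    taxonomy: pd.DataFrame,
    *,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Gram-positive vs gram-negative mean decomposition per timepoint.

    Groups are proxied by phylum (positive: Actinobacteria, Firmicutes;
    negative: Acidobacteria, Gemmatimonadetes, Proteobacteria); OTUs outside
    the five phyla are excluded.  The two-sided t-test runs across OTU-level
    D means; an empty or singleton group yields a missing (NaN) p-value.
    """
    phylum = taxonomy["phylum"]
    ret = _retained(dtable)
    rows = []
    for t, grp in ret.groupby("timepoint_day"):
        ph = grp["otu_id"].map(phylum)
        pos = grp.loc[ph.isin(GRAM_POSITIVE_PHYLA), "d_mean"].values
        neg = grp.loc[ph.isin(GRAM_NEGATIVE_PHYLA), "d_mean"].values
        p = ttest_two_sample(pos, neg, equal_var=equal_var) if len(pos) >= 2 and len(neg) >= 2 else float("nan")
        rows.append(
            {
                "timepoint_day": int(t),
                "n_gram_positive": len(pos),
                "n_gram_negative": len(neg),
                "mean_d_gram_positive": float(np.mean(pos)) if len(pos) else np.nan,
                "mean_d_gram_negative": float(np.mean(neg)) if len(neg) else np.nan,
                "p_value": p,
                "significant": bool(p < alpha) if np.isfinite(p) else pd.NA,
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["significant"].astype("boolean")
    return out


def phylum_range_summary(dtable: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Per-phylum, per-timepoint D range with OTU/genus labels.

    Reports, over retained OTUs (both filters passed): OTU count, the min
    and max mean D with the OTUs and genera attaining them, and the
    proportion of retained OTUs flagged significant.
    """
    if dtable.empty:
        raise ValueError("decomposition table is empty")
    ret = _retained(dtable).copy()
    ret["phylum"] = ret["otu_id"].map(taxonomy["phylum"])
    ret["genus"] = ret["otu_id"].map(taxonomy["genus"])
    rows = []
    for (ph, t), grp in ret.groupby(["phylum", "timepoint_day"]):
        imin = grp["d_mean"].idxmin()
        imax = grp["d_mean"].idxmax()
        sig = grp["significant"].fillna(False)
        rows.append(
            {
                "phylum": ph,
                "timepoint_day": int(t),
                "n_otus": len(grp),
                "d_min": float(grp.loc[imin, "d_mean"]),
                "otu_min": grp.loc[imin, "otu_id"],
                "genus_min": grp.loc[imin, "genus"],
                "d_max": float(grp.loc[imax, "d_mean"]),
                "otu_max": grp.loc[imax, "otu_id"],
                "genus_max": grp.loc[imax, "genus"],
                "prop_significant": float(sig.mean()),
            }
        )
    return pd.DataFrame(rows)
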