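"""Community-ecology analyses for taxa and marker-gene tables.

Covers contaminant filtering, proportion normalization, Bray-Curtis
dissimilarity, PERMANOVA, healthy-reference richness bands, two-group
rank-sum comparisons, and RPKM quantification of marker-gene hits.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from scipy.stats import t as t_dist

from .types import FeatureTable, MarkerHitTable, ValidationError

__all__ = [
    "default_blocklist",
    "filter_contaminants",
    "proportion_normalize",
    "bray_curtis_matrix",
    "species_richness_band",
    "permanova",
    "group_compare",
    "rpkm",
    "aggregate_rpkm_by_class",
]


def default_blocklist() -> list[str]:
    """Reagent/ambiguous-provenance taxa removed by default (editable YAML
    shipped with the package)."""
    text = resources.files("clonecensus.data").joinpath("contaminants.yaml").read_text()
    return yaml.safe_load(text)["blocklist"]


def filter_contaminants(
    table: FeatureTable, blocklist: list[str] | None = None
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop features matching the blocklist (exact id or lineage-prefix
    match, case-insensitive) and report the reads removed per sample.

    Returns (filtered table, removal report); unmatched blocklist entries
    are simply reported as matching nothing.
    """
    if blocklist is None:
        blocklist = default_blocklist()
    patterns = [b.lower() for b in blocklist]

    def matches(feature: str) -> bool:
        f = feature.lower()
        parts = f.replace(";", "|").split("|")
        return any(f == p or f.startswith(p + ";") or f.startswith(p + "|") or p in parts
                   for p in patterns)

    hit = [f for f in table.features if matches(f)]
    removed = table.counts.loc[hit]
    kept = table.counts.drop(index=hit)
    report = removed.copy()
    report.insert(0, "feature", report.index)
    report = report.reset_index(drop=True)
    return FeatureTable(kept, table.sample_meta), report


def proportion_normalize(table: FeatureTable) -> FeatureTable:
    """Convert each sample column to proportions of its total."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"zero-sum sample(s): {list(zero.index)}")
    return table.copy_with(table.counts / totals)


def bray_curtis_matrix(table: FeatureTable, normalize: bool = False) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, sum|x-y| / sum(x+y), between
    sample columns.

    Columns are compared as given; pass ``normalize=True`` (or normalize
    upstream) to compare relative compositions when sequencing depth
    differs between samples.
    """
    if len(table.samples) < 2:
        raise ValidationError("need at least 2 samples")
    t = proportion_normalize(table) if normalize else table
    x = t.counts.to_numpy().T
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.samples, columns=table.samples)


def species_richness_band(
    table: FeatureTable,
    reference_group: str,
    level: float = 0.95,
    group_col: str = "group",
    site_col: str = "body_site",
) -> pd.DataFrame:
    """Per-body-site richness reference band from a healthy group.

    Richness is the number of features with nonzero raw counts per sample.
    The band is mean +/- t-quantile * SE over the reference samples of that
    body site; requires at least 2 reference samples per site.
    """
    richness = (table.counts > 0).sum(axis=0)
    meta = table.sample_meta
    ref = meta[meta[group_col] == reference_group]
    if ref.empty:
        raise ValidationError(f"no samples in reference group {reference_group!r}")
    rows = []
    for site, samples in ref.groupby(site_col).groups.items():
        vals = richness.loc[list(samples)].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValidationError(f"need >= 2 reference samples for body site {site!r}")
        mean = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        tq = t_dist.ppf(0.5 + level / 2, df=len(vals) - 1)
        rows.append({
            "body_site": site, "n_reference": len(vals), "mean": mean,
            "ci_low": mean - tq * se, "ci_high": mean + tq * se,
        })
    return pd.DataFrame(rows)


def permanova(
    dissimilarity,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-way PERMANOVA on a distance matrix.

    SS_total = (1/N) sum_{i<j} d_ij^2; SS_within sums within-group pair
    terms scaled by group size; pseudo-F = (SS_between/(g-1)) /
    (SS_within/(N-g)).  The p-value uses free label permutation with the
    Monte-Carlo +1 correction: p = (1 + #{F_perm >= F_obs}) / (1 + B).
    A constant distance matrix has no group structure to detect: F is NaN
    and p is 1.
    """
    d = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if d.shape != (n, n) or len(labels) != n:
        raise ValidationError("distance matrix and labels must agree in size")
    if n_permutations < 99:
        raise ValidationError("use at least 99 permutations")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2]
        raise ValidationError(f"group(s) of size 1: {list(small)}")
    d2 = d**2
    ss_total = d2.sum() / (2 * n)
    if ss_total <= 0:
        return float("nan"), 1.0
    g = len(groups)
    masks0 = np.stack([labels == grp for grp in groups])  # g x n

    def pseudo_f(masks: np.ndarray) -> float:
        ss_within = sum(
            d2[np.ix_(m, m)].sum() / (2 * m.sum()) for m in masks
        )
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return np.inf
        return (ss_between / (g - 1)) / (ss_within / (n - g))

    f_obs = pseudo_f(masks0)
    rng = np.random.default_rng(seed)
    exceed = 0
    idx = np.arange(n)
    for _ in range(n_permutations):
        perm = rng.permutation(idx)
        if pseudo_f(masks0[:, perm]) >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return float(f_obs), float(p)


def group_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two groups.

    Uses exact enumeration when both groups have at most 8 values and no
    ties; otherwise the normal approximation with tie correction.  Returns
    (rank-sum statistic W for the first group, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic + a.size * (a.size + 1) / 2)  # U -> rank-sum W
    return w, float(res.pvalue)


def rpkm(hits: MarkerHitTable) -> pd.DataFrame:
    """Reads per kilobase of target per million sequenced reads:
    count / ((length/1000) * (total_reads/1e6)), per marker per sample."""
    kb = hits.target_length_bp.to_numpy(dtype=float)[:, None] / 1000.0
    millions = hits.total_reads.to_numpy(dtype=float)[None, :] / 1e6
    return pd.DataFrame(
        hits.hits.to_numpy(dtype=float) / (kb * millions),
        index=hits.hits.index, columns=hits.hits.columns,
    )


def aggregate_rpkm_by_class(rpkm_values: pd.DataFrame, marker_class: pd.Series) -> pd.DataFrame:
    """Sum member-marker RPKM values within each marker class (e.g. an
    antibiotic-resistance gene family)."""
    return rpkm_values.groupby(marker_class.loc[rpkm_values.index]).sum()
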