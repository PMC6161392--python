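"""Chao-type population-size estimators and sonic abundance.

Chao1 (abundance-based) and Chao2 (incidence-based across replicates) are
nonparametric lower-bound estimators of species richness.  Both use the
rarest observed classes: Chao1 the singleton/doubleton counts f1/f2, Chao2
the number of species seen in exactly one (Q1) or two (Q2) replicates.

    Chao1 = S_obs + f1^2 / (2 f2)
    Chao2 = S_obs + ((m-1)/m) * Q1^2 / (2 Q2)      (m replicates)

When the doubleton count is zero the bias-corrected fallback
f1 (f1 - 1) / (2 (f2 + 1)) is used (and analogously for Chao2).  Confidence
intervals use the standard log-transform of the estimated excess over
observed richness with the Chao variance formulas.

Sonic abundance estimates the number of cells in one clone from the number
of distinct sheared-fragment lengths observed at its integration site: with
length distribution theta, the expected number of distinct lengths among n
cells is sum_l (1 - (1 - theta_l)^n); the estimate inverts this occupancy
curve at the observed count k.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .types import IntegrationSite, PopulationEstimate, SonicAbundanceEstimate, ValidationError

__all__ = [
    "chao1",
    "chao2",
    "chao_confidence_interval",
    "intsite_abundance_counts",
    "incidence_matrix",
    "estimate_length_distribution",
    "estimate_clone_abundance",
    "sonic_abundance_table",
]

ABUNDANCE_CAP = 1e9


def _chao_core(s_obs: int, r1: int, r2: int, a: float, bias_corrected: bool):
    """Shared Chao arithmetic.  r1/r2 are the rare-class counts (f1/f2 or
    Q1/Q2); a is the small-sample factor ((m-1)/m for Chao2, 1 for Chao1).
    Returns (estimate, used_bias_corrected_branch)."""
    if bias_corrected or r2 == 0:
        return s_obs + a * r1 * (r1 - 1) / (2.0 * (r2 + 1)), True
    return s_obs + a * r1 * r1 / (2.0 * r2), False


def _chao_variance(r1: int, r2: int, a: float, estimate: float) -> float:
    """Chao estimator variance: the classic form when r2 > 0, the
    bias-corrected form otherwise; ``estimate`` is the full point estimate."""
    if r1 == 0:
        return 0.0
    if r2 > 0:
        ratio = r1 / r2
        return r2 * (a / 2 * ratio**2 + a**2 * ratio**3 + a**2 / 4 * ratio**4)
    var = (a * r1 * (r1 - 1) / 2 + a**2 * r1 * (2 * r1 - 1) ** 2 / 4)
    if estimate > 0:
        var -= a**2 * r1**4 / (4 * estimate)
    return max(var, 0.0)


def chao1(counts, bias_corrected: bool = False) -> PopulationEstimate:
    """Chao1 richness estimate from per-species abundance counts.

    ``counts`` is one positive integer per observed species (e.g. deduplicated
    fragment counts per integration site).
    """
    c = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts)
    if c.size == 0:
        raise ValidationError("Chao1 is undefined on an empty sample")
    if not np.issubdtype(c.dtype, np.number) or (c < 1).any():
        raise ValidationError("abundance counts must be positive integers")
    s_obs = int(c.size)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    est, bc = _chao_core(s_obs, f1, f2, 1.0, bias_corrected)
    return PopulationEstimate(
        observed_richness=s_obs, estimate=float(est),
        estimator="chao1_bc" if bc else "chao1",
        singletons=f1, doubletons=f2,
        variance=_chao_variance(f1, f2, 1.0, est),
    )


def chao2(
    incidence,
    bias_corrected: bool = False,
    small_sample_correction: bool = True,
) -> PopulationEstimate:
    """Chao2 richness estimate from a species x replicate incidence matrix.

    Q1/Q2 count species present in exactly one/two replicates.  The
    small-sample factor (m-1)/m is applied by default (m = number of
    replicates); requires m >= 2.
    """
    inc = np.asarray(incidence, dtype=bool) if not isinstance(incidence, pd.DataFrame) else incidence.to_numpy(dtype=bool)
    if inc.ndim != 2:
        raise ValidationError("incidence must be a 2-D species x replicate matrix")
    m = inc.shape[1]
    if m < 2:
        raise ValidationError("Chao2 requires at least 2 replicates")
    per_species = inc.sum(axis=1)
    per_species = per_species[per_species > 0]
    if per_species.size == 0:
        raise ValidationError("Chao2 is undefined with no presences")
    s_obs = int(per_species.size)
    q1 = int((per_species == 1).sum())
    q2 = int((per_species == 2).sum())
    a = (m - 1) / m if small_sample_correction else 1.0
    est, bc = _chao_core(s_obs, q1, q2, a, bias_corrected)
    return PopulationEstimate(
        observed_richness=s_obs, estimate=float(est),
        estimator="chao2_bc" if bc else "chao2",
        singletons=q1, doubletons=q2, n_replicates=m,
        variance=_chao_variance(q1, q2, a, est),
    )


def chao_confidence_interval(est: PopulationEstimate, level: float = 0.95) -> PopulationEstimate:
    """Attach a log-transformed confidence interval to a Chao estimate.

    The interval is built on T = estimate - S_obs:
    K = exp(z * sqrt(log(1 + var/T^2))), CI = [S_obs + T/K, S_obs + T*K],
    which keeps the lower limit at or above the observed richness.  With no
    singletons the interval degenerates to the point estimate.
    """
    s_obs, t = est.observed_richness, est.estimate - est.observed_richness
    var = est.variance if est.variance is not None else 0.0
    if t <= 0 or var <= 0:
        lo = hi = float(est.estimate) if t > 0 else float(s_obs)
    else:
        z = norm.ppf(0.5 + level / 2)
        k = np.exp(z * np.sqrt(np.log1p(var / t**2)))
        lo, hi = s_obs + t / k, s_obs + t * k
    return PopulationEstimate(
        observed_richness=s_obs, estimate=est.estimate, estimator=est.estimator,
        singletons=est.singletons, doubletons=est.doubletons,
        n_replicates=est.n_replicates, ci_low=float(lo), ci_high=float(hi),
        variance=est.variance,
    )


def intsite_abundance_counts(intsites: pd.DataFrame) -> pd.Series:
    """Per-site abundance for Chao1: distinct (replicate, fragment length)
    observations per site summed over replicates.

    Reads with identical site, replicate and fragment length are PCR
    duplicates of one captured fragment and count once.
    """
    dedup = intsites.drop_duplicates(
        subset=["chromosome", "position", "strand", "replicate_id", "fragment_length"]
    )
    return dedup.groupby(["chromosome", "position", "strand"]).size()


def incidence_matrix(
    df: pd.DataFrame,
    feature_cols,
    replicate_col: str = "replicate_id",
) -> pd.DataFrame:
    """Presence/absence of each feature (site or clonotype) per replicate."""
    present = df.drop_duplicates(subset=list(feature_cols) + [replicate_col])
    present = present.assign(_one=1)
    return (
        present.pivot_table(
            index=list(feature_cols), columns=replicate_col, values="_one", fill_value=0
        ).astype(bool)
    )


def estimate_length_distribution(fragment_lengths) -> pd.Series:
    """Empirical shear-fragment length distribution pooled over all sites.

    Returns relative frequencies indexed by length, summing to 1.
    """
    lengths = pd.Series(fragment_lengths)
    if lengths.empty:
        raise ValidationError("need at least one observation")
    freq = lengths.value_counts(normalize=True).sort_index()
    freq.index.name = "fragment_length"
    return freq


def estimate_clone_abundance(
    k: int,
    theta,
    site: IntegrationSite | None = None,
    tol: float = 1e-6,
) -> SonicAbundanceEstimate:
    """Invert the occupancy curve: find n with E[distinct lengths] = k.

    ``theta`` is the fragment-length probability vector; ``k`` the number
    of distinct lengths observed at the site.  k equal to the full support
    (or beyond the cap of 1e9 cells) is flagged saturated.
    """
    th = np.asarray(theta, dtype=float)
    th = th[th > 0]
    if abs(th.sum() - 1.0) > 1e-9:
        raise ValidationError("theta must sum to 1")
    support = th.size
    if not 1 <= k <= support:
        raise ValidationError(f"k={k} outside [1, support={support}]")
    series = pd.Series(th) if not isinstance(theta, pd.Series) else theta

    if k == support:
        return SonicAbundanceEstimate(site, k, float("inf"), True, series)

    log1m = np.log1p(-th)  # theta < 1 here since support >= 2

    def expected_minus_k(n: float) -> float:
        return float(np.sum(-np.expm1(n * log1m)) - k)

    if expected_minus_k(ABUNDANCE_CAP) < 0:
        return SonicAbundanceEstimate(site, k, float("inf"), True, series)
    n_hat = brentq(expected_minus_k, 1e-12, ABUNDANCE_CAP, xtol=tol)
    return SonicAbundanceEstimate(site, k, float(n_hat), False, series)


def sonic_abundance_table(
    intsites: pd.DataFrame,
    em_refine: bool = False,
    em_tol: float = 1e-6,
    em_max_iter: int = 200,
) -> pd.DataFrame:
    """Per-site sonic-abundance estimates for an observation table.

    The fragment-length distribution theta is the pooled empirical
    distribution over all sites; with ``em_refine`` theta and the per-site
    abundances are alternated (theta re-weighted by estimated clone sizes
    spread over each clone's observed lengths) until the abundances move
    less than ``em_tol``.
    """
    dedup = intsites.drop_duplicates(
        subset=["chromosome", "position", "strand", "fragment_length"]
    )
    theta = estimate_length_distribution(intsites["fragment_length"])
    by_site = dedup.groupby(["chromosome", "position", "strand"])["fragment_length"]
    site_lengths = {s: set(v) for s, v in by_site}

    def solve_all(theta_s: pd.Series) -> dict:
        return {
            s: estimate_clone_abundance(len(lens), theta_s)
            for s, lens in site_lengths.items()
        }

    estimates = solve_all(theta)
    if em_refine:
        for _ in range(em_max_iter):
            weights = pd.Series(0.0, index=theta.index)
            for s, lens in site_lengths.items():
                est = estimates[s]
                n = est.abundance if np.isfinite(est.abundance) else float(len(lens))
                weights[list(lens)] += n / len(lens)
            new_theta = weights / weights.sum()
            new_estimates = solve_all(new_theta)
            delta = max(
                abs(min(new_estimates[s].abundance, ABUNDANCE_CAP) - min(estimates[s].abundance, ABUNDANCE_CAP))
                for s in site_lengths
            )
            theta, estimates = new_theta, new_estimates
            if delta < em_tol:
                break
    rows = [
        {
            "chromosome": chrom, "position": pos, "strand": strand,
            "distinct_lengths": est.distinct_lengths,
            "abundance": est.abundance, "saturated": est.saturated,
        }
        for (chrom, pos, strand), est in estimates.items()
    ]
    return pd.DataFrame(rows)
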