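"""TCR-beta CDR3 repertoire analysis.

Classifies rearrangements as in-frame / frameshift / stop, computes richness
and Pielou evenness, V/J segment usage with chi-squared comparison against a
reference cohort, and clonotype-level Bray-Curtis dissimilarity with a t-SNE
embedding.

Clonotype identity is the CDR3 nucleotide string; statistics are computed on
the productive part of the repertoire (in-frame, no stop codon) unless
stated otherwise, because nonproductive rearrangements do not mark
functional T cell clones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.spatial.distance import squareform, pdist
from scipy.stats import chi2 as chi2_dist
from sklearn.manifold import TSNE

from .types import DNA_ALPHABET, UsageProfile, ValidationError

__all__ = [
    "classify_productivity",
    "translate_cdr3",
    "richness",
    "shannon_evenness",
    "clone_frequencies",
    "vj_usage",
    "compare_usage",
    "repertoire_dissimilarity",
    "embed_2d",
]


def classify_productivity(cdr3_nt: str) -> str:
    """Classify a CDR3 nucleotide sequence as in_frame, frameshift or stop.

    The reading frame is anchored at position 1 of the CDR3 (the conserved
    first codon).  A length not divisible by 3 is a frameshift; otherwise
    any stop codon in the translation makes it ``stop``; otherwise
    ``in_frame``.
    """
    if not cdr3_nt or not set(cdr3_nt) <= DNA_ALPHABET:
        raise ValidationError(f"cdr3_nt must be nonempty over ACGT, got {cdr3_nt!r}")
    if len(cdr3_nt) % 3 != 0:
        return "frameshift"
    aa = str(Seq(cdr3_nt).translate())
    return "stop" if "*" in aa else "in_frame"


def translate_cdr3(cdr3_nt: str) -> str:
    """Amino-acid translation of an in-frame CDR3; empty string otherwise."""
    if len(cdr3_nt) % 3 != 0:
        return ""
    aa = str(Seq(cdr3_nt).translate())
    return "" if "*" in aa else aa


def _productive_mask(clonotypes: pd.DataFrame) -> pd.Series:
    return clonotypes["frame_status"] == "in_frame"


def richness(clonotypes: pd.DataFrame, productive_only: bool = True, identity: str = "nt") -> int:
    """Number of unique clonotypes in a sample.

    identity="nt" counts unique CDR3 nucleotide sequences (default);
    identity="aa" collapses to amino-acid sequences.
    """
    if len(clonotypes) == 0:
        return 0
    df = clonotypes[_productive_mask(clonotypes)] if productive_only else clonotypes
    col = "cdr3_nt" if identity == "nt" else "cdr3_aa"
    return int(df[col].nunique())


def clone_frequencies(
    clonotypes: pd.DataFrame, productive_only: bool = True, identity: str = "nt"
) -> pd.Series:
    """Template-count frequencies per clonotype, summed over replicates and
    normalized to 1."""
    df = clonotypes[_productive_mask(clonotypes)] if productive_only else clonotypes
    col = "cdr3_nt" if identity == "nt" else "cdr3_aa"
    totals = df.groupby(col)["template_count"].sum().astype(float)
    if totals.sum() == 0:
        raise ValidationError("sample has zero total template count")
    return totals / totals.sum()


def shannon_evenness(frequencies) -> float:
    """Pielou's evenness J' = H'/ln(S) with natural-log Shannon entropy.

    Returns NaN for S <= 1, where evenness is undefined.
    """
    p = np.asarray(frequencies, dtype=float)
    p = p[p > 0]
    p = p / p.sum()
    s = len(p)
    if s <= 1:
        return float("nan")
    h = -np.sum(p * np.log(p))
    return float(h / np.log(s))


def vj_usage(
    clonotypes: pd.DataFrame,
    segment_kind: str = "V",
    weight: str = "templates",
    order: list[str] | None = None,
) -> UsageProfile:
    """Segment usage proportions over productive clonotypes.

    weight="templates" weights each clonotype by its template count
    (default); weight="clonotypes" counts each unique clonotype once.
    ``order`` fixes the segment ordering (e.g. by a reference cohort's
    prevalence); otherwise segments are ordered by descending proportion.
    """
    df = clonotypes[_productive_mask(clonotypes)].copy()
    if len(df) == 0:
        raise ValidationError("no productive clonotypes")
    if segment_kind == "V":
        key = df["v_gene"]
    elif segment_kind == "J":
        key = df["j_gene"]
    elif segment_kind in ("VJ", "VJ-pair"):
        key = df["v_gene"] + "|" + df["j_gene"]
    else:
        raise ValueError(f"unknown segment_kind {segment_kind!r}")
    if weight == "templates":
        counts = df.groupby(key)["template_count"].sum()
    elif weight == "clonotypes":
        counts = df.groupby(key)["cdr3_nt"].nunique()
    else:
        raise ValueError(f"unknown weight {weight!r}")
    if order is not None:
        counts = counts.reindex(order, fill_value=0)
    else:
        counts = counts.sort_values(ascending=False)
    total = int(counts.sum())
    return UsageProfile(
        segment_kind=segment_kind,
        segments=list(counts.index),
        proportions=(counts / total).to_numpy(),
        total_templates=total,
        counts=counts.to_numpy(),
    )


def compare_usage(
    observed: UsageProfile,
    reference: UsageProfile,
    pool_threshold: float = 5.0,
) -> tuple[float, int, float]:
    """Pearson chi-squared test of observed segment counts against a
    reference usage distribution.

    Expected counts are reference proportions times the observed template
    total, computed over the union of both segment universes.  Segments
    with expected count below ``pool_threshold`` (the Cochran rule), and
    any observed segment with reference proportion zero, are pooled into an
    "other" category before testing.  Returns (chi2, df, p); a degenerate
    single-category table yields (0.0, 0, 1.0).
    """
    obs = pd.Series(
        observed.counts if observed.counts is not None
        else observed.proportions * observed.total_templates,
        index=observed.segments, dtype=float,
    )
    ref = pd.Series(reference.proportions, index=reference.segments, dtype=float)
    universe = list(dict.fromkeys(list(ref.index) + list(obs.index)))
    obs = obs.reindex(universe, fill_value=0.0)
    ref = ref.reindex(universe, fill_value=0.0)
    expected = ref * obs.sum()

    keep = expected >= pool_threshold
    obs_kept = obs[keep]
    exp_kept = expected[keep]
    if (~keep).any():
        other_obs = obs[~keep].sum()
        other_exp = expected[~keep].sum()
        if other_exp >= pool_threshold or obs_kept.empty:
            obs_kept = pd.concat([obs_kept, pd.Series({"other": other_obs})])
            exp_kept = pd.concat([exp_kept, pd.Series({"other": other_exp})])
        else:
            # "other" still under the threshold: fold it into the smallest
            # kept category so every expected count satisfies the rule
            smallest = exp_kept.idxmin()
            obs_kept[smallest] += other_obs
            exp_kept[smallest] += other_exp

    if len(obs_kept) < 2 or exp_kept.min() <= 0:
        return 0.0, 0, 1.0
    stat = float(((obs_kept - exp_kept) ** 2 / exp_kept).sum())
    df = len(obs_kept) - 1
    p = float(chi2_dist.sf(stat, df))
    return stat, df, p


def repertoire_dissimilarity(samples: dict[str, pd.Series]) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between clonotype frequency
    vectors, on the union of all clonotypes.

    ``samples`` maps sample name -> frequency (or count) Series indexed by
    clonotype; vectors are compared as given (normalize upstream to compare
    compositions of unequal depth).  Returns a symmetric zero-diagonal
    DataFrame in [0, 1].
    """
    if len(samples) < 2:
        raise ValidationError("need at least 2 samples")
    names = list(samples)
    mat = pd.DataFrame(samples).fillna(0.0)[names]
    totals = mat.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"samples with zero total: {list(zero.index)}")
    d = squareform(pdist(mat.to_numpy().T, metric="braycurtis"))
    return pd.DataFrame(d, index=names, columns=names)


def embed_2d(
    dissimilarity: pd.DataFrame | np.ndarray,
    seed: int = 0,
    perplexity: float = 5.0,
) -> np.ndarray:
    """t-SNE embedding of a precomputed dissimilarity matrix into 2-D.

    Deterministic for a fixed seed.  Perplexity must be smaller than the
    number of samples.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-9):
        raise ValidationError("dissimilarity must be square and symmetric")
    if perplexity >= n:
        raise ValidationError(f"perplexity ({perplexity}) must be < number of samples ({n})")
    tsne = TSNE(
        n_components=2, metric="precomputed", init="random",
        random_state=seed, perplexity=perplexity,
    )
    return tsne.fit_transform(d)
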