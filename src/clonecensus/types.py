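"""Core record types shared across the package.

Integration sites are 1-based, strand-specific genomic coordinates; a site
identity is the exact triple ``(chromosome, position, strand)``.  TCR-beta
clonotypes are identified by their CDR3 nucleotide sequence.  Population
estimates carry the intermediate singleton/doubleton (or unique/duplicate)
counts so downstream code and reports can audit how the estimate was formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-")
FRAME_STATUSES = ("in_frame", "frameshift", "stop")
DNA_ALPHABET = frozenset("ACGT")


class ValidationError(ValueError):
    """A record or table violates a type invariant."""


@dataclass(frozen=True)
class IntegrationSite:
    """Identity of a vector-host junction: (chromosome, position, strand)."""

    chromosome: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")


@dataclass
class IntegrationSiteObservation:
    """One detected vector-host junction in one sequencing replicate.

    ``fragment_length`` is the sheared-fragment length in bp; distinct
    lengths at the same site mark distinct cells (sonic abundance).
    """

    subject_id: str
    timepoint_months: float
    chromosome: str
    position: int
    strand: str
    replicate_id: str
    fragment_length: int

    def __post_init__(self) -> None:
        if self.timepoint_months < 0:
            raise ValidationError("timepoint_months must be non-negative")
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.fragment_length < 1:
            raise ValidationError("fragment_length must be >= 1")

    @property
    def site(self) -> IntegrationSite:
        return IntegrationSite(self.chromosome, self.position, self.strand)


@dataclass
class TcrClonotype:
    """One rearranged TCR-beta CDR3 with frame classification."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    frame_status: str
    template_count: int
    replicate_id: str

    def __post_init__(self) -> None:
        if not self.cdr3_nt or not set(self.cdr3_nt) <= DNA_ALPHABET:
            raise ValidationError(f"cdr3_nt must be nonempty over ACGT, got {self.cdr3_nt!r}")
        if self.frame_status not in FRAME_STATUSES:
            raise ValidationError(f"frame_status must be one of {FRAME_STATUSES}")
        if self.template_count < 1:
            raise ValidationError("template_count must be >= 1")

    @property
    def productive(self) -> bool:
        return self.frame_status == "in_frame"


@dataclass
class PopulationEstimate:
    """Chao-type lower-bound population size with its intermediate counts.

    ``singletons``/``doubletons`` are f1/f2 for the abundance-based Chao1 and
    Q1/Q2 for the incidence-based Chao2; ``n_replicates`` (m) applies only to
    Chao2.
    """

    observed_richness: int
    estimate: float
    estimator: str  # chao1 | chao1_bc | chao2 | chao2_bc
    singletons: int
    doubletons: int
    n_replicates: int | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    variance: float | None = None

    def __post_init__(self) -> None:
        if self.estimate < self.observed_richness - 1e-9:
            raise ValidationError("estimate must be >= observed richness")

    def as_dict(self) -> dict:
        return {
            "observed_richness": self.observed_richness,
            "estimate": self.estimate,
            "estimator": self.estimator,
            "singletons": self.singletons,
            "doubletons": self.doubletons,
            "n_replicates": self.n_replicates,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass
class SonicAbundanceEstimate:
    """Clone abundance inferred from distinct shear-fragment lengths."""

    site: IntegrationSite | None
    distinct_lengths: int
    abundance: float
    saturated: bool
    length_distribution: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.saturated and self.abundance < self.distinct_lengths - 1e-6:
            raise ValidationError("abundance must be >= distinct length count")


@dataclass
class DivisionEstimate:
    """Minimum-cell-division bound pairing a TCR and an integration-site
    population estimate for one subject/timepoint.

    ``divisions`` is log2(TCRs - IntSites); undefined when the TCR estimate
    does not exceed the integration-site estimate, in which case
    ``undefined_reason`` is set and ``divisions`` is NaN.
    """

    subject_id: str
    timepoint_months: float
    tcr_estimate: float
    intsite_estimate: float
    divisions: float
    divisions_ceil: int | None
    cell_fraction: str = "CD3"
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None and math.isfinite(self.divisions)


class FeatureTable:
    """Feature x sample count matrix (taxa, markers, or clonotypes) with
    per-sample metadata.

    ``counts`` is a features-by-samples DataFrame of non-negative numbers;
    ``sample_meta`` is indexed by sample id with at least the columns
    subject, body_site, timepoint_months, group (missing ones are added
    empty).
    """

    META_COLUMNS = ("subject", "body_site", "timepoint_months", "group")

    def __init__(self, counts: pd.DataFrame, sample_meta: pd.DataFrame):
        counts = counts.copy()
        sample_meta = sample_meta.copy()
        if counts.index.duplicated().any():
            raise ValidationError("duplicate feature ids")
        if counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        orphans = [s for s in counts.columns if s not in sample_meta.index]
        if orphans:
            raise ValidationError(f"samples without metadata: {orphans}")
        for col in self.META_COLUMNS:
            if col not in sample_meta.columns:
                sample_meta[col] = np.nan
        self.counts = counts
        self.sample_meta = sample_meta.loc[list(counts.columns)]

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def copy_with(self, counts: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(counts, self.sample_meta)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.counts, other.counts,
                check_exact=False, rtol=1e-10, check_names=False,
            )
            common = [c for c in self.META_COLUMNS if c in other.sample_meta.columns]
            pd.testing.assert_frame_equal(
                self.sample_meta[list(common)], other.sample_meta[list(common)],
                check_exact=False, rtol=1e-10, check_dtype=False, check_names=False,
            )
        except AssertionError:
            return False
        return True


@dataclass
class MarkerHitTable:
    """Marker-gene hit counts with per-marker target lengths and per-sample
    sequencing depth, as needed for RPKM."""

    hits: pd.DataFrame  # markers x samples
    target_length_bp: pd.Series  # per marker
    total_reads: pd.Series  # per sample
    marker_class: pd.Series | None = None  # optional marker -> class map

    def __post_init__(self) -> None:
        self.target_length_bp = self.target_length_bp.loc[self.hits.index]
        self.total_reads = self.total_reads.loc[self.hits.columns]
        if (self.hits.to_numpy() < 0).any():
            raise ValidationError("hit counts must be non-negative")
        if (self.target_length_bp <= 0).any():
            raise ValidationError("target lengths must be positive")
        if (self.total_reads <= 0).any():
            raise ValidationError("total read counts must be positive")


@dataclass
class UsageProfile:
    """V/J (or V-J pair) segment usage as a probability vector."""

    segment_kind: str  # V | J | VJ
    segments: list[str]
    proportions: np.ndarray
    total_templates: int
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if len(self.segments) != len(self.proportions):
            raise ValidationError("one proportion per segment required")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValidationError("proportions must sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.segments, name=self.segment_kind)
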