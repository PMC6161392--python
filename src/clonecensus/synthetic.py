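"""Synthetic clonal and community data with known ground truth.

The generator emulates a gene-therapy clone-tracking experiment: a pool of
progenitor cells, each uniquely marked by a vector integration site, expands
by synchronous doubling (a Galton-Watson process with i.i.d. per-division
survival), acquires VDJ-rearranged TCR-beta clonotypes, and is then sampled
in replicate sequencing reactions with optional capture bias.  Every
quantity the estimators try to recover — the number of progenitors, clone
sizes, the number of distinct clonotypes, the true division count — is
recorded as ground truth, so estimators are testable by parameter recovery.

Lineages rearrange their TCR at a configurable depth ``rearrangement_depth``
(r): every surviving branch of a progenitor's lineage tree at depth r gets
its own clonotype, so the number of distinct TCRs can exceed the number of
integration sites, as in real thymic ontogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .repertoire import classify_productivity, translate_cdr3
from .types import FeatureTable, IntegrationSite, TcrClonotype, ValidationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_progenitor_pool",
    "simulate_expansion",
    "generate_vdj_clonotype",
    "simulate_replicate_sampling",
    "simulate_community",
    "simulate_dataset",
]

# Toy germline segments: short, start with the conserved Cys codon (TGT) on
# the V side.  Realistic human germline sets are deliberately out of scope.
DEFAULT_V_SEGMENTS = {
    "TRBV-1": "TGTGCCAGCAGC",
    "TRBV-2": "TGTGCCAGTAGT",
    "TRBV-3": "TGTTCCGCCAGA",
    "TRBV-4": "TGTGCTTGGAGT",
    "TRBV-5": "TGTCAAGAAGGG",
}
DEFAULT_J_SEGMENTS = {
    "TRBJ-1": "AATGAACAGTTCTTC",
    "TRBJ-2": "AGCTACGAGCAGTAC",
    "TRBJ-3": "ACCGGGGAGCTGTTT",
}


class ConfigError(ValueError):
    """Simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Study-design parameters for the clonal simulator.

    Defaults reflect the experimental design the simulator emulates:
    quadruplicate sequencing reactions (to suppress PCR jackpotting) and a
    shear-fragment length spread of 50-250 bp.
    """

    n_progenitors: int = 100
    divisions: int = 10
    per_division_loss: float = 0.0
    n_replicates: int = 4
    reads_per_replicate: int = 10_000
    genome_model: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 10_000_000)])
    fragment_length_model: tuple = ("uniform", 50, 250)
    productive_fraction: float = 0.8
    v_segments: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_V_SEGMENTS))
    j_segments: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_J_SEGMENTS))
    insertion_length_model: tuple = ("uniform", 0, 12)
    rearrangement_depth: int = 0
    capture_bias_sigma: float = 0.0
    subject_id: str = "S1"
    timepoint_months: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("per_division_loss", "productive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_progenitors < 1 or self.n_replicates < 1 or self.divisions < 0:
            raise ConfigError("n_progenitors, n_replicates must be >= 1 and divisions >= 0")
        if not 0 <= self.rearrangement_depth <= self.divisions:
            raise ConfigError("rearrangement_depth must be in [0, divisions]")
        if any(length < 1 for _, length in self.genome_model):
            raise ConfigError("genome lengths must be >= 1")
        if not self.v_segments or not self.j_segments:
            raise ConfigError("segment lists must be nonempty")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Everything the simulator knows that an estimator must recover.

    ``branches`` has one row per surviving lineage branch: the marking site,
    the clonotype index into ``clonotypes``, and the final cell count.
    """

    sites: list[IntegrationSite]
    true_divisions: int
    branches: pd.DataFrame | None = None
    clonotypes: list[TcrClonotype] | None = None

    @property
    def n_progenitors(self) -> int:
        return len(self.sites)

    @property
    def clone_sizes(self) -> dict[IntegrationSite, int]:
        sizes = {s: 0 for s in self.sites}
        if self.branches is not None:
            grouped = self.branches.groupby(["chromosome", "position", "strand"])["cell_count"].sum()
            for (chrom, pos, strand), n in grouped.items():
                sizes[IntegrationSite(chrom, int(pos), strand)] = int(n)
        return sizes

    @property
    def n_distinct_clonotypes(self) -> int:
        if self.clonotypes is None:
            return 0
        return len({c.cdr3_nt for c in self.clonotypes})


def simulate_progenitor_pool(config: SimulationConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Mark ``n_progenitors`` progenitors with distinct integration sites
    drawn uniformly over the genome model (both strands), without collision.
    """
    config.validate()
    rng = rng or config.rng()
    lengths = np.array([length for _, length in config.genome_model], dtype=np.int64)
    n_slots = 2 * int(lengths.sum())
    if config.n_progenitors > n_slots:
        raise ConfigError(
            f"genome has {n_slots} strand-specific positions, cannot host "
            f"{config.n_progenitors} distinct sites"
        )
    chosen: set[int] = set()
    while len(chosen) < config.n_progenitors:
        need = config.n_progenitors - len(chosen)
        for x in rng.integers(0, n_slots, size=max(need * 2, 16)):
            chosen.add(int(x))
            if len(chosen) == config.n_progenitors:
                break
    bounds = np.cumsum(lengths)
    sites = []
    for slot in sorted(chosen):
        strand = "+" if slot < n_slots // 2 else "-"
        offset = slot % (n_slots // 2)
        chrom_idx = int(np.searchsorted(bounds, offset, side="right"))
        start = 0 if chrom_idx == 0 else int(bounds[chrom_idx - 1])
        sites.append(IntegrationSite(config.genome_model[chrom_idx][0], offset - start + 1, strand))
    return GroundTruth(sites=sites, true_divisions=config.divisions)


def _branch_survival(sizes: np.ndarray, rounds: int, loss: float, rng) -> np.ndarray:
    """Advance a vector of subpopulation sizes through synchronous doubling
    rounds; each daughter survives each round independently with
    probability 1 - loss."""
    sizes = sizes.astype(np.int64).copy()
    for _ in range(rounds):
        if loss == 0.0:
            sizes *= 2
        else:
            sizes = rng.binomial(2 * sizes, 1.0 - loss)
    return sizes


def simulate_expansion(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    assign_clonotypes: bool = True,
) -> GroundTruth:
    """Expand each progenitor through ``divisions`` doubling rounds.

    The lineage splits into branch founders at ``rearrangement_depth``; each
    surviving branch is assigned its own VDJ clonotype.  With zero loss
    every clone size equals exactly 2**divisions.
    """
    config.validate()
    rng = rng or config.rng()
    r, d, loss = config.rearrangement_depth, config.divisions, config.per_division_loss

    # cells alive at depth r per progenitor = branch founders
    founders = _branch_survival(np.ones(len(truth.sites), dtype=np.int64), r, loss, rng)
    rows = []
    branch_sizes = []
    for site, k in zip(truth.sites, founders):
        for _ in range(int(k)):
            rows.append((site.chromosome, site.position, site.strand))
            branch_sizes.append(1)
    sizes = _branch_survival(np.array(branch_sizes, dtype=np.int64), d - r, loss, rng)
    keep = sizes > 0
    branches = pd.DataFrame(
        [row for row, k in zip(rows, keep) if k],
        columns=["chromosome", "position", "strand"],
    )
    branches["cell_count"] = sizes[keep]

    clonotypes: list[TcrClonotype] | None = None
    if assign_clonotypes:
        clonotypes = [generate_vdj_clonotype(config, rng) for _ in range(len(branches))]
        branches["clonotype_index"] = np.arange(len(branches))
    return GroundTruth(
        sites=truth.sites, true_divisions=d, branches=branches, clonotypes=clonotypes
    )


_BASES = np.array(list("ACGT"))


def _draw_lengths(model: tuple, rng, size: int) -> np.ndarray:
    kind = model[0]
    if kind == "uniform":
        return rng.integers(model[1], model[2] + 1, size=size)
    if kind == "geometric":
        p = model[1]
        minimum = model[2] if len(model) > 2 else 1
        return minimum + rng.geometric(p, size=size) - 1
    raise ConfigError(f"unknown length model {model!r}")


def _draw_length(model: tuple, rng) -> int:
    return int(_draw_lengths(model, rng, 1)[0])


def generate_vdj_clonotype(
    config: SimulationConfig,
    rng: np.random.Generator,
    productive: bool | None = None,
) -> TcrClonotype:
    """Draw one VDJ-rearranged clonotype: V segment + non-templated
    insertion + J segment.

    The target class is Bernoulli(productive_fraction) unless forced via
    ``productive``; the insertion length is adjusted (and the sequence
    resampled on stop codons) until the realized frame class matches, so
    the realized productive fraction matches the configured one in
    expectation.
    """
    if not config.v_segments or not config.j_segments:
        raise ConfigError("segment lists must be nonempty")
    if productive is None:
        productive = bool(rng.random() < config.productive_fraction)
    v_names = list(config.v_segments)
    j_names = list(config.j_segments)
    for _ in range(1000):
        v = v_names[int(rng.integers(len(v_names)))]
        j = j_names[int(rng.integers(len(j_names)))]
        vs, js = config.v_segments[v], config.j_segments[j]
        ins_len = _draw_length(config.insertion_length_model, rng)
        if productive:
            # pad the insertion so the total length is a codon multiple
            ins_len += (-(len(vs) + len(js) + ins_len)) % 3
        ins = "".join(_BASES[rng.integers(0, 4, size=ins_len)])
        nt = vs + ins + js
        status = classify_productivity(nt)
        if productive and status == "in_frame":
            return TcrClonotype(nt, translate_cdr3(nt), v, j, status, 1, "")
        if not productive and status != "in_frame":
            return TcrClonotype(nt, "", v, j, status, 1, "")
    raise ConfigError("failed to generate a clonotype of the requested class")


def simulate_replicate_sampling(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample sequencing replicates from the expanded pool.

    Each replicate draws ``reads_per_replicate`` cells with replacement,
    with probability proportional to clone-branch size (optionally distorted
    by lognormal capture bias per branch per replicate, emulating PCR
    jackpotting).  Each sampled cell yields one integration-site
    observation with a fresh shear-fragment length, and one template toward
    its clonotype's per-replicate template count.
    """
    config.validate()
    if truth.branches is None or truth.clonotypes is None:
        raise ConfigError("expansion with clonotypes must run before sampling")
    rng = rng or config.rng()
    branches = truth.branches
    weights = branches["cell_count"].to_numpy(dtype=float)

    chrom = branches["chromosome"].to_numpy()
    pos = branches["position"].to_numpy()
    strand = branches["strand"].to_numpy()
    intsite_frames = []
    clono_rows = []
    for rep in range(1, config.n_replicates + 1):
        rep_id = f"R{rep}"
        if config.reads_per_replicate == 0 or weights.sum() == 0:
            continue
        w = weights.copy()
        if config.capture_bias_sigma > 0:
            w *= rng.lognormal(0.0, config.capture_bias_sigma, size=len(w))
        draws = rng.multinomial(config.reads_per_replicate, w / w.sum())
        idx = np.repeat(np.arange(len(draws)), draws)
        intsite_frames.append(pd.DataFrame({
            "subject_id": config.subject_id,
            "timepoint_months": config.timepoint_months,
            "chromosome": chrom[idx],
            "position": pos[idx],
            "strand": strand[idx],
            "replicate_id": rep_id,
            "fragment_length": _draw_lengths(config.fragment_length_model, rng, len(idx)),
        }))
        for b_idx in np.nonzero(draws)[0]:
            c = truth.clonotypes[int(branches["clonotype_index"].iloc[b_idx])]
            clono_rows.append((c.cdr3_nt, c.cdr3_aa, c.v_gene, c.j_gene,
                               c.frame_status, int(draws[b_idx]), rep_id))
    empty_cols = [
        "subject_id", "timepoint_months", "chromosome", "position",
        "strand", "replicate_id", "fragment_length",
    ]
    intsites = (
        pd.concat(intsite_frames, ignore_index=True)
        if intsite_frames else pd.DataFrame(columns=empty_cols)
    )
    clonotypes = pd.DataFrame(clono_rows, columns=[
        "cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "frame_status",
        "template_count", "replicate_id",
    ])
    if len(clonotypes):
        # branches can rarely draw identical sequences; aggregate by identity
        clonotypes = (
            clonotypes.groupby(
                ["cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "frame_status", "replicate_id"],
                as_index=False, sort=False,
            )["template_count"].sum()
        )[clonotypes.columns]
        clonotypes["subject_id"] = config.subject_id
        clonotypes["timepoint_months"] = config.timepoint_months
    if len(intsites) == 0:
        clonotypes = pd.DataFrame(columns=list(clonotypes.columns))
    return intsites, clonotypes


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: pool -> expansion -> replicate sampling.

    Returns (truth, intsite observations, clonotype table), all driven by a
    single generator seeded from the config.
    """
    rng = config.rng()
    truth = simulate_progenitor_pool(config, rng)
    truth = simulate_expansion(truth, config, rng)
    intsites, clonotypes = simulate_replicate_sampling(truth, config, rng)
    return truth, intsites, clonotypes


def simulate_community(
    n_taxa: int,
    n_samples: int,
    group_effect: float = 0.0,
    seed: int = 0,
    body_site: str = "stool",
    base_log_mean: float = 2.0,
    base_log_sd: float = 1.0,
    sample_log_sd: float = 0.7,
) -> FeatureTable:
    """Simulate a taxa x sample count table with two-group block structure.

    Per-taxon log abundances are normal (so abundances are log-normal);
    group "B" samples get a mean shift of ``group_effect`` (natural-log
    units) on a random half of taxa.  Counts are Poisson draws around the
    log-normal intensities.  group_effect=0 gives an exchangeable null.
    """
    if n_taxa < 2 or n_samples < 2:
        raise ConfigError("need n_taxa >= 2 and n_samples >= 2")
    rng = np.random.default_rng(seed)
    base = rng.normal(base_log_mean, base_log_sd, size=n_taxa)
    shifted = rng.permutation(n_taxa) < n_taxa // 2
    groups = np.array(["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2))
    log_lambda = np.tile(base[:, None], (1, n_samples))
    log_lambda += rng.normal(0.0, sample_log_sd, size=(n_taxa, n_samples))
    log_lambda[np.ix_(shifted, groups == "B")] += group_effect
    counts = rng.poisson(np.exp(log_lambda))
    sample_ids = [f"samp{i+1:02d}" for i in range(n_samples)]
    counts_df = pd.DataFrame(
        counts, index=[f"taxon{i+1:03d}" for i in range(n_taxa)], columns=sample_ids
    )
    meta = pd.DataFrame({
        "subject": sample_ids,
        "body_site": body_site,
        "timepoint_months": 0.0,
        "group": groups,
    }, index=pd.Index(sample_ids, name="sample_id"))
    return FeatureTable(counts_df, meta)
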