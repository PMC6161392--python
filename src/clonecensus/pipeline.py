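"""End-to-end orchestration: simulate -> estimate -> divisions -> ecology.

A run is driven by a flat YAML config (paths, estimator options, seeds) and
writes a deterministic bundle of TSV outputs plus a manifest recording the
config hash and library versions, so a manifest suffices to reproduce every
number exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ecology import bray_curtis_matrix, default_blocklist, filter_contaminants, permanova
from .io_formats import (
    read_clonotype_table,
    read_feature_table,
    read_intsite_table,
)
from .models import CloneCensus
from .repertoire import clone_frequencies, richness, shannon_evenness

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    output_dir: str = "clonecensus_out"
    intsites: str | None = None
    clonotypes: str | None = None
    feature_counts: str | None = None
    feature_meta: str | None = None
    blocklist: str | None = None  # YAML with a `blocklist:` list; default shipped list
    bias_corrected: bool = False
    merge_window: int = 0
    conf_level: float = 0.95
    min_replicates: int = 2
    permanova_group: str = "body_site"
    n_permutations: int = 999
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"config: unknown key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _stage(name: str, path):
    if path is not None and not Path(path).exists():
        raise PipelineError(f"stage {name}: input file not found: {path}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the config provides inputs for.

    Emits estimates.tsv, divisions.tsv, repertoire_metrics.tsv, an
    ecology/ directory, and manifest.json under ``config.output_dir``.
    Returns the manifest dict.
    """
    logging.basicConfig(level=config.log_level, format="%(levelname)s %(name)s %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[str] = []

    for name, path in (("intsites", config.intsites), ("clonotypes", config.clonotypes),
                       ("features", config.feature_counts), ("features", config.feature_meta)):
        _stage(name, path)

    intsites = clonotypes = None
    if config.intsites:
        logger.info("stage intsites: reading %s", config.intsites)
        intsites = read_intsite_table(config.intsites, merge_window=config.merge_window)
    if config.clonotypes:
        logger.info("stage clonotypes: reading %s", config.clonotypes)
        clonotypes = read_clonotype_table(config.clonotypes)

    if intsites is not None or clonotypes is not None:
        model = CloneCensus(intsites, clonotypes)
        results = model.fit(
            bias_corrected=config.bias_corrected,
            conf_level=config.conf_level,
            min_replicates=config.min_replicates,
        )
        results.estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
        produced.append("estimates.tsv")
        if len(results.divisions):
            results.divisions.to_csv(out / "divisions.tsv", sep="\t", index=False)
            produced.append("divisions.tsv")
        (out / "summary.txt").write_text(results.summary() + "\n")
        produced.append("summary.txt")

    if clonotypes is not None and len(clonotypes):
        rows = []
        for (subj, tp), grp in clonotypes.groupby(["subject_id", "timepoint_months"]):
            freqs = clone_frequencies(grp)
            rows.append({
                "subject_id": subj, "timepoint_months": tp,
                "richness": richness(grp),
                "evenness": shannon_evenness(freqs),
                "total_templates": int(grp["template_count"].sum()),
            })
        pd.DataFrame(rows).to_csv(out / "repertoire_metrics.tsv", sep="\t", index=False)
        produced.append("repertoire_metrics.tsv")

    if config.feature_counts and config.feature_meta:
        eco_dir = out / "ecology"
        eco_dir.mkdir(exist_ok=True)
        table = read_feature_table(config.feature_counts, config.feature_meta)
        blocklist = default_blocklist()
        if config.blocklist:
            with open(config.blocklist) as fh:
                blocklist = yaml.safe_load(fh)["blocklist"]
        table, removal = filter_contaminants(table, blocklist)
        removal.to_csv(eco_dir / "removed_contaminants.tsv", sep="\t", index=False)
        bc = bray_curtis_matrix(table, normalize=True)
        bc.to_csv(eco_dir / "bray_curtis.tsv", sep="\t")
        labels = table.sample_meta[config.permanova_group]
        perm_result = {}
        if labels.notna().all() and labels.nunique() >= 2 and (labels.value_counts() >= 2).all():
            f, p = permanova(bc.to_numpy(), labels.to_numpy(),
                             n_permutations=config.n_permutations, seed=config.seed)
            perm_result = {"group": config.permanova_group, "pseudo_F": f, "p": p,
                           "n_permutations": config.n_permutations}
        (eco_dir / "permanova.json").write_text(json.dumps(perm_result, indent=2) + "\n")
        produced += ["ecology/removed_contaminants.tsv", "ecology/bray_curtis.tsv",
                     "ecology/permanova.json"]

    manifest = {
        "clonecensus_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "outputs": produced,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def render_report(output_dir) -> str:
    """Render a markdown summary of a completed (or partial) run bundle.

    Missing sections are marked absent rather than failing, and rendering
    is idempotent: the same bundle always yields the same text.
    """
    out = Path(output_dir)
    parts = ["# Clone census report", ""]
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        parts += [f"Config hash: `{manifest['config_hash']}` "
                  f"(clonecensus {manifest['clonecensus_version']})", ""]
    for title, rel in [
        ("Population estimates", "estimates.tsv"),
        ("Minimum cell divisions", "divisions.tsv"),
        ("Repertoire metrics", "repertoire_metrics.tsv"),
    ]:
        parts.append(f"## {title}")
        path = out / rel
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            parts += ["", df.to_markdown(index=False), ""]
        else:
            parts += ["", "_section absent_", ""]
    parts.append("## Community ecology")
    perm = out / "ecology" / "permanova.json"
    if perm.exists():
        res = json.loads(perm.read_text())
        if res:
            parts += ["", f"PERMANOVA on `{res['group']}`: pseudo-F = "
                          f"{res['pseudo_F']:.3f}, p = {res['p']:.4g} "
                          f"({res['n_permutations']} permutations)", ""]
        else:
            parts += ["", "PERMANOVA not run (insufficient group structure)", ""]
    else:
        parts += ["", "_section absent_", ""]
    text = "\n".join(parts)
    (out / "report.md").write_text(text)
    return text
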