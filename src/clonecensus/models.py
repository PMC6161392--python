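"""Model/results interface for the clone-census analysis.

``CloneCensus`` is the modelling front end: it takes an integration-site
observation table and/or a TCR-beta clonotype table, and ``fit()`` returns a
``CloneCensusResults`` carrying per-(subject, timepoint) population
estimates (Chao1 for progenitors from integration sites, Chao2 for
clonotypes from replicate incidence), their confidence intervals, the
minimum-cell-division bounds pairing the two, and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimators import (
    chao1,
    chao2,
    chao_confidence_interval,
    incidence_matrix,
    intsite_abundance_counts,
)
from .ontogeny import division_bound, longitudinal_summary
from .types import DivisionEstimate, ValidationError


class CloneCensus:
    """Clonal population-size model for one cohort.

    Parameters
    ----------
    intsites
        Integration-site observation table (io_formats.read_intsite_table
        layout) or None.
    clonotypes
        TCR-beta clonotype table with subject_id/timepoint_months columns,
        or None.  Clonotype identity is the CDR3 nucleotide sequence of
        productive rearrangements.
    """

    def __init__(
        self,
        intsites: pd.DataFrame | None = None,
        clonotypes: pd.DataFrame | None = None,
    ):
        if intsites is None and clonotypes is None:
            raise ValidationError("need at least one of intsites/clonotypes")
        if clonotypes is not None and "subject_id" not in clonotypes.columns:
            clonotypes = clonotypes.assign(subject_id="S1", timepoint_months=0.0)
        self.intsites = intsites
        self.clonotypes = clonotypes

    @classmethod
    def from_files(cls, intsite_path=None, clonotype_path=None) -> "CloneCensus":
        from .io_formats import read_clonotype_table, read_intsite_table

        ins = read_intsite_table(intsite_path) if intsite_path else None
        clo = read_clonotype_table(clonotype_path) if clonotype_path else None
        return cls(ins, clo)

    def fit(
        self,
        bias_corrected: bool = False,
        conf_level: float = 0.95,
        min_replicates: int = 2,
    ) -> "CloneCensusResults":
        """Estimate population sizes per (subject, timepoint) and pair them
        into division bounds.

        Chao2 groups with fewer than ``min_replicates`` replicates are
        reported with an NaN estimate and a reason, mirroring how samples
        without replicates cannot support an incidence estimator.
        """
        rows = []
        if self.intsites is not None and len(self.intsites):
            for (subj, tp), grp in self.intsites.groupby(["subject_id", "timepoint_months"]):
                est = chao_confidence_interval(
                    chao1(intsite_abundance_counts(grp), bias_corrected), conf_level
                )
                rows.append({"subject_id": subj, "timepoint_months": tp,
                             "kind": "intsites", **est.as_dict(), "note": ""})
        if self.clonotypes is not None and len(self.clonotypes):
            productive = self.clonotypes[self.clonotypes["frame_status"] == "in_frame"]
            for (subj, tp), grp in productive.groupby(["subject_id", "timepoint_months"]):
                n_reps = grp["replicate_id"].nunique()
                if n_reps < min_replicates:
                    rows.append({
                        "subject_id": subj, "timepoint_months": tp, "kind": "tcr",
                        "observed_richness": grp["cdr3_nt"].nunique(),
                        "estimate": float("nan"), "estimator": "chao2",
                        "singletons": np.nan, "doubletons": np.nan,
                        "n_replicates": n_reps, "ci_low": np.nan, "ci_high": np.nan,
                        "note": f"fewer than {min_replicates} replicates",
                    })
                    continue
                inc = incidence_matrix(grp, ["cdr3_nt"])
                est = chao_confidence_interval(chao2(inc, bias_corrected), conf_level)
                rows.append({"subject_id": subj, "timepoint_months": tp,
                             "kind": "tcr", **est.as_dict(), "note": ""})
        estimates = pd.DataFrame(rows)
        divisions = self._pair_divisions(estimates)
        return CloneCensusResults(self, estimates, divisions)

    def _pair_divisions(self, estimates: pd.DataFrame) -> list[DivisionEstimate]:
        if estimates.empty:
            return []
        cell_fraction = {}
        if self.clonotypes is not None and "cell_fraction" in self.clonotypes.columns:
            for (subj, tp), grp in self.clonotypes.groupby(["subject_id", "timepoint_months"]):
                cell_fraction[(subj, tp)] = grp["cell_fraction"].iloc[0]
        out = []
        wide = estimates.pivot_table(
            index=["subject_id", "timepoint_months"], columns="kind",
            values="estimate", aggfunc="first",
        )
        for (subj, tp), row in wide.iterrows():
            tcr = row.get("tcr", np.nan)
            ins = row.get("intsites", np.nan)
            if np.isnan(tcr) or np.isnan(ins):
                continue
            out.append(division_bound(
                tcr, ins, subject_id=subj, timepoint_months=tp,
                cell_fraction=cell_fraction.get((subj, tp), "CD3"),
            ))
        return out


class CloneCensusResults:
    """Fitted clone-census estimates.

    Attributes
    ----------
    estimates : DataFrame
        One row per (subject, timepoint, kind) with observed richness, the
        Chao estimate, its intermediate counts and CI.
    divisions : DataFrame
        Minimum-cell-division bounds for every subject/timepoint with both
        estimates (empty when only one table was modelled).
    cohort : dict | None
        Median/min/max of the defined division bounds.
    """

    def __init__(self, model: CloneCensus, estimates: pd.DataFrame,
                 divisions: list[DivisionEstimate]):
        self.model = model
        self.estimates = estimates
        self._division_estimates = divisions
        self.divisions = pd.DataFrame()
        self.cohort = None
        if divisions:
            if any(d.defined for d in divisions):
                self.divisions, self.cohort = longitudinal_summary(divisions)
            else:
                # all bounds undefined (TCR estimate <= site estimate):
                # keep the flagged rows, no cohort summary to compute
                self.divisions = pd.DataFrame([{
                    "subject_id": d.subject_id,
                    "timepoint_months": d.timepoint_months,
                    "tcr_estimate": d.tcr_estimate,
                    "intsite_estimate": d.intsite_estimate,
                    "divisions": d.divisions,
                    "divisions_ceil": d.divisions_ceil,
                    "cell_fraction": d.cell_fraction,
                    "undefined_reason": d.undefined_reason,
                } for d in divisions])

    def summary(self) -> str:
        lines = ["Clone census", "=" * 60]
        if len(self.estimates):
            lines.append("Population estimates (Chao lower bounds):")
            cols = ["subject_id", "timepoint_months", "kind", "observed_richness",
                    "estimate", "ci_low", "ci_high", "estimator"]
            lines.append(self.estimates[cols].to_string(index=False, float_format=lambda v: f"{v:.1f}"))
        if len(self.divisions):
            lines.append("")
            lines.append("Minimum cell divisions, log2(TCRs - IntSites):")
            cols = ["subject_id", "timepoint_months", "tcr_estimate",
                    "intsite_estimate", "divisions", "divisions_ceil"]
            lines.append(self.divisions[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
            if self.cohort is not None:
                c = self.cohort
                lines.append(
                    f"Cohort: median {c['median']:.1f}, min {c['min']:.1f}, "
                    f"max {c['max']:.1f} ({c['n_defined']} defined, "
                    f"{c['n_undefined']} undefined)"
                )
            else:
                lines.append("Cohort: no defined division bounds")
        return "\n".join(lines)
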