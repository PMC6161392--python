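"""Minimum-cell-division ontogeny bound.

A unique vector integration site marks one transduced progenitor; a unique
TCR-beta CDR3 marks one T cell clone.  Because every clonotype beyond the
progenitor count requires at least one extra division somewhere in the
lineage tree, the smallest number of divisions consistent with the two
population estimates is

    CellDivisions = log2(TCRs - IntSites)

where TCRs and IntSites are the Chao-reconstructed population sizes.  The
bound is a minimum: thymic cell death only increases the true division
count.  An alternative per-progenitor reading, log2(TCRs / IntSites), is
provided as a clearly labeled variant.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import DivisionEstimate, ValidationError

__all__ = ["division_bound", "division_bound_ratio", "longitudinal_summary"]


def division_bound(
    tcr_estimate: float,
    intsite_estimate: float,
    subject_id: str = "",
    timepoint_months: float = float("nan"),
    cell_fraction: str = "CD3",
) -> DivisionEstimate:
    """Minimum divisions as log2(TCR estimate - integration-site estimate).

    Both estimates must be positive.  When the TCR estimate does not exceed
    the integration-site estimate the bound is undefined; the result is
    flagged with a reason code instead of being dropped.
    """
    if tcr_estimate <= 0 or intsite_estimate <= 0:
        raise ValidationError("population estimates must be positive")
    diff = tcr_estimate - intsite_estimate
    if diff <= 0:
        return DivisionEstimate(
            subject_id, timepoint_months, tcr_estimate, intsite_estimate,
            float("nan"), None, cell_fraction,
            undefined_reason="tcr_estimate_not_greater_than_intsite_estimate",
        )
    divisions = math.log2(diff)
    return DivisionEstimate(
        subject_id, timepoint_months, tcr_estimate, intsite_estimate,
        divisions, math.ceil(divisions), cell_fraction,
    )


def division_bound_ratio(tcr_estimate: float, intsite_estimate: float) -> float:
    """Per-progenitor variant: log2(TCR estimate / integration-site
    estimate), i.e. doublings needed for each progenitor to account for its
    share of the clonotype pool."""
    if tcr_estimate <= 0 or intsite_estimate <= 0:
        raise ValidationError("population estimates must be positive")
    if tcr_estimate < intsite_estimate:
        raise ValidationError("ratio bound requires tcr_estimate >= intsite_estimate")
    return math.log2(tcr_estimate / intsite_estimate)


def longitudinal_summary(estimates: list[DivisionEstimate]):
    """Per-subject division-bound series plus cohort summary.

    Undefined estimates are excluded and counted, never silently dropped.
    Returns (per-estimate DataFrame, cohort dict with median/min/max and
    n_undefined).
    """
    if not estimates:
        raise ValidationError("no estimates given")
    rows = [{
        "subject_id": e.subject_id,
        "timepoint_months": e.timepoint_months,
        "tcr_estimate": e.tcr_estimate,
        "intsite_estimate": e.intsite_estimate,
        "divisions": e.divisions,
        "divisions_ceil": e.divisions_ceil,
        "cell_fraction": e.cell_fraction,
        "undefined_reason": e.undefined_reason,
    } for e in estimates]
    df = pd.DataFrame(rows).sort_values(["subject_id", "timepoint_months"]).reset_index(drop=True)
    defined = df[df["undefined_reason"].isna()]["divisions"].dropna()
    if defined.empty:
        raise ValidationError("all division estimates are undefined")
    cohort = {
        "median": float(np.median(defined)),
        "min": float(defined.min()),
        "max": float(defined.max()),
        "n_defined": int(len(defined)),
        "n_undefined": int(len(df) - len(defined)),
    }
    return df, cohort
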