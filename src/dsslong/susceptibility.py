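"""Severity analysis: mild/severe sections, fold changes, biomarker links.

Each inflammatory index (fecal Lcn2, MPO, Hgb) splits the treated
(dose, day) groups into a mild section 'A' and a severe section 'B' by a
threshold on the index value; the negative-control groups (0% dose plus
day 0 of every dose) stay outside both. Per-genus fold changes of the mean
section RA over the mean control RA describe how each taxon responds as
colitis worsens, and pooled group-level Pearson correlations between genus
RA and each index (selected at |r| > 0.6, p < 0.05) link taxa to
neutrophil-derived inflammation versus intestinal bleeding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import BiomarkerTable, CohortValidationError
from .stats_core import CorrelationResult, pearson

BIOMARKER_R_THRESHOLD = 0.6
BIOMARKER_P_THRESHOLD = 0.05

SECTION_MILD = "A"
SECTION_SEVERE = "B"
SECTION_CONTROL = "control"

DYN_INCREASE = "consistent-increase"
DYN_DECREASE = "consistent-decrease"
DYN_DYNAMIC = "dynamic"
DYN_UNCHANGED = "unchanged"


@dataclass(frozen=True)
class SectionAssignment:
    """Mild (A) / severe (B) / control labels per (dose, day) group."""

    index: str
    threshold: float
    sections: dict  # (dose, day) -> "A" | "B" | "control"

    def groups_in(self, section: str) -> list:
        return sorted(g for g, s in self.sections.items() if s == section)


def assign_sections(biomarkers: BiomarkerTable, index: str,
                    control_groups: set, threshold="median") -> SectionAssignment:
    """Split non-control groups into mild/severe by an index threshold.

    ``threshold`` may be a number or ``"median"``, which uses the median of
    the non-control group values that exceed the control mean (so the split
    tracks where the index actually responds). Groups with value <= the
    threshold go to section A, the rest to B.
    """
    vals = biomarkers.values[index]
    noncontrol = vals[[g not in control_groups for g in vals.index]]
    if noncontrol.empty:
        raise CohortValidationError("no non-control groups to assign")
    if threshold == "median":
        control_vals = vals[[g in control_groups for g in vals.index]]
        ref = float(control_vals.mean()) if not control_vals.empty else 0.0
        elevated = noncontrol[noncontrol > ref]
        basis = elevated if not elevated.empty else noncontrol
        thr = float(basis.median())
    else:
        thr = float(threshold)
        if thr <= 0:
            raise ValueError("numeric threshold must be > 0")
    sections = {}
    for g, v in vals.items():
        if g in control_groups:
            sections[g] = SECTION_CONTROL
        else:
            sections[g] = SECTION_MILD if v <= thr else SECTION_SEVERE
    return SectionAssignment(index, thr, sections)


@dataclass
class FoldChangeProfile:
    """Per-genus mean section RA over mean control RA, with dynamics class."""

    index: str
    table: pd.DataFrame  # index genus, columns fc_a, fc_b, dynamics, flagged


def section_fold_change(group_ra: pd.DataFrame, sections: SectionAssignment,
                        control_groups: set, tol: float = 0.05) -> FoldChangeProfile:
    """Fold change of mean section RA against the negative control.

    Genera absent from the control get a +inf sentinel when present in the
    section and 1.0 (no change) when absent from both; either case is
    flagged rather than smoothed over with a pseudocount.
    """
    groups_a = [g for g in sections.groups_in(SECTION_MILD) if g in group_ra.index]
    groups_b = [g for g in sections.groups_in(SECTION_SEVERE) if g in group_ra.index]
    controls = [g for g in group_ra.index if g in control_groups]
    if not controls:
        raise CohortValidationError("no control groups in the RA table")
    if not groups_a and not groups_b:
        raise CohortValidationError("both sections empty")
    control_mean = group_ra.loc[controls].mean(axis=0)

    def _fc(groups):
        if not groups:
            return pd.Series(np.nan, index=group_ra.columns)
        sec_mean = group_ra.loc[groups].mean(axis=0)
        fc = pd.Series(index=group_ra.columns, dtype=float)
        for genus in group_ra.columns:
            c, s = control_mean[genus], sec_mean[genus]
            if c > 0:
                fc[genus] = s / c
            else:
                fc[genus] = math.inf if s > 0 else 1.0
        return fc

    fc_a, fc_b = _fc(groups_a), _fc(groups_b)
    flagged = control_mean == 0
    dyn = [classify_dynamics(fc_a[g], fc_b[g], tol) for g in group_ra.columns]
    table = pd.DataFrame(
        {"fc_a": fc_a, "fc_b": fc_b, "dynamics": dyn, "flagged": flagged}
    )
    return FoldChangeProfile(sections.index, table)


def classify_dynamics(fc_a: float, fc_b: float, tol: float = 0.05) -> str:
    """Classify a (mild, severe) fold-change pair relative to 1 +/- tol."""
    hi, lo = 1.0 + tol, 1.0 - tol
    if fc_a > hi and fc_b > hi:
        return DYN_INCREASE
    if fc_a < lo and fc_b < lo:
        return DYN_DECREASE
    if (fc_a > hi and fc_b < lo) or (fc_a < lo and fc_b > hi):
        return DYN_DYNAMIC
    return DYN_UNCHANGED


@dataclass
class BiomarkerCorrelation:
    """Genus x index correlation table with the |r|>0.6, p<0.05 selection."""

    table: pd.DataFrame  # MultiIndex columns (index, r/p/selected), rows genus
    selected_all: list = field(default_factory=list)
    selected_hgb_only: list = field(default_factory=list)
    selected_neutrophil_only: list = field(default_factory=list)

    def selected_for(self, index: str) -> list:
        return sorted(self.table.index[self.table[(index, "selected")]])

    @property
    def selected_any(self) -> list:
        mask = False
        for idx in BiomarkerTable.INDICES:
            mask = mask | self.table[(idx, "selected")]
        return sorted(self.table.index[mask])


def biomarker_correlation(group_ra: pd.DataFrame, biomarkers: BiomarkerTable,
                          control_groups: set,
                          r_threshold: float = BIOMARKER_R_THRESHOLD,
                          p_threshold: float = BIOMARKER_P_THRESHOLD) -> BiomarkerCorrelation:
    """Pooled group-level Pearson correlation of genus RA with each index.

    Pairs the (dose, day) group RA with the group's biomarker value over
    all non-control groups, pooled across doses. A genus is selected for an
    index when |r| > r_threshold and p < p_threshold (strict).
    """
    groups = [g for g in group_ra.index if g not in control_groups]
    if len(groups) < 3:
        raise CohortValidationError("need >= 3 non-control groups")
    missing = [g for g in groups if g not in biomarkers.values.index]
    if missing:
        raise CohortValidationError(f"biomarker rows missing for groups: {missing[:5]}")
    ra = group_ra.loc[groups]
    cols = {}
    for idx in BiomarkerTable.INDICES:
        bio = biomarkers.values.loc[groups, idx].to_numpy(dtype=float)
        rs, ps, sel = [], [], []
        for genus in ra.columns:
            c = pearson(bio, ra[genus].to_numpy()) if np.ptp(bio) > 0 else \
                CorrelationResult(math.nan, math.nan, len(groups), defined=False)
            rs.append(c.r)
            ps.append(c.p)
            sel.append(c.significant(r_threshold, p_threshold))
        cols[(idx, "r")] = rs
        cols[(idx, "p")] = ps
        cols[(idx, "selected")] = sel
    table = pd.DataFrame(cols, index=list(ra.columns))
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    sel = {idx: set(table.index[table[(idx, "selected")]]) for idx in BiomarkerTable.INDICES}
    selected_all = sorted(sel["lcn2"] & sel["mpo"] & sel["hgb"])
    hgb_only = sorted(sel["hgb"] - sel["lcn2"] - sel["mpo"])
    neutrophil_only = sorted((sel["lcn2"] | sel["mpo"]) - sel["hgb"])
    return BiomarkerCorrelation(table, selected_all, hgb_only, neutrophil_only)
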