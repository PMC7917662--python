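"""Dose-duration screen for colitis-associated genera.

The screen works on genus-level group relative abundances: samples of each
(dose, day) cell are merged by summing counts and renormalizing, then each
genus's trajectory over exposure duration is correlated with day within
every dose series. Genera with a strong, significant duration correlation
(|r| > 0.7, p < 0.05, strict) in a serial-dose-consistent pattern — all
dose groups, the two highest, or only the highest — are reported as induced
(positive r) or depleted (negative r). A significant correlation in the
untreated 0% series marks temporal drift and disqualifies the genus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CohortMetadata, CohortValidationError, FeatureTable, TaxonomyMap
from .community_metrics import agglomerate
from .stats_core import CorrelationResult, pearson

logger = logging.getLogger(__name__)

R_THRESHOLD = 0.7
P_THRESHOLD = 0.05

CATEGORY_ALL = "all-doses"
CATEGORY_HIGH2 = "2-3%"
CATEGORY_TOP = "3%-only"
CATEGORY_NONE = "none"


def merge_groups(table: FeatureTable, metadata: CohortMetadata,
                 mode: str = "sum") -> pd.DataFrame:
    """Merge samples of each (dose, day) cell into one composition.

    ``mode='sum'`` (default) sums counts across the cell's mice and then
    normalizes — merge-samples semantics, equivalent to a depth-weighted
    mean of per-mouse compositions. ``mode='mean'`` averages per-mouse
    relative abundances instead (sensitivity analysis).
    Returns a DataFrame indexed by (dose, day), columns = taxa, rows sum 1.
    """
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    meta = metadata.samples
    missing = set(table.sample_ids) - set(meta.index)
    if missing:
        raise CohortValidationError(f"samples without metadata: {sorted(missing)[:5]}")
    df = table.to_dataframe()
    key = meta.loc[df.index]
    grouped_counts = df.groupby([key["dose"], key["day"]]).sum()
    totals = grouped_counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(grouped_counts.index[totals == 0])
        raise CohortValidationError(f"groups with zero total count: {bad}")
    if mode == "sum":
        out = grouped_counts.div(totals, axis=0)
    else:
        ra = df.div(df.sum(axis=1), axis=0)
        out = ra.groupby([key["dose"], key["day"]]).mean()
    out.index.names = ["dose", "day"]
    return out.sort_index()


def duration_correlation(group_ra: pd.DataFrame, dose: int) -> dict[str, CorrelationResult]:
    """Per-genus Pearson r/p of group RA against day within one dose series."""
    sub = group_ra.xs(dose, level="dose").sort_index()
    if len(sub) < 3:
        raise CohortValidationError(
            f"dose {dose}% series has {len(sub)} time points; need >= 3"
        )
    days = np.asarray(sub.index, dtype=float)
    return {genus: pearson(days, sub[genus].to_numpy()) for genus in sub.columns}


def select_correlated(results: dict[str, CorrelationResult],
                      r_threshold: float = R_THRESHOLD,
                      p_threshold: float = P_THRESHOLD) -> tuple[set, set]:
    """Split genera into positively / negatively duration-correlated sets.

    Strict inequalities on both r and p; undefined (constant-abundance)
    correlations are never selected.
    """
    positive = {g for g, c in results.items()
                if c.defined and c.r > r_threshold and c.p < p_threshold}
    negative = {g for g, c in results.items()
                if c.defined and c.r < -r_threshold and c.p < p_threshold}
    return positive, negative


def classify_serial_dose(passes: dict[int, int]) -> str:
    """Category from the per-dose pass pattern.

    ``passes`` maps dose (1, 2, 3) to +1 / -1 / 0 for a positive pass,
    negative pass, or no pass. Serial-dose categories require a consistent
    sign extending down from the highest dose; anything else (1%-only,
    gaps, mixed signs) is 'none'.
    """
    s1, s2, s3 = passes.get(1, 0), passes.get(2, 0), passes.get(3, 0)
    if s3 == 0:
        return CATEGORY_NONE
    if s2 == s3 and s1 == s3:
        return CATEGORY_ALL
    if s2 == s3 and s1 == 0:
        return CATEGORY_HIGH2
    if s2 == 0 and s1 == 0:
        return CATEGORY_TOP
    return CATEGORY_NONE


@dataclass
class ScreenResult:
    """One genus's outcome in the dose-duration screen."""

    genus: str
    correlations: dict  # dose -> CorrelationResult (includes 0)
    direction: str  # "induced" | "depleted"
    category: str

    def to_row(self) -> dict:
        row = {"genus": self.genus, "direction": self.direction, "category": self.category}
        for dose, c in sorted(self.correlations.items()):
            row[f"r_{dose}pct"] = c.r
            row[f"p_{dose}pct"] = c.p
        return row


@dataclass
class ScreenOutput:
    selected: list  # ScreenResult, category != none
    all_correlations: dict  # dose -> {genus -> CorrelationResult}
    group_ra: pd.DataFrame
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        if not self.selected:
            return pd.DataFrame(columns=["genus", "direction", "category"])
        return pd.DataFrame([r.to_row() for r in self.selected])


def run_screen(table: FeatureTable, taxonomy: TaxonomyMap, metadata: CohortMetadata,
               r_threshold: float = R_THRESHOLD, p_threshold: float = P_THRESHOLD,
               control_disqualifies: bool = True, merge_mode: str = "sum") -> ScreenOutput:
    """Full screen: agglomerate to genus, merge groups, correlate, classify.

    Returns the selected genera (serial-dose category != 'none') sorted by
    direction (induced first) then category, together with the full per-dose
    correlation tables for reporting.
    """
    genus_table = agglomerate(table, taxonomy, rank="genus")
    group_ra = merge_groups(genus_table, metadata, mode=merge_mode)
    doses = sorted({d for d, _ in group_ra.index})
    exposure_doses = [d for d in doses if d > 0]
    correlations = {d: duration_correlation(group_ra, d) for d in doses}
    selections = {}
    for d in exposure_doses:
        pos, neg = select_correlated(correlations[d], r_threshold, p_threshold)
        selections[d] = (pos, neg)
    control_pos, control_neg = (set(), set())
    if 0 in correlations and control_disqualifies:
        control_pos, control_neg = select_correlated(correlations[0], r_threshold, p_threshold)
    drifting = control_pos | control_neg

    results = []
    for genus in group_ra.columns:
        passes = {}
        for d in exposure_doses:
            pos, neg = selections[d]
            passes[d] = 1 if genus in pos else (-1 if genus in neg else 0)
        category = classify_serial_dose(passes)
        if category == CATEGORY_NONE:
            continue
        if genus in drifting:
            logger.info("screen: %s disqualified (significant 0%% drift)", genus)
            continue
        direction = "induced" if passes[max(exposure_doses)] > 0 else "depleted"
        per_genus = {d: correlations[d][genus] for d in doses}
        results.append(ScreenResult(genus, per_genus, direction, category))

    cat_order = {CATEGORY_ALL: 0, CATEGORY_HIGH2: 1, CATEGORY_TOP: 2}
    results.sort(key=lambda r: (r.direction != "induced", cat_order[r.category], r.genus))
    params = {
        "r_threshold": r_threshold,
        "p_threshold": p_threshold,
        "control_disqualifies": control_disqualifies,
        "merge_mode": merge_mode,
    }
    return ScreenOutput(results, correlations, group_ra, params)
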