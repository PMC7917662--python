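"""Rarefaction, relative abundance, taxonomic agglomeration, alpha diversity.

Alpha diversity delegates to scikit-bio's estimators (bias-corrected Chao1
and Shannon entropy); rarefaction is exact sampling without replacement via
the multivariate hypergeometric distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity import alpha as _skbio_alpha

from .cohort_io import RANKS, CohortValidationError, FeatureTable, TaxonomyMap
from .stats_core import CorrelationResult, RegressionFit, linear_regression, pearson

logger = logging.getLogger(__name__)

DEFAULT_RAREFACTION_DEPTH = 10_000


def rarefy(table: FeatureTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int | None = None) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (and logged),
    mirroring the usual removal of shallow libraries before diversity
    analysis. Deterministic under ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.counts.sum(axis=1)
    keep = sums >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, ", ".join(dropped[:10]))
    if not keep.any():
        raise CohortValidationError(f"all samples below rarefaction depth {depth}")
    out = np.empty((int(keep.sum()), table.counts.shape[1]), dtype=np.int64)
    for i, row in enumerate(table.counts[keep]):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return FeatureTable(kept_ids, list(table.feature_ids), out)


def to_relative_abundance(table: FeatureTable) -> pd.DataFrame:
    """Counts -> per-sample proportions; rows sum to 1."""
    sums = table.counts.sum(axis=1)
    if (sums == 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise CohortValidationError(f"samples with zero total reads: {bad}")
    ra = table.counts / sums[:, None]
    return pd.DataFrame(ra, index=table.sample_ids, columns=table.feature_ids)


def _agglomerated_label(lineage, rank_idx: int) -> str:
    """Taxon label at the target rank, with 'uncultured <parent>' binning.

    A feature unassigned at the target rank is binned under its deepest
    assigned ancestor as e.g. 'uncultured Enterobacteriaceae'; a feature
    with no assignment at all becomes 'Unassigned'.
    """
    name = lineage[rank_idx]
    if name is not None:
        return name
    for i in range(rank_idx - 1, -1, -1):
        if lineage[i] is not None:
            return f"uncultured {lineage[i]}"
    return "Unassigned"


def agglomerate(table: FeatureTable, taxonomy: TaxonomyMap, rank: str = "genus") -> FeatureTable:
    """Sum counts of features sharing a lineage truncated at ``rank``.

    Per-sample totals are conserved. Output feature ids are the rank-level
    taxon names (or 'uncultured <parent>' / 'Unassigned' bins).
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    if not taxonomy.lineages:
        raise CohortValidationError("empty taxonomy")
    missing = [f for f in table.feature_ids if f not in taxonomy]
    if missing:
        raise CohortValidationError(f"taxonomy missing features: {missing[:5]}")
    rank_idx = RANKS.index(rank)
    labels = [_agglomerated_label(taxonomy[f], rank_idx) for f in table.feature_ids]
    order = list(dict.fromkeys(labels))
    pos = {lab: i for i, lab in enumerate(order)}
    out = np.zeros((len(table.sample_ids), len(order)), dtype=np.int64)
    for col, lab in enumerate(labels):
        out[:, pos[lab]] += table.counts[:, col]
    return FeatureTable(list(table.sample_ids), order, out)


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate; bias-corrected by default.

    Bias-corrected form: S_obs + F1(F1-1)/(2(F2+1)) with F1/F2 the
    singleton/doubleton counts, finite even when no doubletons exist.
    """
    arr = np.asarray(counts)
    if arr.ndim != 1 or (arr < 0).any():
        raise ValueError("counts must be a 1-d non-negative vector")
    if arr.sum() == 0:
        raise CohortValidationError("all-zero count vector")
    return float(_skbio_alpha.chao1(arr, bias_corrected=bias_corrected))


def shannon(counts, base: float = np.e) -> float:
    """Shannon entropy H = -sum p_i log p_i; natural log by default."""
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1 or (arr < 0).any():
        raise ValueError("counts must be a 1-d non-negative vector")
    if arr.sum() == 0:
        raise CohortValidationError("all-zero count vector")
    return float(_skbio_alpha.shannon(arr, base=base))


def alpha_diversity(table: FeatureTable, bias_corrected: bool = True,
                    base: float = np.e) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon, as a DataFrame indexed by sample id."""
    rows = {
        s: (chao1(row, bias_corrected), shannon(row, base))
        for s, row in zip(table.sample_ids, table.counts)
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["chao1", "shannon"])


@dataclass(frozen=True)
class PhylumRatioSeries:
    """Per-day ratio of two phylum abundances within one dose group."""

    dose: int
    numerator: str
    denominator: str
    days: tuple
    ratios: tuple
    correlation: CorrelationResult
    fit: RegressionFit | None
    excluded_days: tuple


def phylum_ratio_series(group_ra: pd.DataFrame, numerator: str, denominator: str,
                        dose: int) -> PhylumRatioSeries:
    """Ratio of two phyla over the day series of one dose group.

    ``group_ra`` is a (dose, day)-indexed relative-abundance table at phylum
    rank (see :func:`dsslong.exposure_screen.merge_groups`). Days where the
    denominator is absent are excluded and recorded. Returns the per-day
    ratios with their Pearson correlation and regression fit against day.
    """
    for phy in (numerator, denominator):
        if phy not in group_ra.columns:
            raise CohortValidationError(f"phylum {phy!r} not present in the table")
    sub = group_ra.xs(dose, level="dose").sort_index()
    den = sub[denominator]
    ok = den > 0
    if not ok.any():
        raise CohortValidationError(
            f"denominator phylum {denominator!r} absent from every day of dose {dose}%"
        )
    excluded = tuple(int(d) for d in sub.index[~ok])
    if excluded:
        logger.info("phylum ratio %s/%s dose %d%%: excluded days %s (zero denominator)",
                    numerator, denominator, dose, excluded)
    days = np.asarray(sub.index[ok], dtype=float)
    ratios = (sub.loc[ok, numerator] / den[ok]).to_numpy()
    corr = pearson(days, ratios) if len(days) >= 3 else CorrelationResult(np.nan, np.nan, len(days), defined=False)
    fit = None
    if corr.defined:
        fit = linear_regression(days, ratios)
    return PhylumRatioSeries(int(dose), numerator, denominator,
                             tuple(int(d) for d in days), tuple(map(float, ratios)),
                             corr, fit, excluded)
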