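"""Shared data model and file I/O for longitudinal colitis cohorts.

Artifacts handled here: the feature (OTU/ASV) count table, the taxonomy map,
the rooted phylogeny, per-sample metadata on the dose x day design grid, and
the group-level fecal biomarker table (Lcn2, MPO in ng/g; Hgb in mg/g).

Formats are deliberately plain: TSV for tables (both orientations accepted
for the count table), BIOM v1 JSON, and newick for trees. Validation is
centralised in :func:`validate_cohort`, which reports design-grid coverage
and id mismatches without mutating anything.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Greengenes-style rank prefixes, stripped on read.
_GG_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

_FEATURE_HEADER_TOKENS = {"#otu id", "#otu_id", "otu id", "otu_id", "feature_id", "feature", "taxon", "taxon_id"}
_SAMPLE_HEADER_TOKENS = {"sample_id", "sample", "#sampleid", "sample-id"}


class CohortValidationError(ValueError):
    """Raised when an artifact violates a structural invariant."""


@dataclass
class FeatureTable:
    """Integer count matrix, samples x features.

    The central observational object: one row per sample, one column per
    feature (OTU/ASV or, after agglomeration, a taxon). Ids must be unique
    and counts non-negative integers.
    """

    sample_ids: list
    feature_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise CohortValidationError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise CohortValidationError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        self.counts = counts.astype(np.int64, copy=False)
        if self.counts.size and self.counts.min() < 0:
            raise CohortValidationError("counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CohortValidationError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise CohortValidationError("duplicate feature ids")

    @property
    def shape(self):
        return self.counts.shape

    def sample_sums(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=1), index=self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, ids) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in ids]
        return FeatureTable(list(ids), list(self.feature_ids), self.counts[idx])


@dataclass
class TaxonomyMap:
    """feature id -> 7-rank lineage (kingdom..species); None marks unassigned."""

    lineages: dict

    def __post_init__(self):
        clean = {}
        for fid, lin in self.lineages.items():
            lin = tuple(lin)
            if len(lin) > len(RANKS):
                raise CohortValidationError(f"{fid}: lineage longer than {len(RANKS)} ranks")
            lin = lin + (None,) * (len(RANKS) - len(lin))
            clean[str(fid)] = tuple(v if v not in ("", None) else None for v in lin)
        self.lineages = clean

    def __getitem__(self, fid):
        return self.lineages[fid]

    def __contains__(self, fid):
        return fid in self.lineages

    def at_rank(self, fid: str, rank: str):
        return self.lineages[fid][RANKS.index(rank)]


@dataclass
class CohortMetadata:
    """Per-sample dose (%), day, and mouse id on the study's design grid."""

    samples: pd.DataFrame  # index sample_id, columns dose, day, mouse

    def __post_init__(self):
        df = self.samples
        missing = {"dose", "day", "mouse"} - set(df.columns)
        if missing:
            raise CohortValidationError(f"metadata missing columns: {sorted(missing)}")
        df = df.copy()
        df.index = df.index.astype(str)
        df["dose"] = df["dose"].astype(int)
        df["day"] = df["day"].astype(int)
        df["mouse"] = df["mouse"].astype(str)
        if df.index.duplicated().any():
            raise CohortValidationError("duplicate sample ids in metadata")
        self.samples = df

    @property
    def doses(self):
        return sorted(self.samples["dose"].unique())

    @property
    def days(self):
        return sorted(self.samples["day"].unique())

    def group_of(self, sample_id: str):
        row = self.samples.loc[sample_id]
        return int(row["dose"]), int(row["day"])

    def samples_in_group(self, dose: int, day: int) -> list:
        m = (self.samples["dose"] == dose) & (self.samples["day"] == day)
        return list(self.samples.index[m])


def negative_control_set(metadata: CohortMetadata) -> set:
    """All 0%-dose samples plus the day-0 samples of every dose group.

    This is the study's untreated reference: water-only mice for the whole
    course, and every mouse sacrificed before exposure started.
    """
    df = metadata.samples
    ids = set(df.index[(df["dose"] == 0) | (df["day"] == 0)])
    if not ids:
        raise CohortValidationError("negative control set is empty")
    return ids


def negative_control_groups(metadata: CohortMetadata) -> set:
    """(dose, day) groups belonging to the negative control."""
    df = metadata.samples
    mask = (df["dose"] == 0) | (df["day"] == 0)
    return set(zip(df.loc[mask, "dose"].astype(int), df.loc[mask, "day"].astype(int)))


@dataclass
class BiomarkerTable:
    """(dose, day) group -> Lcn2 (ng/g), MPO (ng/g), Hgb (mg/g feces)."""

    values: pd.DataFrame  # MultiIndex (dose, day), columns lcn2, mpo, hgb

    INDICES = ("lcn2", "mpo", "hgb")

    def __post_init__(self):
        df = self.values
        missing = set(self.INDICES) - set(df.columns)
        if missing:
            raise CohortValidationError(f"biomarker table missing columns: {sorted(missing)}")
        if not isinstance(df.index, pd.MultiIndex) or df.index.names != ["dose", "day"]:
            raise CohortValidationError("biomarker table must be indexed by (dose, day)")
        if (df[list(self.INDICES)] < 0).any().any():
            raise CohortValidationError("biomarker values must be non-negative")
        self.values = df[list(self.INDICES)].astype(float)

    def series(self, index: str, dose: int) -> pd.Series:
        """One biomarker's trajectory over day within a dose group."""
        sub = self.values.xs(dose, level="dose")[index]
        return sub.sort_index()


# ---------------------------------------------------------------------------
# readers / writers


def _detect_orientation(df: pd.DataFrame, header_token: str, metadata=None) -> str:
    token = header_token.strip().lower()
    if token in _FEATURE_HEADER_TOKENS:
        return "features"
    if token in _SAMPLE_HEADER_TOKENS:
        return "samples"
    if metadata is not None:
        known = set(metadata.samples.index)
        col_hits = len(set(map(str, df.columns)) & known)
        row_hits = len(set(map(str, df.index)) & known)
        if col_hits > row_hits:
            return "features"
        if row_hits > col_hits:
            return "samples"
    raise CohortValidationError(
        f"cannot determine table orientation from header token {header_token!r}; "
        "use 'feature_id' or 'sample_id' as the first column name"
    )


def read_feature_table(path, format_hint: str | None = None, metadata: CohortMetadata | None = None) -> FeatureTable:
    """Read a count table from TSV (either orientation) or BIOM v1 JSON.

    TSV orientation is resolved from the first header token ('feature_id' /
    '#OTU ID' vs 'sample_id'), falling back to matching ids against
    ``metadata``; ambiguous tables are rejected rather than guessed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        fmt = "biom" if path.suffix in (".biom", ".json") else "tsv"
    if fmt == "biom":
        return _read_biom_json(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    header_token = pd.read_csv(path, sep="\t", nrows=0).columns[0]
    orient = _detect_orientation(df, header_token, metadata)
    if orient == "features":
        df = df.T
    return FeatureTable.from_dataframe(df)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write features x samples TSV with a 'feature_id' header token."""
    df = table.to_dataframe().T
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def _read_biom_json(path: Path) -> FeatureTable:
    with open(path) as fh:
        obj = json.load(fh)
    rows = [r["id"] for r in obj["rows"]]  # BIOM rows are observations/features
    cols = [c["id"] for c in obj["columns"]]
    mat = np.zeros((len(rows), len(cols)))
    if obj.get("matrix_type") == "sparse":
        for r, c, v in obj["data"]:
            mat[int(r), int(c)] = v
    else:
        mat[:] = np.asarray(obj["data"], dtype=float)
    return FeatureTable(cols, rows, mat.T)


def write_biom_json(table: FeatureTable, path) -> None:
    obj = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "dsslong",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [len(table.feature_ids), len(table.sample_ids)],
        "rows": [{"id": f, "metadata": None} for f in table.feature_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": table.counts.T.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def read_taxonomy(path) -> TaxonomyMap:
    """2-column TSV: feature id, semicolon-joined lineage (g__ prefixes ok)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise CohortValidationError("taxonomy TSV needs 2 columns (feature_id, lineage)")
    lineages = {}
    for fid, lin in zip(df.iloc[:, 0], df.iloc[:, 1]):
        parts = [] if pd.isna(lin) else [p.strip() for p in str(lin).split(";")]
        clean = []
        for p in parts:
            for pref in _GG_PREFIXES:
                if p.startswith(pref):
                    p = p[len(pref):]
                    break
            clean.append(p if p else None)
        lineages[str(fid)] = clean
    return TaxonomyMap(lineages)


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tlineage\n")
        for fid, lin in taxonomy.lineages.items():
            fh.write(f"{fid}\t{';'.join(v if v is not None else '' for v in lin)}\n")


def read_metadata(path) -> CohortMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise CohortValidationError("metadata TSV needs a sample_id column")
    df = df.set_index("sample_id")
    return CohortMetadata(df)


def write_metadata(metadata: CohortMetadata, path) -> None:
    out = metadata.samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_biomarkers(path) -> BiomarkerTable:
    """TSV with dose, day, lcn2, mpo, hgb; per-mouse rows are averaged.

    Biomarkers are measured on pooled group feces, so the canonical storage
    is one row per (dose, day) group. Replicated rows are mean-aggregated
    with a log note.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"dose", "day", "lcn2", "mpo", "hgb"}
    missing = need - set(df.columns)
    if missing:
        raise CohortValidationError(f"biomarker TSV missing columns: {sorted(missing)}")
    df["dose"] = df["dose"].astype(int)
    df["day"] = df["day"].astype(int)
    grouped = df.groupby(["dose", "day"])[["lcn2", "mpo", "hgb"]].mean()
    if len(grouped) != len(df):
        logger.info(
            "biomarkers: averaged %d rows to %d (dose, day) groups", len(df), len(grouped)
        )
    return BiomarkerTable(grouped)


def write_biomarkers(biomarkers: BiomarkerTable, path) -> None:
    biomarkers.values.reset_index().to_csv(path, sep="\t", index=False)


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; every non-root edge must carry a length."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.postorder(include_self=False):
        if node.length is None:
            raise CohortValidationError(
                f"tree edge above {node.name or '<internal>'} lacks a branch length"
            )
        if not np.isfinite(node.length) or node.length < 0:
            raise CohortValidationError("branch lengths must be finite and >= 0")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def total_branch_length(tree: TreeNode) -> float:
    return float(sum(n.length or 0.0 for n in tree.postorder(include_self=False)))


# ---------------------------------------------------------------------------
# cohort-level validation


@dataclass
class ValidationReport:
    n_samples: int
    n_features: int
    n_groups: int
    design_cells: dict = field(default_factory=dict)  # (dose, day) -> replicate count
    samples_missing_metadata: list = field(default_factory=list)
    samples_missing_table: list = field(default_factory=list)
    features_missing_taxonomy: list = field(default_factory=list)
    features_missing_tree: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.samples_missing_metadata
            or self.samples_missing_table
            or self.features_missing_taxonomy
            or self.features_missing_tree
        )

    def summary(self) -> str:
        lines = [
            f"{self.n_samples} samples, {self.n_features} features, "
            f"{self.n_groups} (dose, day) groups"
        ]
        for name in (
            "samples_missing_metadata",
            "samples_missing_table",
            "features_missing_taxonomy",
            "features_missing_tree",
        ):
            vals = getattr(self, name)
            if vals:
                lines.append(f"{name}: {len(vals)} ({', '.join(map(str, vals[:5]))}...)")
        if self.ok:
            lines.append("no defects")
        return "\n".join(lines)


def validate_cohort(table: FeatureTable, metadata: CohortMetadata,
                    taxonomy: TaxonomyMap | None = None,
                    tree: TreeNode | None = None) -> ValidationReport:
    """Cross-check ids and design coverage; reports, never mutates."""
    table_samples = set(table.sample_ids)
    meta_samples = set(metadata.samples.index)
    df = metadata.samples.loc[list(meta_samples & table_samples)]
    cells = {
        (int(d), int(t)): int(n)
        for (d, t), n in df.groupby(["dose", "day"]).size().items()
    }
    report = ValidationReport(
        n_samples=len(table.sample_ids),
        n_features=len(table.feature_ids),
        n_groups=len(cells),
        design_cells=cells,
        samples_missing_metadata=sorted(table_samples - meta_samples),
        samples_missing_table=sorted(meta_samples - table_samples),
    )
    if taxonomy is not None:
        report.features_missing_taxonomy = sorted(
            f for f in table.feature_ids if f not in taxonomy
        )
    if tree is not None:
        leaves = {t.name for t in tree.tips()}
        report.features_missing_tree = sorted(set(table.feature_ids) - leaves)
    return report
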