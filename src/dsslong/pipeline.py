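"""End-to-end orchestration of the analysis stages.

Each stage reads the previous stage's files, so any stage can be re-run
independently; ``run_all`` chains them and writes a JSON manifest capturing
the full configuration and all seeds, sufficient to reproduce a run.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .beta_diversity import adonis, baseline_distance, gunifrac, nmds
from .cohort_io import (
    CohortValidationError,
    negative_control_groups,
    negative_control_set,
    read_biomarkers,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    read_tree,
    validate_cohort,
    write_biomarkers,
    write_feature_table,
    write_metadata,
    write_taxonomy,
    write_tree,
)
from .community_metrics import (
    DEFAULT_RAREFACTION_DEPTH,
    agglomerate,
    alpha_diversity,
    rarefy,
)
from .exposure_screen import P_THRESHOLD, R_THRESHOLD, merge_groups, run_screen
from .susceptibility import (
    BIOMARKER_P_THRESHOLD,
    BIOMARKER_R_THRESHOLD,
    assign_sections,
    biomarker_correlation,
    section_fold_change,
)
from .synthetic_cohort import CohortConfig, generate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Keyed configuration for a full pipeline run.

    ``synthetic=True`` generates the cohort instead of reading the five
    input files. CLI flags override file values.
    """

    outdir: str = "dsslong_out"
    seed: int = 0
    synthetic: bool = True
    table: str | None = None
    taxonomy: str | None = None
    tree: str | None = None
    metadata: str | None = None
    biomarkers: str | None = None

    rarefaction_depth: int = DEFAULT_RAREFACTION_DEPTH
    gunifrac_alpha: float = 0.5
    nmds_k: int = 2
    nmds_restarts: int = 10
    adonis_permutations: int = 999
    screen_r_threshold: float = R_THRESHOLD
    screen_p_threshold: float = P_THRESHOLD
    biomarker_r_threshold: float = BIOMARKER_R_THRESHOLD
    biomarker_p_threshold: float = BIOMARKER_P_THRESHOLD
    section_threshold: str | float = "median"
    fold_change_tol: float = 0.05
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_inputs(config: RunConfig, outdir: Path):
    if config.synthetic:
        cohort_cfg = CohortConfig(**{**config.cohort, "seed": config.seed})
        cohort = generate(cohort_cfg)
        sim_dir = outdir / "simulated"
        sim_dir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, sim_dir)
        return (cohort.table, cohort.taxonomy, cohort.tree, cohort.metadata,
                cohort.biomarkers)
    for name in ("table", "taxonomy", "tree", "metadata", "biomarkers"):
        if getattr(config, name) is None:
            raise CohortValidationError(f"missing input artifact: {name}")
    metadata = read_metadata(config.metadata)
    table = read_feature_table(config.table, metadata=metadata)
    taxonomy = read_taxonomy(config.taxonomy)
    tree = read_tree(config.tree)
    biomarkers = read_biomarkers(config.biomarkers)
    return table, taxonomy, tree, metadata, biomarkers


def write_cohort(cohort, outdir: Path) -> dict:
    """Write a synthetic cohort in the exact formats cohort_io reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": outdir / "feature_table.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "tree": outdir / "tree.nwk",
        "metadata": outdir / "metadata.tsv",
        "biomarkers": outdir / "biomarkers.tsv",
        "truth": outdir / "truth.json",
    }
    write_feature_table(cohort.table, paths["table"])
    write_taxonomy(cohort.taxonomy, paths["taxonomy"])
    write_tree(cohort.tree, paths["tree"])
    write_metadata(cohort.metadata, paths["metadata"])
    write_biomarkers(cohort.biomarkers, paths["biomarkers"])
    cohort.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def run_all(config: RunConfig) -> Path:
    """Execute rarefy -> diversity -> beta diversity -> screen -> susceptibility."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": {k: (v if not isinstance(v, Path) else str(v))
                   for k, v in asdict(config).items()},
        "stages": {},
    }
    try:
        table, taxonomy, tree, metadata, biomarkers = _load_inputs(config, outdir)

        report = validate_cohort(table, metadata, taxonomy, tree)
        (outdir / "validation.txt").write_text(report.summary() + "\n")
        manifest["stages"]["validate"] = {
            "n_samples": report.n_samples, "n_groups": report.n_groups,
            "ok": report.ok,
        }

        rare = rarefy(table, config.rarefaction_depth, seed=config.seed)
        manifest["stages"]["rarefy"] = {
            "depth": config.rarefaction_depth, "seed": config.seed,
            "samples_in": len(table.sample_ids),
            "samples_out": len(rare.sample_ids),
        }

        alpha = alpha_diversity(rare)
        alpha.index.name = "sample_id"
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")

        dm = gunifrac(rare, tree, alpha=config.gunifrac_alpha)
        dm.write(str(outdir / "gunifrac.tsv"))
        ord_res = nmds(dm, k=config.nmds_k, seed=config.seed,
                       restarts=config.nmds_restarts)
        coords = ord_res.to_frame()
        coords.index.name = "sample_id"
        coords.to_csv(outdir / "nmds.tsv", sep="\t")
        (outdir / "nmds.json").write_text(json.dumps(
            {"stress": ord_res.stress, "k": ord_res.k, "seed": ord_res.seed,
             "restarts": ord_res.restarts}))
        groups = [f"{d}_{t}" for d, t in
                  (metadata.group_of(s) for s in dm.ids)]
        perm = adonis(dm, groups, n_perm=config.adonis_permutations,
                      seed=config.seed)
        manifest["stages"]["beta"] = {
            "gunifrac_alpha": config.gunifrac_alpha,
            "nmds_stress": ord_res.stress,
            "adonis_r2": perm.r2, "adonis_p": perm.p,
            "adonis_pseudo_f": perm.pseudo_f,
        }
        baseline = sorted(
            s for s in dm.ids
            if metadata.group_of(s) == (0, 0)
        )
        bdist = baseline_distance(dm, baseline)
        bdist.index.name = "sample_id"
        bdist.to_csv(outdir / "baseline_distance.tsv", sep="\t")

        screen = run_screen(rare, taxonomy, metadata,
                            r_threshold=config.screen_r_threshold,
                            p_threshold=config.screen_p_threshold)
        screen.to_frame().to_csv(outdir / "screen.tsv", sep="\t", index=False)
        manifest["stages"]["screen"] = {
            **screen.params,
            "n_selected": len(screen.selected),
            "n_induced": sum(r.direction == "induced" for r in screen.selected),
            "n_depleted": sum(r.direction == "depleted" for r in screen.selected),
        }

        control_groups = negative_control_groups(metadata)
        group_ra = screen.group_ra
        bio_rows = {}
        for index in ("lcn2", "mpo", "hgb"):
            sections = assign_sections(biomarkers, index, control_groups,
                                       threshold=config.section_threshold)
            fc = section_fold_change(group_ra, sections, control_groups,
                                     tol=config.fold_change_tol)
            fc.table.index.name = "genus"
            fc.table.to_csv(outdir / f"fold_change_{index}.tsv", sep="\t")
            bio_rows[index] = {"threshold": sections.threshold,
                               "n_mild": len(sections.groups_in("A")),
                               "n_severe": len(sections.groups_in("B"))}
        corr = biomarker_correlation(group_ra, biomarkers, control_groups,
                                     r_threshold=config.biomarker_r_threshold,
                                     p_threshold=config.biomarker_p_threshold)
        flat = corr.table.copy()
        flat.columns = [f"{a}_{b}" for a, b in flat.columns]
        flat.index.name = "genus"
        flat.to_csv(outdir / "biomarker_correlation.tsv", sep="\t")
        manifest["stages"]["susceptibility"] = {
            "sections": bio_rows,
            "n_selected_any": len(corr.selected_any),
            "selected_all_indices": corr.selected_all,
            "selected_hgb_only": corr.selected_hgb_only,
            "selected_neutrophil_only": corr.selected_neutrophil_only,
        }
    except Exception as exc:
        manifest["failed"] = repr(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (outdir / "FAILED").write_text(repr(exc) + "\n")
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
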