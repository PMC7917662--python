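"""Synthetic longitudinal colitis cohorts with known ground truth.

Emulates the statistical structure of a two-factor DSS study: a 4 dose x 7
day design with 4 mice per cell, compositional genus abundances with
planted dose-scaled duration trends, biomarker trajectories (neutrophil
markers rising after an onset delay for moderate/high doses; fecal blood
rising only at high doses, with a transient non-monotone excursion at the
low dose), and genera coupled to those trajectories. Counts are drawn
Dirichlet-multinomial per mouse at a lognormal library depth, so group
compositions carry realistic overdispersion on top of multinomial noise.

Signals are injected on the log scale and renormalized (softmax), so a
blooming genus displaces the rest of the community exactly the way a real
DSS bloom does; depleted genera are balanced against induced ones so the
community total shifts, but does not drift monotonically for bystanders.

Ground truth (class and effect per genus, deterministic biomarker means)
is returned alongside the tables so any screen output can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .cohort_io import (
    BiomarkerTable,
    CohortMetadata,
    FeatureTable,
    TaxonomyMap,
)

__all__ = ["CohortConfig", "SyntheticTruth", "SyntheticCohort", "generate",
           "random_tree", "score_against_truth"]

PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
         "Verrucomicrobia")

CLASS_NULL = "null"
CLASS_INDUCED = "induced"
CLASS_DEPLETED = "depleted"
CLASS_BLEEDING = "bleeding-coupled"
CLASS_NEUTROPHIL = "neutrophil-coupled"


@dataclass
class CohortConfig:
    """Study-design and signal parameters for one synthetic cohort.

    Effect sizes are per-day log-RA slopes at the highest dose; lower doses
    scale linearly with dose/max_dose. Coupled classes follow the z-scored
    deterministic biomarker trajectory with the given coupling on the log
    scale. Defaults mirror the magnitudes seen in acute DSS colitis:
    induced genera bloom from ~0.1% to a dominant share of the community
    over 12 days at the top dose, depleted genera collapse by several
    natural logs, and the two planted groups roughly balance so bystander
    genera see no monotone compositional drift.
    """

    doses: tuple = (0, 1, 2, 3)
    days: tuple = (0, 2, 4, 6, 8, 10, 12)
    mice_per_cell: int = 4

    n_induced: int = 6
    n_depleted: int = 10
    n_bleeding: int = 2
    n_neutrophil: int = 2
    n_null: int = 40

    induced_effect: float = 0.30   # log-RA per day at the highest dose
    depleted_effect: float = -0.25
    coupling: float = 0.7          # log-RA per biomarker z-unit

    # baseline log-abundance ~ Normal(offset, sd) per class
    induced_baseline: float = -2.9
    depleted_baseline: float = 0.5
    coupled_baseline: float = -1.5
    null_baseline: float = -0.5
    planted_baseline_sd: float = 0.8
    null_baseline_sd: float = 2.0  # heavy rare tail: most bystanders are scarce

    concentration: float = 800.0   # Dirichlet overdispersion (higher = tighter)
    mouse_sd: float = 0.10         # per-mouse lognormal wobble on the log scale
    #: rescale induced baselines so the planted bloom mass gained by the last
    #: day at the top dose equals the mass lost by the depleted collapse;
    #: keeps bystander genera free of a monotone compositional drift, the way
    #: real turnover replaces one clade's share with another's
    balance_planted: bool = True

    depth_log_mean: float = float(np.log(3.0e5))
    depth_log_sd: float = 0.5
    depth_min: int = 10_000

    # biomarker model: value = base * (1 + amp * dose_scale * time_profile),
    # multiplicative lognormal noise
    lcn2_base: float = 20.0        # ng/g feces
    lcn2_amp: float = 25.0
    mpo_base: float = 50.0         # ng/g feces
    mpo_amp: float = 15.0
    hgb_base: float = 0.5          # mg/g feces
    hgb_amp: float = 20.0
    hgb_low_dose_bump: float = 0.4  # transient mid-course excursion at 1%
    neutrophil_onset_day: float = 4.0
    biomarker_noise_sd: float = 0.10
    hgb_noise_sd: float = 0.05

    features_per_genus: int = 2
    seed: int = 0

    @property
    def n_genera(self) -> int:
        return (self.n_induced + self.n_depleted + self.n_bleeding
                + self.n_neutrophil + self.n_null)

    def validate(self) -> None:
        if self.n_genera < 2:
            raise ValueError("need at least 2 genera")
        if min(self.n_induced, self.n_depleted, self.n_bleeding,
               self.n_neutrophil, self.n_null) < 0:
            raise ValueError("class sizes must be non-negative")
        if self.mice_per_cell < 1:
            raise ValueError("mice_per_cell must be >= 1")
        if self.features_per_genus < 1:
            raise ValueError("features_per_genus must be >= 1")
        if not np.isfinite([self.induced_effect, self.depleted_effect,
                            self.coupling]).all():
            raise ValueError("effect sizes must be finite")


@dataclass
class SyntheticTruth:
    """Ground truth for scoring: genus classes, effects, biomarker means."""

    classes: dict            # genus label -> class name
    effects: dict            # genus label -> per-day log slope (top dose) or coupling
    biomarker_mean: pd.DataFrame  # deterministic (dose, day) -> lcn2/mpo/hgb
    seed: int

    def genera_in(self, *class_names) -> set:
        return {g for g, c in self.classes.items() if c in class_names}

    def to_json(self, path) -> None:
        obj = {
            "seed": self.seed,
            "classes": self.classes,
            "effects": self.effects,
            "biomarker_mean": {
                f"{d}|{t}": row.to_dict()
                for (d, t), row in self.biomarker_mean.iterrows()
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


@dataclass
class SyntheticCohort:
    table: FeatureTable
    taxonomy: TaxonomyMap
    tree: TreeNode
    metadata: CohortMetadata
    biomarkers: BiomarkerTable
    truth: SyntheticTruth
    config: CohortConfig


def _neutrophil_profile(day: np.ndarray, onset: float, horizon: float) -> np.ndarray:
    """Flat until onset, then a linear rise — Lcn2/MPO-style kinetics."""
    return np.clip((day - onset) / (horizon - onset), 0.0, None)


def _biomarker_means(cfg: CohortConfig) -> pd.DataFrame:
    """Deterministic group-level biomarker surface over the design grid.

    Neutrophil markers respond at every non-zero dose after an onset delay,
    scaled sub-linearly in dose; fecal Hgb rises through the course only at
    doses >= 2%, while the 1% group shows a small symmetric mid-course
    excursion (transient bleeding) with no net time trend.
    """
    days = np.asarray(cfg.days, dtype=float)
    horizon = float(days.max()) if days.max() > 0 else 1.0
    max_dose = max(cfg.doses)
    rows = {}
    for dose in cfg.doses:
        frac = dose / max_dose if max_dose else 0.0
        # neutrophil markers respond at every dose and saturate above the
        # middle dose; bleeding is strongly dose-graded and starts earlier
        neut_scale = min(1.0, 1.45 * frac**0.7) if frac > 0 else 0.0
        hinge = _neutrophil_profile(days, cfg.neutrophil_onset_day, horizon)
        lcn2 = cfg.lcn2_base * (1 + cfg.lcn2_amp * neut_scale * hinge)
        mpo = cfg.mpo_base * (1 + cfg.mpo_amp * neut_scale * hinge)
        if frac >= 2 / 3 - 1e-9:  # doses >= 2% of 3%: progressive bleeding
            bleed = (0.35 + 0.65 * (dose - 2) / (max_dose - 2)) if max_dose > 2 else 1.0
            hgb = cfg.hgb_base * (1 + cfg.hgb_amp * bleed * np.sqrt(days / horizon))
        elif dose > 0:  # low dose: transient, day-symmetric excursion
            mid = horizon / 2.0
            bump = np.exp(-((days - mid) ** 2) / (2 * (horizon / 6) ** 2))
            hgb = cfg.hgb_base * (1 + cfg.hgb_low_dose_bump * bump)
        else:
            hgb = np.full_like(days, cfg.hgb_base)
        for i, day in enumerate(days):
            rows[(int(dose), int(day))] = (lcn2[i], mpo[i], hgb[i])
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["lcn2", "mpo", "hgb"])
    df.index = pd.MultiIndex.from_tuples(df.index, names=["dose", "day"])
    return df.sort_index()


def _genus_layout(cfg: CohortConfig):
    """Assign class, phylum and lineage to every genus.

    Induced genera sit in the phyla that expand under DSS (Proteobacteria,
    Verrucomicrobia, Bacteroidetes), depleted genera in those that contract
    (Firmicutes, Actinobacteria); bystanders are spread over all five. Two
    null genera carry family-only lineages so genus-level agglomeration
    exercises the 'uncultured <family>' binning.
    """
    classes, phyla = [], []
    for _ in range(cfg.n_induced):
        classes.append(CLASS_INDUCED)
    for _ in range(cfg.n_depleted):
        classes.append(CLASS_DEPLETED)
    for _ in range(cfg.n_bleeding):
        classes.append(CLASS_BLEEDING)
    for _ in range(cfg.n_neutrophil):
        classes.append(CLASS_NEUTROPHIL)
    for _ in range(cfg.n_null):
        classes.append(CLASS_NULL)
    # Proteobacteria carries most of the bloom (Enterobacteriaceae-style),
    # so the Bacteroidetes/Proteobacteria ratio falls as exposure continues
    induced_homes = ["Proteobacteria", "Proteobacteria", "Verrucomicrobia",
                     "Bacteroidetes"]
    depleted_homes = ["Firmicutes", "Actinobacteria"]
    i_ind = i_dep = i_null = 0
    for c in classes:
        if c == CLASS_INDUCED:
            phyla.append(induced_homes[i_ind % len(induced_homes)])
            i_ind += 1
        elif c == CLASS_DEPLETED:
            phyla.append(depleted_homes[i_dep % len(depleted_homes)])
            i_dep += 1
        elif c == CLASS_BLEEDING:
            phyla.append("Verrucomicrobia")
        elif c == CLASS_NEUTROPHIL:
            phyla.append("Firmicutes")
        else:
            phyla.append(PHYLA[i_null % len(PHYLA)])
            i_null += 1
    labels, lineages = [], []
    n_unnamed = 0
    for k, (cls, phy) in enumerate(zip(classes, phyla)):
        family = f"{phy[:4]}aceae_{k:02d}"
        if cls == CLASS_NULL and n_unnamed < 2:
            # family-only assignment -> agglomerates as 'uncultured <family>'
            label = f"uncultured {family}"
            lineage = ("Bacteria", phy, f"{phy}_c", f"{phy}_o", family, None, None)
            n_unnamed += 1
        else:
            label = f"Genus_{k:02d}"
            lineage = ("Bacteria", phy, f"{phy}_c", f"{phy}_o", family, label, None)
        labels.append(label)
        lineages.append(lineage)
    return labels, classes, phyla, lineages


def random_tree(n_leaves: int, seed: int | None = None,
                leaf_names=None) -> TreeNode:
    """Random bifurcating tree with exponential branch lengths."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    if leaf_names is None:
        leaf_names = [f"L{i}" for i in range(n_leaves)]
    if len(leaf_names) != n_leaves:
        raise ValueError("leaf_names length must equal n_leaves")
    nodes = []
    for name in leaf_names:
        tip = TreeNode(name=str(name))
        tip.length = float(rng.exponential(0.5))
        nodes.append(tip)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(0.5))
        nodes.append(parent)
    root = TreeNode(children=list(nodes))
    root.length = None
    return root


def generate(config: CohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Draw one complete synthetic cohort; deterministic under the seed."""
    cfg = config or CohortConfig()
    cfg.validate()
    if seed is not None:
        cfg = CohortConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)

    labels, classes, phyla, lineages = _genus_layout(cfg)
    n_genera = cfg.n_genera
    baseline_offsets = {
        CLASS_INDUCED: (cfg.induced_baseline, cfg.planted_baseline_sd),
        CLASS_DEPLETED: (cfg.depleted_baseline, cfg.planted_baseline_sd),
        CLASS_BLEEDING: (cfg.coupled_baseline, cfg.planted_baseline_sd),
        CLASS_NEUTROPHIL: (cfg.coupled_baseline, cfg.planted_baseline_sd),
        CLASS_NULL: (cfg.null_baseline, cfg.null_baseline_sd),
    }
    base_log = np.array([
        rng.normal(*baseline_offsets[c]) for c in classes
    ])
    if cfg.balance_planted and cfg.n_induced and cfg.n_depleted:
        horizon = float(max(cfg.days))
        is_ind = np.array([c == CLASS_INDUCED for c in classes])
        is_dep = np.array([c == CLASS_DEPLETED for c in classes])
        w_ind = np.exp(base_log[is_ind])
        w_dep = np.exp(base_log[is_dep])
        gain = w_ind.sum() * (np.exp(cfg.induced_effect * horizon) - 1.0)
        loss = w_dep.sum() * (1.0 - np.exp(cfg.depleted_effect * horizon))
        if gain > 0 and loss > 0:
            base_log[is_ind] += np.log(loss / gain)

    bio_mean = _biomarker_means(cfg)
    # z-score the deterministic trajectories over the whole grid
    z = (bio_mean - bio_mean.mean()) / bio_mean.std(ddof=0)
    z_neut = (z["lcn2"] + z["mpo"]) / 2.0

    max_dose = max(cfg.doses)
    effects = {}
    slope = np.zeros(n_genera)
    coup = np.zeros(n_genera)
    for g, (lab, cls) in enumerate(zip(labels, classes)):
        if cls == CLASS_INDUCED:
            slope[g] = cfg.induced_effect
            effects[lab] = cfg.induced_effect
        elif cls == CLASS_DEPLETED:
            slope[g] = cfg.depleted_effect
            effects[lab] = cfg.depleted_effect
        elif cls == CLASS_BLEEDING:
            coup[g] = cfg.coupling
            effects[lab] = cfg.coupling
        elif cls == CLASS_NEUTROPHIL:
            coup[g] = -cfg.coupling
            effects[lab] = -cfg.coupling
        else:
            effects[lab] = 0.0

    # split each genus over its ASV-like features with fixed proportions
    fpg = cfg.features_per_genus
    feature_ids, feature_genus = [], []
    for g, lab in enumerate(labels):
        for a in range(fpg):
            feature_ids.append(f"F{g:02d}_{a}")
            feature_genus.append(g)
    split = rng.dirichlet(np.full(fpg, 5.0), size=n_genera)  # per-genus ASV split

    sample_ids, meta_rows = [], []
    counts = np.zeros((len(cfg.doses) * len(cfg.days) * cfg.mice_per_cell,
                       len(feature_ids)), dtype=np.int64)
    s = 0
    for dose in cfg.doses:
        for day in cfg.days:
            zb = float(z.loc[(dose, day), "hgb"])
            zn = float(z_neut.loc[(dose, day)])
            # trend genera follow the dose-scaled day ramp, coupled genera
            # the z-scored deterministic biomarker trajectory
            is_bleed = np.array([c == CLASS_BLEEDING for c in classes])
            is_neut = np.array([c == CLASS_NEUTROPHIL for c in classes])
            logit_group = base_log + slope * day * (dose / max_dose)
            logit_group = logit_group + np.where(is_bleed, cfg.coupling * zb, 0.0)
            logit_group = logit_group + np.where(is_neut, -cfg.coupling * zn, 0.0)
            for m in range(cfg.mice_per_cell):
                sid = f"d{dose}t{day:02d}m{m}"
                sample_ids.append(sid)
                meta_rows.append((sid, dose, day, f"M{dose}{day:02d}{m}"))
                logit = logit_group + rng.normal(0.0, cfg.mouse_sd, n_genera)
                p_genus = np.exp(logit - logit.max())
                p_genus /= p_genus.sum()
                p_feat = (p_genus[:, None] * split).ravel()
                alpha = np.maximum(cfg.concentration * p_feat, 1e-9)
                p_draw = rng.dirichlet(alpha)
                depth = int(max(cfg.depth_min,
                                round(rng.lognormal(cfg.depth_log_mean,
                                                    cfg.depth_log_sd))))
                counts[s] = rng.multinomial(depth, p_draw)
                s += 1

    table = FeatureTable(sample_ids, feature_ids, counts)
    taxonomy = TaxonomyMap({
        fid: lineages[feature_genus[i]] for i, fid in enumerate(feature_ids)
    })
    metadata = CohortMetadata(pd.DataFrame(
        [(d, t, m) for _, d, t, m in meta_rows],
        index=[r[0] for r in meta_rows], columns=["dose", "day", "mouse"],
    ))
    noise = np.exp(rng.normal(
        0.0,
        [[cfg.biomarker_noise_sd, cfg.biomarker_noise_sd, cfg.hgb_noise_sd]],
        size=bio_mean.shape,
    ))
    biomarkers = BiomarkerTable(bio_mean * noise)
    tree = random_tree(len(feature_ids), seed=int(rng.integers(2**31 - 1)),
                       leaf_names=feature_ids)
    truth = SyntheticTruth(
        classes=dict(zip(labels, classes)),
        effects=effects,
        biomarker_mean=bio_mean,
        seed=cfg.seed,
    )
    return SyntheticCohort(table, taxonomy, tree, metadata, biomarkers, truth, cfg)


def score_against_truth(selected, truth: SyntheticTruth,
                        positive_classes=(CLASS_INDUCED, CLASS_DEPLETED)) -> dict:
    """Precision/recall of a selected-genus set against the planted classes.

    False positives are counted among genera planted as null; coupled
    genera legitimately respond to the study conditions and are tallied
    separately in the per-class confusion.
    """
    selected = set(selected)
    unknown = selected - set(truth.classes)
    if unknown:
        raise ValueError(f"selected genera not in truth: {sorted(unknown)[:5]}")
    positives = truth.genera_in(*positive_classes)
    nulls = truth.genera_in(CLASS_NULL)
    tp = selected & positives
    fp_null = selected & nulls
    recall = len(tp) / len(positives) if positives else float("nan")
    precision = len(tp) / len(selected) if selected else None
    confusion = {}
    for cls in set(truth.classes.values()):
        members = truth.genera_in(cls)
        confusion[cls] = {
            "selected": len(selected & members),
            "total": len(members),
        }
    return {
        "precision": precision,
        "recall": recall,
        "false_positives_null": len(fp_null),
        "confusion": confusion,
    }
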