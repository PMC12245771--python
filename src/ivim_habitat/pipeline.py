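"""End-to-end orchestration: simulate -> fit -> habitats -> features ->
train -> evaluate, with a reproducibility manifest.

Two strands run side by side, mirroring how the study's data divide:

* an imaging strand on a DWI phantom (IVIM fitting, habitat clustering,
  feature extraction for one lesion), exercising the voxel-level chain;
* a cohort strand on synthetic lesion-by-feature tables with planted
  endpoint effects, exercising the ICC filter, redundancy removal, model
  search, and evaluation for every endpoint x feature family (whole-tumor,
  habitat, conventional-features, hybrid = habitat + CF).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dwi import DEFAULT_PROTOCOL
from .evaluation import (auc_delong, decision_curve, delong_paired_test,
                         metric_panel, youden_threshold)
from .habitat import (assign_habitats, collect_vectors, habitat_summary,
                      select_k, standardize)
from .ivim import fit_volume
from .modeling import (SelectionConfig, cv_model_search, filter_by_icc,
                       pcc_dedup, predict_probabilities, predict_scores)
from .phantom import (CohortSpec, default_cohort_spec, default_phantom_config,
                      feature_families, make_ivim_phantom,
                      make_synthetic_cohort)
from .features import (DiscretizationSpec, extract_habitat_features,
                       extract_whole_tumor)

__all__ = ["PipelineConfig", "run_all", "simulate", "train_test_split_stratified"]

FAMILIES = ("whole", "habitat", "cf", "hybrid")


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    b_threshold: float = 200.0
    phantom_sigma: float = 20.0          # SNR 50 at S0 = 1000
    k_range: tuple[int, int] = (2, 8)
    bins: int = 32
    cohort_n: int = 299
    train_fraction: float = 0.7
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    endpoints: tuple[str, ...] = ("HER2", "Ki67", "HR", "LNM")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sel = SelectionConfig(**raw.pop("selection", {}))
        cfg = cls(**{k: v for k, v in raw.items()}, selection=sel)
        cfg.k_range = tuple(cfg.k_range)
        cfg.endpoints = tuple(cfg.endpoints)
        cfg.selection.seed = cfg.seed
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in
             ("outdir", "seed", "b_threshold", "phantom_sigma", "bins",
              "cohort_n", "train_fraction")}
        d["k_range"] = list(self.k_range)
        d["endpoints"] = list(self.endpoints)
        Path(path).write_text(yaml.safe_dump(d))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: PipelineConfig) -> None:
    files = sorted(p for p in outdir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "checksums": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def train_test_split_stratified(labels: pd.Series, train_fraction: float,
                                seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified split of lesion indices (positional)."""
    rng = np.random.default_rng(seed)
    y = labels.to_numpy()
    train_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        train_idx.append(idx[:n_train])
    train = np.sort(np.concatenate(train_idx))
    test = np.setdiff1d(np.arange(y.size), train)
    return train, test


def simulate(config: PipelineConfig) -> dict[str, Path]:
    """Write the phantom DWI stack, mask, truth maps, and cohort tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pconf = default_phantom_config(sigma=config.phantom_sigma, seed=config.seed)
    dwi, mask, truth = make_ivim_phantom(pconf, DEFAULT_PROTOCOL)
    dwi.save(outdir / "phantom_dwi.nii.gz", outdir / "phantom.bval")
    mask.save(outdir / "phantom_mask.nii.gz")
    truth_df = pd.DataFrame({
        "label": truth.labels[mask.data],
        "D": truth.d[mask.data], "Dstar": truth.dstar[mask.data],
        "f": truth.f[mask.data],
    })
    truth_df.to_csv(outdir / "phantom_truth.csv", index=False)

    cspec = default_cohort_spec(n=config.cohort_n, seed=config.seed)
    table, labels, replicate = make_synthetic_cohort(cspec)
    table.to_csv(outdir / "cohort_features.csv")
    labels.to_csv(outdir / "cohort_labels.csv")
    replicate.to_csv(outdir / "cohort_features_replicate.csv")
    config.to_yaml(outdir / "config.yaml")
    _write_manifest(outdir, config)
    return {"outdir": outdir}


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns a summary dict and writes reports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    # --- stage 1: phantom + IVIM fitting -------------------------------
    pconf = default_phantom_config(sigma=config.phantom_sigma, seed=config.seed)
    dwi, mask, truth = make_ivim_phantom(pconf, DEFAULT_PROTOCOL)
    maps = fit_volume(dwi, mask, threshold=config.b_threshold)
    maps.save(outdir, prefix="ivim")
    report["stages"]["fit-ivim"] = {
        "n_voxels": mask.n_voxels,
        "convergence_fraction": maps.convergence_fraction,
    }

    # --- stage 2: habitat clustering -----------------------------------
    vectors = standardize(collect_vectors(maps, mask))
    model = select_k(vectors, range(config.k_range[0], config.k_range[1] + 1),
                     seed=config.seed)
    model.to_json(outdir / "habitat_model.json")
    label_map = assign_habitats(maps, mask, model)
    summary = habitat_summary(label_map, mask.spacing, model.k)
    summary.to_csv(outdir / "habitat_summary.csv", index=False)
    report["stages"]["habitats"] = {
        "k": model.k,
        "ch_curve": {int(k): v for k, v in model.ch_curve.items()},
    }

    # --- stage 3: feature extraction for the phantom lesion -------------
    spec = DiscretizationSpec(bins=config.bins)
    fv = extract_whole_tumor(maps, mask, spec)
    fv.update(extract_habitat_features(maps, label_map, mask, model.k, spec))
    pd.Series(fv.values).to_csv(outdir / "phantom_features.csv",
                                header=["value"])
    report["stages"]["features"] = {"n_features": len(fv.values)}

    # --- stage 4 + 5: cohort modeling and evaluation ---------------------
    cspec = default_cohort_spec(n=config.cohort_n, seed=config.seed)
    table, labels, replicate = make_synthetic_cohort(cspec)
    families = feature_families(cspec)
    families["hybrid"] = families["habitat"] + families["cf"]

    # robustness filter on the re-segmentation-sensitive radiomic families
    stable: dict[str, list[str]] = {}
    for fam in ("whole", "habitat"):
        stable[fam] = filter_by_icc(table[families[fam]],
                                    replicate[families[fam]],
                                    config.selection.icc_threshold)
    stable["cf"] = families["cf"]
    stable["hybrid"] = stable["habitat"] + stable["cf"]

    bundles = {}
    evaluation: dict[str, dict] = {}
    for endpoint in config.endpoints:
        y = labels[endpoint]
        train, test = train_test_split_stratified(y, config.train_fraction,
                                                  config.seed)
        evaluation[endpoint] = {}
        scores_by_family = {}
        for fam in FAMILIES:
            cols = pcc_dedup(table.iloc[train][stable[fam]],
                             config.selection.pcc_threshold,
                             config.seed)
            bundle = cv_model_search(
                table.iloc[train][cols], y.iloc[train], config.selection,
                endpoint=endpoint, family=fam, use_lasso=(fam == "whole"))
            bundle.to_json(outdir / f"bundle_{endpoint}_{fam}.json")
            bundles[(endpoint, fam)] = bundle

            train_scores = predict_scores(bundle, table.iloc[train])
            thr = youden_threshold(train_scores, y.iloc[train].to_numpy())
            test_scores = predict_scores(bundle, table.iloc[test])
            scores_by_family[fam] = test_scores
            roc = auc_delong(test_scores, y.iloc[test].to_numpy())
            panel = metric_panel(test_scores, y.iloc[test].to_numpy(), thr)
            probs = predict_probabilities(bundle, table.iloc[test])
            dca = decision_curve(probs, y.iloc[test].to_numpy())
            evaluation[endpoint][fam] = {
                "cv_auc": bundle.cv_auc,
                "test_auc": roc.auc,
                "ci": [roc.ci_low, roc.ci_high],
                "acc": panel.acc, "sen": panel.sen, "spe": panel.spe,
                "ppv": panel.ppv, "npv": panel.npv, "mcc": panel.mcc,
                "selector": bundle.selector, "classifier": bundle.classifier,
                "features": bundle.features,
                "max_net_benefit": float(np.max(dca.net_benefit)),
            }
        z, p = delong_paired_test(scores_by_family["habitat"],
                                  scores_by_family["whole"],
                                  y.iloc[test].to_numpy())
        evaluation[endpoint]["delong_habitat_vs_whole"] = {"z": z, "p": p}

    (outdir / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
    report["stages"]["train-evaluate"] = {
        "n_bundles": len(bundles),
        "endpoints": list(config.endpoints),
    }
    report["evaluation"] = evaluation
    _write_manifest(outdir, config)
    return report
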