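#!/usr/bin/env python
"""Train one model per endpoint x feature family on the synthetic cohort.

For each of the four endpoints (HER2, Ki-67, HR, LNM) and four families
(whole-tumor, habitat, conventional features, hybrid = habitat + CF):
features failing the ICC(2,1) >= 0.75 re-segmentation robustness filter are
dropped, near-duplicates (|r| > 0.99) removed, the whole-tumor family is
LASSO-pre-selected, and the best selector x classifier x feature-count x C
combination is chosen by stratified 5-fold cross-validated AUC on the 70%
training split.  Bundles are saved as JSON under results/analysis/.
"""

import json
from pathlib import Path

import pandas as pd

from ivim_habitat.modeling import (SelectionConfig, cv_model_search,
                                   filter_by_icc, pcc_dedup)
from ivim_habitat.phantom import default_cohort_spec, feature_families
from ivim_habitat.pipeline import train_test_split_stratified

OUTDIR = Path("results/analysis")
ENDPOINTS = ("HER2", "Ki67", "HR", "LNM")


def main() -> None:
    table = pd.read_csv(OUTDIR / "cohort_features.csv", index_col=0)
    replicate = pd.read_csv(OUTDIR / "cohort_features_replicate.csv",
                            index_col=0)
    labels = pd.read_csv(OUTDIR / "cohort_labels.csv", index_col=0)
    families = feature_families(default_cohort_spec(n=len(table), seed=0))

    config = SelectionConfig(seed=0)
    stable = {
        fam: filter_by_icc(table[cols], replicate[cols],
                           config.icc_threshold)
        for fam, cols in families.items() if fam in ("whole", "habitat")
    }
    stable["cf"] = families["cf"]
    stable["hybrid"] = stable["habitat"] + stable["cf"]
    for fam in ("whole", "habitat"):
        print(f"{fam}: {len(stable[fam])}/{len(families[fam])} features "
              "pass the ICC filter")

    split_record = {}
    for endpoint in ENDPOINTS:
        y = labels[endpoint]
        train, test = train_test_split_stratified(y, 0.7, 0)
        split_record[endpoint] = {"train": train.tolist(), "test": test.tolist()}
        for fam, cols in stable.items():
            kept = pcc_dedup(table.iloc[train][cols], config.pcc_threshold, 0)
            bundle = cv_model_search(table.iloc[train][kept], y.iloc[train],
                                     config, endpoint=endpoint, family=fam,
                                     use_lasso=(fam == "whole"))
            bundle.to_json(OUTDIR / f"bundle_{endpoint}_{fam}.json")
            print(f"{endpoint:5s} {fam:8s} -> {bundle.selector}+"
                  f"{bundle.classifier} on {len(bundle.features)} features, "
                  f"CV AUC {bundle.cv_auc:.3f}")
    (OUTDIR / "splits.json").write_text(json.dumps(split_record))


if __name__ == "__main__":
    main()
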