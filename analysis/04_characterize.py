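#!/usr/bin/env python
"""Characterize which features drove classification in each cohort.

Collates the 20 features selected in each LOOCV fold into selection-rate
profiles by channel, measure and frequency band (plus the signed
early-vs-late difference profile), then compares the 20 most frequently
selected features between outcome groups with Bonferroni-corrected t
tests (results/top_features_{early,late}.csv, Table-3-style layout).
"""

import json

import pandas as pd

from nldeeg.characterization import (collate_selections, difference_profile,
                                     group_feature_tests, top_features,
                                     write_group_comparison)
from nldeeg.evaluation import (ClassifierSpec, FoldResult, Metrics,
                               SelectorSpec, CvRun)
from nldeeg.features import FeatureId, read_feature_table, read_labels

import common


def load_run(path) -> CvRun:
    d = json.loads(path.read_text())
    folds = [FoldResult(subject_id=f["subject_id"], y_true=f["y_true"],
                        y_pred=f["y_pred"], selected_idx=[],
                        selected=[FeatureId.parse(s) for s in f["selected"]])
             for f in d["folds"]]
    m = d["metrics"]
    return CvRun(folds=folds,
                 metrics=Metrics(**m),
                 selector=SelectorSpec(**d["selector"]),
                 classifier=ClassifierSpec(**d["classifier"]),
                 seed=d["seed"])


def characterize(name):
    run = load_run(common.RESULTS / f"cv_run_{name}.json")
    table = read_feature_table(getattr(common, f"FEATURES_{name.upper()}"))
    labels = read_labels(getattr(common, f"LABELS_{name.upper()}"))

    prof = collate_selections(run)
    for axis, fname in (("channel", "channel"), ("measure", "measure"),
                        ("band_or_scale", "band")):
        df = prof.axis_frame(axis)
        df.insert(0, "cohort", name)
        df.to_csv(common.RESULTS / f"selection_by_{fname}_{name}.csv",
                  index=False)

    top = top_features(prof, 20, order=table.feature_ids)
    comp = group_feature_tests(table, labels, top, n_comparisons=20,
                               profile=prof)
    out = common.RESULTS / f"top_features_{name}.csv"
    write_group_comparison(comp, out)

    n_sig = int(comp.table["significant"].sum())
    lead = comp.table.iloc[0]
    print(f"{name}: top-20 selection rates {comp.table['pct_iterations_selected'].min():.0f}-"
          f"{comp.table['pct_iterations_selected'].max():.0f}% of iterations; "
          f"{n_sig}/20 survive Bonferroni (alpha = {comp.bonferroni_alpha})")
    print(f"  most stable feature: {lead['feature']} "
          f"(positive {lead['mean_positive']:.3f} ± {lead['sd_positive']:.3f} "
          f"vs negative {lead['mean_negative']:.3f} ± {lead['sd_negative']:.3f}, "
          f"p = {lead['p']:.2e}) -> {out.name}")
    return prof


def main():
    profs = {name: characterize(name) for name in ("early", "late")}
    rows = []
    for axis in ("channel", "measure", "band_or_scale"):
        diff = difference_profile(profs["late"], profs["early"], axis)
        rows += [{"axis": axis, "category": c, "late_minus_early": v}
                 for c, v in diff.items()]
    out = common.RESULTS / "selection_difference_late_minus_early.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    meas = [r for r in rows if r["axis"] == "measure"]
    biggest = max(meas, key=lambda r: abs(r["late_minus_early"]))
    print(f"largest measure-axis shift late vs early: {biggest['category']} "
          f"({biggest['late_minus_early']:+.2f} selections/iteration) -> {out.name}")


if __name__ == "__main__":
    main()
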