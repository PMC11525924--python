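"""Evaluate the ensemble's risk scores: whole-cohort ROC and the stage-I
hold-out.

Whole-cohort discrimination is measured on out-of-fold risk scores
(each subject scored by the fold model that did not train on it) and on
the deployed averaged model. The stage-I protocol retrains from scratch on
the 76 later-stage cancers + 75 noncancer subjects and tests on the 24
stage-I cancers + 25 held-out noncancer subjects.

Reads results/{data,normalized}/, writes results/evaluate/
"""

from pathlib import Path

from evmir import (FitConfig, auroc, auroc_confint, confusion_at_threshold,
                   cv_attribute_selection, log2_transform, risk_scores,
                   stage_holdout_protocol)
from evmir import io as eio
from evmir.matrix import to_design

DATA = Path("results/data")
OUT = Path("results/evaluate")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    norm = eio.read_intensity_tsv(Path("results/normalized/normalized.tsv"),
                                  state="normalized")
    labels = eio.read_metadata_tsv(DATA / "metadata.tsv")
    log2m = log2_transform(norm)
    X, y, ids, _ = to_design(log2m, labels)

    model = cv_attribute_selection(X, y, ids, FitConfig(seed=SEED))
    oof = model.trace.oof_scores
    dep = risk_scores(model, X, ids)
    ci = auroc_confint(oof, y)
    conf = confusion_at_threshold(oof, y)
    print(f"whole-cohort out-of-fold AUROC: {auroc(oof, y):.3f} "
          f"(95% CI {ci[0]:.3f}-{ci[1]:.3f})")
    print(f"  accuracy {conf.accuracy:.1%}, sensitivity {conf.sensitivity:.1%}, "
          f"specificity {conf.specificity:.1%} at the 0.5 rule")
    print(f"deployed-model AUROC on all subjects: {auroc(dep, y):.3f}")

    res = stage_holdout_protocol(log2m, labels, FitConfig(seed=SEED), seed=11)
    print(f"stage-I hold-out: train {res.n_train_cancer}+{res.n_train_noncancer}, "
          f"test {res.n_test_cancer}+{res.n_test_noncancer}")
    print(f"  test AUROC {res.roc.auroc:.3f} "
          f"(95% CI {res.roc.ci[0]:.3f}-{res.roc.ci[1]:.3f}), "
          f"accuracy {res.confusion.accuracy:.1%}")
    metrics = {
        "oof_auroc": auroc(oof, y), "oof_auroc_ci": list(ci),
        "deployed_auroc": auroc(dep, y),
        "accuracy": conf.accuracy, "sensitivity": conf.sensitivity,
        "specificity": conf.specificity,
        "stage_holdout_auroc": res.roc.auroc,
        "stage_holdout_ci": list(res.roc.ci),
        "stage_holdout_accuracy": res.confusion.accuracy,
    }
    eio.write_json(metrics, OUT / "metrics.json")


if __name__ == "__main__":
    main()
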