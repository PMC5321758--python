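"""Stage 3a: signature scores, group separation, status classifier and ROC.

Scores every cohort with the discovered core signature (z-sum and geometric
mean), tests mutant-vs-wild-type separation with a pooled t-test, fits the
logistic status classifier on cohort 0 and evaluates it on the held-out
cohort 3 by AUC.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from krassig import (
    fit_status_classifier,
    geometric_mean_score,
    roc_auc,
    score_group_ttest,
    zsum_score,
)
from krassig.io import read_cls, read_expression, read_gene_sets

BASE = Path(__file__).resolve().parents[1] / "results"
DATA = BASE / "data"


def main() -> None:
    core = read_gene_sets(BASE / "core_signature.gmt").genes("core_signature")
    print(f"scoring with the {len(core)}-gene core signature\n")
    cohorts = []
    for k in range(4):
        m = read_expression(DATA / f"cohort{k}.gct", format="gct")
        m.phenotype = read_cls(DATA / f"cohort{k}.cls", m.sample_ids)
        cohorts.append(m)

    rows = []
    for k, cohort in enumerate(cohorts):
        z = zsum_score(cohort, core)
        g = geometric_mean_score(cohort, core)
        t, p, means = score_group_ttest(z, cohort.phenotype)
        rows += [{"cohort": k, "sample": s, "zsum": z.scores[s], "geomean": g.scores[s],
                  "status": cohort.phenotype[s]} for s in cohort.sample_ids]
        print(f"cohort {k}: mutant mean z-sum {means['KRAS_mut']:+.2f} vs "
              f"wild-type {means['KRAS_wt']:+.2f} (t={t:.2f}, p={p:.3g})")
    pd.DataFrame(rows).to_csv(BASE / "signature_scores.tsv", sep="\t", index=False)

    train, test = cohorts[0], cohorts[3]
    fit = fit_status_classifier(zsum_score(train, core), train.phenotype,
                                positive_label="KRAS_mut")
    test_scores = zsum_score(test, core)
    auc, points = roc_auc(test_scores, test.phenotype, positive_label="KRAS_mut")
    pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(BASE / "roc_heldout.tsv",
                                                        sep="\t", index=False)
    with open(BASE / "classifier.json", "w") as fh:
        json.dump({"intercept": fit.intercept, "slope": fit.slope,
                   "separated": fit.separated, "heldout_auc": auc}, fh, indent=2)
    sep = " (training data perfectly separated)" if fit.separated else ""
    print(f"\nlogistic status classifier on cohort 0: slope {fit.slope:+.3f}{sep}")
    print(f"held-out cohort 3: AUC = {auc:.3f}")


if __name__ == "__main__":
    main()
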