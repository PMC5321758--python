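"""Stage 2: preranked GSEA of the candidates in every cohort + recurrence filter.

Each validation cohort is ranked by the KRAS_mut-vs-KRAS_wt log2 fold
change; the candidate set's enrichment score, permutation p and leading
edge are computed per cohort, and genes recurrent in more than half of the
leading edges form the core signature (written to core_signature.gmt).
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from krassig import (
    filter_low_expression,
    gsea_permutation,
    leading_edge_recurrence,
    moderated_de,
    rank_by_logfc,
)
from krassig.io import read_cls, read_expression, read_gene_sets, write_gene_sets

BASE = Path(__file__).resolve().parents[1] / "results"
DATA = BASE / "data"


def main() -> None:
    candidates = read_gene_sets(BASE / "candidates.gmt").genes("candidates")
    truth = set(json.loads((DATA / "truth.json").read_text())["planted_genes"])
    rows, edges = [], []
    for k in range(4):
        cohort = read_expression(DATA / f"cohort{k}.gct", format="gct")
        cohort.phenotype = read_cls(DATA / f"cohort{k}.cls", cohort.sample_ids)
        filtered = filter_low_expression(cohort)
        ranked = rank_by_logfc(moderated_de(filtered, "KRAS_mut", "KRAS_wt"))
        res = gsea_permutation(ranked, candidates, n_perm=1000, seed=7 + k)
        sign = "+" if res.es > 0 else "-"
        print(f"cohort {k}: ES={res.es:+.3f} ({sign}) NES={res.nes:.2f} "
              f"p={res.p_value:.4g} leading edge {len(res.leading_edge)}/{len(candidates)}")
        rows.append({"cohort": k, "es": res.es, "nes": res.nes, "p": res.p_value,
                     "leading_edge": ",".join(res.leading_edge)})
        edges.append(res.leading_edge)
    pd.DataFrame(rows).to_csv(BASE / "cohort_gsea.tsv", sep="\t", index=False)

    core = leading_edge_recurrence(edges, min_fraction=0.5)
    genes = core.genes("core_signature") if "core_signature" in core else []
    write_gene_sets(core, BASE / "core_signature.gmt")
    print(f"\ncore signature (recurrent in >50% of {len(edges)} leading edges): {len(genes)} genes")
    print(f"  subset of candidates: {set(genes) <= set(candidates)}; "
          f"{len(set(genes) & truth)}/{len(truth)} planted genes")


if __name__ == "__main__":
    main()
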