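"""Stage 1: moderated DE per discovery system and the cross-system candidates.

Reads the GCT/CLS pairs written by 01, applies the expression floor filter
(<5 log2 units in more than half the samples), fits the moderated t / B
statistics and intersects the per-system hits (B>0 and logFC>1 in at least
two of the three systems).  Writes per-system DE tables and candidates.gmt.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from krassig import filter_low_expression, moderated_de, select_cross_system_candidates
from krassig.io import read_cls, read_expression, write_gene_sets

BASE = Path(__file__).resolve().parents[1] / "results"
DATA = BASE / "data"


def main() -> None:
    truth = set(json.loads((DATA / "truth.json").read_text())["planted_genes"])
    results = []
    for k in range(3):
        matrix = read_expression(DATA / f"system{k}.gct", format="gct")
        matrix.phenotype = read_cls(DATA / f"system{k}.cls", matrix.sample_ids)
        filtered = filter_low_expression(matrix, floor=5.0, max_low_fraction=0.5)
        de = moderated_de(filtered, "KRAS_mut", "KRAS_wt")
        de.to_frame().to_csv(BASE / f"system{k}_de.tsv", sep="\t")
        n_hits = int(((de.b_stat > 0) & (de.log2fc > 1)).sum())
        print(f"system {k}: {len(de.genes)} genes kept by floor filter, "
              f"{n_hits} with B>0 & logFC>1 "
              f"(d0={de.hyperparams['d0']:.3g}, s0^2={de.hyperparams['s0_sq']:.3g})")
        results.append(de)

    candidates = select_cross_system_candidates(results, logfc_min=1.0, b_min=0.0, min_systems=2)
    genes = candidates.genes("candidates") if "candidates" in candidates else []
    write_gene_sets(candidates, BASE / "candidates.gmt")
    recovered = len(set(genes) & truth)
    print(f"\ncross-system candidates (B>0 & logFC>1 in >=2/3 systems): {len(genes)} genes")
    print(f"  {recovered}/{len(truth)} planted genes recovered, "
          f"{len(genes) - recovered} false positives")


if __name__ == "__main__":
    main()
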