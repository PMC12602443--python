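"""Differential expression for both contrasts in each organ.

Median-of-ratios normalization, moment dispersion with a central floor,
and the NB Wald test for sepsis-vs-sham and treated-vs-sham. Full DE
tables go to scratch/analysis/; a per-contrast significance summary and
the top induced/suppressed genes land in results/analysis/.
"""

from pathlib import Path

import pandas as pd

from ieireprog import de_core
from ieireprog.io_formats import read_counts, read_sample_sheet, write_de_table
from ieireprog.pipeline import CONTRASTS

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results/analysis")


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    for organ_dir in sorted(SCRATCH.iterdir()):
        if not (organ_dir / "counts.tsv").exists():
            continue
        organ = organ_dir.name
        cm = read_counts(organ_dir / "counts.tsv")
        sheet = read_sample_sheet(organ_dir / "sample_sheet.csv")
        sf = de_core.size_factors(cm)
        groups = sheet.conditions()
        disp = de_core.estimate_dispersion(cm, sf, groups)
        print(f"{organ}: size factors " +
              ", ".join(f"{s}={v:.3f}" for s, v in sf.items()))
        for name, contrast in CONTRASTS.items():
            de = de_core.de_test(cm, sf, disp, groups, contrast)
            write_de_table(de, organ_dir / f"de_{name}.tsv")
            t = de.table
            sig = t[t["padj"] < 0.05]
            top_up = t.loc[t["log2fc"].idxmax()]
            top_down = t.loc[t["log2fc"].idxmin()]
            print(f"  {name}: {len(sig)} / {len(t)} significant at padj<0.05; "
                  f"top up {top_up['gene']} (log2FC {top_up['log2fc']:.2f}), "
                  f"top down {top_down['gene']} ({top_down['log2fc']:.2f})")
            rows.append({
                "organ": organ, "contrast": name, "n_genes": len(t),
                "n_significant": len(sig),
                "top_up_gene": top_up["gene"], "top_up_log2fc": top_up["log2fc"],
                "top_down_gene": top_down["gene"], "top_down_log2fc": top_down["log2fc"],
            })
    pd.DataFrame(rows).to_csv(RESULTS / "de_summary.tsv", sep="\t", index=False)
    print(f"summary -> {RESULTS / 'de_summary.tsv'}")


if __name__ == "__main__":
    main()
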