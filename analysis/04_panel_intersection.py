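"""Map the human immunodeficiency panel to mouse symbols and intersect.

The bundled 485-gene human panel is resolved to mouse ortholog symbols
(explicit entries, then curated exceptions, then the case convention) and
intersected with each organ's gene universe. Unmapped and absent symbols
are reported, never guessed.
"""

from pathlib import Path

from ieireprog.io_formats import read_counts
from ieireprog.panel_map import load_bundled_panel, map_orthologs

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results/analysis")


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    panel = load_bundled_panel()
    for organ_dir in sorted(SCRATCH.iterdir()):
        organ = organ_dir.name
        cm = read_counts(organ_dir / "counts.tsv")
        inter = map_orthologs(panel, cm.gene_ids)
        inter.to_csv(RESULTS / f"panel_intersection_{organ}.tsv", sep="\t", index=False)
        unmapped = inter.loc[~inter["mapped"], "human_symbol"].tolist()
        absent = inter.loc[inter["mapped"] & ~inter["present_in_data"], "mouse_symbol"]
        print(f"{organ}: panel {len(panel)}, mapped {int(inter['mapped'].sum())}, "
              f"present in data {int(inter['present_in_data'].sum())}")
        print(f"  unmapped (no mouse ortholog): {unmapped}")
        print(f"  mapped but absent from data: {len(absent)}")


if __name__ == "__main__":
    main()
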