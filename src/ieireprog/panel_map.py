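"""Human-to-mouse mapping of the immunodeficiency gene panel.

Human symbols are mapped to mouse ortholog symbols by, in order of
precedence: an explicit mouse symbol in the panel file, a curated exception
table, and finally the standard nomenclature convention (human ALL-CAPS ->
mouse Title-case, IL10 -> Il10). Symbols that resolve to nothing are
reported as unmapped, never guessed. Mapping is deterministic and
idempotent.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import GenePanel, read_panel

__all__ = [
    "DEFAULT_EXCEPTIONS",
    "default_mouse_symbol",
    "map_orthologs",
    "panel_summary",
    "load_bundled_panel",
]

#: curated human -> mouse overrides where the case convention fails;
#: an empty string marks a human gene with no mouse ortholog.
DEFAULT_EXCEPTIONS: dict[str, str] = {
    "G6PD": "G6pdx",  # mouse gene carries the -x suffix
    "ADA2": "",       # no mouse ortholog (Cecr1 lost in mouse)
    "FCN3": "",       # human-specific ficolin
}


def default_mouse_symbol(human_symbol: str) -> str:
    """Nomenclature convention: ALL-CAPS human symbol -> Title-case mouse."""
    return human_symbol.capitalize()


def map_orthologs(
    panel: GenePanel,
    genes: Iterable[str],
    exceptions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Resolve each panel entry to a mouse symbol and test data presence.

    Returns one row per panel entry with columns ``human_symbol``,
    ``mouse_symbol`` (empty when unmapped), ``mapped`` and
    ``present_in_data`` (True iff the mouse symbol occurs among ``genes``).
    Unmapped and absent symbols are reported, not raised.
    """
    if exceptions is None:
        exceptions = DEFAULT_EXCEPTIONS
    gene_set = set(genes)
    rows = []
    for human, explicit in panel.table[["human_symbol", "mouse_symbol"]].itertuples(index=False):
        if explicit:
            mouse = explicit
        elif human in exceptions:
            mouse = exceptions[human]
        else:
            mouse = default_mouse_symbol(human)
        rows.append(
            {
                "human_symbol": human,
                "mouse_symbol": mouse,
                "mapped": bool(mouse),
                "present_in_data": bool(mouse) and mouse in gene_set,
            }
        )
    return pd.DataFrame(rows)


def panel_summary(
    intersection: pd.DataFrame,
    classes: pd.DataFrame,
    contrast: str | None = None,
) -> dict:
    """Category counts over significantly expressed panel genes.

    ``classes`` is the per-gene classification of one contrast (columns
    gene, category). Counts cover panel genes present in the data whose
    category is not ``not_significant``; percentages are relative to that
    significant panel universe (they sum to 100 up to rounding).
    """
    if classes is None or len(classes) == 0:
        raise ValueError(f"no classification available for contrast {contrast!r}")
    panel_genes = set(intersection.loc[intersection["present_in_data"], "mouse_symbol"])
    sub = classes[classes["gene"].isin(panel_genes)]
    sig = sub[sub["category"] != "not_significant"]
    counts = {c: int((sig["category"] == c).sum()) for c in ("increased", "decreased", "unchanged")}
    n_sig = len(sig)
    pct = {
        f"pct_{c}": (100.0 * v / n_sig if n_sig else 0.0) for c, v in counts.items()
    }
    return {
        "contrast": contrast,
        "n_panel_in_data": len(panel_genes & set(sub["gene"])),
        "n_panel_significant": n_sig,
        **{f"n_{c}": v for c, v in counts.items()},
        **pct,
    }


def load_bundled_panel() -> GenePanel:
    """Load the vendored immunodeficiency panel (485 human symbols).

    The bundled table is a synthetic stand-in for the published
    classification: the well-known immunodeficiency genes are genuine, and
    clearly labelled placeholder symbols pad the list to the published panel
    size (see the file header).
    """
    ref = resources.files("ieireprog.data").joinpath("iei_panel_synthetic.tsv")
    with resources.as_file(ref) as path:
        return read_panel(path)
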