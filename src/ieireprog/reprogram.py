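"""Treatment-induced reprogramming between two contrasts.

For every panel gene the sepsis contrast (CM vs sham) and the treated
contrast (CM+NTCI vs sham) are paired; the fold-change ratio
fc_ratio = 2**(log2fc_cm - log2fc_ntci) quantifies how much the treatment
moved the gene, and a reprogramming class is called:

``delta`` rule (default)
    A gene significantly expressed (padj < alpha) in at least one contrast
    is *enhanced* when the treated log2FC exceeds the sepsis log2FC by more
    than a threshold delta, *suppressed* when it falls short by more than
    delta. delta defaults to the fitted width of the treated contrast's
    background distribution, so a shift has to clear the background spread.
    This matches fold statements such as "reduced 6.5-fold" (a 170-fold
    induction attenuated to 26-fold is suppressed even though it stays
    induced).

``category_change`` rule
    Parameter-free alternative: enhanced/suppressed when the category moves
    strictly up/down the ordering decreased < unchanged < increased
    (non-significant genes rank with unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["pair_contrasts", "summarize", "fold_statement", "SummaryReport"]

_RANK = {"decreased": -1, "unchanged": 0, "not_significant": 0, "increased": 1}

REPROGRAM_RULES = ("delta", "category_change")


@dataclass(frozen=True)
class SummaryReport:
    """Per-organ counts of the panel response and its reprogramming."""

    organ: str
    n_panel_significant: int
    n_increased: int
    n_decreased: int
    n_unchanged: int
    n_enhanced: int
    n_suppressed: int
    n_reprogrammed: int
    pct_increased: float
    pct_decreased: float
    pct_unchanged: float
    pct_reprogrammed_of_panel: float

    def __post_init__(self) -> None:
        if self.n_reprogrammed != self.n_enhanced + self.n_suppressed:
            raise ValueError("n_reprogrammed must equal n_enhanced + n_suppressed")

    def as_dict(self) -> dict:
        return asdict(self)


def pair_contrasts(
    classes_cm: pd.DataFrame,
    classes_ntci: pd.DataFrame,
    panel_genes: list[str] | pd.Series,
    rule: str = "delta",
    delta_threshold: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pair the two contrasts per panel gene and call reprogramming.

    ``classes_*`` are classification frames (gene, log2fc, padj, category)
    from :func:`ieireprog.fc_classifier.classify_genes`. Genes missing from
    either contrast are excluded (their ids are recorded in the frame's
    ``attrs['excluded']``). Under the ``delta`` rule ``delta_threshold``
    must be supplied (the fitted width of the treated contrast's background
    is the conventional choice).
    """
    if rule not in REPROGRAM_RULES:
        raise ValueError(f"unknown reprogram rule {rule!r}; expected one of {REPROGRAM_RULES}")
    if rule == "delta" and delta_threshold is None:
        raise ValueError("the delta rule needs a delta_threshold (e.g. the treated fit's width)")

    panel = list(dict.fromkeys(panel_genes))
    cm = classes_cm.set_index("gene")
    ntci = classes_ntci.set_index("gene")
    in_both = [g for g in panel if g in cm.index and g in ntci.index]
    excluded = [g for g in panel if g not in in_both]

    lfc_cm = cm.loc[in_both, "log2fc"].to_numpy(dtype=float)
    lfc_nt = ntci.loc[in_both, "log2fc"].to_numpy(dtype=float)
    cat_cm = cm.loc[in_both, "category"].to_numpy(dtype=object)
    cat_nt = ntci.loc[in_both, "category"].to_numpy(dtype=object)
    padj_cm = cm.loc[in_both, "padj"].to_numpy(dtype=float)
    padj_nt = ntci.loc[in_both, "padj"].to_numpy(dtype=float)

    delta = lfc_nt - lfc_cm
    fc_ratio = np.power(2.0, -delta)  # = 2**(lfc_cm - lfc_nt), exactly 2**(-delta)

    if rule == "category_change":
        rank_cm = np.array([_RANK[c] for c in cat_cm])
        rank_nt = np.array([_RANK[c] for c in cat_nt])
        cls = np.where(rank_nt > rank_cm, "enhanced", np.where(rank_nt < rank_cm, "suppressed", "not_reprogrammed"))
    else:
        sig = (padj_cm < alpha) | (padj_nt < alpha)
        cls = np.full(len(in_both), "not_reprogrammed", dtype=object)
        cls[sig & (delta > delta_threshold)] = "enhanced"
        cls[sig & (delta < -delta_threshold)] = "suppressed"
    cls = np.where(delta == 0.0, "not_reprogrammed", cls)

    records = pd.DataFrame(
        {
            "gene": in_both,
            "log2fc_cm": lfc_cm,
            "log2fc_ntci": lfc_nt,
            "cat_cm": cat_cm,
            "cat_ntci": cat_nt,
            "delta_log2fc": delta,
            "fc_ratio": fc_ratio,
            "reprogram_class": cls,
        }
    )
    records.attrs["excluded"] = excluded
    records.attrs["rule"] = rule
    records.attrs["delta_threshold"] = delta_threshold
    return records


def summarize(
    records: pd.DataFrame,
    classes_cm: pd.DataFrame,
    panel_genes: list[str] | pd.Series,
    organ: str,
) -> SummaryReport:
    """Counts of the panel's sepsis response and treatment reprogramming.

    The response counts come from the sepsis-contrast categories of panel
    genes (significantly expressed only); the reprogramming counts from the
    paired records. Percentages of the response categories are relative to
    the significant panel universe.
    """
    panel = set(panel_genes)
    sub = classes_cm[classes_cm["gene"].isin(panel)]
    sig = sub[sub["category"] != "not_significant"]
    n_sig = len(sig)
    n_inc = int((sig["category"] == "increased").sum())
    n_dec = int((sig["category"] == "decreased").sum())
    n_unc = int((sig["category"] == "unchanged").sum())
    n_enh = int((records["reprogram_class"] == "enhanced").sum()) if len(records) else 0
    n_sup = int((records["reprogram_class"] == "suppressed").sum()) if len(records) else 0
    n_panel = len(panel)

    def pct(x: int, denom: int) -> float:
        return 100.0 * x / denom if denom else 0.0

    return SummaryReport(
        organ=organ,
        n_panel_significant=n_sig,
        n_increased=n_inc,
        n_decreased=n_dec,
        n_unchanged=n_unc,
        n_enhanced=n_enh,
        n_suppressed=n_sup,
        n_reprogrammed=n_enh + n_sup,
        pct_increased=pct(n_inc, n_sig),
        pct_decreased=pct(n_dec, n_sig),
        pct_unchanged=pct(n_unc, n_sig),
        pct_reprogrammed_of_panel=pct(n_enh + n_sup, n_panel),
    )


def fold_statement(record: pd.Series | dict) -> str:
    """Human-readable fold statement for one reprogramming record.

    An induced gene (log2fc_cm > 0) attenuated by treatment reads
    "reduced k-fold" with k = fc_ratio; a suppressed gene (log2fc_cm < 0)
    whose suppression the treatment relieved reads "reversed k-fold" with
    k = 1 / fc_ratio. Ratios are linear-scale, one decimal.
    """
    lfc_cm = float(record["log2fc_cm"])
    delta = float(record["delta_log2fc"])
    fc_ratio = float(record["fc_ratio"])
    if delta == 0.0:
        return "unchanged (1.0-fold)"
    if lfc_cm > 0 and delta < 0:
        return f"reduced {fc_ratio:.1f}-fold"
    if lfc_cm < 0 and delta > 0:
        return f"reversed {1.0 / fc_ratio:.1f}-fold"
    if delta > 0:
        return f"increased further {1.0 / fc_ratio:.1f}-fold"
    return f"decreased further {fc_ratio:.1f}-fold"
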