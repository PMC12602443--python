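"""End-to-end orchestration: counts -> DE -> fit -> classify -> reprogram.

:func:`analyze_contrasts` is the in-memory engine used by the tests, the
simulator's recovery experiment and the CLI; :func:`run_all` is the
file-based driver that reads a run configuration, processes each organ in
the sample sheet and writes every stage artifact (DE tables, fit reports,
classifications, reprogramming table, summary JSON) under
``output_dir/{organ}/``. Externally produced DE tables (e.g. from another
engine) can replace the internal one per contrast; every downstream stage
is then identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import de_core, fc_classifier, panel_map, reprogram
from .fc_classifier import DistributionFit
from .io_formats import (
    CountMatrix,
    DETable,
    GenePanel,
    SampleSheet,
    read_counts,
    read_de_table,
    read_panel,
    read_run_config,
    read_sample_sheet,
    write_de_table,
)
from .reprogram import SummaryReport

__all__ = ["RunConfig", "ContrastResult", "analyze_contrasts", "run_all", "CONTRASTS"]

log = logging.getLogger(__name__)

#: contrast name -> (treatment condition, reference condition)
CONTRASTS: dict[str, tuple[str, str]] = {
    "cm": ("cm", "sham"),
    "cm_ntci": ("cm_ntci", "sham"),
}


@dataclass(frozen=True)
class RunConfig:
    """File-level run configuration (mirrors the YAML keys and CLI flags)."""

    counts: str
    sample_sheet: str
    output_dir: str
    panel: str | None = None  # None -> bundled panel
    external_de: Mapping[str, str] = field(default_factory=dict)  # contrast -> path
    alpha: float = 0.05
    bin_width: float = 0.1
    fit_model: str = "auto"  # auto | gaussian | lorentzian
    reprogram_rule: str = "delta"  # delta | category_change
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.fit_model not in ("auto", "gaussian", "lorentzian"):
            raise ValueError(f"unknown fit_model {self.fit_model!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**read_run_config(path))


@dataclass
class ContrastResult:
    """Everything one organ's analysis produced, stage by stage."""

    organ: str
    de: dict[str, DETable]
    fits: dict[str, DistributionFit]
    classes: dict[str, pd.DataFrame]
    intersection: pd.DataFrame | None
    records: pd.DataFrame
    summary: SummaryReport


def _fit_background(
    de: DETable, bin_width: float, fit_model: str
) -> DistributionFit:
    expressed = de.table["base_mean"] > 0
    hist = fc_classifier.build_histogram(
        de.table.loc[expressed, "log2fc"], bin_width=bin_width
    )
    if fit_model == "auto":
        return fc_classifier.select_model(hist)
    return fc_classifier.fit_distribution(hist, fit_model)


def analyze_contrasts(
    cm: CountMatrix,
    sheet: SampleSheet,
    panel: GenePanel | None = None,
    panel_genes: list[str] | None = None,
    external_de: Mapping[str, DETable] | None = None,
    alpha: float = 0.05,
    bin_width: float = 0.1,
    fit_model: str = "auto",
    reprogram_rule: str = "delta",
    organ: str = "spleen",
) -> ContrastResult:
    """Run every stage for one organ's count matrix.

    Either a :class:`GenePanel` (mapped to mouse symbols here) or an
    explicit ``panel_genes`` list of mouse symbols defines the panel
    universe. ``external_de`` supplies pre-computed DE tables per contrast
    name ("cm", "cm_ntci"); contrasts not covered are computed internally.
    """
    external_de = dict(external_de or {})

    de_tables: dict[str, DETable] = {}
    need_internal = [c for c in CONTRASTS if c not in external_de]
    if need_internal:
        sf = de_core.size_factors(cm)
        groups = sheet.conditions()
        disp = de_core.estimate_dispersion(cm, sf, groups)
        for name in need_internal:
            de_tables[name] = de_core.de_test(cm, sf, disp, groups, CONTRASTS[name])
            log.info("de %s: %d genes, %d significant at padj<%g", name,
                     len(de_tables[name]),
                     int((de_tables[name].table["padj"] < alpha).sum()), alpha)
    for name, table in external_de.items():
        if name not in CONTRASTS:
            raise ValueError(f"unknown contrast {name!r}")
        de_tables[name] = table
        log.info("de %s: ingested external table with %d genes", name, len(table))

    fits = {name: _fit_background(de_tables[name], bin_width, fit_model) for name in CONTRASTS}
    for name, fit in fits.items():
        log.info("fit %s: model=%s center=%.4f width=%.4f converged=%s",
                 name, fit.model, fit.center, fit.width, fit.converged)

    classes = {
        name: fc_classifier.classify_genes(de_tables[name], fits[name], alpha=alpha)
        for name in CONTRASTS
    }

    intersection = None
    if panel_genes is None:
        if panel is None:
            panel = panel_map.load_bundled_panel()
        intersection = panel_map.map_orthologs(panel, cm.gene_ids)
        panel_genes = list(intersection.loc[intersection["present_in_data"], "mouse_symbol"])
    else:
        panel_genes = [g for g in panel_genes if g in set(cm.gene_ids)]

    records = reprogram.pair_contrasts(
        classes["cm"],
        classes["cm_ntci"],
        panel_genes,
        rule=reprogram_rule,
        delta_threshold=fits["cm_ntci"].width,
        alpha=alpha,
    )
    summary = reprogram.summarize(records, classes["cm"], panel_genes, organ=organ)
    log.info("reprogram %s: rule=%s delta=%.4f enhanced=%d suppressed=%d",
             organ, reprogram_rule, fits["cm_ntci"].width,
             summary.n_enhanced, summary.n_suppressed)

    return ContrastResult(
        organ=organ,
        de=de_tables,
        fits=fits,
        classes=classes,
        intersection=intersection,
        records=records,
        summary=summary,
    )


def _write_fit_report(fit: DistributionFit, path: Path) -> None:
    payload = {
        "model": fit.model,
        "center": fit.center,
        "width": fit.width,
        "amplitude": fit.amplitude,
        "sse": fit.sse,
        "converged": fit.converged,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_all(cfg: RunConfig) -> dict[str, SummaryReport]:
    """Process every organ present in the sample sheet and write artifacts.

    Outputs per organ under ``output_dir/{organ}/``: ``de_{contrast}.tsv``,
    ``fit_{contrast}.json``, ``classes_{contrast}.tsv``,
    ``panel_intersection.tsv``, ``reprogramming.tsv`` and ``summary.json``.
    Reruns with the same configuration are byte-identical.
    """
    cm_all = read_counts(cfg.counts)
    sheet_all = read_sample_sheet(cfg.sample_sheet)
    panel = read_panel(cfg.panel) if cfg.panel else panel_map.load_bundled_panel()

    external: dict[str, DETable] = {
        name: read_de_table(path) for name, path in cfg.external_de.items()
    }

    out: dict[str, SummaryReport] = {}
    for organ in sorted(sheet_all.table["organ"].unique()):
        sheet = SampleSheet(
            sheet_all.table[sheet_all.table["organ"] == organ].reset_index(drop=True)
        )
        cm = cm_all.subset_samples(sheet.sample_ids)
        result = analyze_contrasts(
            cm,
            sheet,
            panel=panel,
            external_de=external,
            alpha=cfg.alpha,
            bin_width=cfg.bin_width,
            fit_model=cfg.fit_model,
            reprogram_rule=cfg.reprogram_rule,
            organ=organ,
        )
        organ_dir = Path(cfg.output_dir) / organ
        organ_dir.mkdir(parents=True, exist_ok=True)
        for name in CONTRASTS:
            write_de_table(result.de[name], organ_dir / f"de_{name}.tsv")
            _write_fit_report(result.fits[name], organ_dir / f"fit_{name}.json")
            result.classes[name].to_csv(organ_dir / f"classes_{name}.tsv", sep="\t", index=False)
        if result.intersection is not None:
            result.intersection.to_csv(organ_dir / "panel_intersection.tsv", sep="\t", index=False)
        result.records.to_csv(organ_dir / "reprogramming.tsv", sep="\t", index=False)
        (organ_dir / "summary.json").write_text(
            json.dumps(result.summary.as_dict(), indent=2, sort_keys=True) + "\n"
        )
        out[organ] = result.summary
    return out
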