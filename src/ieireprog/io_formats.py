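"""Readers and writers for the tabular formats shared by every pipeline stage.

All files are tab-separated (the sample sheet is comma-separated), UTF-8,
with ``.`` as the decimal separator. Gene identifiers are symbols, matched
case-sensitively within a species. Validation is strict: malformed input
raises :class:`FormatError` naming the offending cell rather than being
silently coerced.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "Condition",
    "Organ",
    "SampleSheet",
    "CountMatrix",
    "GenePanel",
    "DETable",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_panel",
    "write_panel",
    "read_de_table",
    "write_de_table",
    "read_run_config",
]


class FormatError(ValueError):
    """A file violated the dialect contract (structure, types or uniqueness)."""


class Condition(str, enum.Enum):
    """Experimental arm: sham challenge, cecal-microbiome sepsis, or sepsis
    treated with the nuclear transport checkpoint inhibitor peptide."""

    SHAM = "sham"
    CM = "cm"
    CM_NTCI = "cm_ntci"


class Organ(str, enum.Enum):
    SPLEEN = "spleen"
    LUNGS = "lungs"


# ---------------------------------------------------------------------------
# Sample sheet


@dataclass(frozen=True)
class SampleSheet:
    """Assignment of each sequencing sample to a condition and an organ."""

    table: pd.DataFrame  # columns: sample_id, condition, organ

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "organ"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing column(s): {sorted(missing)}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise FormatError(f"duplicate sample_id {dup!r} in sample sheet")
        bad = set(self.table["condition"]) - {c.value for c in Condition}
        if bad:
            raise FormatError(
                f"unknown condition label(s) {sorted(bad)}; "
                f"expected one of {[c.value for c in Condition]}"
            )
        bad_organ = set(self.table["organ"]) - {o.value for o in Organ}
        if bad_organ:
            raise FormatError(f"unknown organ label(s) {sorted(bad_organ)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_for(self, condition: Condition | str, organ: Organ | str | None = None) -> list[str]:
        cond = Condition(condition).value
        sel = self.table["condition"] == cond
        if organ is not None:
            sel &= self.table["organ"] == Organ(organ).value
        return list(self.table.loc[sel, "sample_id"])

    def conditions(self) -> pd.Series:
        """sample_id -> condition label, aligned to sheet order."""
        return self.table.set_index("sample_id")["condition"]

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        keep = self.table["sample_id"].isin(list(sample_ids))
        return SampleSheet(self.table.loc[keep].reset_index(drop=True))


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Count matrix


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene x sample count matrix.

    ``counts`` is indexed by gene symbol with one column per sample; entries
    are non-negative integers (raw, un-normalized library counts).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in count matrix")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in count matrix")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("count matrix must hold integers")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)])


def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV (first column gene id, header = sample ids).

    Gene order is preserved. A non-integer cell or a duplicated gene id is a
    :class:`FormatError` naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise FormatError(f"{path}: non-numeric count {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}")
        if vals.isna().any():
            gene = df.index[vals.isna()][0]
            raise FormatError(f"{path}: missing count at gene {gene!r}, sample {col!r}")
        frac = vals % 1 != 0
        if frac.any():
            gene = df.index[frac][0]
            raise FormatError(f"{path}: non-integer count {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}")
        out[col] = vals.astype(np.int64)
    counts = pd.DataFrame(out, index=df.index)
    return CountMatrix(counts)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.rename_axis("gene").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene panel


@dataclass(frozen=True)
class GenePanel:
    """Curated human gene panel with optional explicit mouse ortholog symbols.

    An empty ``mouse_symbol`` means "no explicit mapping"; the ortholog
    mapper applies the case convention (or a curated exception) downstream.
    """

    table: pd.DataFrame  # columns: human_symbol, mouse_symbol

    def __post_init__(self) -> None:
        required = {"human_symbol", "mouse_symbol"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"gene panel missing column(s): {sorted(missing)}")
        hs = self.table["human_symbol"]
        if hs.duplicated().any():
            raise FormatError(f"duplicate human_symbol {hs[hs.duplicated()].iloc[0]!r}")
        ms = self.table["mouse_symbol"]
        nonempty = ms[ms != ""]
        if nonempty.duplicated().any():
            raise FormatError(f"duplicate mouse_symbol {nonempty[nonempty.duplicated()].iloc[0]!r}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def human_symbols(self) -> list[str]:
        return list(self.table["human_symbol"])


def read_panel(path: str | Path) -> GenePanel:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df["mouse_symbol"] = df.get("mouse_symbol", pd.Series(dtype=str)).fillna("")
    return GenePanel(df)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Differential-expression table


#: external column spelling (DESeq2-style) used on disk
_DE_COLUMNS = {
    "gene": "gene",
    "baseMean": "base_mean",
    "log2FoldChange": "log2fc",
    "lfcSE": "se",
    "pvalue": "p",
    "padj": "padj",
}
_DE_REQUIRED = ["gene", "baseMean", "log2FoldChange", "pvalue", "padj"]


@dataclass(frozen=True)
class DETable:
    """Per-gene differential-expression result for one contrast.

    Columns: ``gene``, ``base_mean`` (mean normalized count over the
    contrast's samples), ``log2fc`` (treatment over reference), ``se``
    (standard error of log2fc; NaN when externally produced tables omit it),
    ``p``, ``padj`` and ``padj_imputed`` (True where a missing adjusted
    p-value was conservatively set to 1).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "base_mean", "log2fc", "se", "p", "padj", "padj_imputed"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"DE table missing column(s): {sorted(missing)}")
        if self.table["gene"].duplicated().any():
            dup = self.table["gene"][self.table["gene"].duplicated()].iloc[0]
            raise FormatError(f"duplicate gene {dup!r} in DE table")
        for col, lo, hi in [("p", 0.0, 1.0), ("padj", 0.0, 1.0)]:
            v = self.table[col]
            if ((v < lo) | (v > hi)).any():
                raise FormatError(f"{col} outside [0, 1] in DE table")
        if (self.table["base_mean"] < 0).any():
            raise FormatError("negative base_mean in DE table")
        bm_pos = self.table["base_mean"] > 0
        if not np.isfinite(self.table.loc[bm_pos, "log2fc"]).all():
            raise FormatError("non-finite log2fc for an expressed gene")

    def __len__(self) -> int:
        return len(self.table)


def read_de_table(path: str | Path) -> DETable:
    """Read a DESeq2-style DE table (gene, baseMean, log2FoldChange, pvalue, padj).

    ``lfcSE`` is optional; extra columns are ignored. Rows with a missing
    ``padj`` are kept with padj = 1 and flagged ``padj_imputed`` (a warning is
    emitted) so the gene universe stays intact for histogram construction.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _DE_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: DE table missing required column(s): {missing}")
    if "lfcSE" not in df.columns:
        df["lfcSE"] = np.nan
    df = df[list(_DE_COLUMNS)].rename(columns=_DE_COLUMNS)
    df["gene"] = df["gene"].astype(str)
    imputed = df["padj"].isna()
    if imputed.any():
        warnings.warn(
            f"{path}: {int(imputed.sum())} row(s) with missing padj set to 1",
            stacklevel=2,
        )
        df.loc[imputed, "padj"] = 1.0
    df["padj_imputed"] = imputed
    return DETable(df.reset_index(drop=True))


def write_de_table(de: DETable, path: str | Path) -> None:
    """Write in the on-disk (DESeq2-style) column spelling; round-trips with
    :func:`read_de_table` up to the ``padj_imputed`` flag semantics."""
    inv = {v: k for k, v in _DE_COLUMNS.items()}
    out = de.table[list(inv)].rename(columns=inv)
    # %.17g guarantees the written decimals parse back to the same doubles
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Run configuration


def read_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration (keys such as contrasts, alpha,
    bin_width, fit_model, reprogram_rule, seed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise FormatError(f"{path}: run config must be a mapping")
    return dict(cfg)
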