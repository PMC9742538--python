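"""Differential-expression table parsing and cutoff filtering.

Operates on published result tables (locus tag, annotation, mean expression,
log2-fold change, optional adjusted p), not on read counts: upstream
quantification and shrinkage are the domain of dedicated RNA-seq tools and
are deliberately out of scope.  The filter classifies genes as up- or
down-regulated by a symmetric log2FC cutoff, optionally intersected with an
adjusted-p cutoff.

Printed tables round their fold changes; a row printed as 2.0 may be
2.0499… or 1.9501… underneath.  When the caller declares the table's
printed precision, comparisons are made on values rounded to that precision
with an inclusive boundary, so a printed 2.0 passes a cutoff of 2 — the only
reading under which such a table reproduces its own row count.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: Accepted header spellings, normalised to canonical names.
COLUMN_SYNONYMS: dict[str, str] = {
    "locus_tag": "locus_tag",
    "locus tag": "locus_tag",
    "annotation": "annotation",
    "mean_expression": "mean_expression",
    "mean expression": "mean_expression",
    "basemean": "mean_expression",
    "log2fc": "log2fc",
    "log2_fold_change": "log2fc",
    "log2-fold change": "log2fc",
    "log2foldchange": "log2fc",
    "padj": "padj",
    "p_adjust": "padj",
    "p-adjust": "padj",
    "adjusted_p": "padj",
}


@dataclass
class DERecord:
    """One gene's differential-expression result (condition vs reference)."""

    locus_tag: str
    annotation: str = ""
    mean_expression: float = 0.0
    log2fc: float = 0.0
    padj: float | None = None

    def __post_init__(self) -> None:
        if not self.locus_tag:
            raise ValueError("locus_tag must be non-empty")
        if self.mean_expression < 0:
            raise ValueError(f"{self.locus_tag}: mean_expression must be >= 0")
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"{self.locus_tag}: padj must be in [0, 1], got {self.padj}")


@dataclass
class DEFilterResult:
    """Locus tags passing the up/down cutoffs, plus the cutoffs used."""

    up: list[str]
    down: list[str]
    cutoff_lfc: float
    cutoff_padj: float | None = None

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("a gene cannot be both up- and down-regulated")

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)


def read_de_table(path: str | Path) -> list[DERecord]:
    """Parse a TSV/CSV differential-expression table into records.

    Requires at least locus_tag and log2fc columns (synonyms accepted,
    case-insensitive); duplicate locus tags are rejected.  Comment lines
    starting with '#' are ignored.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    df.columns = [COLUMN_SYNONYMS.get(c.strip().lower(), c.strip().lower()) for c in df.columns]

    for required in ("locus_tag", "log2fc"):
        if required not in df.columns:
            raise ValueError(f"{path}: missing required column '{required}' "
                             f"(found: {list(df.columns)})")
    if not pd.api.types.is_numeric_dtype(df["log2fc"]):
        bad = df.loc[pd.to_numeric(df["log2fc"], errors="coerce").isna(), "log2fc"]
        raise ValueError(f"{path}: non-numeric log2fc value(s): {bad.head().tolist()}")

    dup = df["locus_tag"][df["locus_tag"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicated locus tag '{dup.iloc[0]}'")

    records = []
    for row in df.itertuples(index=False):
        padj = getattr(row, "padj", None)
        if padj is not None and (isinstance(padj, float) and np.isnan(padj)):
            padj = None
        records.append(DERecord(
            locus_tag=str(row.locus_tag),
            annotation=str(getattr(row, "annotation", "")),
            mean_expression=float(getattr(row, "mean_expression", 0.0)),
            log2fc=float(row.log2fc),
            padj=None if padj is None else float(padj),
        ))
    return records


def filter_de(records: list[DERecord], lfc_cutoff: float,
              padj_cutoff: float | None = None,
              printed_precision: int | None = None) -> DEFilterResult:
    """Classify records as up/down by a symmetric log2FC cutoff.

    up: log2fc >= +cutoff; down: log2fc <= −cutoff; when a record carries a
    padj and ``padj_cutoff`` is given, additionally require padj < cutoff.
    With ``printed_precision`` set, the comparison uses log2fc rounded to
    that many decimals (inclusive boundary), treating printed table values
    as rounded representatives.
    """
    if lfc_cutoff <= 0:
        raise ValueError(f"lfc_cutoff must be > 0, got {lfc_cutoff}")

    up, down = [], []
    for rec in records:
        lfc = rec.log2fc
        if printed_precision is not None:
            lfc = round(lfc, printed_precision)
        if padj_cutoff is not None and rec.padj is not None and not rec.padj < padj_cutoff:
            continue
        if lfc >= lfc_cutoff:
            up.append(rec.locus_tag)
        elif lfc <= -lfc_cutoff:
            down.append(rec.locus_tag)
    return DEFilterResult(up=up, down=down, cutoff_lfc=lfc_cutoff, cutoff_padj=padj_cutoff)


def load_biofilm_vs_planktonic_table() -> list[DERecord]:
    """The packaged biofilm-vs-planktonic DE table (38 genes, |log2FC| >= 2)."""
    with resources.as_file(
        resources.files("biofilmoct.data") / "biofilm_vs_planktonic_de.tsv"
    ) as p:
        return read_de_table(p)
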