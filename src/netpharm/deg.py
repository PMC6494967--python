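"""Differential-expression tables and top-k seed-gene selection.

A finished differential-expression contrast arrives as a delimited text
table of (gene id, log2 fold change, p-value).  Candidate seed genes are
the rows passing ``|log2FC| > 0.585`` and ``p < 0.05`` (both strict),
re-ranked by ``|log2FC|`` descending, truncated to the top ``k`` (default
300).  Ties in ``|log2FC|`` break by p-value ascending, then by gene id,
so the selected list is a deterministic function of the table contents
and never of its row order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, InputDataError

logger = logging.getLogger(__name__)

#: default column names for DE tables written by this package
DEFAULT_COLUMNS = {"gene": "gene", "log2fc": "log2FoldChange", "p": "pvalue"}

DEFAULT_LFC_THRESHOLD = 0.585
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_TOP_K = 300


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result."""

    gene_id: str
    log2fc: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise InputDataError("gene_id must be non-empty")
        if not math.isfinite(self.log2fc):
            raise InputDataError(f"non-finite log2fc for gene {self.gene_id!r}")
        if not (0.0 <= self.p_value <= 1.0):
            raise InputDataError(
                f"p-value {self.p_value} outside [0, 1] for gene {self.gene_id!r}"
            )


@dataclass
class DEGTable:
    """An ordered collection of DEG records for one contrast.

    Gene ids must be unique; a duplicate indicates the upstream DE run
    exported the same gene twice and is rejected rather than silently
    deduplicated.
    """

    records: list[DEGRecord]
    contrast_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise InputDataError(
                    f"duplicate gene id {rec.gene_id!r} in table "
                    f"{self.contrast_label!r}"
                )
            seen.add(rec.gene_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [r.gene_id for r in self.records],
                "log2FoldChange": [r.log2fc for r in self.records],
                "pvalue": [r.p_value for r in self.records],
            }
        )


@dataclass
class RankedGeneList:
    """Top-k genes ordered by |log2FC| descending.

    ``n_up``/``n_down`` count selected genes with positive/negative
    log2FC, mirroring the up/down split usually reported alongside a
    DEG list.
    """

    gene_ids: list[str]
    log2fcs: list[float] = field(repr=False)
    k_requested: int = DEFAULT_TOP_K
    contrast_label: str = ""

    @property
    def n_up(self) -> int:
        return sum(1 for x in self.log2fcs if x > 0)

    @property
    def n_down(self) -> int:
        return sum(1 for x in self.log2fcs if x < 0)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def write(self, path: str | Path, *, sidecar: bool = True, **extra) -> None:
        """Write one gene id per line, plus a JSON sidecar of metadata."""
        path = Path(path)
        path.write_text("".join(f"{g}\n" for g in self.gene_ids))
        if sidecar:
            meta = {
                "contrast_label": self.contrast_label,
                "k_requested": self.k_requested,
                "n_selected": len(self.gene_ids),
                "n_up": self.n_up,
                "n_down": self.n_down,
            }
            meta.update(extra)
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, sort_keys=True, indent=2) + "\n"
            )


def _detect_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_de_table(
    source: str | Path,
    column_map: Mapping[str, str] | None = None,
    contrast_label: str | None = None,
) -> DEGTable:
    """Parse a delimited DE result table into a :class:`DEGTable`.

    Parameters
    ----------
    source
        Path to a TSV (default) or CSV (by ``.csv`` extension) file with a
        header row.
    column_map
        Maps the logical names ``gene``, ``log2fc`` and ``p`` to the actual
        column headers; defaults to ``gene`` / ``log2FoldChange`` /
        ``pvalue``.

    Rows whose log2FC or p-value fail to parse as numbers are dropped with
    a per-row diagnostic; a duplicated gene id is an error.
    """
    source = Path(source)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    frame = pd.read_csv(source, sep=_detect_sep(source), float_precision="round_trip")
    missing = [c for c in cols.values() if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"{source}: missing column(s) {missing}; found {list(frame.columns)}"
        )

    gene = frame[cols["gene"]].astype(str)
    lfc = pd.to_numeric(frame[cols["log2fc"]], errors="coerce")
    pval = pd.to_numeric(frame[cols["p"]], errors="coerce")

    records: list[DEGRecord] = []
    n_dropped = 0
    for i in range(len(frame)):
        if pd.isna(lfc.iloc[i]) or pd.isna(pval.iloc[i]):
            n_dropped += 1
            logger.warning(
                "%s row %d (gene %s): non-numeric log2fc/p-value, row dropped",
                source.name,
                i + 2,  # 1-based, after the header
                gene.iloc[i],
            )
            continue
        records.append(DEGRecord(gene.iloc[i], float(lfc.iloc[i]), float(pval.iloc[i])))
    if n_dropped:
        logger.warning("%s: dropped %d unparseable row(s)", source.name, n_dropped)
    return DEGTable(records, contrast_label or source.stem)


def write_de_table(table: DEGTable, path: str | Path) -> None:
    """Write a DE table as TSV with round-trip-exact float formatting."""
    path = Path(path)
    lines = ["gene\tlog2FoldChange\tpvalue"]
    for r in table.records:
        lines.append(f"{r.gene_id}\t{r.log2fc!r}\t{r.p_value!r}")
    path.write_text("\n".join(lines) + "\n")


def filter_degs(
    table: DEGTable,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> DEGTable:
    """Keep rows with ``|log2fc| > lfc_threshold`` and ``p < p_threshold``.

    Both inequalities are strict; a gene sitting exactly on either
    threshold is excluded.  An empty result is legal.
    """
    if lfc_threshold <= 0 or p_threshold <= 0:
        raise ConfigurationError("thresholds must be positive")
    kept = [
        r
        for r in table.records
        if abs(r.log2fc) > lfc_threshold and r.p_value < p_threshold
    ]
    return DEGTable(kept, table.contrast_label)


def rank_and_select(table: DEGTable, k: int = DEFAULT_TOP_K) -> RankedGeneList:
    """Rank by |log2FC| descending and keep the top ``k`` genes.

    Ties break by p-value ascending, then gene id lexicographic, giving a
    total order independent of input row order.  Fewer than ``k`` rows is
    not an error: all rows are returned and a warning logged.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    ordered = sorted(
        table.records, key=lambda r: (-abs(r.log2fc), r.p_value, r.gene_id)
    )
    if len(ordered) < k:
        logger.warning(
            "requested top %d but table %r has only %d rows; returning all",
            k,
            table.contrast_label,
            len(ordered),
        )
    top = ordered[:k]
    return RankedGeneList(
        gene_ids=[r.gene_id for r in top],
        log2fcs=[r.log2fc for r in top],
        k_requested=k,
        contrast_label=table.contrast_label,
    )


def load_gene_list(source: str | Path) -> list[str]:
    """Read a one-gene-id-per-line text file, skipping blanks."""
    return [
        line.strip()
        for line in Path(source).read_text().splitlines()
        if line.strip()
    ]
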