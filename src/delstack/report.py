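"""Screening summaries and interval-track rendering.

Reproduces the shapes the analysis is read from: per-gene cross tables with
significance flags and a bold marker for expected-but-absent classes, a
totals row of progeny screened, and a plain-text per-mutant deletion track
over the marker panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .cross_model import (
    ChiSquareResult,
    DetectedClass,
    ObservedCrossTable,
    SignificanceConfig,
    evaluate_cross_table,
)
from .synteny_map import DeletionInterval, MarkerPanel

CLASS_ORDER = ("A", "B", "D", "AB", "AD", "BD", "ABD")

__all__ = ["ReportTable", "summarize_screening", "segregation_report", "render_interval_track"]


@dataclass
class ReportTable:
    """Per-cross rows plus a totals row for one gene's screening campaign."""

    gene: str
    rows: pd.DataFrame
    total_screened: int
    class_totals: Dict[str, int] = field(default_factory=dict)


def _format_cell(result: ChiSquareResult) -> str:
    text = f"{result.observed}{result.flag}"
    if result.bold:
        text = f"[{text}]"  # bold marker: expected class never seen, significantly
    return text


def segregation_report(
    tables: Sequence[ObservedCrossTable],
    cfg: SignificanceConfig = SignificanceConfig(),
) -> pd.DataFrame:
    """One row per cross: counts with '*'/'**' flags, bold in brackets.

    Cells are blank for classes the cross did not record; a separate column
    per class carries the chi-square p-value.
    """
    rows = []
    for t in tables:
        results = {r.detected_class.label: r for r in evaluate_cross_table(t, cfg)}
        row: Dict[str, object] = {
            "gene": t.gene,
            "cross": t.cross.label,
            "index": t.cross.index,
            "n_screened": t.n,
        }
        for label in CLASS_ORDER:
            r = results.get(label)
            row[label] = _format_cell(r) if r else ""
            row[f"p_{label}"] = r.p_value if r else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_screening(
    cross_tables: Sequence[ObservedCrossTable],
    gene: str,
    cfg: SignificanceConfig = SignificanceConfig(),
) -> ReportTable:
    """Aggregate one gene's crosses: flags per cross plus screening totals."""
    mismatched = [t.gene for t in cross_tables if t.gene and t.gene != gene]
    if mismatched:
        raise ValueError(
            f"cross tables for {sorted(set(mismatched))} mixed into the {gene} summary"
        )
    frame = segregation_report(cross_tables, cfg)
    total = int(sum(t.n for t in cross_tables))
    class_totals: Dict[str, int] = {}
    for t in cross_tables:
        for cls, count in t.counts.items():
            class_totals[cls.label] = class_totals.get(cls.label, 0) + count
    return ReportTable(
        gene=gene, rows=frame, total_screened=total, class_totals=class_totals
    )


def render_interval_track(
    intervals: Mapping[Tuple[str, str], DeletionInterval],
    panel: MarkerPanel,
) -> str:
    """Plain-text deletion track over the marker grid.

    Per mutant row: '#' marks markers inside the deleted run (minimum span),
    '~' the possible-extension zone up to the bounding intact markers, '|'
    the bounds themselves, '>'/'<' an open end, '.' elsewhere.
    """
    markers = list(panel)
    header_cells = [f"{m.offset_kb:+.0f}" for m in markers]
    width = max(len(c) for c in header_cells) + 1
    lines = ["offset_kb".ljust(24) + "".join(c.rjust(width) for c in header_cells)]
    for (mutant, sub), iv in sorted(intervals.items()):
        cells = []
        for m in markers:
            o = m.offset_kb
            if iv.up_edge_kb <= o <= iv.down_edge_kb:
                glyph = "#"
            elif not iv.up_open and o == _offset_of(panel, iv.up_bound_marker):
                glyph = "|"
            elif not iv.down_open and o == _offset_of(panel, iv.down_bound_marker):
                glyph = "|"
            elif o < iv.up_edge_kb:
                if iv.up_open:
                    glyph = "<"
                else:
                    glyph = "~" if o > _offset_of(panel, iv.up_bound_marker) else "."
            else:
                if iv.down_open:
                    glyph = ">"
                else:
                    glyph = "~" if o < _offset_of(panel, iv.down_bound_marker) else "."
            cells.append(glyph)
        max_txt = "open" if iv.max_size is None else f"{iv.max_size:.0f}"
        label = f"{mutant}:{sub} [{iv.min_size:.0f},{max_txt}]"
        lines.append(label.ljust(24) + "".join(c.rjust(width) for c in cells))
    return "\n".join(lines)


def _offset_of(panel: MarkerPanel, gene_id: str) -> float:
    for m in panel:
        if m.gene_id == gene_id:
            return m.offset_kb
    return float("nan")
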