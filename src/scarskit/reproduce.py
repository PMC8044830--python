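"""Replay of the transcribed printed-count fixtures through the statistics
layer, with a side-by-side comparison report.

For every fixture row the hypergeometric statistics (table-convention p at
the printed significant figures, O/E at 2 dp) or the percent (at the printed
decimal places) are recomputed from the counts alone and compared with the
transcribed printed value.  O/E and percent disagreements are hard failures;
p-value disagreements and the stemness node-total consistency check are
reported as warnings only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .enrichment import OverlapParams, hypergeom_overlap_test
from .overlap import StemnessMatrix, round_half_up, stemness_nodes

__all__ = ["ComparisonReport", "reproduce_tables"]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["table_id", "row_label", "metric", "printed", "recomputed", "match"]


def _sig_figs(printed: str) -> int:
    mantissa = printed.upper().split("E")[0].lstrip("+-").replace(".", "")
    return len(mantissa.lstrip("0"))


def _decimal_places(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


def round_to_sig_figs(value: float, sf: int) -> float:
    if value == 0:
        return 0.0
    return float(f"{value:.{sf - 1}e}")


@dataclass
class ComparisonReport:
    rows: list[dict] = field(default_factory=list)

    def add(self, table_id: str, row_label: str, metric: str, printed: str,
            recomputed: str, match: bool, hard: bool = True) -> None:
        self.rows.append(
            {
                "table_id": table_id,
                "row_label": row_label,
                "metric": metric,
                "printed": printed,
                "recomputed": recomputed,
                "match": match,
                "_hard": hard,
            }
        )
        if not match:
            level = logging.ERROR if hard else logging.WARNING
            logger.log(
                level,
                "%s / %s: %s printed %s but recomputed %s",
                table_id, row_label, metric, printed, recomputed,
            )

    @property
    def ok(self) -> bool:
        """True when every hard-checked metric (O/E, percent) matches."""
        return all(r["match"] for r in self.rows if r["_hard"])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([{k: r[k] for k in REPORT_COLUMNS} for r in self.rows])

    def write_tsv(self, path: str | Path) -> None:
        self.frame().to_csv(Path(path), sep="\t", index=False)


def reproduce_tables(fixture_dir: str | Path) -> ComparisonReport:
    """Recompute every fixture row and compare with the transcribed print."""
    fixture_dir = Path(fixture_dir)
    report = ComparisonReport()

    enr = pd.read_csv(fixture_dir / "enrichment_params.tsv", sep="\t", dtype=str)
    for _, row in enr.iterrows():
        params = OverlapParams(
            N=int(row.N), K=int(row.K), n=int(row.n), k=int(row.k)
        )
        result = hypergeom_overlap_test(params)

        dp = _decimal_places(row.printed_percent)
        pct = round_half_up(100.0 * params.k / params.n, dp)
        report.add(row.table_id, row.row_label, "percent", row.printed_percent,
                   f"{pct:.{dp}f}", match=(pct == float(row.printed_percent)))

        oe = round_half_up(result.oe_ratio, 2)
        report.add(row.table_id, row.row_label, "oe_ratio", row.printed_oe,
                   f"{oe:.2f}", match=(oe == float(row.printed_oe)))

        sf = _sig_figs(row.printed_p)
        p = round_to_sig_figs(result.p_point, sf)
        report.add(row.table_id, row.row_label, "p", row.printed_p,
                   f"{result.p_point:.{max(sf, 4) - 1}e}",
                   match=(p == float(row.printed_p)), hard=False)

    counts = pd.read_csv(fixture_dir / "overlap_counts.tsv", sep="\t", dtype=str)
    for _, row in counts.iterrows():
        total, overlap = int(row.total), int(row.overlap)
        dp = _decimal_places(row.printed_percent)
        pct = round_half_up(100.0 * overlap / total, dp)
        report.add(row.table_id, row.row_label, "percent", row.printed_percent,
                   f"{pct:.{dp}f}", match=(pct == float(row.printed_percent)))

    stem_path = fixture_dir / "stemness_matrix.tsv"
    if stem_path.exists():
        meta: dict[str, int] = {}
        for line in stem_path.read_text().splitlines():
            if line.startswith("#") and "=" in line:
                key, value = line.lstrip("# ").split("=", 1)
                meta[key] = int(value)
        stem = pd.read_csv(stem_path, sep="\t", comment="#")
        matrix = StemnessMatrix(
            counts={
                r.cancer_type: (int(r.silenced), int(r.activated))
                for r in stem.itertuples()
            },
            family_count=meta.get("family_count", 3),
        )
        sil_nodes, act_nodes = stemness_nodes(matrix)
        for metric, printed, recomputed in (
            ("silenced_nodes", meta.get("printed_silenced_nodes"), sil_nodes),
            ("activated_nodes", meta.get("printed_activated_nodes"), act_nodes),
        ):
            if printed is not None:
                report.add("T5", "node totals", metric, str(printed),
                           str(recomputed), match=(printed == recomputed), hard=False)
    return report
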