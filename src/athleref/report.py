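"""Batch reference-table production: one table per outcome and sex.

Drives :func:`athleref.model.build_reference_table` over the full outcome
catalogue, writes each table as CSV (optionally with a human-readable
markdown mirror), and keeps a structured run log of fitted
hyperparameters, effective prior weights and per-outcome skips.  Rows
below the reporting gate (n < 8 by default) are rendered with the sample
size visible and the estimates blanked.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .anthropometry import OUTCOME_CATALOGUE
from .model import (
    DEFAULT_PERCENTILES,
    ReferenceTable,
    SharingRuleError,
    FitError,
    build_reference_table,
)

__all__ = ["RunConfig", "run_pipeline", "render_table_csv", "render_table_markdown"]

log = logging.getLogger("athleref")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a reference-table run.

    ``outcomes`` defaults to the full 40-variable catalogue; ``sexes``
    restricts the run.  ``min_share`` is the sharing gate (posterior
    computed when n >= min_share) and ``min_report`` the reporting gate
    (estimates displayed when n >= min_report).
    """

    input_path: Optional[str] = None
    output_dir: str = "reference_tables"
    outcomes: Sequence[str] = field(default_factory=lambda: tuple(OUTCOME_CATALOGUE))
    sexes: Sequence[str] = ("female", "male")
    percentiles: Sequence[float] = DEFAULT_PERCENTILES
    min_share: int = 2
    min_report: int = 8
    level: float = 0.95
    grid: tuple[int, int] = (200, 200)
    seed: int = 0
    markdown: bool = False

    def __post_init__(self) -> None:
        if self.min_share < 2:
            raise ValueError("min_share must be >= 2")
        if self.min_report < self.min_share:
            raise ValueError("min_report must be >= min_share")
        ranks = list(self.percentiles)
        if ranks != sorted(ranks) or any(not 0 < p < 100 for p in ranks):
            raise ValueError("percentile ranks must be sorted and within (0, 100)")


def render_table_csv(table: ReferenceTable) -> pd.DataFrame:
    """CSV-ready frame; estimates are blanked where reported is False."""
    df = table.estimates.copy()
    df.insert(0, "outcome", table.outcome)
    df.insert(1, "sex", table.sex)
    for col in ("point", "lo", "hi"):
        df[col] = df.apply(
            lambda r, c=col: f"{r[c]:.4g}" if r["reported"] else "", axis=1
        )
    return df[["outcome", "sex", "sport", "n", "p", "point", "lo", "hi", "reported"]]


def render_table_markdown(table: ReferenceTable) -> str:
    """Wide markdown mirror: one row per sport, 'point (lo; hi)' cells."""
    ranks = sorted(table.estimates["p"].unique())
    header = f"### {table.outcome} — {table.sex or 'all'}\n\n"
    cols = ["sport", "n"] + [f"P{p:g}" for p in ranks]
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for sport, sub in table.estimates.groupby("sport", observed=True):
        n = int(sub["n"].iloc[0])
        cells = [str(sport), str(n)]
        for p in ranks:
            row = sub[sub["p"] == p].iloc[0]
            cells.append(
                f"{row['point']:.4g} ({row['lo']:.4g}; {row['hi']:.4g})" if row["reported"] else "—"
            )
        lines.append("| " + " | ".join(cells) + " |")
    return header + "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig, data: Optional[pd.DataFrame] = None) -> dict:
    """Produce reference tables for every requested outcome and sex.

    ``data`` may be passed directly (a derived frame); otherwise
    ``config.input_path`` is read and derived.  Per-outcome failures
    (missing columns, too few groups) are logged and skipped; only an
    unreadable input is fatal.  Returns the structured run summary, which
    is also written to ``run_summary.json`` in the output directory.
    """
    if data is None:
        if config.input_path is None:
            raise ValueError("either data or config.input_path is required")
        from .anthropometry import derive_frame
        from .records import read_dataset

        data = derive_frame(read_dataset(config.input_path))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"tables": [], "skipped": [], "config": {
        "outcomes": list(config.outcomes), "sexes": list(config.sexes),
        "percentiles": list(config.percentiles), "min_share": config.min_share,
        "min_report": config.min_report, "level": config.level,
        "grid": list(config.grid), "seed": config.seed,
    }}
    for outcome in config.outcomes:
        for sex in config.sexes:
            if outcome not in data.columns:
                log.warning("outcome %s: source column missing, skipped", outcome)
                summary["skipped"].append({"outcome": outcome, "sex": sex, "reason": "missing column"})
                continue
            try:
                table = build_reference_table(
                    data,
                    outcome,
                    sex,
                    percentiles=config.percentiles,
                    min_share=config.min_share,
                    min_report=config.min_report,
                    level=config.level,
                    grid=config.grid,
                )
            except (SharingRuleError, FitError, ValueError) as exc:
                log.warning("outcome %s (%s): %s — skipped", outcome, sex, exc)
                summary["skipped"].append({"outcome": outcome, "sex": sex, "reason": str(exc)})
                continue
            path = outdir / f"{outcome}__{sex}.csv"
            render_table_csv(table).to_csv(path, index=False)
            if config.markdown:
                (outdir / f"{outcome}__{sex}.md").write_text(render_table_markdown(table))
            h = table.hyperparams
            summary["tables"].append(
                {
                    "outcome": outcome,
                    "sex": sex,
                    "file": path.name,
                    "log_scale": table.log_scale,
                    "hyperparams": {"mu0": h.mu0, "kappa0": h.kappa0, "alpha0": h.alpha0, "beta0": h.beta0},
                    "prior_weight_persons": table.prior_weight,
                    "n_groups": int(table.estimates["sport"].nunique()),
                }
            )
            log.info(
                "outcome %s (%s): %d groups, prior weight %.3g persons",
                outcome, sex, summary["tables"][-1]["n_groups"], table.prior_weight,
            )
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
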