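"""Gap computation, scenario summaries and deterministic result files.

The gap is ``requirement - supply`` per (profession, year); positive values
are shortages, negative values surpluses.  Values are kept at full precision
everywhere and rounded to whole FTEs only in display helpers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .domain import GapRecord, GapSeries
from .errors import KeyMismatchError


def compute_gap(
    requirements: Mapping[tuple[str, int], float],
    supply: Mapping[tuple[str, int], float],
) -> GapSeries:
    """Pair requirement and supply series into a :class:`GapSeries`.

    Both inputs must cover exactly the same (profession, year) keys.
    """
    req_keys, sup_keys = set(requirements), set(supply)
    if req_keys != sup_keys:
        raise KeyMismatchError(req_keys - sup_keys, sup_keys - req_keys)
    records = {
        key: GapRecord(
            requirement_fte=requirements[key],
            supply_fte=supply[key],
            gap_fte=requirements[key] - supply[key],
        )
        for key in requirements
    }
    return GapSeries(records)


@dataclass
class ScenarioComparison:
    """Per-scenario gap trajectories and first/final-year changes.

    ``per_year`` has one row per (scenario, profession, year); ``summary`` one
    row per (scenario, profession) with the gap in the first and final horizon
    years and the change between them.  Both hold full-precision values;
    :meth:`display` rounds gaps to whole FTEs for reading.
    """

    per_year: "pandas.DataFrame"
    summary: "pandas.DataFrame"

    def display(self):
        shown = self.summary.copy()
        for col in ("first_gap_fte", "final_gap_fte", "change_fte"):
            shown[col] = shown[col].round(0).astype(int)
        return shown


def summarize(gaps_by_scenario: Mapping[str, GapSeries]) -> ScenarioComparison:
    """Summarize one or more scenarios' gap series."""
    import pandas as pd

    if not gaps_by_scenario:
        raise ValueError("summarize requires at least one scenario")
    per_year_rows, summary_rows = [], []
    for name, series in gaps_by_scenario.items():
        for (n, t), rec in series.records.items():
            per_year_rows.append(
                {"scenario": name, "profession": n, "year": t, "gap_fte": rec.gap_fte}
            )
        years = series.years()
        first, final = years[0], years[-1]
        for n in series.professions():
            g0, g1 = series.gap(n, first), series.gap(n, final)
            summary_rows.append(
                {
                    "scenario": name,
                    "profession": n,
                    "first_year": first,
                    "first_gap_fte": g0,
                    "final_year": final,
                    "final_gap_fte": g1,
                    "change_fte": g1 - g0,
                }
            )
    return ScenarioComparison(
        per_year=pd.DataFrame(
            per_year_rows, columns=["scenario", "profession", "year", "gap_fte"]
        ),
        summary=pd.DataFrame(
            summary_rows,
            columns=[
                "scenario", "profession", "first_year", "first_gap_fte",
                "final_year", "final_gap_fte", "change_fte",
            ],
        ),
    )


def _fmt(value) -> str:
    # repr-style shortest round-trip float formatting: byte-deterministic and
    # lossless on re-read.
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow([_fmt(v) for v in row])


def write_results(runs: Mapping[str, "ScenarioRun"], out_dir, plot: str = "none") -> list[Path]:
    """Write per-scenario gap and stock/flow CSVs (and optional plots).

    ``runs`` maps scenario name to objects exposing ``gaps`` (GapSeries),
    ``trajectory`` (StockTrajectory), ``supply`` (effective supply map) and
    ``error``; failed scenarios are skipped here (the run manifest records
    them).  Files are deterministic given inputs: fixed column order and
    shortest round-trip float formatting.  An empty ``runs`` writes nothing.
    """
    out = Path(out_dir)
    written: list[Path] = []
    if not runs:
        return written
    out.mkdir(parents=True, exist_ok=True)
    for name, run in runs.items():
        if getattr(run, "error", None):
            continue
        gaps_path = out / f"gaps_{name}.csv"
        rows = [
            [name, n, t, rec.requirement_fte, rec.supply_fte, rec.gap_fte]
            for (n, t), rec in sorted(run.gaps.records.items())
        ]
        _write_csv(
            gaps_path,
            ["scenario", "profession", "year", "requirement_fte", "supply_fte", "gap_fte"],
            rows,
        )
        written.append(gaps_path)

        traj = run.trajectory
        flow_path = out / f"stockflow_{name}.csv"
        flow_rows = []
        for (n, a, t), s in sorted(traj.stock.items()):
            flow_rows.append(
                [
                    n, a, t, s,
                    traj.entrants.get((n, t), 0.0),
                    traj.graduates.get((n, t), 0.0),
                    traj.exits.get((n, t), 0.0),
                    run.supply[(n, t)],
                ]
            )
        _write_csv(
            flow_path,
            ["profession", "age_group", "year", "stock",
             "entrants", "graduates", "exits", "effective_supply_fte"],
            flow_rows,
        )
        written.append(flow_path)

        if plot and plot != "none":
            written.extend(_plot_gaps(run.gaps, name, out, plot))
    return written


def _plot_gaps(series: GapSeries, scenario: str, out: Path, fmt: str) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    years = series.years()
    for n in series.professions():
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(years, [series.gap(n, t) for t in years], marker="o", ms=3)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("year")
        ax.set_ylabel("gap (FTE, + = shortage)")
        ax.set_title(f"{scenario}: {n}")
        fig.tight_layout()
        path = out / f"gap_{scenario}_{n}.{fmt}"
        fig.savefig(path)
        plt.close(fig)
        paths.append(path)
    return paths
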