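"""ERD/ERS polarization analysis of a labeled band-power session.

For each repetition cycle of each task, the band-limited power (mu/alpha and
beta by default) is averaged over each hemisphere's electrodes. The rest
block of the same repetition provides the baseline; the analysis reports the
baseline, the maximum excursions above and below it, the classical
percent-change of mean event power relative to baseline (negative = ERD,
positive = ERS), and the ratio of maximum increase to maximum decrease.
Results are keyed by (arm, movement, hemisphere, band, cycle) — a full
2 x 2 x 2 x 2 x repetitions cross; cells without data are reported absent,
never fabricated.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MibciError, ReportError
from .labels import ACTIVE_LABELS, EpochLabel
from .synth import DEFAULT_LATERALITY, BandPowerTable

#: band columns entering the polarization analysis (mu is the alpha column)
ANALYSIS_BANDS: tuple[str, ...] = ("alpha", "beta")


def compute_baseline(series: np.ndarray) -> float:
    """Arithmetic mean of a series — the per-cycle baseline."""
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise MibciError("cannot compute a baseline from an empty series")
    return float(s.mean())


def max_excursions(series: np.ndarray, baseline: float) -> tuple[float, float]:
    """(max increase above, max decrease below) the baseline; both >= 0."""
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise MibciError("cannot compute excursions of an empty series")
    return (
        max(0.0, float(s.max()) - baseline),
        max(0.0, baseline - float(s.min())),
    )


def erd_ers_percent(event_power: float, baseline_power: float) -> float | None:
    """Classical percent change: 100 * (event - baseline) / baseline.

    Negative values are ERD (power suppression), positive values ERS.
    Returns None (undefined) for a non-positive baseline.
    """
    if baseline_power <= 0:
        return None
    return 100.0 * (event_power - baseline_power) / baseline_power


@dataclass(frozen=True)
class GroupingKey:
    arm: str  # left | right
    movement: str  # flexion | extension
    hemisphere: str  # left | right
    band: str  # alpha | beta
    cycle: int  # 1..repetitions


@dataclass
class ERDERSResult:
    """Polarization summary for one (arm, movement, hemisphere, band, cycle) cell."""

    baseline: float
    max_increase: float
    max_decrease: float
    percent_change: float | None  # mean event power vs baseline, signed
    max_increase_percent: float | None
    max_decrease_percent: float | None
    ratio: float | None  # max_increase / max_decrease; None when undefined
    n_samples: int

    @property
    def ratio_defined(self) -> bool:
        return self.ratio is not None


def _label_runs(labels: np.ndarray) -> list[tuple[EpochLabel, slice]]:
    """Contiguous runs of identical labels, in order."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] is not labels[start]:
            runs.append((labels[start], slice(start, i)))
            start = i
    return runs


def analyze_session(
    table: BandPowerTable,
    laterality_map: dict[int, str] | None = None,
    repetitions: int | None = None,
    bands: tuple[str, ...] = ANALYSIS_BANDS,
    edge_trim_s: float = 0.25,
) -> dict[GroupingKey, ERDERSResult]:
    """Per-cycle ERD/ERS results for every populated grouping cell.

    ``edge_trim_s`` drops rows whose sliding band-power window straddles a
    segment boundary (half the generator's default window each side), so event
    and rest statistics are not cross-contaminated. Cycle ``k``'s baseline is
    the mean power over rest run ``k``; when a cycle has no rest rows the
    event series' own mean serves as baseline.
    """
    lat = laterality_map if laterality_map is not None else DEFAULT_LATERALITY
    n_channels = len(table.feature_columns) // len(
        {c.rsplit("_", 1)[1] for c in table.feature_columns}
    )
    missing = [ch for ch in range(n_channels) if ch not in lat]
    if missing:
        raise MibciError(f"laterality_map does not cover channels {missing}")

    labels = table.labels
    ts = table.timestamps
    runs = _label_runs(labels)
    active_counts = {lab: sum(1 for l, _ in runs if l is lab) for lab in ACTIVE_LABELS}
    n_cycles = max(active_counts.values(), default=0)
    if repetitions is not None:
        if any(c > repetitions for c in active_counts.values()):
            raise MibciError(
                f"label track has more runs than the stated {repetitions} repetitions: "
                f"{ {l.value: c for l, c in active_counts.items()} }"
            )
        n_cycles = repetitions

    def trimmed(sl: slice) -> np.ndarray:
        idx = np.arange(sl.start, sl.stop)
        lo, hi = ts[sl.start] + edge_trim_s, ts[sl.stop - 1] - edge_trim_s
        keep = idx[(ts[idx] >= lo) & (ts[idx] <= hi)]
        return keep if keep.size else idx  # never drop a run entirely

    hemi_channels = {
        h: [ch for ch in range(n_channels) if lat[ch] == h] for h in ("left", "right")
    }
    hemi_cols = {
        (h, b): [f"ch{ch + 1}_{b}" for ch in chans]
        for h, chans in hemi_channels.items()
        for b in bands
    }

    # rest run index -> cycle number (1-based)
    rest_runs = [sl for lab, sl in runs if lab is EpochLabel.REST]
    event_runs: dict[EpochLabel, list[slice]] = {lab: [] for lab in ACTIVE_LABELS}
    for lab, sl in runs:
        if lab is not EpochLabel.REST:
            event_runs[lab].append(sl)

    frame = table.frame
    results: dict[GroupingKey, ERDERSResult] = {}
    for lab in ACTIVE_LABELS:
        for cycle_idx, sl in enumerate(event_runs[lab]):
            cycle = cycle_idx + 1
            ev_idx = trimmed(sl)
            rest_idx = (
                trimmed(rest_runs[cycle_idx]) if cycle_idx < len(rest_runs) else None
            )
            for (hemi, band), cols in hemi_cols.items():
                series = frame.iloc[ev_idx][cols].to_numpy().mean(axis=1)
                if rest_idx is not None:
                    baseline = compute_baseline(
                        frame.iloc[rest_idx][cols].to_numpy().mean(axis=1)
                    )
                else:
                    baseline = compute_baseline(series)
                inc, dec = max_excursions(series, baseline)
                pct = erd_ers_percent(float(series.mean()), baseline)
                results[GroupingKey(lab.arm, lab.movement, hemi, band, cycle)] = ERDERSResult(
                    baseline=baseline,
                    max_increase=inc,
                    max_decrease=dec,
                    percent_change=pct,
                    max_increase_percent=100.0 * inc / baseline if baseline > 0 else None,
                    max_decrease_percent=100.0 * dec / baseline if baseline > 0 else None,
                    ratio=inc / dec if dec > 0 else None,
                    n_samples=len(ev_idx),
                )
    return results


def results_to_frame(results: dict[GroupingKey, ERDERSResult]) -> pd.DataFrame:
    """Tidy table: one row per populated grouping cell."""
    if not results:
        raise ReportError("no ERD/ERS results to tabulate")
    rows = []
    for key in sorted(
        results, key=lambda k: (k.arm, k.movement, k.hemisphere, k.band, k.cycle)
    ):
        r = results[key]
        rows.append(
            {
                "arm": key.arm,
                "movement": key.movement,
                "hemisphere": key.hemisphere,
                "band": key.band,
                "cycle": key.cycle,
                "baseline": r.baseline,
                "max_increase": r.max_increase,
                "max_decrease": r.max_decrease,
                "percent_change": r.percent_change,
                "max_increase_percent": r.max_increase_percent,
                "max_decrease_percent": r.max_decrease_percent,
                "ratio": r.ratio if r.ratio is not None else np.nan,
                "ratio_defined": r.ratio is not None,
                "n_samples": r.n_samples,
            }
        )
    return pd.DataFrame(rows)


def render_reports(
    results: dict[GroupingKey, ERDERSResult], outdir: str | Path, make_plots: bool = True
) -> dict[str, Path]:
    """Write the tidy CSV and per-category summary plots.

    Plots aggregate by simple group means; all computation beyond averaging
    happens in :func:`analyze_session`. The ratio convention
    (max_increase / max_decrease) is recorded in the CSV header comment file.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    frame = results_to_frame(results)
    paths: dict[str, Path] = {}
    csv_path = out / "erd_ers_cells.csv"
    frame.to_csv(csv_path, index=False)
    paths["cells"] = csv_path
    meta_path = out / "erd_ers_metadata.txt"
    meta_path.write_text(
        "percent_change: 100*(mean event power - baseline)/baseline; negative = ERD\n"
        "ratio convention: max_increase / max_decrease (undefined when max_decrease == 0)\n"
        "baseline: mean power over the same repetition's rest block\n"
    )
    paths["metadata"] = meta_path

    if make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        task = frame.assign(task=frame["arm"] + " " + frame["movement"])
        # ratio differential per task across cycles
        fig, ax = plt.subplots(figsize=(7, 4))
        for name, grp in task.groupby("task"):
            by_cycle = grp.dropna(subset=["ratio"]).groupby("cycle")["ratio"].mean()
            ax.plot(by_cycle.index, by_cycle.values, marker="o", label=name)
        ax.set_xlabel("repetition cycle")
        ax.set_ylabel("ERD/ERS ratio (max increase / max decrease)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = out / "ratio_by_cycle.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths["ratio_plot"] = p

        fig, ax = plt.subplots(figsize=(7, 4))
        pivot = task.groupby(["task", "band", "hemisphere"])["percent_change"].mean().unstack([1, 2])
        pivot.plot.bar(ax=ax)
        ax.set_ylabel("mean power change vs baseline (%)")
        ax.axhline(0, color="k", lw=0.8)
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / "percent_change_by_task.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths["percent_plot"] = p
    return paths
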