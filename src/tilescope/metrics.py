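"""Viewer performance metrics computed from simulation event logs.

Definitions (all on the simulated clock; no wall-clock time is ever
reported as a result):

* **Frame-rate** -- inverse of the time between drawn frames.
* **Buffer-rate** -- bytes of decompressed tile data whose transfer (and
  enhancement) completed between the start of a frame and the prior frame,
  divided by that frame's duration in seconds.
* **TeFOV** (time to an entirely new field of view) -- time from a
  move-field request, whose new view rectangle shares no pixels with the
  previous one, until every tile of the new field *plus its buffering
  perimeter* is resident for a layer.  Fields whose tiles were already all
  resident at move time (accidental re-tracing) are excluded and counted.
* **TPT** (time per tile) -- TeFOV divided by the number of tiles buffered,
  perimeter included, so ``TPT * n_tiles == TeFOV`` identically.

Summaries report medians with 25th-75th percentiles (linear interpolation
between order statistics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .pyramid import SlidePyramid, TileRef, ViewState, buffer_region, layer_assignment
from .scheduler import EngineConfig, EventLog


@dataclass
class FieldRecord:
    """One marked move-field event, per resolution layer."""

    move_time_ms: float
    layer: str  # "LR" | "HR"
    n_tiles: int
    tefov_ms: Optional[float]  # None -> layer never completed within the log
    excluded: bool = False  # fully pre-buffered at move time

    @property
    def tpt_ms(self) -> Optional[float]:
        if self.tefov_ms is None or self.n_tiles == 0:
            return None
        return self.tefov_ms / self.n_tiles


def compute_tefov(
    log: EventLog, pyramid: SlidePyramid, config: EngineConfig
) -> list[FieldRecord]:
    """Per-field TeFOV/TPT records for every MOVE_FIELD marker in the log.

    The target set of a field is re-derived from the logged view exactly as
    the scheduler derives its buffer regions (view tiles dilated by the
    perimeter radius).  Residency is replayed from MTX_DONE/PURGE records.
    """
    active: set[TileRef] = set()
    # open fields: list of dicts with missing-set trackers
    open_fields: list[dict] = []
    records: list[FieldRecord] = []

    def targets_for(view: ViewState) -> list[tuple[str, set[TileRef]]]:
        la = layer_assignment(view, pyramid)
        out = []
        if la.lr_level is not None:
            out.append(("LR", buffer_region(view, pyramid, la.lr_level, config.perimeter_radius)))
        if la.hr_level is not None:
            out.append(("HR", buffer_region(view, pyramid, la.hr_level, config.perimeter_radius)))
        return out

    for rec in log:
        if rec.kind == "MTX_DONE":
            done = {TileRef(*t) for t, _slot in rec.data["tiles"]}
            active |= done
            for f in open_fields:
                f["missing"] -= done
                if not f["missing"] and f["tefov"] is None:
                    f["tefov"] = rec.time - f["move_time"]
        elif rec.kind == "PURGE":
            active -= {TileRef(*t) for t in rec.data["tiles"]}
        elif rec.kind == "MOVE_FIELD":
            view = ViewState.from_dict(rec.data["view"])
            for layer, targets in targets_for(view):
                missing = targets - active
                rec_field = {
                    "move_time": rec.time,
                    "layer": layer,
                    "n": len(targets),
                    "missing": missing,
                    "tefov": None if missing else 0.0,
                    "excluded": not missing,
                }
                open_fields.append(rec_field)

    for f in open_fields:
        records.append(
            FieldRecord(
                move_time_ms=f["move_time"],
                layer=f["layer"],
                n_tiles=f["n"],
                tefov_ms=f["tefov"] if not f["excluded"] else None,
                excluded=f["excluded"],
            )
        )
    records.sort(key=lambda r: (r.move_time_ms, r.layer))
    return records


def compute_tpt(record: FieldRecord) -> Optional[float]:
    """TeFOV divided by tiles buffered (view + perimeter)."""
    return record.tpt_ms


def compute_rates(log: EventLog) -> pd.DataFrame:
    """Per-frame series: frame duration, frame-rate, bytes completed, buffer-rate."""
    frames = [r for r in log if r.kind == "FRAME"]
    if len(frames) < 2:
        raise ValueError("need at least two FRAME records")
    rows = []
    prev_t = 0.0
    for i, fr in enumerate(frames):
        dt = fr.time - prev_t
        rows.append(
            {
                "time_ms": fr.time,
                "duration_ms": dt,
                "frame_rate_fps": 1000.0 / dt,
                "bytes": fr.data["bytes"],
                "buffer_rate_bps": fr.data["bytes"] / (dt / 1000.0),
                "drawn_tiles": len(fr.data["drawn"]),
            }
        )
        prev_t = fr.time
    return pd.DataFrame(rows)


def _summary(values: list[float]) -> dict:
    if not values:
        return {"median": None, "p25": None, "p75": None, "n": 0}
    arr = np.asarray(values, dtype=float)
    q25, q50, q75 = np.percentile(arr, [25, 50, 75], method="linear")
    return {"median": float(q50), "p25": float(q25), "p75": float(q75), "n": len(arr)}


@dataclass
class MetricsReport:
    fields: pd.DataFrame
    frames: pd.DataFrame
    summary: dict
    excluded_fields: int
    incomplete_fields: int
    empty: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "summary": self.summary,
                "excluded_fields": self.excluded_fields,
                "incomplete_fields": self.incomplete_fields,
                "empty": self.empty,
            },
            indent=1,
        )

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fields.to_csv(out / "fields.csv", index=False)
        self.frames.to_csv(out / "frames.csv", index=False)
        (out / "summary.json").write_text(self.to_json())


def report(log: EventLog, pyramid: SlidePyramid, config: EngineConfig) -> MetricsReport:
    """Aggregate a run's event log into field/frame tables and a summary."""
    if len(log) == 0:
        return MetricsReport(
            fields=pd.DataFrame(),
            frames=pd.DataFrame(),
            summary={},
            excluded_fields=0,
            incomplete_fields=0,
            empty=True,
        )
    recs = compute_tefov(log, pyramid, config)
    fields = pd.DataFrame(
        [
            {
                "move_time_ms": r.move_time_ms,
                "layer": r.layer,
                "n_tiles": r.n_tiles,
                "tefov_ms": r.tefov_ms,
                "tpt_ms": r.tpt_ms,
                "excluded": r.excluded,
            }
            for r in recs
        ]
    )
    frames = compute_rates(log)
    included = [r for r in recs if not r.excluded and r.tefov_ms is not None]
    summary = {
        "lr_tefov_ms": _summary([r.tefov_ms for r in included if r.layer == "LR"]),
        "hr_tefov_ms": _summary([r.tefov_ms for r in included if r.layer == "HR"]),
        "lr_tpt_ms": _summary([r.tpt_ms for r in included if r.layer == "LR"]),
        "hr_tpt_ms": _summary([r.tpt_ms for r in included if r.layer == "HR"]),
        "frame_rate_fps": _summary(frames["frame_rate_fps"].tolist()),
        "buffer_rate_bps": _summary(frames["buffer_rate_bps"].tolist()),
        # buffering happens in short bursts around field moves; the burst
        # figure summarizes only frames in which transfers completed
        "buffer_rate_bps_bursts": _summary(
            frames.loc[frames["bytes"] > 0, "buffer_rate_bps"].tolist()
        ),
    }
    return MetricsReport(
        fields=fields,
        frames=frames,
        summary=summary,
        excluded_fields=sum(r.excluded for r in recs),
        incomplete_fields=sum((not r.excluded) and r.tefov_ms is None for r in recs),
    )


def plot_trace(report_: MetricsReport, path: str | Path, smooth_ms: float = 48.0) -> None:
    """Optional frame/buffer-rate trace plot (cosmetic smoothing configurable)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fr = report_.frames
    t = fr["time_ms"].to_numpy() / 1000.0
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(9, 5))
    win = max(1, int(round(smooth_ms / max(fr["duration_ms"].median(), 1e-9))))
    ax1.plot(t, fr["frame_rate_fps"].rolling(win, min_periods=1).mean())
    ax1.set_ylabel("frame rate (fps)")
    ax2.plot(t, fr["buffer_rate_bps"].rolling(win, min_periods=1).mean() / 1e9)
    ax2.set_ylabel("buffer rate (GB/s)")
    ax2.set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
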