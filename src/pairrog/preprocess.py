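"""Fluorescence-trace preprocessing: Delta-F/F and the responsivity criterion.

Trials are fixed-length 24-frame traces: 4 pre-stimulus blank frames, 3
stimulus frames, 17 post-stimulus frames.  Baseline F0 is the median over the
pre-stimulus frames plus one extra frame (frames 1-5, 1-based) to absorb onset
delays; the evoked window symmetrically takes the stimulus frames plus one
extra frame (frames 6-9).  Both windows are configurable.  Cells are retained
for analysis when their mean evoked Delta-F/F at the highest contrast is at
least two standard deviations above the spontaneous (blank-trial) mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import FRAMES_PER_TRIAL

__all__ = ["FrameLayout", "TraceTable", "compute_dff", "apply_inclusion",
           "preprocess_traces"]


@dataclass(frozen=True)
class FrameLayout:
    """1-based inclusive frame windows within a trial."""

    baseline: tuple = (1, 5)
    evoked: tuple = (6, 9)
    n_frames: int = FRAMES_PER_TRIAL

    def baseline_slice(self) -> slice:
        return slice(self.baseline[0] - 1, self.baseline[1])

    def evoked_slice(self) -> slice:
        return slice(self.evoked[0] - 1, self.evoked[1])


class TraceTable:
    """Wide table of frame-wise fluorescence: cell_id, trial, stimulus, f01..f24.

    ``stimulus`` is a contrast percent or the string ``"blank"``.
    """

    def __init__(self, frame: pd.DataFrame, layout: FrameLayout = FrameLayout()):
        self.layout = layout
        cols = [f"f{i:02d}" for i in range(1, layout.n_frames + 1)]
        missing = [c for c in ("cell_id", "trial", "stimulus", *cols)
                   if c not in frame.columns]
        if missing:
            raise ValueError(f"trace table missing column(s): {', '.join(missing)}")
        self.frame = frame.reset_index(drop=True)
        self._frame_cols = cols

    def traces(self) -> np.ndarray:
        return self.frame[self._frame_cols].to_numpy(dtype=float)

    @classmethod
    def read(cls, path, layout: FrameLayout = FrameLayout(), sep: str = ",") -> "TraceTable":
        return cls(pd.read_csv(path, sep=sep), layout=layout)

    def write(self, path, sep: str = ",") -> None:
        self.frame.to_csv(path, sep=sep, index=False)


def compute_dff(trace, layout: FrameLayout = FrameLayout()):
    """Baseline fluorescence and evoked Delta-F/F for one 24-frame trace.

    F0 is the median over the baseline window; Delta-F/F is the mean of
    (F(i) - F0)/F0 over the evoked window.  Returns ``(F0, dff)``; a zero
    baseline yields ``(0, nan)`` — a flagged record, not an exception.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.shape[-1] != layout.n_frames:
        raise ValueError(f"expected {layout.n_frames} frames, got {trace.shape[-1]}")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    f0 = float(np.median(trace[layout.baseline_slice()]))
    if f0 == 0:
        return 0.0, float("nan")
    dff = float(np.mean((trace[layout.evoked_slice()] - f0) / f0))
    return f0, dff


def preprocess_traces(table: TraceTable) -> pd.DataFrame:
    """Per-trial F0 and evoked Delta-F/F for every record in a trace table."""
    traces = table.traces()
    lay = table.layout
    f0 = np.median(traces[:, lay.baseline_slice()], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = np.where(
            f0 != 0,
            np.mean((traces[:, lay.evoked_slice()] - f0[:, None]) / np.where(f0 == 0, 1.0, f0)[:, None],
                    axis=1),
            np.nan,
        )
    out = table.frame[["cell_id", "trial", "stimulus"]].copy()
    out["f0"] = f0
    out["dff"] = dff
    out["flagged"] = f0 == 0
    return out


def apply_inclusion(dff_table: pd.DataFrame, sd_factor: float = 2.0) -> pd.DataFrame:
    """Visual-responsivity criterion per cell.

    A cell is included when its mean evoked Delta-F/F at the highest contrast
    is at least ``sd_factor`` standard deviations above the spontaneous mean
    (both from blank trials); the threshold is inclusive.  Cells without blank
    trials cannot be assessed and are flagged indeterminate.

    ``dff_table`` is the output of :func:`preprocess_traces` (columns cell_id,
    stimulus, dff).  Returns one row per cell with columns ``included`` (a
    nullable boolean: pd.NA when indeterminate), ``evoked_max``,
    ``spont_mean``, ``spont_sd`` and ``threshold``.
    """
    rows = []
    for cell, sub in dff_table.groupby("cell_id", sort=True):
        blanks = sub[sub["stimulus"].astype(str) == "blank"]["dff"].dropna()
        stim = sub[sub["stimulus"].astype(str) != "blank"].copy()
        stim["stimulus"] = pd.to_numeric(stim["stimulus"])
        if stim.empty:
            raise ValueError(f"cell {cell!r} has no stimulus trials")
        cmax = stim["stimulus"].max()
        evoked = float(stim.loc[stim["stimulus"] == cmax, "dff"].mean())
        if len(blanks) == 0:
            rows.append({"cell_id": cell, "included": pd.NA, "evoked_max": evoked,
                         "spont_mean": np.nan, "spont_sd": np.nan, "threshold": np.nan})
            continue
        mu = float(blanks.mean())
        sd = float(blanks.std(ddof=1)) if len(blanks) > 1 else 0.0
        thr = mu + sd_factor * sd
        rows.append({"cell_id": cell, "included": bool(evoked >= thr),
                     "evoked_max": evoked, "spont_mean": mu, "spont_sd": sd,
                     "threshold": thr})
    out = pd.DataFrame(rows)
    out["included"] = out["included"].astype("boolean")
    return out
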