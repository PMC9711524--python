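"""Container for multi-community fluorescence traces.

One microfluidic "community" (a trapping region of ~10,000 cells) contributes
one mean-fluorescence trace; a recording is a rectangular matrix of
communities × time points on a shared uniform grid.  The CSV layout is
``time_h`` first, then one column per community (``c01``, ``c02``, ...), with
an optional JSON sidecar holding sampling interval, channel, and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CommunityTraces", "TraceError", "read_traces", "write_traces"]


class TraceError(ValueError):
    """Malformed trace table."""


@dataclass
class CommunityTraces:
    """Fluorescence values for a set of communities on one time grid.

    values:     (n_communities, n_time) array, arbitrary fluorescence units
    time_h:     shared time grid in hours, uniform spacing
    communities: identifiers, one per row
    channel:    reporter name (ThT | dEGFP | KcsA-EGFP | mCherry)
    meta:       provenance (generator config, seed, or source path)
    """

    values: np.ndarray
    time_h: np.ndarray
    communities: list[str] = field(default_factory=list)
    channel: str = "dEGFP"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_h = np.asarray(self.time_h, dtype=float)
        if self.values.ndim != 2:
            raise TraceError("values must be a 2-D communities × time matrix")
        if self.values.shape[1] != self.time_h.shape[0]:
            raise TraceError(
                f"matrix has {self.values.shape[1]} time points but grid has {self.time_h.shape[0]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise TraceError("trace values must be finite")
        steps = np.diff(self.time_h)
        if len(steps) == 0 or np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
            raise TraceError("time grid must be strictly increasing with uniform spacing")
        if not self.communities:
            self.communities = [f"c{i + 1:02d}" for i in range(self.values.shape[0])]
        if len(self.communities) != self.values.shape[0]:
            raise TraceError("one identifier per community row required")

    @property
    def n_communities(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def dt(self) -> float:
        """Sampling interval in hours."""
        return float(self.time_h[1] - self.time_h[0])

    @property
    def duration(self) -> float:
        return float(self.time_h[-1] - self.time_h[0])

    def with_values(self, values: np.ndarray, **meta_updates) -> "CommunityTraces":
        """Same grid/identifiers, new matrix (the shape must match)."""
        meta = {**self.meta, **meta_updates}
        return CommunityTraces(
            values=values, time_h=self.time_h, communities=list(self.communities),
            channel=self.channel, meta=meta,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.time_h})
        for name, row in zip(self.communities, self.values):
            df[name] = row
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, channel: str = "dEGFP", meta: dict | None = None) -> "CommunityTraces":
        if "time_h" not in df.columns:
            raise TraceError("trace table must have a 'time_h' first column")
        names = [c for c in df.columns if c != "time_h"]
        if not names:
            raise TraceError("trace table has no community columns")
        bad = [c for c in names if not np.issubdtype(df[c].dtype, np.number)]
        if bad:
            raise TraceError(f"non-numeric community column(s): {bad}")
        return cls(
            values=df[names].to_numpy().T, time_h=df["time_h"].to_numpy(),
            communities=list(names), channel=channel, meta=meta or {},
        )


def write_traces(traces: CommunityTraces, csv_path, meta_path=None) -> None:
    """Write the trace CSV and (optionally) its JSON metadata sidecar."""
    traces.to_frame().to_csv(csv_path, index=False)
    if meta_path is not None:
        meta = {
            "sampling_interval_h": traces.dt,
            "channel": traces.channel,
            "n_communities": traces.n_communities,
            **traces.meta,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def read_traces(csv_path, meta_path=None, channel: str | None = None) -> CommunityTraces:
    """Load a trace CSV (and sidecar) written by :func:`write_traces`."""
    df = pd.read_csv(csv_path)
    meta: dict = {"source": str(csv_path)}
    ch = channel or "dEGFP"
    if meta_path is not None:
        with open(meta_path) as fh:
            side = json.load(fh)
        meta.update(side)
        ch = channel or side.get("channel", ch)
    return CommunityTraces.from_frame(df, channel=ch, meta=meta)
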