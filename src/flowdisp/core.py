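"""Core containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Acquisition channels every event table must carry. ``FL`` holds the
#: log-scale fluorescence intensity of the stained protein; the scatter and
#: DAPI channels are on the instrument's raw scale.
CHANNELS = ("FSC-A", "SSC-A", "FSC-W", "DAPI", "FL")


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class NoValleyError(RuntimeError):
    """A density was unimodal where a peak-valley-peak motif was expected."""


@dataclass
class EventTable:
    """One acquisition sample: events x channels plus sample metadata.

    ``data`` rows are events; required columns are :data:`CHANNELS`.
    """

    data: pd.DataFrame
    sample_id: str
    line_id: str = ""
    protein: str = ""
    replicate_index: int = 0
    batch_id: str = "batch0"

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table missing channels: {missing}")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame) -> "EventTable":
        return replace(self, data=data.reset_index(drop=True))

    def meta(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "line_id": self.line_id,
            "protein": self.protein,
            "replicate_index": self.replicate_index,
            "batch_id": self.batch_id,
        }


@dataclass
class SampleSummary:
    """Per-sample expression summary after gating."""

    sample_id: str
    line_id: str
    protein: str
    n_cells: int
    mean: float
    sd: float
    cv: float
    cv_given_mean: float = float("nan")
    K: float = float("nan")
    outlier: bool = False
    extrapolated: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class QCReport:
    """Per-sample retention trace and replicate-reproducibility scores."""

    retention: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    k_scores: dict[str, float] = field(default_factory=dict)
    outliers: dict[str, bool] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)

    def record(self, sample_id: str, step: str, retained: int) -> None:
        trace = self.retention.setdefault(sample_id, [])
        if trace and retained > trace[-1][1]:
            raise ValueError(
                f"retention increased at step {step!r} for sample {sample_id!r}"
            )
        trace.append((step, retained))

    def log(self, message: str) -> None:
        self.messages.append(message)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sample_id, trace in self.retention.items():
            for step, retained in trace:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "step": step,
                        "events_retained": retained,
                        "K": self.k_scores.get(sample_id, float("nan")),
                        "outlier": self.outliers.get(sample_id, False),
                        "dropped_reason": self.dropped.get(sample_id, ""),
                    }
                )
        return pd.DataFrame(rows)
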