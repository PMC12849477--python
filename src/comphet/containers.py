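"""Shared lightweight data containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EventTable:
    """Flow-cytometry events for one strain x timepoint sample.

    ``values`` hold the selected fluorescence channel on a linear scale
    (raw detector units); log transformation is an explicit downstream
    step, never applied silently here.
    """

    strain: str
    timepoint_h: float
    channel: str
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.values.size

    def to_frame(self, sample_id: str | None = None) -> pd.DataFrame:
        sid = sample_id or f"{self.strain}_t{self.timepoint_h:g}"
        return pd.DataFrame(
            {
                "sample_id": sid,
                "strain": self.strain,
                "timepoint_h": self.timepoint_h,
                "value": self.values,
            }
        )
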