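"""Per-event cytometry table container.

Events carry four channels from a blue/red-laser bench cytometer:
forward-scatter height (``fsc_h``, cell size and acquisition trigger),
pulse width (``width``, singlet/doublet discrimination), green
fluorescence height (``fl1_h``, GFP growth reporter) and red
fluorescence height (``fl3_h``, propidium iodide viability stain).
Synthetic tables additionally carry a ``label`` column with the
ground-truth mixture component of each event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Channel columns required in every event table, in canonical order.
CHANNELS = ("fsc_h", "width", "fl1_h", "fl3_h")


class EmptyTableError(ValueError):
    """Raised when an operation requires at least one event."""


@dataclass
class EventTable:
    """A validated per-event channel table.

    Parameters
    ----------
    data
        DataFrame with columns ``fsc_h, width, fl1_h, fl3_h`` and
        optionally ``event_id`` and ``label``. All channel values must
        be finite and non-negative; all columns share one length.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table is missing channel column(s): {missing}")
        values = self.data[list(CHANNELS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("channel values must be finite")
        if np.any(values < 0):
            raise ValueError("channel values must be non-negative")
        if "event_id" not in self.data.columns:
            self.data = self.data.copy()
            self.data.insert(0, "event_id", np.arange(len(self.data)))

    @classmethod
    def from_arrays(
        cls,
        fsc_h,
        width,
        fl1_h,
        fl3_h,
        label=None,
    ) -> "EventTable":
        cols = {
            "fsc_h": np.asarray(fsc_h, dtype=float),
            "width": np.asarray(width, dtype=float),
            "fl1_h": np.asarray(fl1_h, dtype=float),
            "fl3_h": np.asarray(fl3_h, dtype=float),
        }
        lengths = {len(v) for v in cols.values()}
        if len(lengths) != 1:
            raise ValueError("all channel vectors must have equal length")
        if label is not None:
            cols["label"] = np.asarray(label)
            if len(cols["label"]) != lengths.pop():
                raise ValueError("label vector length must match channels")
        return cls(pd.DataFrame(cols))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def fsc_h(self) -> np.ndarray:
        return self.data["fsc_h"].to_numpy(dtype=float)

    @property
    def width(self) -> np.ndarray:
        return self.data["width"].to_numpy(dtype=float)

    @property
    def fl1_h(self) -> np.ndarray:
        return self.data["fl1_h"].to_numpy(dtype=float)

    @property
    def fl3_h(self) -> np.ndarray:
        return self.data["fl3_h"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray | None:
        if "label" in self.data.columns:
            return self.data["label"].to_numpy()
        return None
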