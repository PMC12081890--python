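"""Readers, writers and pipeline configuration.

CSV is the canonical interchange format (event tables, time series,
reports); a minimal list-mode FCS 3.0/3.1 reader is provided as an
optional extra for tables exported directly from an acquisition
workstation. Output tables carry a ``# config_hash: …`` comment line
above the header so every artefact is traceable to the configuration
that produced it (read them back with ``comment="#"``).
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import CHANNELS, EventTable

#: FCS $PnN parameter names mapped onto internal channel columns.
FCS_CHANNEL_MAP = {
    "fsc-h": "fsc_h",
    "width": "width",
    "fl1-h": "fl1_h",
    "fl3-h": "fl3_h",
}


class SchemaError(ValueError):
    """An input file is missing required columns or channels."""


# --------------------------------------------------------------------------
# CSV event tables
# --------------------------------------------------------------------------

def read_event_table(path, format: str | None = None) -> EventTable:
    """Read a per-event table from CSV or FCS.

    The format is inferred from the suffix unless given explicitly.
    Missing channels raise :class:`SchemaError` naming the channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "csv":
        frame = pd.read_csv(path, comment="#")
        missing = [c for c in CHANNELS if c not in frame.columns]
        if missing:
            raise SchemaError(
                f"{path.name}: missing channel column(s) {missing}"
            )
        return EventTable(frame)
    if format == "fcs":
        return read_fcs(path)
    raise ValueError(f"unknown format {format!r}")


def write_event_table(events: EventTable, path, config_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        events.data.to_csv(fh, index=False)


def write_table(frame: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """Write any result table as CSV with the traceability comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        frame.to_csv(fh, index=False)


# --------------------------------------------------------------------------
# minimal list-mode FCS 3.0 / 3.1
# --------------------------------------------------------------------------
# Covers the subset produced by bench cytometers for this analysis:
# list mode ($MODE L), float32 or uint32 data, uniform $PnB, little- or
# big-endian $BYTEORD. No analysis segment, no compensation.

def read_fcs(path) -> EventTable:
    raw = Path(path).read_bytes()
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r}")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin : text_end + 1].decode("latin-1")
    delim = text[0]
    tokens = text[1:].split(delim)
    keywords = {
        tokens[i].strip().upper(): tokens[i + 1]
        for i in range(0, len(tokens) - 1, 2)
    }

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    datatype = keywords["$DATATYPE"].strip().upper()
    byteord = keywords["$BYTEORD"].strip()
    endian = "<" if byteord.startswith("1") else ">"
    data_begin = int(keywords.get("$BEGINDATA") or raw[26:34])
    data_end = int(keywords.get("$ENDDATA") or raw[34:42])

    if keywords.get("$MODE", "L").strip().upper() != "L":
        raise ValueError("only list-mode ($MODE L) FCS files are supported")
    if datatype == "F":
        fmt = "f"
        itemsize = 4
    elif datatype == "I":
        bits = {int(keywords[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if bits != {32}:
            raise ValueError("integer FCS data must be uniform 32-bit")
        fmt = "I"
        itemsize = 4
    else:
        raise ValueError(f"unsupported $DATATYPE {datatype!r}")

    expected = n_par * n_tot * itemsize
    payload = raw[data_begin : data_begin + expected]
    if len(payload) < expected:
        raise ValueError("FCS data segment truncated")
    values = np.array(
        struct.unpack(f"{endian}{n_par * n_tot}{fmt}", payload), dtype=float
    ).reshape(n_tot, n_par)

    names = [
        keywords.get(f"$P{i}N", f"P{i}").strip().lower()
        for i in range(1, n_par + 1)
    ]
    columns = {}
    for j, name in enumerate(names):
        if name in FCS_CHANNEL_MAP:
            columns[FCS_CHANNEL_MAP[name]] = values[:, j]
    missing = [c for c in CHANNELS if c not in columns]
    if missing:
        raise SchemaError(f"FCS file missing channel(s) {missing} ($PnN {names})")
    return EventTable(pd.DataFrame(columns))


def write_fcs(events: EventTable, path) -> None:
    """Write a minimal FCS 3.0 file (float32, little-endian, list mode)."""
    data = np.column_stack(
        [events.fsc_h, events.width, events.fl1_h, events.fl3_h]
    ).astype("<f4")
    n_tot, n_par = data.shape
    pnn = ["FSC-H", "Width", "FL1-H", "FL3-H"]

    payload = data.tobytes()
    keywords = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(pnn, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}R"] = "16777216"
        keywords[f"$P{i}E"] = "0,0"

    header_len = 58  # "FCS3.0" + 4 spaces + 6 x 8-byte offsets
    # iterate: text length depends on the offsets it encodes
    for _ in range(3):
        text = "/" + "".join(f"{k}/{v}/" for k, v in keywords.items())
        text_begin = header_len
        text_end = text_begin + len(text) - 1
        data_begin = text_end + 1
        data_end = data_begin + len(payload) - 1
        keywords["$BEGINDATA"] = str(data_begin)
        keywords["$ENDDATA"] = str(data_end)

    header = (
        b"FCS3.0    "
        + f"{text_begin:>8d}{text_end:>8d}{data_begin:>8d}{data_end:>8d}"
        .encode("ascii")
        + f"{0:>8d}{0:>8d}".encode("ascii")
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(header + text.encode("latin-1") + payload)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one end-to-end analysis run.

    A single ``seed`` governs every stochastic component; stage seeds
    are spawned from it deterministically.
    """

    seed: int
    outdir: str
    width_cutoff: float
    fl1_cutoff: float
    fsc_threshold: float = 80_000.0
    max_events: int = 10_000
    n_events: int = 3_000
    n_timepoints: int = 5
    n_replicates: int = 4
    groups: tuple[str, ...] = ("I", "II", "III")
    # weak-acid partitioning (pyruvate defaults)
    pka: float = 2.5
    ph_out: float = 5.0
    ph_in_starved: float = 6.0
    ph_in_growth: float = 7.0
    mw: float = 88.06
    # yields
    ba0_mm: float = 5.0
    yield_basis: str = "initial"
    producer_variants: dict = field(
        default_factory=lambda: {"1x": 1.1, "6x_alt1d": 2.0, "7x_alt1d": 2.9}
    )
    # statistics
    stats_method: str = "mannwhitney"
    stats_direction: str = "x"

    def __post_init__(self) -> None:
        if self.width_cutoff <= 0 or self.fl1_cutoff <= 0:
            raise ValueError("gate cut-offs must be strictly positive")
        if self.max_events < 1 or self.n_events < 1:
            raise ValueError("event counts must be >= 1")
        if self.yield_basis not in ("initial", "consumed"):
            raise ValueError("yield_basis must be 'initial' or 'consumed'")
        if self.stats_method not in ("mannwhitney", "welch", "gated-t"):
            raise ValueError("unknown stats_method")
        for g in self.groups:
            if g not in ("I", "II", "III"):
                raise ValueError(f"unknown phenotype group {g!r}")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "groups" in raw:
        raw["groups"] = tuple(raw["groups"])
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ValueError(f"invalid configuration {path.name}: {exc}") from exc
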