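"""Reading flow-cytometry events and building log-fluorescence histograms.

CFSE experiments produce list-mode flow-cytometry events (one fluorescence
intensity per cell, optionally a viability-dye channel).  Downstream model
fitting works on one-dimensional histograms of log10 fluorescence, built on a
single bin grid shared by every time point of a time course so that model and
data histograms are directly comparable bin by bin.

Supported inputs are FCS 3.0/3.1 list-mode files (single dataset, float or
integer data) and plain CSV.  A minimal FCS writer is provided for producing
synthetic fixtures; it is not intended for archival output.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Smallest linear intensity kept after floor clamping; events at or below zero
#: are moved here before the log transform so no cell is silently dropped.
MIN_INTENSITY = 1e-3


@dataclass
class EventTable:
    """Raw per-event channel intensities (linear scale, a.u.)."""

    fluorescence: np.ndarray
    viability: Optional[np.ndarray] = None
    time_h: float = 0.0

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.size == 0:
            raise ValueError("EventTable requires at least one event")
        # floor-clamp rather than drop: totals must match instrument counts
        self.fluorescence = np.maximum(self.fluorescence, MIN_INTENSITY)
        if self.viability is not None:
            self.viability = np.asarray(self.viability, dtype=float)
            if self.viability.shape != self.fluorescence.shape:
                raise ValueError("viability/fluorescence length mismatch")

    def __len__(self) -> int:
        return self.fluorescence.size


@dataclass
class Histogram:
    """Binned log10-fluorescence counts for one sample at one time."""

    bin_edges: np.ndarray
    counts: np.ndarray
    time_h: float = 0.0
    run_id: str = "run0"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("negative bin count")

    @property
    def total_cells(self) -> float:
        return float(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def density(self) -> np.ndarray:
        """Probability mass per bin (sums to 1; zero histogram stays zero)."""
        tot = self.counts.sum()
        if tot == 0:
            return np.zeros_like(self.counts)
        return self.counts / tot


@dataclass
class HistogramTimecourse:
    """Histograms for one experiment, ordered by time, on one shared grid.

    ``undivided_mean`` anchors the linear-scale fluorescence of the undivided
    population at every time point (set manually in real experiments, known
    exactly for generated data); the fluorescence model treats it as fixed.
    """

    histograms: list[Histogram]
    undivided_mean: Sequence[float]
    runs: int = 1

    def __post_init__(self) -> None:
        if not self.histograms:
            raise ValueError("empty time course")
        edges0 = self.histograms[0].bin_edges
        for h in self.histograms[1:]:
            if h.bin_edges.shape != edges0.shape or not np.allclose(h.bin_edges, edges0):
                raise ValueError("all histograms must share one bin grid")
        times = [h.time_h for h in self.histograms]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("histogram times must be non-decreasing")
        self.undivided_mean = list(self.undivided_mean)
        if len(self.undivided_mean) != len(self.histograms):
            raise ValueError("one undivided_mean per histogram required")

    @property
    def times(self) -> np.ndarray:
        return np.array([h.time_h for h in self.histograms])

    @property
    def bin_edges(self) -> np.ndarray:
        return self.histograms[0].bin_edges


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 minimal reader & synthetic writer
# ---------------------------------------------------------------------------

def _parse_fcs_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise ValueError("empty FCS TEXT segment")
    delim = raw[0:1].decode("latin-1")
    parts = raw.decode("latin-1").strip(delim).split(delim)
    return {k.strip(): v for k, v in zip(parts[::2], parts[1::2])}


def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read a single-dataset FCS 3.0/3.1 list-mode file into a DataFrame.

    Columns are the $PnN short channel names.  Supports $DATATYPE F/D/I and
    both byte orders; enough for instrument exports of the kind used here.
    """
    data = Path(path).read_bytes()
    if len(data) < 58:
        raise ValueError(f"{path}: not an FCS file (too short)")
    version = data[0:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise ValueError(f"{path}: not an FCS file (header {version!r})")
    text_start, text_end = int(data[10:18]), int(data[18:26])
    text = _parse_fcs_text(data[text_start:text_end + 1])
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    data_start = int(data[26:34]) or int(text.get("$BEGINDATA", 0))
    data_end = int(data[34:42]) or int(text.get("$ENDDATA", 0))
    dtype_code = text.get("$DATATYPE", "F").upper()
    order = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if order.startswith("1") else ">"
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if dtype_code == "F":
        np_dtype = np.dtype(f"{endian}f4")
    elif dtype_code == "D":
        np_dtype = np.dtype(f"{endian}f8")
    elif dtype_code == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise ValueError(f"{path}: unsupported integer widths {bits}")
        np_dtype = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_code}")
    raw = data[data_start:data_end + 1]
    values = np.frombuffer(raw[: n_tot * n_par * np_dtype.itemsize], dtype=np_dtype)
    if values.size < n_tot * n_par:
        raise ValueError(f"{path}: truncated DATA segment")
    table = values.astype(float).reshape(n_tot, n_par)
    return pd.DataFrame(table, columns=names)


def write_fcs(path: str | Path, channels: dict[str, np.ndarray]) -> None:
    """Write a minimal FCS 3.1 file (float32 list mode).

    Intended for synthetic fixtures and round-trip tests only.
    """
    names = list(channels)
    cols = [np.asarray(channels[n], dtype=np.float32) for n in names]
    n_tot = cols[0].size
    if any(c.size != n_tot for c in cols):
        raise ValueError("all channels must have equal length")
    n_par = len(names)
    body = np.column_stack(cols).astype("<f4").tobytes()

    def render_text(begin_data: int, end_data: int) -> bytes:
        kv = {
            "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
            "$PAR": str(n_par), "$TOT": str(n_tot),
            "$BEGINDATA": str(begin_data), "$ENDDATA": str(end_data),
            "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0", "$BEGINSTEXT": "0",
            "$ENDSTEXT": "0", "$NEXTDATA": "0",
        }
        for i, name in enumerate(names, start=1):
            kv[f"$P{i}N"] = name
            kv[f"$P{i}B"] = "32"
            kv[f"$P{i}E"] = "0,0"
            kv[f"$P{i}R"] = "262144"
        return ("/" + "/".join(f"{k}/{v}" for k, v in kv.items()) + "/").encode("ascii")

    text_start = 58
    # fixed-width offsets: iterate once to stabilise lengths
    text = render_text(0, 0)
    for _ in range(3):
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(body) - 1
        new = render_text(data_start, data_end)
        if len(new) == len(text):
            text = new
            break
        text = new
    header = (
        b"FCS3.1    "
        + f"{text_start:8d}{text_end:8d}{data_start:8d}{data_end:8d}".encode()
        + f"{0:8d}{0:8d}".encode()
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(body)


# ---------------------------------------------------------------------------
# Event ingestion and gating
# ---------------------------------------------------------------------------

def read_events(
    path: str | Path,
    fl_channel: str = "FL1-A",
    viability_channel: Optional[str] = None,
    time_h: float = 0.0,
) -> EventTable:
    """Read events of the named channel(s) from an FCS file or a CSV.

    CSV files may either carry a header naming the channels or be headerless
    with one (fluorescence) or two (fluorescence, viability) columns.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    head = path.open("rb").read(6)
    if head.startswith(b"FCS"):
        frame = read_fcs(path)
    else:
        frame = pd.read_csv(path)
        # headerless numeric CSV: first "column name" parses as a number
        try:
            float(str(frame.columns[0]))
        except ValueError:
            pass
        else:
            ncol = frame.shape[1]
            names = [fl_channel, viability_channel or "viability"][:ncol]
            frame = pd.read_csv(path, header=None, names=names)
    if frame.empty:
        raise ValueError(f"{path}: no events")

    def pick(channel: str) -> np.ndarray:
        if channel not in frame.columns:
            raise KeyError(
                f"channel {channel!r} not found; available: {', '.join(map(str, frame.columns))}"
            )
        return frame[channel].to_numpy(dtype=float)

    fl = pick(fl_channel)
    via = None
    if viability_channel is not None and viability_channel in frame.columns:
        via = pick(viability_channel)
    return EventTable(fluorescence=fl, viability=via, time_h=time_h)


def gate_viable(events: EventTable, threshold: float) -> EventTable:
    """Keep viable events: viability-dye intensity strictly below threshold.

    Follows the PI-negative convention — dead cells take up the dye and
    fluoresce brightly, so viable cells sit below the gate.
    """
    if events.viability is None:
        raise ValueError(
            "no viability channel present; skip gating or re-read the file "
            "with viability_channel set"
        )
    keep = events.viability < threshold
    if not keep.any():
        log.warning("viability gate at %g keeps 0 of %d events", threshold, len(events))
        return _empty_gated(events)
    return EventTable(
        fluorescence=events.fluorescence[keep],
        viability=events.viability[keep],
        time_h=events.time_h,
    )


class _EmptyEventTable(EventTable):
    """Zero-event table returned by a gate that removes everything."""

    def __post_init__(self) -> None:  # relax the ≥1-event invariant
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.viability is not None:
            self.viability = np.asarray(self.viability, dtype=float)


def _empty_gated(events: EventTable) -> EventTable:
    return _EmptyEventTable(
        fluorescence=events.fluorescence[:0],
        viability=None,
        time_h=events.time_h,
    )


def build_histogram(
    events: EventTable,
    n_bins: int = 256,
    log_range: Optional[tuple[float, float]] = None,
    run_id: str = "run0",
) -> Histogram:
    """Bin events into a uniform log10-fluorescence histogram.

    Events outside ``log_range`` accumulate into the terminal bins so the
    total cell count is conserved.  When ``log_range`` is None it is chosen
    to encompass all events with a small margin.
    """
    if n_bins < 16:
        raise ValueError("n_bins must be >= 16")
    logfl = np.log10(np.maximum(events.fluorescence, MIN_INTENSITY))
    if log_range is None:
        lo, hi = float(logfl.min()), float(logfl.max())
        pad = max(0.05, 0.02 * (hi - lo))
        lo, hi = lo - pad, hi + pad
    else:
        lo, hi = float(log_range[0]), float(log_range[1])
    if not lo < hi:
        raise ValueError("log_range must satisfy lo < hi")
    edges = np.linspace(lo, hi, n_bins + 1)
    clipped = np.clip(logfl, lo, np.nextafter(hi, lo))
    counts, _ = np.histogram(clipped, bins=edges)
    return Histogram(bin_edges=edges, counts=counts.astype(float),
                     time_h=events.time_h, run_id=run_id)


def shared_log_range(event_tables: Sequence[EventTable]) -> tuple[float, float]:
    """Log range encompassing all events across all time points and runs."""
    lo = min(float(np.log10(np.maximum(e.fluorescence, MIN_INTENSITY)).min()) for e in event_tables)
    hi = max(float(np.log10(e.fluorescence).max()) for e in event_tables)
    pad = max(0.05, 0.02 * (hi - lo))
    return lo - pad, hi + pad


# ---------------------------------------------------------------------------
# Histogram CSV serialization
# ---------------------------------------------------------------------------

CSV_HEADER = ["time_h", "run_id", "bin_lo_log10", "bin_hi_log10", "count"]


def write_histogram_csv(path: str | Path, histograms: Sequence[Histogram]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for h in histograms:
            for lo, hi, c in zip(h.bin_edges[:-1], h.bin_edges[1:], h.counts):
                writer.writerow([repr(float(h.time_h)), h.run_id,
                                 repr(float(lo)), repr(float(hi)), repr(float(c))])


def read_histogram_csv(path: str | Path) -> list[Histogram]:
    frame = pd.read_csv(path)
    missing = set(CSV_HEADER) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: list[Histogram] = []
    for (t, run), grp in frame.groupby(["time_h", "run_id"], sort=True):
        grp = grp.sort_values("bin_lo_log10")
        edges = np.concatenate([grp["bin_lo_log10"].to_numpy(),
                                grp["bin_hi_log10"].to_numpy()[-1:]])
        out.append(Histogram(bin_edges=edges, counts=grp["count"].to_numpy(dtype=float),
                             time_h=float(t), run_id=str(run)))
    return out
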