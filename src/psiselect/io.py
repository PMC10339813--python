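"""Readers and writers for the package's on-disk formats.

Plain-text formats (delimited signals, square connectivity CSV, edge
lists, feature tables, label manifests) are handled with pandas/numpy.
EDF is the one binary format: reading goes through :mod:`mne` (an optional
dependency), while writing uses a small self-contained EDF encoder below,
since the scientific Python stack has readers but no ubiquitous writer.
The writer emits standard 16-bit EDF with one-second data records and is
round-trip compatible with mne's reader.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import Recording
from .connectivity import BinaryNetwork, ConnectivityMatrix
from .graph_features import FEATURE_NAMES

__all__ = [
    "write_edf",
    "read_edf",
    "read_delimited",
    "write_delimited",
    "write_epochs",
    "write_label_manifest",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_edge_list",
    "feature_table_to_frame",
    "write_feature_table",
    "read_feature_table",
]


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    samples: np.ndarray,
    fs: float,
    channel_names: list[str] | None = None,
    physical_unit: str = "uV",
) -> Path:
    """Write a channels x time matrix as a standard EDF file.

    Uses one-second data records (so ``fs`` must be a positive integer) and
    scales each channel to the full signed-16-bit digital range.  Trailing
    samples that do not fill a whole record are dropped.
    """
    path = Path(path)
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    n_ch, n_t = x.shape
    fs_i = int(round(fs))
    if abs(fs - fs_i) > 1e-9 or fs_i <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = n_t // fs_i
    if n_rec == 0:
        raise ValueError("signal shorter than one 1-s data record")
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]

    phys_min = x.min(axis=1)
    phys_max = x.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),  # local patient id (anonymous)
            _edf_field("Startdate X", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 + 256 * n_ch, 8),
            _edf_field("", 44),
            _edf_field(n_rec, 8),
            _edf_field(1, 8),  # record duration, s
            _edf_field(n_ch, 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_edf_field(name, 16) for name in channel_names),
            b"".join(_edf_field("", 80) for _ in range(n_ch)),  # transducer
            b"".join(_edf_field(physical_unit, 8) for _ in range(n_ch)),
            b"".join(_edf_field(f"{phys_min[i]:.6g}"[:8], 8) for i in range(n_ch)),
            b"".join(_edf_field(f"{phys_max[i]:.6g}"[:8], 8) for i in range(n_ch)),
            b"".join(_edf_field(dig_min, 8) for _ in range(n_ch)),
            b"".join(_edf_field(dig_max, 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 80) for _ in range(n_ch)),  # prefiltering
            b"".join(_edf_field(fs_i, 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 32) for _ in range(n_ch)),
        ]
    )

    # re-parse the 8-char physical extremes so the stored gain matches the
    # truncated header values exactly
    pmin = np.array([float(f"{phys_min[i]:.6g}"[:8]) for i in range(n_ch)])
    pmax = np.array([float(f"{phys_max[i]:.6g}"[:8]) for i in range(n_ch)])
    gain = (pmax - pmin) / (dig_max - dig_min)
    digital = np.round((x - pmin[:, None]) / gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_rec):
            chunk = digital[:, r * fs_i : (r + 1) * fs_i]
            fh.write(chunk.tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (channel names from the
    header).  Requires mne."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional dependency mne") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # mne rescales EEG-like channels to volts; undo to recover native units
    return Recording(np.asarray(raw.get_data()) * 1e6, raw.info["sfreq"], list(raw.ch_names))


def read_delimited(path: str | Path, fs: float, delimiter: str = ",") -> Recording:
    """Plain-text recording: one column per channel, header row with names."""
    frame = pd.read_csv(path, delimiter=delimiter)
    return Recording(frame.to_numpy().T, fs, list(frame.columns))


def write_delimited(
    path: str | Path, samples: np.ndarray, channel_names: list[str] | None = None,
    delimiter: str = ",",
) -> Path:
    path = Path(path)
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(x.shape[0])]
    pd.DataFrame(x.T, columns=channel_names).to_csv(path, index=False, sep=delimiter)
    return path


def write_epochs(
    out_dir: str | Path,
    labeled_epochs,
    fmt: str = "csv",
    epochs_per_subject: int = 12,
) -> Path:
    """Write every epoch of a :class:`~psiselect.synthetic.LabeledEpochs` to
    ``out_dir`` (one file per epoch) plus a label manifest CSV.

    ``fmt`` is "csv" (delimited text) or "edf".
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for eid, group, epoch in zip(
        labeled_epochs.epoch_ids, labeled_epochs.groups, labeled_epochs.epochs
    ):
        stem = out_dir / f"epoch_{eid:04d}"
        if fmt == "csv":
            write_delimited(stem.with_suffix(".csv"), epoch, labeled_epochs.channel_names)
        elif fmt == "edf":
            write_edf(stem.with_suffix(".edf"), epoch, labeled_epochs.fs,
                      labeled_epochs.channel_names)
        else:
            raise ValueError("fmt must be 'csv' or 'edf'")
    write_label_manifest(out_dir / "labels.csv", labeled_epochs, epochs_per_subject)
    return out_dir


def write_label_manifest(path: str | Path, labeled_epochs, epochs_per_subject: int = 12) -> Path:
    """Label manifest: epoch_id, group, subject_id (epochs assigned to
    pseudo-subjects in blocks, mirroring a 12-epochs-per-subject design)."""
    path = Path(path)
    rows = []
    counters: dict[str, int] = {}
    for eid, group in zip(labeled_epochs.epoch_ids, labeled_epochs.groups):
        k = counters.get(group, 0)
        counters[group] = k + 1
        rows.append(
            {"epoch_id": eid, "group": group,
             "subject_id": f"{group}{k // epochs_per_subject:02d}"}
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_matrix_csv(path: str | Path, matrix, channel_names: list[str] | None = None) -> Path:
    """Square CSV with a channel-name header; accepts a ConnectivityMatrix,
    BinaryNetwork or raw array."""
    if isinstance(matrix, ConnectivityMatrix):
        values, names = matrix.values, matrix.channel_names
    elif isinstance(matrix, BinaryNetwork):
        values, names = matrix.adjacency, matrix.channel_names
    else:
        values, names = np.asarray(matrix), None
    names = channel_names or names or [f"ch{i}" for i in range(values.shape[0])]
    pd.DataFrame(values, index=names, columns=names).to_csv(path)
    return Path(path)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, index_col=0)
    return frame.to_numpy(), list(frame.columns)


def write_edge_list(path: str | Path, net: BinaryNetwork) -> Path:
    """Adjacency as an edge list (node_i, node_j), one undirected edge per row."""
    path = Path(path)
    names = net.channel_names or [f"ch{i}" for i in range(net.n)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_i", "node_j"])
        rows, cols = np.nonzero(np.triu(net.adjacency, k=1))
        for i, j in zip(rows, cols):
            writer.writerow([names[i], names[j]])
    return path


def feature_table_to_frame(ds, layout: str = "wide") -> pd.DataFrame:
    """Feature table as a DataFrame.

    "wide": one row per epoch, band-major feature columns plus epoch_id and
    group.  "long": one row per (epoch, band) with the 14 feature columns.
    """
    names = list(ds.feature_names)
    wide = pd.DataFrame(ds.table, columns=names)
    wide.insert(0, "group", ds.labels)
    wide.insert(0, "epoch_id", np.arange(ds.n_samples))
    if layout == "wide":
        return wide
    if layout != "long":
        raise ValueError("layout must be 'wide' or 'long'")
    records = []
    for _, row in wide.iterrows():
        for band in dict.fromkeys(n.split(":")[0] for n in names):
            rec = {"epoch_id": row["epoch_id"], "group": row["group"], "band": band}
            for feat in FEATURE_NAMES:
                col = f"{band}:{feat}"
                if col in wide.columns:
                    rec[feat] = row[col]
            records.append(rec)
    return pd.DataFrame(records)


def write_feature_table(path: str | Path, ds, layout: str = "wide") -> Path:
    feature_table_to_frame(ds, layout).to_csv(path, index=False)
    return Path(path)


def read_feature_table(path: str | Path):
    """Read a wide-layout feature table CSV back into a Dataset."""
    from .objectives import Dataset

    frame = pd.read_csv(path)
    labels = frame["group"].to_numpy()
    cols = [c for c in frame.columns if c not in ("epoch_id", "group")]
    return Dataset(frame[cols].to_numpy(), labels, cols)
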