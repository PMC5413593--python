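"""Text I/O: trial-file reader, epoch store, and feature CSV.

Three on-disk layouts are supported, all plain text:

* the per-trial whitespace-delimited layout used by the public
  alcoholism EEG database (read-only): lines are either ``#`` comments or
  ``trial_index channel_name sample_index value`` rows;
* a self-describing epoch store for :class:`~gammase.epochs.EpochSet`
  round-trips;
* a feature CSV with one row per epoch, a ``label`` column and one column
  per channel.

All floats are written with 17 significant digits so write→read is the
identity on IEEE doubles.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .epochs import GROUP_LABELS, EpochSet, FeatureMatrix
from .errors import (
    DuplicateSampleError,
    FormatError,
    IncompleteChannelError,
    InvariantError,
    ParseError,
)

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# UCI/SUNY-style trial files
# ---------------------------------------------------------------------------

def read_uci_trial(
    path: str | Path,
    fs: float = 256.0,
    duration_s: float = 1.0,
    label: str = "control",
) -> EpochSet:
    """Read one trial file in the public alcoholism-database dialect.

    Each data row is ``trial_index channel_name sample_index value``;
    ``#``-prefixed comment lines may appear anywhere. Channel order follows
    first appearance in the file; sample indices are 0-based and must cover
    ``0 .. round(fs*duration_s)-1`` exactly once per channel.

    The trial files carry no group tag, so the caller supplies ``label``
    (typically recovered from the file naming convention of the archive).

    Returns a single-epoch :class:`EpochSet`.
    """
    path = Path(path)
    n_samples = int(round(fs * duration_s))
    order: list[str] = []
    traces: dict[str, np.ndarray] = {}
    seen: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(
                    f"expected 4 whitespace-delimited fields, got {len(fields)}",
                    line=lineno,
                )
            _trial, chan, idx_s, val_s = fields
            try:
                idx = int(idx_s)
            except ValueError:
                raise ParseError(f"sample index {idx_s!r} is not an integer",
                                 line=lineno) from None
            try:
                val = float(val_s)
            except ValueError:
                raise ParseError(f"value {val_s!r} is not a number",
                                 line=lineno) from None
            if not 0 <= idx < n_samples:
                raise ParseError(
                    f"sample index {idx} outside declared range 0..{n_samples - 1}",
                    line=lineno,
                )
            if chan not in traces:
                order.append(chan)
                traces[chan] = np.zeros(n_samples)
                seen[chan] = np.zeros(n_samples, dtype=bool)
            if seen[chan][idx]:
                raise DuplicateSampleError(
                    f"duplicate sample (channel {chan!r}, index {idx})",
                    line=lineno,
                )
            traces[chan][idx] = val
            seen[chan][idx] = True
    if not order:
        raise IncompleteChannelError(f"{path}: file contains no data rows")
    for chan in order:
        missing = int(n_samples - seen[chan].sum())
        if missing:
            raise IncompleteChannelError(
                f"{path}: channel {chan!r} is missing {missing} of "
                f"{n_samples} samples"
            )
    data = np.stack([traces[c] for c in order])[np.newaxis]
    return EpochSet(
        data=data,
        labels=np.asarray([label], dtype=object),
        fs=fs,
        channel_names=order,
        duration_s=duration_s,
    )


# ---------------------------------------------------------------------------
# Epoch store
# ---------------------------------------------------------------------------

_MAGIC = "# gammase epochs v1"


def write_epochs(es: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` to a self-describing text file."""
    if len(set(es.channel_names)) != len(es.channel_names):
        raise InvariantError("refusing to write epochs with non-unique channel names")
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write(_MAGIC + "\n")
            fh.write(f"fs\t{_FLOAT_FMT % es.fs}\n")
            fh.write(f"duration_s\t{_FLOAT_FMT % es.duration_s}\n")
            fh.write("channels\t" + "\t".join(es.channel_names) + "\n")
            fh.write(f"n_epochs\t{es.n_epochs}\n")
            for e in range(es.n_epochs):
                fh.write(f"epoch\t{e}\t{es.labels[e]}\n")
                for c in range(es.n_channels):
                    fh.write(" ".join(_FLOAT_FMT % v for v in es.data[e, c]) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing epochs to {path}: {exc}") from exc


def read_epochs(path: str | Path) -> EpochSet:
    """Read an epoch store written by :func:`write_epochs`."""
    path = Path(path)
    try:
        with open(path) as fh:
            lines = fh.read().splitlines()
    except OSError as exc:
        raise OSError(f"failed reading epochs from {path}: {exc}") from exc
    if not lines or lines[0] != _MAGIC:
        raise FormatError(f"{path}: missing '{_MAGIC}' header")

    def _header(i: int, key: str) -> list[str]:
        parts = lines[i].split("\t")
        if parts[0] != key:
            raise FormatError(f"{path}: expected '{key}' on line {i + 1}")
        return parts[1:]

    fs = float(_header(1, "fs")[0])
    duration_s = float(_header(2, "duration_s")[0])
    channels = _header(3, "channels")
    n_epochs = int(_header(4, "n_epochs")[0])
    n_samples = int(round(fs * duration_s))
    n_channels = len(channels)

    data = np.empty((n_epochs, n_channels, n_samples))
    labels = np.empty(n_epochs, dtype=object)
    pos = 5
    for e in range(n_epochs):
        parts = lines[pos].split("\t")
        if len(parts) != 3 or parts[0] != "epoch" or int(parts[1]) != e:
            raise FormatError(f"{path}: malformed epoch header on line {pos + 1}")
        labels[e] = parts[2]
        pos += 1
        for c in range(n_channels):
            row = np.fromstring(lines[pos], sep=" ")
            if row.size != n_samples:
                raise FormatError(
                    f"{path}: line {pos + 1}: expected {n_samples} samples, "
                    f"got {row.size}"
                )
            data[e, c] = row
            pos += 1
    return EpochSet(data=data, labels=labels, fs=fs,
                    channel_names=channels, duration_s=duration_s)


# ---------------------------------------------------------------------------
# Feature CSV
# ---------------------------------------------------------------------------

def write_features(fm: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV: a band comment, a header, one row
    per epoch with the label first."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# band {_FLOAT_FMT % fm.band[0]} {_FLOAT_FMT % fm.band[1]}\n")
        writer = csv.writer(fh)
        writer.writerow(["label", *fm.channel_names])
        for e in range(fm.n_epochs):
            writer.writerow(
                [fm.labels[e], *(_FLOAT_FMT % v for v in fm.values[e])]
            )


def read_features(path: str | Path) -> FeatureMatrix:
    """Read a feature CSV written by :func:`write_features`."""
    path = Path(path)
    band = (30.0, 55.0)
    with open(path, newline="") as fh:
        first = fh.readline()
        if first.startswith("# band"):
            parts = first.split()
            band = (float(parts[2]), float(parts[3]))
        else:
            fh.seek(0)
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty feature file") from None
        if not header or header[0] != "label":
            raise ParseError(f"{path}: first column must be 'label'")
        channels = header[1:]
        rows, labels = [], []
        for lineno, row in enumerate(reader, start=3):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: expected {len(header)} cells, got {len(row)}",
                    line=lineno,
                )
            if row[0] not in GROUP_LABELS:
                raise ParseError(
                    f"{path}: label {row[0]!r} not in {GROUP_LABELS}", line=lineno
                )
            labels.append(row[0])
            try:
                rows.append([float(v) if v != "" else _missing(lineno)
                             for v in row[1:]])
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}: {exc}", line=lineno) from None
    values = np.asarray(rows) if rows else np.empty((0, len(channels)))
    return FeatureMatrix(
        values=values,
        labels=np.asarray(labels, dtype=object),
        channel_names=channels,
        band=band,
    )


def _missing(lineno: int):
    raise ParseError("missing cell", line=lineno)
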