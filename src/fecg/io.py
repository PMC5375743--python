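"""ECG record container and plain-text (CSV) persistence.

A record is a uniformly sampled waveform with a sampling rate, optional named
R-peak annotation sets (0-based sample indices) and free-form metadata.  The
on-disk format is a single numeric column with ``#``-prefixed header lines::

    # fs=1000
    # meta:source=synthetic
    # ann:fetal=412,840,1267
    0.0132
    -0.0078
    ...

Multi-column files are accepted on read when an explicit ``channel`` is
given.  All indices are 0-based and intervals half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EcgRecord", "read_record", "write_record"]


@dataclass
class EcgRecord:
    """Uniformly sampled ECG waveform.

    Parameters
    ----------
    samples : ndarray of float
        Amplitude sequence in arbitrary linear units (gain is not assumed).
    fs : float
        Sampling frequency in Hz, strictly positive.
    annotations : dict of str -> ndarray of int
        Named sets of R-peak sample indices, each sorted and within range.
    meta : dict of str -> str
        Free-form provenance strings.
    """

    samples: np.ndarray
    fs: float
    annotations: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN or Inf")
        self.fs = float(self.fs)
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError(f"fs must be positive and finite, got {self.fs}")
        clean = {}
        for name, idx in self.annotations.items():
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= self.samples.size):
                raise ValueError(
                    f"annotation {name!r} has indices outside "
                    f"[0, {self.samples.size})"
                )
            clean[name] = np.sort(idx)
        self.annotations = clean

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size

    def with_samples(self, samples: np.ndarray) -> "EcgRecord":
        """Same-grid copy carrying a new waveform."""
        return EcgRecord(
            samples=np.asarray(samples, dtype=float),
            fs=self.fs,
            annotations={k: v.copy() for k, v in self.annotations.items()},
            meta=dict(self.meta),
        )


def _parse_header_line(line: str, fs: float | None,
                       annotations: dict, meta: dict) -> float | None:
    body = line.lstrip("#").strip()
    if body.startswith("fs="):
        fs = float(body[3:])
    elif body.startswith("ann:"):
        name, _, values = body[4:].partition("=")
        idx = ([int(v) for v in values.split(",") if v.strip() != ""]
               if values.strip() else [])
        annotations[name.strip()] = np.array(idx, dtype=np.int64)
    elif body.startswith("meta:"):
        key, _, value = body[5:].partition("=")
        meta[key.strip()] = value
    return fs


def read_record(path: str | Path, format: str = "csv", *,
                fs: float | None = None,
                channel: int | None = None) -> EcgRecord:
    """Read an ECG record from a single- or multi-column CSV file.

    The sampling rate comes from a ``# fs=<Hz>`` header line or the ``fs``
    keyword; the keyword wins when both are present.  Multi-column files
    require an explicit ``channel`` (0-based column index).

    Raises
    ------
    ValueError
        On unsupported format, non-numeric content, a missing sampling rate
        or an ambiguous multi-column file without ``channel``.
    FileNotFoundError
        When ``path`` does not exist.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}; only 'csv' is supported")
    path = Path(path)
    header_fs: float | None = None
    annotations: dict[str, np.ndarray] = {}
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header_fs = _parse_header_line(line, header_fs, annotations, meta)
                continue
            fields = line.replace("\t", ",").split(",")
            try:
                rows.append([float(v) for v in fields])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric content {line!r}"
                ) from exc
    if not rows:
        raise ValueError(f"{path}: no samples found")
    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows):
        raise ValueError(f"{path}: ragged rows (inconsistent column count)")
    data = np.asarray(rows, dtype=float)
    if ncols > 1:
        if channel is None:
            raise ValueError(
                f"{path}: {ncols} channels present; an explicit channel "
                "selector is required"
            )
        if not 0 <= channel < ncols:
            raise ValueError(f"channel {channel} out of range [0, {ncols})")
        samples = data[:, channel]
    else:
        samples = data[:, 0]
    effective_fs = fs if fs is not None else header_fs
    if effective_fs is None:
        raise ValueError(
            f"{path}: sampling rate not stated; add a '# fs=<Hz>' header "
            "line or pass fs explicitly"
        )
    return EcgRecord(samples=samples, fs=effective_fs,
                     annotations=annotations, meta=meta)


def write_record(record: EcgRecord, path: str | Path,
                 format: str = "csv") -> None:
    """Write a record (waveform, fs, annotations, meta) to a CSV file.

    ``read_record(write_record(r))`` reproduces the samples within the text
    quantisation step (12 significant digits) and fs and annotation indices
    exactly.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}; only 'csv' is supported")
    path = Path(path)
    lines = [f"# fs={record.fs:.12g}"]
    for key, value in record.meta.items():
        lines.append(f"# meta:{key}={value}")
    for name, idx in record.annotations.items():
        lines.append(f"# ann:{name}={','.join(str(int(i)) for i in idx)}")
    lines.extend(f"{v:.12g}" for v in record.samples)
    path.write_text("\n".join(lines) + "\n")


def read_peak_indices(path: str | Path) -> np.ndarray:
    """Read a one-column CSV of sample indices (``#`` comments allowed)."""
    indices = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            indices.append(int(float(line)))
    return np.sort(np.asarray(indices, dtype=np.int64))


def write_peak_indices(indices: np.ndarray, path: str | Path) -> None:
    """Write sample indices as a one-column CSV."""
    Path(path).write_text("\n".join(str(int(i)) for i in indices) + "\n")
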