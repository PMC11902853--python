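"""ROI time-series container, delimited-text I/O, epoching and standardization.

The pipeline operates on region-of-interest (ROI) signal matrices: one row
per brain region, one column per time sample.  Upstream source
reconstruction (beamforming, parcellation) is outside the scope of this
package; inputs are plain tab-separated matrices plus a one-label-per-line
region file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ROITimeSeries",
    "aal116_labels",
    "read_roi_timeseries",
    "write_roi_timeseries",
    "segment_epochs",
    "select_representative",
    "zscore",
]


def aal116_labels() -> list[str]:
    """Return the 116 AAL atlas region names in standard atlas order."""
    text = (
        importlib.resources.files("grangernet.data")
        .joinpath("aal116_labels.txt")
        .read_text()
    )
    return text.split()


@dataclass
class ROITimeSeries:
    """One subject's regions x samples signal matrix.

    Attributes
    ----------
    data : ndarray, shape (n_regions, n_samples)
        Signal values; units arbitrary, all finite.
    region_labels : list of str
        Unique region names, one per row.
    sampling_rate_hz : float
        Sampling frequency in Hz (> 0).
    subject_id, group : str
        Cohort bookkeeping; ``group`` may be empty for unlabelled data.
    """

    data: np.ndarray
    region_labels: list[str]
    sampling_rate_hz: float
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (regions x samples), got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite value at region row {bad[0]}, sample column {bad[1]}"
            )
        self.region_labels = [str(l) for l in self.region_labels]
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.region_labels)} labels for {self.data.shape[0]} regions"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if not self.sampling_rate_hz > 0:
            raise ValueError(f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_roi_timeseries(
    path,
    labels_path=None,
    sampling_rate_hz: float = 500.0,
    *,
    labels: list[str] | None = None,
    subject_id: str = "",
    group: str = "",
) -> ROITimeSeries:
    """Read a rectangular TSV matrix of regions x samples.

    Every row must have the same number of tab-separated numeric cells; a
    ragged row, a non-numeric cell or a NaN/Inf is rejected with its
    location.  Labels come from ``labels_path`` (one name per line) or the
    ``labels`` list; if neither is given, rows are named ``ROI_001`` ...
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        width = None
        for r, line in enumerate(fh):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ValueError(
                    f"{path}: ragged row {r}: {len(cells)} cells, expected {width}"
                )
            vals = []
            for c, cell in enumerate(cells):
                try:
                    v = float(cell)
                except ValueError:
                    raise ValueError(f"{path}: non-numeric cell at row {r}, column {c}: {cell!r}")
                if not np.isfinite(v):
                    raise ValueError(f"{path}: non-finite value at row {r}, column {c}: {cell!r}")
                vals.append(v)
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    data = np.asarray(rows, dtype=float)
    if labels_path is not None:
        with open(labels_path) as fh:
            labels = [ln.strip() for ln in fh if ln.strip()]
    if labels is None:
        labels = [f"ROI_{i + 1:03d}" for i in range(data.shape[0])]
    if len(labels) != data.shape[0]:
        raise ValueError(
            f"{path}: {data.shape[0]} rows but {len(labels)} region labels"
        )
    return ROITimeSeries(data, labels, sampling_rate_hz, subject_id=subject_id, group=group)


def write_roi_timeseries(ts: ROITimeSeries, path) -> None:
    """Write the signal matrix as TSV at full double round-trip precision."""
    np.savetxt(path, ts.data, fmt="%.17g", delimiter="\t")


def segment_epochs(ts: ROITimeSeries, epoch_seconds: float) -> list[ROITimeSeries]:
    """Cut the recording into consecutive non-overlapping fixed-length epochs.

    The epoch length ``epoch_seconds * sampling_rate_hz`` must be a positive
    integer number of samples; a trailing partial epoch is discarded.
    """
    n_per = epoch_seconds * ts.sampling_rate_hz
    if not np.isclose(n_per, round(n_per)) or round(n_per) < 1:
        raise ValueError(
            f"epoch of {epoch_seconds} s at {ts.sampling_rate_hz} Hz is not a "
            f"positive integer number of samples ({n_per})"
        )
    n_per = int(round(n_per))
    n_epochs = ts.n_samples // n_per
    if n_epochs < 1:
        raise ValueError(
            f"series of {ts.n_samples} samples shorter than one {n_per}-sample epoch"
        )
    out = []
    for e in range(n_epochs):
        out.append(
            replace(
                ts,
                data=ts.data[:, e * n_per : (e + 1) * n_per].copy(),
                subject_id=f"{ts.subject_id}_ep{e:02d}" if ts.subject_id else f"ep{e:02d}",
            )
        )
    return out


def select_representative(candidates) -> np.ndarray:
    """Pick the candidate signal with the highest total power (sum of squares).

    Ties break to the lowest index.  All candidates must have equal length.
    """
    candidates = [np.asarray(c, dtype=float) for c in candidates]
    if not candidates:
        raise ValueError("no candidate signals")
    n = candidates[0].shape[-1]
    if any(c.shape[-1] != n for c in candidates):
        raise ValueError("candidate signals have unequal lengths")
    power = [float(np.sum(c**2)) for c in candidates]
    return candidates[int(np.argmax(power))]


def zscore(ts: ROITimeSeries) -> ROITimeSeries:
    """Standardize each region to mean 0, standard deviation 1 (population sd)."""
    mu = ts.data.mean(axis=1, keepdims=True)
    sd = ts.data.std(axis=1, keepdims=True)  # ddof=0 convention
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(
            f"constant signal in region(s): {[ts.region_labels[i] for i in flat]}"
        )
    return replace(ts, data=(ts.data - mu) / sd)
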