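"""Amplitude of low-frequency fluctuations (ALFF).

ALFF indexes the intensity of spontaneous slow fluctuations in a signal:
after removing the linear trend, the single-sided amplitude spectrum
(square root of periodogram power) is averaged over the frequency bins
falling in a low-frequency band, 0.01-0.1 Hz by default. Averaging
(rather than summing) over band bins makes the value invariant to the
number of bins the grid happens to place in the band. No taper is
applied. For a pure on-grid sinusoid of amplitude A the band total
contributed is A, so ALFF is linear in signal amplitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .synthetic import ParcelTimeseriesSet

__all__ = [
    "ALFFMaps",
    "compute_alff",
    "alff_maps",
    "roi_mean",
    "parcel_mean_table",
    "write_parcel_set",
    "read_parcel_set",
    "load_nifti_parcels",
]

DEFAULT_BAND = (0.01, 0.1)
_EDGE_TOL = 1e-9  # band edges are inclusive up to float rounding of the bin grid


def _linear_detrend(x: np.ndarray) -> np.ndarray:
    """Remove per-series least-squares linear trend along the last axis.

    Exact projection, hence idempotent; preserves float32 input dtype.
    """
    n = x.shape[-1]
    dtype = x.dtype if x.dtype.kind == "f" else np.float64
    t = np.arange(n, dtype=dtype)
    t = t - t.mean()
    # orthonormal [constant, linear] basis; projection via two GEMMs keeps
    # large multi-voxel arrays fast and the operation exactly idempotent
    q = np.stack([np.full(n, 1 / np.sqrt(n), dtype=dtype),
                  (t / np.sqrt((t**2).sum())).astype(dtype)], axis=1)
    flat = x.reshape(-1, n)
    trend = (flat @ q) @ q.T
    np.subtract(flat, trend, out=trend)
    return trend.reshape(x.shape)


def _band_mask(n: int, tr_seconds: float, band) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    lo, hi = band
    nyquist = 0.5 / tr_seconds
    if not 0 < lo < hi or hi > nyquist + _EDGE_TOL:
        raise ValueError(f"band {band} must lie within (0, Nyquist={nyquist:g}]")
    mask = (freqs >= lo - _EDGE_TOL) & (freqs <= hi + _EDGE_TOL)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins (n={n}, TR={tr_seconds})")
    return mask


def _alff_nd(x: np.ndarray, tr_seconds: float, band, chunk_rows: int = 8192) -> np.ndarray:
    """ALFF along the last axis for an array of series.

    Processes the (flattened) series in row chunks so detrend + FFT stay
    cache-resident for large voxel arrays.
    """
    x = np.asarray(x)
    n = x.shape[-1]
    if n < 32:
        raise ValueError("need >= 32 timepoints")
    mask = _band_mask(n, tr_seconds, band)
    flat = np.ascontiguousarray(x.reshape(-1, n))
    out = np.empty(flat.shape[0])
    for r0 in range(0, flat.shape[0], chunk_rows):
        blk = _linear_detrend(flat[r0:r0 + chunk_rows])
        spec = sp_fft.rfft(blk, axis=-1, overwrite_x=True)[:, mask]
        # single-sided amplitude spectrum = 2|X|/n, i.e. sqrt of power
        out[r0:r0 + chunk_rows] = (2.0 * np.abs(spec) / n).mean(axis=-1)
    return out.reshape(x.shape[:-1]) if x.ndim > 1 else out[0]


def compute_alff(series, tr_seconds: float, band=DEFAULT_BAND) -> float:
    """ALFF of a single time series (signal units)."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    return float(_alff_nd(series, tr_seconds, band))


@dataclass
class ALFFMaps:
    """Per-subject parcel x voxel amplitude maps.

    ``values`` has shape (n_subjects, n_parcels, n_voxels); ``normalization``
    is 'raw' (all values >= 0) or 'zscored' (per-subject mean 0, sd 1
    across all voxels).
    """

    values: np.ndarray
    band: tuple
    subject_ids: list
    normalization: str = "raw"

    @property
    def n_subjects(self):
        return self.values.shape[0]

    @property
    def n_parcels(self):
        return self.values.shape[1]

    def parcel_means(self) -> np.ndarray:
        """(n_subjects, n_parcels) mean ALFF per parcel."""
        return self.values.mean(axis=2)


def alff_maps(
    data: ParcelTimeseriesSet, band=DEFAULT_BAND, zscore: bool = False
) -> ALFFMaps:
    """Voxel-wise ALFF for every subject/parcel/voxel.

    With ``zscore=True`` each subject's map is standardized across all of
    their voxels (mean 0, sd 1), a common step before group comparison;
    the default keeps raw amplitudes.
    """
    values = _alff_nd(data.data, data.tr_seconds, band)
    values = np.asarray(values, dtype=np.float64)
    tag = "raw"
    if zscore:
        flat = values.reshape(values.shape[0], -1)
        mu = flat.mean(axis=1)
        sd = flat.std(axis=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance subject map; cannot z-score")
        values = (values - mu[:, None, None]) / sd[:, None, None]
        tag = "zscored"
    return ALFFMaps(values=values, band=tuple(band), subject_ids=list(data.subject_ids),
                    normalization=tag)


def roi_mean(maps: ALFFMaps, parcel_ids) -> np.ndarray:
    """Per-subject mean ALFF over the voxels of the selected parcels."""
    parcel_ids = np.atleast_1d(np.asarray(parcel_ids, dtype=int))
    if parcel_ids.size == 0:
        raise ValueError("empty ROI selection")
    if parcel_ids.min() < 0 or parcel_ids.max() >= maps.n_parcels:
        raise IndexError(f"parcel ids out of range 0..{maps.n_parcels - 1}")
    return maps.values[:, parcel_ids, :].reshape(maps.n_subjects, -1).mean(axis=1)


def parcel_mean_table(maps: ALFFMaps) -> pd.DataFrame:
    """Subjects x parcels table of parcel-mean ALFF."""
    return pd.DataFrame(
        maps.parcel_means(),
        index=pd.Index(maps.subject_ids, name="subject_id"),
        columns=[f"parcel{j:03d}" for j in range(maps.n_parcels)],
    )


# ---------------------------------------------------------------- I/O


def write_parcel_set(data: ParcelTimeseriesSet, outdir) -> Path:
    """Write one .npy per subject plus a JSON manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for i, sid in enumerate(data.subject_ids):
        fname = f"{sid}_parcels.npy"
        np.save(outdir / fname, data.data[i])
        entries[sid] = fname
    manifest = {
        "tr_seconds": data.tr_seconds,
        "n_parcels": int(data.data.shape[1]),
        "n_voxels": int(data.data.shape[2]),
        "n_timepoints": int(data.data.shape[3]),
        "subjects": entries,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_parcel_set(manifest_path) -> ParcelTimeseriesSet:
    """Read a parcel time-series directory written by write_parcel_set."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    subject_ids = list(manifest["subjects"])
    arrays = []
    shape = (manifest["n_parcels"], manifest["n_voxels"], manifest["n_timepoints"])
    for sid in subject_ids:
        arr = np.load(root / manifest["subjects"][sid])
        if arr.shape != shape:
            raise ValueError(f"subject {sid}: shape {arr.shape} != manifest {shape}")
        arrays.append(arr)
    return ParcelTimeseriesSet(
        data=np.stack(arrays), tr_seconds=float(manifest["tr_seconds"]),
        subject_ids=subject_ids,
    )


def load_nifti_parcels(bold_path, labels_path, tr_seconds: float | None = None):
    """Extract per-parcel voxel time series from a 4D NIfTI volume.

    ``labels_path`` is an integer-label parcellation NIfTI on the same
    grid (label 0 = background). Returns ``(series_by_label, tr)`` where
    ``series_by_label`` maps label -> (n_voxels_in_parcel, n_timepoints)
    array with a deterministic voxel order (C-order of the grid). The
    same parcellation applied to every subject yields aligned voxel
    correspondence across subjects.
    """
    import nibabel as nib

    bold = nib.load(str(bold_path))
    labels_img = nib.load(str(labels_path))
    if bold.shape[:3] != labels_img.shape[:3]:
        raise ValueError("BOLD and parcellation grids differ")
    vol = np.asarray(bold.dataobj)
    if vol.ndim != 4:
        raise ValueError("BOLD image must be 4D")
    labels = np.asarray(labels_img.dataobj).astype(int)
    if tr_seconds is None:
        tr_seconds = float(bold.header.get_zooms()[3])
    flat = vol.reshape(-1, vol.shape[3])
    flat_labels = labels.reshape(-1)
    series = {
        int(lab): flat[flat_labels == lab]
        for lab in np.unique(flat_labels) if lab != 0
    }
    return series, tr_seconds
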