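"""Events-table and volume readers/writers plus respiration feature extraction.

Events tables are tab-separated with a header (BIDS-events-like dialect:
0-based indices, onsets in seconds); volumes go through NIfTI with an
affine passthrough, with an ``.npy`` portable-array fallback for
dependency-free artifacts.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal

REQUIRED_EVENT_COLUMNS = ("trial", "block", "state_id", "choice_type")
ONSET_COLUMNS = ("onset", "onset_cue", "onset_choice", "onset_us", "onset_rating")


def write_events(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"events table missing mandatory columns: {missing}")
    table.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing mandatory columns: {missing}")
    for col in ONSET_COLUMNS:
        if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"malformed onset column {col!r}: non-numeric values")
    return df


def write_volume(array: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    """3-D or 4-D array to NIfTI (``.nii``/``.nii.gz``) or ``.npy``."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, np.asarray(array))
        return
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (array, affine); affine is identity for the array container."""
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path, allow_pickle=False), np.eye(4)
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def check_grid(volume: np.ndarray, mask: np.ndarray) -> None:
    if volume.shape[:3] != mask.shape:
        raise ValueError(
            f"volume grid {volume.shape[:3]} does not match mask grid {mask.shape}"
        )


# ---------------------------------------------------------------------------
# respiration traces
# ---------------------------------------------------------------------------


def sniff_features(
    trace: np.ndarray,
    cue_onsets: np.ndarray,
    fs: float,
    smooth_ms: float = 250.0,
    highpass_s: float = 50.0,
    baseline_s: float = 0.5,
    window_s: float = 5.0,
    nuisance_hz: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-trial sniff peak amplitude and duration from a respiration trace.

    Processing: moving-average smoothing over ``smooth_ms``; high-pass
    filtering (Butterworth, cutoff ``1/highpass_s`` Hz) to remove slow
    drifts; z-normalisation over the run; per-trial baseline subtraction
    over the ``baseline_s`` window preceding the sniff cue; division by
    the maximum amplitude over all trials of the run.  Peak amplitude is
    the maximum within ``window_s`` of cue onset and duration the time
    from cue to that maximum.  Also returns the smoothed, normalised
    trace down-sampled to ``nuisance_hz`` for use as a GLM nuisance
    regressor.
    """
    trace = np.asarray(trace, dtype=float)
    cue_onsets = np.asarray(cue_onsets, dtype=float)
    n = trace.shape[0]
    if cue_onsets.size and (cue_onsets.max() + window_s) * fs > n:
        raise ValueError("trace shorter than the span of the events")

    win = max(1, int(round(smooth_ms / 1000.0 * fs)))
    smoothed = np.convolve(trace, np.ones(win) / win, mode="same")
    sos = signal.butter(2, 1.0 / highpass_s, btype="highpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, smoothed)
    sd = filtered.std()
    normed = (filtered - filtered.mean()) / (sd if sd > 0 else 1.0)

    step = max(1, int(round(fs / nuisance_hz)))
    downsampled = normed[::step].copy()

    n_trials = cue_onsets.shape[0]
    segs = []
    for onset in cue_onsets:
        i0 = int(round(onset * fs))
        b0 = max(0, i0 - int(round(baseline_s * fs)))
        baseline = normed[b0:i0].mean() if i0 > b0 else 0.0
        seg = normed[i0 : i0 + int(round(window_s * fs))] - baseline
        segs.append(seg)
    run_max = max((np.abs(s).max() for s in segs), default=1.0)
    if run_max == 0:
        run_max = 1.0
    peaks = np.empty(n_trials)
    durations = np.empty(n_trials)
    for i, seg in enumerate(segs):
        seg = seg / run_max
        k = int(np.argmax(seg))
        peaks[i] = seg[k]
        durations[i] = k / fs
    return pd.DataFrame({"trial": np.arange(n_trials), "peak": peaks, "duration": durations}), downsampled
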