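"""FIR and event-related design matrices with parametric modulators, and OLS fitting.

The univariate engine: finite-impulse-response (FIR) designs model the
response to each odor delivery in nine post-onset scan bins without
assuming a hemodynamic shape; each bin carries one unmodulated column
plus one column per parametric modulator (mean-centered modulator value
times the bin indicator).  Serial orthogonalization of modulators is
deliberately not offered — correlated modulators share variance, and
variance-inflation factors are reported instead.  Event-related designs
(used by the pattern analyses) are boxcars convolved with a canonical
double-gamma HRF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

N_BINS_DEFAULT = 9
PEAK_BINS_DEFAULT = (3, 4, 5)  # 1-based; 6-10 s post onset at TR = 2 s


def double_gamma_hrf(
    t: np.ndarray, peak: float = 5.0, undershoot: float = 15.0, ratio: float = 1.0 / 6.0
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    h = _gamma_dist.pdf(t, peak + 1.0) - ratio * _gamma_dist.pdf(t, undershoot + 1.0)
    return h


def fir_hrf_kernel(
    tr: float = 2.0, n_bins: int = N_BINS_DEFAULT, peak: float = 5.0, undershoot: float = 15.0
) -> np.ndarray:
    """HRF sampled on the FIR bin grid, scaled so bins 3-5 average to 1.

    With this normalisation a response of planted amplitude ``a`` yields
    a bin-3-5-averaged FIR estimate of exactly ``a``.
    """
    h = double_gamma_hrf(np.arange(n_bins) * tr, peak=peak, undershoot=undershoot)
    idx = [b - 1 for b in PEAK_BINS_DEFAULT]
    return h / np.mean(h[idx])


@dataclass
class DesignMatrix:
    """time x regressors matrix plus per-column metadata.

    Each entry of ``columns`` is a dict with keys ``kind`` ("fir",
    "event", "nuisance", "constant"), ``name``, and for FIR columns
    ``bin`` (1-based) and ``modulator`` (None for the unmodulated set).
    """

    matrix: np.ndarray
    columns: list[dict]
    tr: float
    rank: int = 0

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError("column metadata does not match matrix width")
        self.rank = int(np.linalg.matrix_rank(self.matrix))

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    def column_index(self, **query) -> list[int]:
        """Indices of columns whose metadata matches all query items."""
        out = []
        for i, meta in enumerate(self.columns):
            if all(meta.get(k) == v for k, v in query.items()):
                out.append(i)
        return out

    def vif(self) -> np.ndarray:
        """Variance inflation factor per column (collinearity diagnostic)."""
        X = self.matrix - self.matrix.mean(axis=0)
        sd = X.std(axis=0)
        keep = sd > 0
        Xn = X[:, keep] / sd[keep]
        c = np.linalg.pinv(Xn.T @ Xn / Xn.shape[0])
        out = np.full(self.matrix.shape[1], np.nan)
        out[keep] = np.diag(c)
        return out


def _onset_to_scan(onsets: np.ndarray, tr: float, mapping: str) -> np.ndarray:
    if mapping == "nearest":
        return np.rint(np.asarray(onsets) / tr).astype(int)
    if mapping == "floor":
        return np.floor(np.asarray(onsets) / tr).astype(int)
    raise ValueError(f"unknown onset mapping {mapping!r}")


def build_fir_design(
    onsets: np.ndarray,
    modulators: dict[str, np.ndarray] | None,
    n_scans: int,
    tr: float = 2.0,
    n_bins: int = N_BINS_DEFAULT,
    nuisance: dict[str, np.ndarray] | None = None,
    onset_mapping: str = "nearest",
    event_name: str = "us",
    add_constant: bool = True,
    extra_event_sets: dict[str, np.ndarray] | None = None,
) -> DesignMatrix:
    """FIR design: unmodulated bin indicators plus modulated bin columns.

    For each event at onset ``o`` and bin ``b`` (1-based) an indicator is
    placed at scan ``scan(o) + b - 1``; modulator columns multiply the
    indicator by the per-run mean-centered modulator value.  Modulator
    values may contain NaN (trial excluded from that modulator, e.g. an
    undefined update on the last trial); NaNs contribute 0 after
    centering over the defined trials.  ``extra_event_sets`` adds further
    FIR sets (e.g. free-choice odor deliveries modeled separately): each
    value is either an onset array (unmodulated set) or an
    ``(onsets, modulators)`` tuple.  Bins that would fall past the run
    end are truncated; onsets outside the run raise with the offending
    indices listed.
    """
    onsets = np.asarray(onsets, dtype=float)
    scans = _onset_to_scan(onsets, tr, onset_mapping)
    bad = np.where((scans < 0) | (scans >= n_scans))[0]
    if bad.size:
        raise ValueError(f"events extend past run end: onsets at indices {bad.tolist()}")
    modulators = modulators or {}
    for name, vals in modulators.items():
        if np.asarray(vals).shape[0] != onsets.shape[0]:
            raise ValueError(f"modulator {name!r} length != number of events")

    cols: list[np.ndarray] = []
    meta: list[dict] = []

    def add_fir_set(ev_scans: np.ndarray, mod_name: str | None, values: np.ndarray | None, set_name: str):
        for b in range(1, n_bins + 1):
            col = np.zeros(n_scans)
            for e, s in enumerate(ev_scans):
                idx = s + b - 1
                if idx < n_scans:
                    col[idx] += 1.0 if values is None else values[e]
            cols.append(col)
            meta.append({"kind": "fir", "name": set_name, "bin": b, "modulator": mod_name})

    add_fir_set(scans, None, None, event_name)
    for name, vals in modulators.items():
        vals = np.asarray(vals, dtype=float)
        centered = vals - np.nanmean(vals)
        centered = np.where(np.isnan(centered), 0.0, centered)
        add_fir_set(scans, name, centered, event_name)
    for set_name, spec in (extra_event_sets or {}).items():
        ev_onsets, set_mods = spec if isinstance(spec, tuple) else (spec, {})
        ev_scans = _onset_to_scan(np.asarray(ev_onsets, dtype=float), tr, onset_mapping)
        bad = np.where((ev_scans < 0) | (ev_scans >= n_scans))[0]
        if bad.size:
            raise ValueError(f"events in set {set_name!r} extend past run end: {bad.tolist()}")
        add_fir_set(ev_scans, None, None, set_name)
        for mod_name, vals in set_mods.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape[0] != ev_scans.shape[0]:
                raise ValueError(f"modulator {mod_name!r} length != events in set {set_name!r}")
            centered = vals - np.nanmean(vals)
            centered = np.where(np.isnan(centered), 0.0, centered)
            add_fir_set(ev_scans, mod_name, centered, set_name)

    for name, series in (nuisance or {}).items():
        series = np.asarray(series, dtype=float)
        if series.shape[0] != n_scans:
            raise ValueError(f"nuisance {name!r} length {series.shape[0]} != n_scans {n_scans}")
        cols.append(series - series.mean())
        meta.append({"kind": "nuisance", "name": name, "bin": None, "modulator": None})
    if add_constant:
        cols.append(np.ones(n_scans))
        meta.append({"kind": "constant", "name": "constant", "bin": None, "modulator": None})
    return DesignMatrix(matrix=np.column_stack(cols), columns=meta, tr=tr)


def build_event_design(
    events: list[dict],
    n_scans: int,
    tr: float = 2.0,
    nuisance: dict[str, np.ndarray] | None = None,
    hrf_peak: float = 5.0,
    hrf_undershoot: float = 15.0,
    add_constant: bool = True,
) -> DesignMatrix:
    """Event-related design: HRF-convolved boxcars grouped by regressor name.

    Each event dict has ``onset`` (s), ``duration`` (s, 0 for an
    impulse) and ``name``; events sharing a name share one column.  The
    boxcar is sampled on the scan grid (a zero-duration event occupies
    its onset scan) and convolved with the double-gamma HRF.  Duplicate
    (name, onset) pairs raise.
    """
    seen = set()
    groups: dict[str, list[tuple[float, float]]] = {}
    for ev in events:
        key = (ev["name"], float(ev["onset"]))
        if key in seen:
            raise ValueError(f"duplicate regressor/onset pair {key}")
        seen.add(key)
        groups.setdefault(ev["name"], []).append((float(ev["onset"]), float(ev["duration"])))

    kernel = double_gamma_hrf(np.arange(0, 30.0, tr), peak=hrf_peak, undershoot=hrf_undershoot)
    peak_val = kernel.max()
    kernel = kernel / peak_val if peak_val > 0 else kernel

    cols, meta = [], []
    for name, evs in groups.items():
        box = np.zeros(n_scans)
        for onset, duration in evs:
            s0 = int(np.rint(onset / tr))
            s1 = max(s0 + 1, int(np.ceil((onset + duration) / tr)))
            if s0 < 0 or s0 >= n_scans:
                raise ValueError(f"event {name!r} at {onset}s outside the run")
            box[s0 : min(s1, n_scans)] = 1.0
        col = np.convolve(box, kernel)[:n_scans]
        cols.append(col)
        meta.append({"kind": "event", "name": name, "bin": None, "modulator": None})
    for name, series in (nuisance or {}).items():
        series = np.asarray(series, dtype=float)
        if series.shape[0] != n_scans:
            raise ValueError(f"nuisance {name!r} length {series.shape[0]} != n_scans {n_scans}")
        cols.append(series - series.mean())
        meta.append({"kind": "nuisance", "name": name, "bin": None, "modulator": None})
    if add_constant:
        cols.append(np.ones(n_scans))
        meta.append({"kind": "constant", "name": "constant", "bin": None, "modulator": None})
    return DesignMatrix(matrix=np.column_stack(cols), columns=meta, tr=tr)


@dataclass
class GlmFit:
    """OLS fit: betas are (n_columns, n_voxels); design retained for lookup."""

    betas: np.ndarray
    design: DesignMatrix
    resid_var: np.ndarray
    dof: int
    rank_deficient: bool = False
    excluded_voxels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def fit_ols(bold: np.ndarray, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares per voxel.

    ``bold`` is (n_voxels, n_scans) or a single (n_scans,) series.
    Rank-deficient designs fall back to the pseudo-inverse with an
    explicit flag; all-NaN voxels are excluded and their indices
    recorded (betas NaN).
    """
    X = design.matrix
    squeeze = bold.ndim == 1
    Y = np.atleast_2d(bold)
    if Y.shape[1] != X.shape[0]:
        raise ValueError(f"bold has {Y.shape[1]} time points but design has {X.shape[0]} scans")
    nan_vox = np.where(np.all(np.isnan(Y), axis=1))[0]
    ok = np.setdiff1d(np.arange(Y.shape[0]), nan_vox)
    rank_deficient = design.rank < X.shape[1]
    pinv = np.linalg.pinv(X)
    betas = np.full((X.shape[1], Y.shape[0]), np.nan)
    betas[:, ok] = pinv @ Y[ok].T
    resid = Y[ok].T - X @ betas[:, ok]
    dof = X.shape[0] - design.rank
    rv = np.full(Y.shape[0], np.nan)
    rv[ok] = np.sum(resid**2, axis=0) / max(dof, 1)
    if squeeze:
        pass  # callers index betas[:, 0]
    return GlmFit(
        betas=betas,
        design=design,
        resid_var=rv,
        dof=dof,
        rank_deficient=rank_deficient,
        excluded_voxels=nan_vox,
    )


def bin_average_contrast(
    fit: GlmFit, modulator: str | None, bins: tuple[int, ...] = PEAK_BINS_DEFAULT,
    event_name: str = "us",
) -> np.ndarray:
    """Per-voxel mean of a FIR set's betas over the requested 1-based bins.

    ``modulator=None`` averages the unmodulated response.  Bins 3-5
    correspond to 6-10 s after odor onset at TR = 2 s, bracketing the
    hemodynamic peak.
    """
    idx = []
    for b in bins:
        cols = fit.design.column_index(kind="fir", name=event_name, bin=b, modulator=modulator)
        if not cols:
            raise ValueError(f"no FIR column for modulator {modulator!r} bin {b}")
        idx.extend(cols)
    return fit.betas[idx].mean(axis=0)
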