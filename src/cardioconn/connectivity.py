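"""Voxel-wise weighted-degree centrality from aligned 4D volumes.

The per-subject chain (on already-aligned data):

1. drop initial equilibration volumes per run,
2. spatial Gaussian smoothing (6 mm FWHM default),
3. grand-mean intensity scaling to 10,000 (configurable off),
4. zero-phase band-pass 0.01-0.08 Hz per run,
5. run concatenation, framewise-displacement scrubbing (> 0.5 mm) and
   retention of the first 120 usable volumes,
6. confound regression: 6 motion parameters + temporal derivatives,
   linear and quadratic trends, and 5 principal components each from
   white-matter and CSF voxel series,
7. weighted degree on the shared grey-matter mask: per voxel, the sum of
   positive Fisher r-to-z transformed correlations to all other mask
   voxels (negatives removed, diagonal excluded, no further threshold).

The voxel-by-voxel correlation matrix is never materialized in full: the
degree sum is accumulated over row blocks, and the result is independent
of block size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

__all__ = [
    "MotionTrace",
    "PreprocConfig",
    "MaskedSeriesMatrix",
    "WeightedDegreeMap",
    "compute_fd",
    "select_volumes",
    "confound_regress",
    "bandpass",
    "spatial_smooth",
    "make_gm_mask",
    "extract_series",
    "weighted_degree",
    "subject_wd_qc",
    "process_subject",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MotionTrace:
    """Six rigid-body parameters per volume plus framewise displacement."""

    params: np.ndarray  # (t, 6): 3 translations mm, 3 rotations rad
    head_radius_mm: float = 50.0

    def __post_init__(self) -> None:
        p = np.asarray(self.params, dtype=float)
        if p.ndim != 2 or p.shape[1] != 6:
            raise ValueError("motion parameters must be (n_volumes, 6)")
        if not np.all(np.isfinite(p)):
            raise ValueError("motion parameters must be finite")
        self.params = p

    @property
    def fd_mm(self) -> np.ndarray:
        return compute_fd(self.params, self.head_radius_mm)


@dataclass(frozen=True)
class PreprocConfig:
    drop_initial_volumes: int = 4
    band_hz: tuple[float, float] = (0.01, 0.08)
    fd_threshold_mm: float = 0.5
    n_keep_volumes: int = 120
    n_noise_components: int = 5
    smoothing_fwhm_mm: float = 6.0
    gm_pv_threshold: float = 0.2
    tr_s: float = 3.0
    grand_mean_scale: float | None = 10000.0
    head_radius_mm: float = 50.0
    filter_confounds: bool = True

    def validate(self) -> None:
        nyq = 1.0 / (2.0 * self.tr_s)
        lo, hi = self.band_hz
        if not (0 < lo < hi < nyq):
            raise ValueError(
                f"band {self.band_hz} must satisfy 0 < low < high < Nyquist ({nyq:.4g} Hz)"
            )
        if self.n_keep_volumes <= 25:
            raise ValueError("n_keep_volumes must exceed the confound count")


@dataclass
class MaskedSeriesMatrix:
    """Voxel x time matrix restricted to the grey-matter mask."""

    data: np.ndarray  # (n_voxels, n_timepoints)
    mask: np.ndarray  # boolean 3D
    affine: np.ndarray
    tr_s: float

    @property
    def voxel_coords(self) -> np.ndarray:
        return np.argwhere(self.mask)

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]


@dataclass
class WeightedDegreeMap:
    """Per-voxel non-negative centrality on the shared mask geometry."""

    wd: np.ndarray  # (n_voxels,)
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.wd.shape[0] != int(self.mask.sum()):
            raise ValueError("wd length must equal mask voxel count")
        if np.any(self.wd < 0):
            raise ValueError("weighted degree must be non-negative")

    @property
    def mean_wd(self) -> float:
        return float(self.wd.mean())

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.mask.shape, dtype=np.float32)
        vol[self.mask] = self.wd
        return vol


# ---------------------------------------------------------------------------
# motion


def compute_fd(params: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement: sum of absolute backward differences of the
    three translations plus ``head_radius_mm`` times those of the three
    rotations (radians).  fd[0] = 0 by convention."""
    p = np.asarray(params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion parameters must be (n_volumes, 6)")
    if p.shape[0] < 2:
        raise ValueError("need at least two volumes")
    if not np.all(np.isfinite(p)):
        raise ValueError("motion parameters must be finite")
    d = np.abs(np.diff(p, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate(([0.0], fd))


def select_volumes(
    fd_runs: list[np.ndarray],
    threshold_mm: float = 0.5,
    n_keep: int = 120,
    subject: str = "<unnamed>",
) -> tuple[np.ndarray, np.ndarray]:
    """Scrub high-motion volumes and keep the first ``n_keep`` survivors.

    ``fd_runs`` holds per-run FD series in acquisition order (initial
    equilibration volumes already dropped).  Returns ``(indices, run_ids)``
    into/of the run concatenation.  Raises if fewer than ``n_keep``
    volumes survive scrubbing.
    """
    fd = np.concatenate(fd_runs)
    run_ids = np.concatenate([np.full(r.size, i) for i, r in enumerate(fd_runs)])
    usable = np.flatnonzero(fd <= threshold_mm)
    if usable.size < n_keep:
        raise ValueError(
            f"subject {subject}: only {usable.size} usable volumes after scrubbing "
            f"(need {n_keep})"
        )
    keep = usable[:n_keep]
    return keep, run_ids[keep]


# ---------------------------------------------------------------------------
# temporal / spatial filtering


def bandpass(
    series: np.ndarray, band_hz: tuple[float, float] = (0.01, 0.08), tr_s: float = 3.0
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    nyq = 1.0 / (2.0 * tr_s)
    lo, hi = band_hz
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyq:.4g}) for TR {tr_s}")
    sos = sps.butter(2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(series, dtype=np.float64), axis=-1)


def spatial_smooth(
    volume: np.ndarray, fwhm_mm: float = 6.0, voxel_size_mm: float = 3.0
) -> np.ndarray:
    """Per-volume Gaussian smoothing of a 3D or 4D array (last axis = time)."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return volume.copy()
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    sigmas = (sigma,) * 3 + ((0,) if volume.ndim == 4 else ())
    vol = np.asarray(volume)
    if not np.issubdtype(vol.dtype, np.floating):
        vol = vol.astype(np.float64)
    return gaussian_filter(vol, sigma=sigmas, mode="constant")


# ---------------------------------------------------------------------------
# masks and extraction


def make_gm_mask(gm_pv: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Grey-matter mask: partial-volume estimate strictly greater than the
    threshold.  The identical mask is reused for every subject."""
    pv = np.asarray(gm_pv, dtype=float)
    if pv.min() < 0 or pv.max() > 1:
        raise ValueError("partial-volume values must lie in [0, 1]")
    mask = pv > threshold
    if not mask.any():
        raise ValueError("empty grey-matter mask")
    return mask


def extract_series(
    volume: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    tr_s: float,
    drop_zero_variance: bool = True,
    flat: bool = False,
) -> MaskedSeriesMatrix:
    """Extract voxel x time series inside the mask, removing (with a warning)
    any zero-variance voxel so later correlation stages stay well-defined.

    With ``flat=True``, ``volume`` is already a (n_mask_voxels, T) matrix
    in mask order."""
    data = np.asarray(volume) if flat else np.asarray(volume)[mask]
    if drop_zero_variance:
        variances = data.var(axis=1)
        dead = variances <= 0
        if dead.any():
            warnings.warn(
                f"removed {int(dead.sum())} zero-variance voxels from the mask"
            )
            coords = np.argwhere(mask)[dead]
            mask = mask.copy()
            mask[tuple(coords.T)] = False
            data = data[~dead]
    return MaskedSeriesMatrix(data=data, mask=mask, affine=affine, tr_s=tr_s)


# ---------------------------------------------------------------------------
# confound regression


def build_confound_design(
    motion_params: np.ndarray,
    wm_series: np.ndarray,
    csf_series: np.ndarray,
    n_components: int = 5,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the nuisance design: intercept, linear and quadratic trends,
    6 motion estimates + their temporal derivatives, and the top principal
    components of the demeaned white-matter and CSF voxel series."""
    T = motion_params.shape[0]
    t = np.linspace(-1.0, 1.0, T)
    cols = [np.ones(T), t, t**2]
    names = ["intercept", "trend_lin", "trend_quad"]
    motion = np.asarray(motion_params, dtype=float)
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    for j in range(6):
        cols.append(motion[:, j])
        names.append(f"motion_{j}")
    for j in range(6):
        cols.append(deriv[:, j])
        names.append(f"motion_deriv_{j}")
    for label, series in (("wm", wm_series), ("csf", csf_series)):
        X = np.asarray(series, dtype=float)  # (voxels, T)
        Xc = (X - X.mean(axis=1, keepdims=True)).T  # (T, voxels)
        k = min(n_components, min(Xc.shape) - 1)
        if k > 0:
            u, s, _ = np.linalg.svd(Xc, full_matrices=False)
            comps = u[:, :k] * np.sqrt(T)  # unit-variance components
            for j in range(k):
                cols.append(comps[:, j])
                names.append(f"{label}_pc_{j}")
    return np.column_stack(cols), names


def confound_regress(series: np.ndarray, design: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Project the confound design out of each voxel series.

    ``series`` is (voxels, T); ``design`` is (T, p).  Raises on a
    rank-deficient design, naming the dependent columns.
    """
    X = np.asarray(design, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"confound design has {X.shape[1]} regressors for {X.shape[0]} time points"
        )
    q, r, piv = _qr_with_pivoting(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * X.shape[0] * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = sorted(piv[rank:])
        labels = [names[i] if names else str(i) for i in bad]
        raise ValueError(f"confound design is rank deficient; collinear columns: {labels}")
    Y = np.asarray(series, dtype=np.float64)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ beta).T


def _qr_with_pivoting(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


# ---------------------------------------------------------------------------
# weighted degree


def weighted_degree(
    series: MaskedSeriesMatrix | np.ndarray,
    clip_eps: float = 1e-7,
    block_size: int = 256,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> WeightedDegreeMap:
    """Weighted-degree centrality: WD_i = sum_{j != i} max(0, atanh(r_ij)).

    Pearson correlations are clipped to |r| <= 1 - clip_eps before the
    Fisher transform (which diverges at |r| = 1); negative correlations
    contribute nothing.  The sum is accumulated over row blocks so the
    full voxel x voxel matrix is never stored; the result is independent
    of ``block_size``.
    """
    if isinstance(series, MaskedSeriesMatrix):
        X = series.data
        mask = series.mask
        affine = series.affine
    else:
        X = np.asarray(series, dtype=float)
        if mask is None:
            mask = np.ones((X.shape[0], 1, 1), dtype=bool)
        if affine is None:
            affine = np.eye(4)
    n, T = X.shape
    if n < 2:
        raise ValueError("need at least 2 voxels")
    if T < 8:
        raise ValueError("need at least 8 time points")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-variance voxel encountered; mask hygiene violated")
    Z = Xc / norms[:, None]

    hi = 1.0 - clip_eps
    self_term = np.arctanh(hi)  # own-row diagonal after clipping
    wd = np.empty(n)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        R = Z[start:stop] @ Z.T
        np.clip(R, -hi, hi, out=R)
        np.arctanh(R, out=R)
        np.maximum(R, 0.0, out=R)
        wd[start:stop] = R.sum(axis=1) - self_term
    wd = np.maximum(wd, 0.0)
    return WeightedDegreeMap(wd=wd, mask=mask, affine=affine)


def subject_wd_qc(mean_wds: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Cohort-level exclusion flags: a subject is flagged iff their mean
    whole-mask weighted degree falls outside [Q1 - k*IQR, Q3 + k*IQR]."""
    v = np.asarray(mean_wds, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 subjects for IQR screening")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - k * iqr) | (v > q3 + k * iqr)


# ---------------------------------------------------------------------------
# per-subject pipeline


def process_subject(
    bold_runs: list[np.ndarray],
    motion_runs: list[np.ndarray],
    gm_pv: np.ndarray,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    affine: np.ndarray,
    config: PreprocConfig = PreprocConfig(),
    gm_mask: np.ndarray | None = None,
    subject: str = "<unnamed>",
    voxel_size_mm: float | None = None,
) -> tuple[MaskedSeriesMatrix, dict]:
    """Run the full nuisance pipeline on one subject.

    Order per run: drop equilibration volumes, smooth, grand-mean scale,
    band-pass.  Runs are then concatenated, scrubbed by FD, trimmed to
    the first ``n_keep_volumes`` survivors, and confound-regressed.
    Tissue noise components are computed from the pre-band-pass series at
    the retained volumes.  Returns the residual grey-matter series and a
    QC dict (mean FD, scrub count).
    """
    config.validate()
    if voxel_size_mm is None:
        voxel_size_mm = float(np.abs(affine[0, 0])) or 3.0
    if gm_mask is None:
        gm_mask = make_gm_mask(gm_pv, config.gm_pv_threshold)

    d = config.drop_initial_volumes
    brain = gm_mask | wm_mask | csf_mask
    gm_runs, wm_runs, csf_runs, fd_runs, motion_kept = [], [], [], [], []
    for bold, motion in zip(bold_runs, motion_runs):
        bold = bold[..., d:]
        motion = np.asarray(motion, dtype=float)[d:]
        sm = spatial_smooth(bold, config.smoothing_fwhm_mm, voxel_size_mm)
        if config.grand_mean_scale:
            gm_mean = float(sm[brain].mean())
            if gm_mean <= 0:
                raise ValueError(f"subject {subject}: non-positive grand mean")
            sm *= np.asarray(config.grand_mean_scale / gm_mean, dtype=sm.dtype)
        # band-pass only the extracted series; the filter is voxel-wise so
        # this is identical to filtering the full grid first
        gm_runs.append(bandpass(sm[gm_mask], config.band_hz, config.tr_s))
        if config.filter_confounds:
            # filter nuisance series identically to the data, otherwise the
            # regression removes only part of the band-limited noise and
            # reintroduces broadband regressor noise
            wm_runs.append(bandpass(sm[wm_mask], config.band_hz, config.tr_s))
            csf_runs.append(bandpass(sm[csf_mask], config.band_hz, config.tr_s))
            motion_kept.append(bandpass(motion.T, config.band_hz, config.tr_s).T)
        else:
            wm_runs.append(np.asarray(sm[wm_mask], dtype=np.float64))
            csf_runs.append(np.asarray(sm[csf_mask], dtype=np.float64))
            motion_kept.append(motion)
        fd_runs.append(compute_fd(motion, config.head_radius_mm))

    keep, _ = select_volumes(
        fd_runs, config.fd_threshold_mm, config.n_keep_volumes, subject=subject
    )
    filt = np.concatenate(gm_runs, axis=-1)[:, keep]
    wm_series = np.concatenate(wm_runs, axis=-1)[:, keep]
    csf_series = np.concatenate(csf_runs, axis=-1)[:, keep]
    motion_all = np.concatenate(motion_kept, axis=0)[keep]
    fd_all = np.concatenate(fd_runs)

    design, names = build_confound_design(
        motion_all, wm_series, csf_series, config.n_noise_components
    )
    gm = extract_series(filt, gm_mask, affine, config.tr_s, flat=True)
    resid = confound_regress(gm.data, design, names)
    qc = {
        "subject": subject,
        "mean_fd_mm": float(fd_all.mean()),
        "n_scrubbed": int((fd_all > config.fd_threshold_mm).sum()),
        "n_retained": int(keep.size),
    }
    return (
        MaskedSeriesMatrix(data=resid, mask=gm.mask, affine=affine, tr_s=config.tr_s),
        qc,
    )
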