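"""Mass-univariate GLMs linking weighted-degree maps to autonomic metrics.

The central object is :class:`WeightedDegreeGLM`: a model built from a
stack of per-subject weighted-degree maps and a subject-level design
matrix (the autonomic metric of interest plus nuisance covariates such
as age, mean framewise displacement and medication flags).  ``fit()``
runs ordinary least squares at every voxel and returns a
:class:`WeightedDegreeGLMResults` carrying per-voxel betas, t- and
z-statistics (t converted through the exact t CDF / normal quantile
composition, evaluated in log space so deep tails do not saturate),
residual maps for smoothness estimation, and ``summary()`` /
``cluster_correct()`` methods.

``run_association`` chains the full inference twice -- once under the
primary covariate set and once under the extended post-hoc set -- and
intersects the surviving-cluster masks (the voxels significant under
both models).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .clusters import (
    ACFParams,
    ClusterInferenceResult,
    InferenceConfig,
    estimate_smoothness,
    extract_clusters,
    simulate_cluster_threshold,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "WeightedDegreeGLM",
    "WeightedDegreeGLMResults",
    "AssociationResult",
    "fit_voxel_glm",
    "t_to_z",
    "run_association",
    "PRIMARY_COVARIATES",
    "POSTHOC_COVARIATES",
]

PRIMARY_COVARIATES = ("age", "mean_fd_mm", "ssri_snri", "beta_blocker")
POSTHOC_COVARIATES = PRIMARY_COVARIATES + ("alpha_blocker", "stimulant")


# ---------------------------------------------------------------------------
# design


@dataclass(frozen=True)
class DesignMatrix:
    """Subject-level design with a designated regressor of interest."""

    X: np.ndarray  # (n_subjects, p), includes intercept
    names: tuple[str, ...]
    interest: int  # column index of the regressor of interest

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, interest: str, covariates: tuple[str, ...] = ()
    ) -> "DesignMatrix":
        cols = [interest, *covariates]
        X = np.column_stack(
            [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in cols]
        )
        return cls(X=X, names=("intercept", *cols), interest=1)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        n, p = X.shape
        if n <= p:
            raise ValueError(f"need more subjects ({n}) than regressors ({p})")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("design matrix is rank deficient")
        if not (0 <= self.interest < p):
            raise ValueError("regressor-of-interest index out of range")
        object.__setattr__(self, "X", X)

    @property
    def df_resid(self) -> int:
        return self.X.shape[0] - self.X.shape[1]


# ---------------------------------------------------------------------------
# core computations


def fit_voxel_glm(Y: np.ndarray, design: DesignMatrix):
    """Voxel-wise OLS.  ``Y`` is (n_subjects, n_voxels).

    Returns ``(beta, t, resid, df)`` where ``beta`` and ``t`` refer to the
    regressor of interest and ``resid`` is (n_subjects, n_voxels).
    """
    X = design.X
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("one map per design row required")
    pinv = np.linalg.pinv(X)
    B = pinv @ Y  # (p, voxels)
    resid = Y - X @ B
    df = n - p
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[design.interest, design.interest], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B[design.interest] / se, np.inf * np.sign(B[design.interest]))
    return B[design.interest], t, resid, df


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Convert t-statistics to standard-normal z with the sign preserved.

    The one-sided tail probability is computed in log space
    (``t.logsf`` composed with ``ndtri_exp``) so that very large |t| maps
    to the correct large |z| instead of saturating at the double-
    precision probability floor.  Non-finite t propagates (with inf
    mapped to signed inf z).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    finite = np.isfinite(t)
    if not finite.all():
        import warnings

        warnings.warn("non-finite t-statistics propagated to z-map")
        out[~finite] = t[~finite]
    at = np.abs(t[finite])
    logp = stats.t.logsf(at, df)
    z = -special.ndtri_exp(logp)  # upper-tail quantile of |t|'s p-value
    out[finite] = np.sign(t[finite]) * z
    return out


# ---------------------------------------------------------------------------
# model / results


class WeightedDegreeGLM:
    """Mass-univariate GLM of weighted-degree maps on an autonomic metric.

    Parameters
    ----------
    wd : (n_subjects, n_voxels) array
        Per-subject weighted-degree values on the shared mask.
    design : DesignMatrix
        Subject-level design (intercept + metric + nuisance covariates).
    mask : 3D boolean array
        The shared grey-matter mask the voxel axis refers to.
    voxel_size_mm : float
        Isotropic voxel size, used for smoothness estimation.
    """

    def __init__(
        self,
        wd: np.ndarray,
        design: DesignMatrix,
        mask: np.ndarray,
        voxel_size_mm: float = 3.0,
    ) -> None:
        wd = np.asarray(wd, dtype=float)
        if wd.ndim != 2:
            raise ValueError("wd must be (n_subjects, n_voxels)")
        if wd.shape[1] != int(mask.sum()):
            raise ValueError("voxel axis must match the mask voxel count")
        self.wd = wd
        self.design = design
        self.mask = np.asarray(mask, dtype=bool)
        self.voxel_size_mm = float(voxel_size_mm)

    @classmethod
    def from_cohort(
        cls,
        wd_maps,
        covariates: pd.DataFrame,
        metric: str,
        nuisance: tuple[str, ...] = PRIMARY_COVARIATES,
        voxel_size_mm: float = 3.0,
    ) -> "WeightedDegreeGLM":
        """Build from a list of WeightedDegreeMap and a covariate table.

        Subjects with missing covariate values are dropped with a log entry.
        """
        cols = [metric, *nuisance]
        complete = covariates[cols].notna().all(axis=1).to_numpy()
        if not complete.all():
            dropped = covariates.loc[~complete, "subject_id"].tolist() if "subject_id" in covariates else list(np.flatnonzero(~complete))
            logger.warning("dropping subjects with missing covariates: %s", dropped)
        table = covariates.loc[complete].reset_index(drop=True)
        maps = [m for m, ok in zip(wd_maps, complete) if ok]
        wd = np.stack([m.wd for m in maps])
        design = DesignMatrix.from_dataframe(table, metric, tuple(nuisance))
        return cls(wd, design, maps[0].mask, voxel_size_mm)

    def fit(self) -> "WeightedDegreeGLMResults":
        beta, t, resid, df = fit_voxel_glm(self.wd, self.design)
        z = t_to_z(t, df)
        return WeightedDegreeGLMResults(model=self, beta=beta, t=t, z=z, resid=resid, df=df)


@dataclass
class WeightedDegreeGLMResults:
    """Per-voxel estimates from a fitted :class:`WeightedDegreeGLM`."""

    model: WeightedDegreeGLM
    beta: np.ndarray
    t: np.ndarray
    z: np.ndarray
    resid: np.ndarray  # (n_subjects, n_voxels)
    df: int

    def _to_volume(self, values: np.ndarray) -> np.ndarray:
        vol = np.zeros(self.model.mask.shape)
        vol[self.model.mask] = values
        return vol

    @property
    def z_volume(self) -> np.ndarray:
        return self._to_volume(self.z)

    def residual_volumes(self) -> list[np.ndarray]:
        return [self._to_volume(r) for r in self.resid]

    def estimate_smoothness(self, max_lag_vox: int = 8) -> ACFParams:
        return estimate_smoothness(
            self.residual_volumes(),
            self.model.mask,
            voxel_size_mm=self.model.voxel_size_mm,
            max_lag_vox=max_lag_vox,
        )

    def cluster_correct(
        self,
        config: InferenceConfig = InferenceConfig(),
        acf: ACFParams | None = None,
        rng: np.random.Generator | None = None,
    ) -> ClusterInferenceResult:
        """Monte-Carlo cluster-extent correction of the z-map."""
        if acf is None:
            acf = self.estimate_smoothness()
        null_sizes, k_alpha = simulate_cluster_threshold(
            acf, self.model.mask, config, self.model.voxel_size_mm, rng=rng
        )
        return extract_clusters(
            self.z_volume, self.model.mask, k_alpha, config, null_max_sizes=null_sizes
        )

    def summary(self) -> pd.DataFrame:
        """Voxel-level summary of the regressor of interest."""
        name = self.model.design.names[self.model.design.interest]
        return pd.DataFrame(
            {
                "regressor": [name],
                "n_subjects": [self.model.wd.shape[0]],
                "n_voxels": [self.model.wd.shape[1]],
                "df_resid": [self.df],
                "beta_mean": [float(self.beta.mean())],
                "z_min": [float(self.z.min())],
                "z_max": [float(self.z.max())],
                "n_voxels_abs_z_gt_1.96": [int((np.abs(self.z) > 1.959964).sum())],
            }
        )

    def plot_z_slices(self, axis: int = 2, n_slices: int = 4):
        """Quick-look montage of the z-map (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        vol = self.z_volume
        idx = np.linspace(0, vol.shape[axis] - 1, n_slices + 2, dtype=int)[1:-1]
        fig, axes = plt.subplots(1, len(idx), figsize=(3 * len(idx), 3))
        vmax = max(2.0, float(np.abs(self.z).max()))
        for ax, i in zip(np.atleast_1d(axes), idx):
            sl = np.take(vol, i, axis=axis)
            ax.imshow(sl.T, origin="lower", cmap="coolwarm", vmin=-vmax, vmax=vmax)
            ax.set_title(f"slice {i}")
            ax.axis("off")
        return fig


# ---------------------------------------------------------------------------
# primary / post-hoc association chain


@dataclass
class AssociationResult:
    """Primary and post-hoc cluster inferences plus their intersection."""

    metric: str
    primary: ClusterInferenceResult
    posthoc: ClusterInferenceResult | None
    intersection_mask: np.ndarray


def run_association(
    wd_maps,
    covariates: pd.DataFrame,
    metric: str,
    config: InferenceConfig = InferenceConfig(),
    primary_covariates: tuple[str, ...] = PRIMARY_COVARIATES,
    posthoc_covariates: tuple[str, ...] | None = POSTHOC_COVARIATES,
    voxel_size_mm: float = 3.0,
    rng: np.random.Generator | None = None,
) -> AssociationResult:
    """Full GLM -> z -> smoothness -> cluster chain under the primary and
    post-hoc covariate sets; the intersection mask holds the voxels
    significant under both (the "remains significant after additional
    adjustment" logic).

    Set ``posthoc_covariates=None`` to run the primary model only, in
    which case the intersection equals the primary mask.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    primary = (
        WeightedDegreeGLM.from_cohort(
            wd_maps, covariates, metric, primary_covariates, voxel_size_mm
        )
        .fit()
        .cluster_correct(config, rng=rng)
    )
    if posthoc_covariates is None:
        return AssociationResult(metric, primary, None, primary.significant_mask.copy())
    posthoc = (
        WeightedDegreeGLM.from_cohort(
            wd_maps, covariates, metric, posthoc_covariates, voxel_size_mm
        )
        .fit()
        .cluster_correct(config, rng=rng)
    )
    inter = primary.significant_mask & posthoc.significant_mask
    return AssociationResult(metric, primary, posthoc, inter)
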