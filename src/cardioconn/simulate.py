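"""Synthetic brain-autonomic cohorts with known ground truth.

Every downstream stage of the pipeline (HRV extraction, weighted-degree
centrality, mass-univariate GLM with cluster correction) is testable on
these artifacts without any external data:

* beat series: 10-min resting recordings built by direct interval
  modulation -- a mean IBI plus high-frequency (respiratory band) and
  low-frequency sinusoids plus Gaussian jitter -- with ectopic-like
  artifacts injected as isolated halved/doubled intervals whose indices
  are retained as ground truth.  Direct modulation keeps the planted
  band power analytically known (a sinusoid of amplitude a contributes
  a^2/2 ms^2).
* 4D brain volumes: a small grid containing a grey-matter shell, white
  matter and CSF cores, and a contiguous "hub" region whose voxels share
  a latent time series with loading g = base_loading + coupling_beta *
  covariate, so the hub's pairwise correlation (hence weighted degree)
  increases with the subject's autonomic covariate.  Non-hub voxels are
  independent noise plus a weak global signal; volumes are spatially
  smoothed to a target FWHM.
* motion traces: bounded Gaussian random walks with a known framewise-
  displacement distribution.
* a covariate table with group labels, age, and medication flags.

All generation is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .cardiac import BeatRecord

__all__ = [
    "AutonomicSimConfig",
    "BrainSimConfig",
    "CohortSpec",
    "SimulatedBeats",
    "BrainSubject",
    "CohortBundle",
    "generate_beats",
    "generate_brain_subject",
    "generate_cohort",
    "write_cohort",
    "brain_geometry",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class AutonomicSimConfig:
    """Parameters of the interval-modulation beat generator."""

    duration_s: float = 600.0
    mean_ibi_ms: float = 800.0
    hf_freq_hz: float = 0.25
    hf_amp_ms: float = 30.0
    lf_freq_hz: float = 0.10
    lf_amp_ms: float = 40.0
    noise_sd_ms: float = 5.0
    artifact_rate: float = 0.5  # expected artifacts per minute
    seed: int = 0

    def validate(self) -> None:
        if self.mean_ibi_ms <= 0:
            raise ValueError("mean_ibi_ms must be positive")
        if not (0.15 <= self.hf_freq_hz <= 0.40):
            raise ValueError("hf_freq_hz must lie in the HF band [0.15, 0.40] Hz")
        if not (0.04 <= self.lf_freq_hz < 0.15):
            raise ValueError("lf_freq_hz must lie in the LF band [0.04, 0.15) Hz")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be non-negative")
        if self.noise_sd_ms < 0 or self.hf_amp_ms < 0 or self.lf_amp_ms < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.hf_amp_ms + self.lf_amp_ms + 4.0 * self.noise_sd_ms >= self.mean_ibi_ms:
            raise ValueError(
                "configuration admits non-positive intervals: require "
                "hf_amp_ms + lf_amp_ms + 4*noise_sd_ms < mean_ibi_ms"
            )


@dataclass(frozen=True)
class BrainSimConfig:
    """Parameters of the 4D volume generator."""

    grid_dims: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    tr_s: float = 3.0
    n_volumes: int = 128
    coupling_beta: float = 0.375
    base_loading: float = 1.25
    noise_sd: float = 1.0
    global_signal_frac: float = 0.10
    applied_fwhm_mm: float = 6.0
    motion_sd_mm: float = 0.03
    hub_voxels: tuple | None = None  # (3, k) voxel indices; default block
    seed: int = 0

    def validate(self) -> None:
        if any(d < 8 for d in self.grid_dims):
            raise ValueError("grid_dims must be at least 8 per axis")
        if self.n_volumes < 128:
            raise ValueError("n_volumes must be >= 128 so 120 usable volumes survive")
        if self.voxel_size_mm <= 0 or self.tr_s <= 0 or self.noise_sd <= 0:
            raise ValueError("voxel_size_mm, tr_s, noise_sd must be positive")
        if self.applied_fwhm_mm < 0 or self.motion_sd_mm < 0:
            raise ValueError("applied_fwhm_mm and motion_sd_mm must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition emulating a two-group clinical covariate table."""

    n_group_a: int = 20
    n_group_b: int = 23
    group_labels: tuple[str, str] = ("FND", "PC")
    age_mean_sd: tuple[float, float] = (35.0, 13.0)
    medication_prevalences: dict = field(
        default_factory=lambda: {
            "ssri_snri": 0.50,
            "beta_blocker": 0.15,
            "alpha_blocker": 0.20,
            "stimulant": 0.30,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_group_a <= 0 or self.n_group_b <= 0:
            raise ValueError("group counts must be positive")
        for name, p in self.medication_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence for {name!r} must be in [0, 1]")


# ---------------------------------------------------------------------------
# beats


@dataclass(frozen=True)
class SimulatedBeats:
    """A beat record plus the ground-truth indices of injected artifacts."""

    record: BeatRecord
    artifact_indices: np.ndarray  # interval indices that were halved/doubled
    config: AutonomicSimConfig


def generate_beats(config: AutonomicSimConfig) -> SimulatedBeats:
    """Generate a beat-time series by direct interval modulation.

    IBI(t) = mean + hf_amp sin(2 pi f_hf t) + lf_amp sin(2 pi f_lf t) + noise;
    beats are laid down sequentially until ``duration_s`` is covered.
    Artifacts (count ~ Poisson(rate * minutes)) are then injected as
    isolated interval halvings or doublings and subsequent beat times
    shifted accordingly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    intervals_ms: list[float] = []
    t = 0.0
    while t < config.duration_s:
        ibi = (
            config.mean_ibi_ms
            + config.hf_amp_ms * np.sin(2 * np.pi * config.hf_freq_hz * t)
            + config.lf_amp_ms * np.sin(2 * np.pi * config.lf_freq_hz * t)
            + config.noise_sd_ms * rng.standard_normal()
        )
        ibi = max(ibi, 1.0)  # invariant guards against this; belt and braces
        intervals_ms.append(ibi)
        t += ibi / 1000.0
    intervals = np.array(intervals_ms)

    n_art = rng.poisson(config.artifact_rate * config.duration_s / 60.0)
    candidates = np.arange(2, intervals.size - 2)
    chosen: list[int] = []
    rng.shuffle(candidates)
    for idx in candidates:
        if len(chosen) >= n_art:
            break
        if all(abs(idx - c) > 4 for c in chosen):  # keep artifacts isolated
            chosen.append(int(idx))
    chosen_arr = np.array(sorted(chosen), dtype=int)
    for idx in chosen_arr:
        intervals[idx] *= 0.5 if rng.random() < 0.5 else 2.0

    times = np.concatenate(([0.0], np.cumsum(intervals) / 1000.0))
    return SimulatedBeats(
        record=BeatRecord(beat_times_s=times),
        artifact_indices=chosen_arr,
        config=config,
    )


# ---------------------------------------------------------------------------
# brain geometry (deterministic given the grid)


def brain_geometry(config: BrainSimConfig) -> dict:
    """Deterministic tissue layout: CSF core, white-matter ring, grey-matter
    shell, and a contiguous hub block inside the shell.

    Returns a dict with ``gm_pv`` (partial-volume map), boolean ``wm_mask``,
    ``csf_mask``, ``hub_mask``, and the NIfTI ``affine``.
    """
    dims = config.grid_dims
    center = (np.array(dims) - 1) / 2.0
    ijk = np.indices(dims).reshape(3, -1).T
    r = np.linalg.norm(ijk - center, axis=1).reshape(dims)

    r_gm_out = min(dims) / 2.0 - 1.0  # shell fits inside the grid
    csf_mask = r <= 2.0
    wm_mask = (r > 2.0) & (r <= 3.5)
    gm_mask = (r > 3.5) & (r <= r_gm_out)

    gm_pv = np.zeros(dims)
    gm_pv[csf_mask] = 0.05
    gm_pv[wm_mask] = 0.10
    gm_pv[gm_mask] = 0.90

    if config.hub_voxels is not None:
        hub_idx = np.asarray(config.hub_voxels, dtype=int)
        hub_mask = np.zeros(dims, dtype=bool)
        hub_mask[hub_idx[0], hub_idx[1], hub_idx[2]] = True
        if not np.all(gm_mask[hub_mask]):
            raise ValueError("hub_voxels must lie inside the grey-matter mask")
    else:
        # a cap of the outer shell, kept clear of the white-matter ring so
        # the smoothed hub signal does not leak into the nuisance masks
        rel = ijk - center
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_x = np.where(
                r.reshape(-1) > 0, rel[:, 0] / np.maximum(r.reshape(-1), 1e-9), 0.0
            )
        hub_mask = ((r > 5.2) & (r <= r_gm_out)).reshape(-1) & (cos_x >= 0.64)
        hub_mask = hub_mask.reshape(dims) & gm_mask

    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    return {
        "gm_pv": gm_pv,
        "gm_mask": gm_mask,
        "wm_mask": wm_mask,
        "csf_mask": csf_mask,
        "hub_mask": hub_mask,
        "affine": affine,
    }


@dataclass(frozen=True)
class BrainSubject:
    """One subject's simulated scan bundle."""

    bold: np.ndarray  # (x, y, z, t) float32
    motion_params: np.ndarray  # (t, 6): 3 translations mm, 3 rotations rad
    gm_pv: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    hub_mask: np.ndarray
    affine: np.ndarray
    tr_s: float
    hub_loading: float


def generate_brain_subject(
    config: BrainSimConfig,
    covariate_value: float,
    rng: np.random.Generator | None = None,
) -> BrainSubject:
    """Generate one subject's 4D volume, motion trace, and tissue masks.

    Hub voxels share a latent time series with loading
    ``g = base_loading + coupling_beta * covariate_value`` (clipped at 0)
    on top of independent voxel noise; all brain voxels carry a weak
    global signal; white matter and CSF carry their own shared
    fluctuations so anatomical noise components are non-trivial.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    geo = brain_geometry(config)
    dims, T = config.grid_dims, config.n_volumes

    data = rng.standard_normal((*dims, T), dtype=np.float32) * np.float32(config.noise_sd)

    brain = geo["gm_mask"] | geo["wm_mask"] | geo["csf_mask"]
    global_ts = rng.standard_normal(T).astype(np.float32)
    data[brain] += np.float32(config.global_signal_frac * config.noise_sd) * global_ts

    loading = max(0.0, config.base_loading + config.coupling_beta * covariate_value)
    latent = rng.standard_normal(T).astype(np.float32)
    data[geo["hub_mask"]] += np.float32(loading * config.noise_sd) * latent

    # tissue compartments carry their own shared fluctuation plus a strong
    # loading of the global signal (as physiological noise does in CSF and
    # white matter), so anatomical noise components can remove the global
    # fluctuation from grey matter the way they do on real data
    for tissue in ("wm_mask", "csf_mask"):
        shared = rng.standard_normal(T).astype(np.float32)
        weights = 0.6 + 0.2 * rng.random(int(geo[tissue].sum()), dtype=np.float32)
        data[geo[tissue]] += np.float32(config.noise_sd) * (
            weights[:, None] * shared + np.float32(0.5) * global_ts
        )

    if config.applied_fwhm_mm > 0:
        sigma_vox = config.applied_fwhm_mm * FWHM_TO_SIGMA / config.voxel_size_mm
        gaussian_filter(data, sigma=(sigma_vox,) * 3 + (0,), output=data)
    data += np.float32(100.0)  # scanner-like positive baseline

    trans = np.cumsum(rng.standard_normal((T, 3)) * config.motion_sd_mm, axis=0)
    rots = np.cumsum(rng.standard_normal((T, 3)) * config.motion_sd_mm / 50.0, axis=0)
    motion = np.hstack([trans, rots])
    motion[0] = 0.0

    return BrainSubject(
        bold=data,
        motion_params=motion,
        gm_pv=geo["gm_pv"],
        wm_mask=geo["wm_mask"],
        csf_mask=geo["csf_mask"],
        hub_mask=geo["hub_mask"],
        affine=geo["affine"],
        tr_s=config.tr_s,
        hub_loading=loading,
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortBundle:
    """In-memory cohort: covariate table, per-subject beats and scans,
    and a ground-truth manifest."""

    covariates: pd.DataFrame
    beats: dict[str, SimulatedBeats]
    brains: dict[str, BrainSubject]
    manifest: dict


def generate_cohort(
    spec: CohortSpec,
    autonomic_cfg: AutonomicSimConfig | None = None,
    brain_cfg: BrainSimConfig | None = None,
    include_brains: bool = True,
) -> CohortBundle:
    """Generate a full synthetic cohort with known autonomic-hub coupling.

    Each subject's HF modulation amplitude (and hence measured RMSSD/HF
    power) is scaled by a uniform factor; the standardized amplitude is
    the "autonomic covariate" passed to the brain generator, so hub
    coupling is planted against a quantity the cardiac chain can recover.
    """
    spec.validate()
    autonomic_cfg = autonomic_cfg or AutonomicSimConfig(seed=spec.seed)
    brain_cfg = brain_cfg or BrainSimConfig(seed=spec.seed)
    autonomic_cfg.validate()
    brain_cfg.validate()

    root_ss = np.random.SeedSequence(spec.seed)
    cohort_rng = np.random.default_rng(root_ss.spawn(1)[0])
    n_total = spec.n_group_a + spec.n_group_b
    subject_seeds = root_ss.spawn(n_total)

    rows = []
    beats: dict[str, SimulatedBeats] = {}
    brains: dict[str, BrainSubject] = {}

    hf_scales = cohort_rng.uniform(0.3, 1.7, size=n_total)
    covariate = (hf_scales - hf_scales.mean()) / hf_scales.std()
    ages = cohort_rng.normal(spec.age_mean_sd[0], spec.age_mean_sd[1], size=n_total)
    ages = np.clip(ages, 18.0, 80.0)
    flags = {
        name: cohort_rng.random(n_total) < p
        for name, p in spec.medication_prevalences.items()
    }

    manifest_subjects = {}
    for i in range(n_total):
        group = spec.group_labels[0] if i < spec.n_group_a else spec.group_labels[1]
        sid = f"sub-{i + 1:03d}"
        child = np.random.default_rng(subject_seeds[i])
        a_cfg = AutonomicSimConfig(
            **{
                **asdict(autonomic_cfg),
                "hf_amp_ms": autonomic_cfg.hf_amp_ms * hf_scales[i],
                "seed": int(child.integers(2**31 - 1)),
            }
        )
        sb = generate_beats(a_cfg)
        beats[sid] = sb
        if include_brains:
            brains[sid] = generate_brain_subject(brain_cfg, covariate[i], rng=child)
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": round(float(ages[i]), 2),
                **{name: bool(v[i]) for name, v in flags.items()},
            }
        )
        manifest_subjects[sid] = {
            "hf_scale": float(hf_scales[i]),
            "true_covariate": float(covariate[i]),
            "artifact_indices": [int(k) for k in sb.artifact_indices],
            "hub_loading": float(brains[sid].hub_loading) if include_brains else None,
        }

    geo = brain_geometry(brain_cfg)
    manifest = {
        "spec": {**asdict(spec), "medication_prevalences": dict(spec.medication_prevalences)},
        "autonomic_config": asdict(autonomic_cfg),
        "brain_config": {
            **asdict(brain_cfg),
            "grid_dims": list(brain_cfg.grid_dims),
            "hub_voxels": None,
        },
        "hub_voxel_indices": [[int(v) for v in xyz] for xyz in np.argwhere(geo["hub_mask"])],
        "subjects": manifest_subjects,
    }
    return CohortBundle(
        covariates=pd.DataFrame(rows),
        beats=beats,
        brains=brains,
        manifest=manifest,
    )


def write_cohort(bundle: CohortBundle, out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write a cohort bundle to disk in the pipeline's external formats.

    Beats: one-column CSV of beat times (s); volumes and maps: NIfTI-1
    (.nii.gz); motion: 6-column CSV; covariates: CSV; manifest: JSON.
    """
    import nibabel as nib

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)

    bundle.covariates.to_csv(out / "covariates.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)

    wrote_shared = False
    for sid, sb in bundle.beats.items():
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        pd.DataFrame({"beat_time_s": sb.record.beat_times_s}).to_csv(
            sdir / "beats.csv", index=False
        )
        if sid in bundle.brains:
            brain = bundle.brains[sid]
            nib.save(
                nib.Nifti1Image(brain.bold, brain.affine), sdir / "bold.nii.gz"
            )
            pd.DataFrame(
                brain.motion_params,
                columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
            ).to_csv(sdir / "motion.csv", index=False)
            if not wrote_shared:
                for name in ("gm_pv", "wm_mask", "csf_mask", "hub_mask"):
                    arr = getattr(brain, name).astype(np.float32)
                    nib.save(nib.Nifti1Image(arr, brain.affine), out / f"{name}.nii.gz")
                wrote_shared = True
    return out
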