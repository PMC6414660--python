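"""Digital kidney phantoms for quantitative SPECT/CT.

Each phantom is a paired CT-like and SPECT-like volume with a known
parenchyma VOI and known per-kidney percent injected dose (%ID).  The
anatomy is deliberately minimal — two tilted ellipsoidal kidneys with a
medial pelvis carved out, optional cysts / stones / tumors, inside a
soft-tissue body — but it reproduces the quantification bookkeeping and
the characteristic segmentation traps of clinical data:

* pelvis and lesions are *excluded* from the parenchyma ground truth;
* iodine contrast may remain in the pelvis (bright on CT) in a
  configurable fraction of subjects;
* parenchyma / soft-tissue / cyst CT contrast is weak, as on
  non-contrast CT;
* occasional single-kidney subjects;
* the SPECT volume is PSF-blurred and count-noise corrupted.

Ground-truth %ID is defined as the fraction of injected activity inside
the parenchyma VOI of the *ideal noise-free reconstructed* (post-PSF)
activity map — i.e. the quantity a perfect VOI measurement on a perfect
reconstruction would return.  The pre-blur target sampled by the
generator is kept alongside as ``target_pid``.

An emulator of sparse-slice manual VOI drawing with inter-slice
shape-based interpolation is included; its failure modes (pelvis
inclusion, missed off-slice stones) are the error sources the network
is meant to beat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import LabeledMask, Unit, VolumeGrid, smooth_mask, write_volume
from .quantify import SubjectRecord

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "ConfigError",
    "generate_phantom",
    "generate_cohort_truths",
    "generate_cohort",
    "emulate_manual_voi",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class ConfigError(ValueError):
    """Geometrically or statistically impossible phantom configuration."""


@dataclass
class PhantomConfig:
    """All knobs of the phantom generator.

    Defaults reproduce the acquisition geometry of the clinical system
    (CT 512×512×161 @ 0.977×0.977×2.5 mm, SPECT 128³ @ 3.452 mm,
    370 MBq injected, 22.6% residual pelvis contrast).  ``test_scale``
    returns a coarse small-FOV variant for fast CPU experiments.
    """

    # grids
    ct_shape: tuple[int, int, int] = (512, 512, 161)
    ct_spacing_mm: tuple[float, float, float] = (0.977, 0.977, 2.5)
    spect_shape: tuple[int, int, int] = (128, 128, 128)
    spect_spacing_mm: tuple[float, float, float] = (3.452, 3.452, 3.452)

    # kidney geometry (mm); long axis ~ inferior-superior with coronal tilt
    kidney_center_x_mm: tuple[float, float] = (48.0, 62.0)  # lateral offset range
    kidney_center_jitter_mm: tuple[float, float, float] = (4.0, 6.0, 10.0)
    kidney_semi_lr_mm: tuple[float, float] = (20.0, 26.0)
    kidney_semi_ap_mm: tuple[float, float] = (16.0, 22.0)
    kidney_semi_is_mm: tuple[float, float] = (45.0, 55.0)
    kidney_tilt_deg: tuple[float, float] = (-12.0, 12.0)
    body_semi_mm: tuple[float, float] = (165.0, 110.0)  # elliptic cylinder

    # pelvis (fraction of kidney semi-axes; medially offset)
    pelvis_semi_frac: tuple[float, float, float] = (0.50, 0.45, 0.45)
    pelvis_offset_frac: float = 0.55
    pelvis_contrast_prob: float = 0.226

    # lesions
    cyst_count_range: tuple[int, int] = (0, 2)
    cyst_diameter_mm: tuple[float, float] = (6.0, 16.0)
    tumor_prob: float = 0.15
    tumor_diameter_mm: tuple[float, float] = (10.0, 24.0)
    small_stone_diameter_mm: tuple[float, float] = (3.0, 9.0)
    large_stone_diameter_mm: tuple[float, float] = (11.0, 16.0)

    # CT appearance (HU mean, sd)
    hu_soft_tissue: tuple[float, float] = (40.0, 10.0)
    hu_parenchyma: tuple[float, float] = (35.0, 5.0)
    hu_cyst: tuple[float, float] = (10.0, 5.0)
    hu_pelvis: tuple[float, float] = (15.0, 5.0)
    hu_pelvis_contrast: tuple[float, float] = (200.0, 25.0)  # clipped >= 150
    hu_stone: tuple[float, float] = (600.0, 80.0)  # clipped >= 300
    hu_tumor: tuple[float, float] = (45.0, 8.0)
    hu_air: float = -1000.0
    #: the HU noise SDs above describe the native CT grid; per-voxel noise
    #: scales as sqrt(ref_voxel_volume / voxel_volume), the usual CT
    #: noise-volume tradeoff, so coarse test grids are not artificially noisy
    hu_noise_ref_voxel_mm3: float = 0.977 * 0.977 * 2.5

    # cohort composition
    single_kidney_prob: float = 0.01
    donor_prob: float = 0.25
    ureter_stone_prob: float = 0.5  # among symptomatic kidneys
    contralateral_small_stone_prob: float = 0.4

    # tracer
    injected_activity_mbq: float = 370.0
    pid_range: tuple[float, float] = (1.8, 4.2)  # per normal kidney
    symptomatic_pid_factor: float = 0.5
    acquisition_minutes: float = 1.0
    psf_fwhm_mm: float = 6.0
    noise_scale: float = 1.0  # 0 disables count noise

    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.pelvis_contrast_prob,
            self.single_kidney_prob,
            self.donor_prob,
            self.ureter_stone_prob,
            self.contralateral_small_stone_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        fov = np.asarray(self.ct_shape) * np.asarray(self.ct_spacing_mm)
        max_x = self.kidney_center_x_mm[1] + self.kidney_center_jitter_mm[0] + (
            self.kidney_semi_lr_mm[1] + 0.25 * self.kidney_semi_is_mm[1]
        )
        max_z = self.kidney_center_jitter_mm[2] + self.kidney_semi_is_mm[1]
        if 2 * max_x > fov[0] or 2 * max_z > fov[2]:
            raise ConfigError(
                f"kidney geometry cannot fit the CT field of view {tuple(fov)} mm"
            )
        if self.kidney_semi_lr_mm[0] <= 0 or self.pid_range[0] <= 0:
            raise ConfigError("geometric and %ID ranges must be positive")

    @classmethod
    def test_scale(cls, **overrides) -> "PhantomConfig":
        """Coarse small-FOV configuration for fast CPU runs."""
        kw = dict(
            ct_shape=(56, 40, 40),
            ct_spacing_mm=(3.5, 3.5, 3.5),
            spect_shape=(48, 36, 36),
            spect_spacing_mm=(4.0, 4.0, 4.0),
            kidney_center_x_mm=(34.0, 42.0),
            kidney_center_jitter_mm=(3.0, 4.0, 5.0),
            kidney_semi_lr_mm=(18.0, 22.0),
            kidney_semi_ap_mm=(15.0, 18.0),
            kidney_semi_is_mm=(36.0, 44.0),
            body_semi_mm=(92.0, 62.0),
            cyst_diameter_mm=(8.0, 16.0),
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PhantomTruth:
    """One generated subject: images, ground-truth VOI and %ID."""

    ct: VolumeGrid
    spect: VolumeGrid
    truth_mask: LabeledMask  # on the CT grid
    truth_mask_spect: LabeledMask  # same VOI painted on the SPECT grid
    true_pid: dict[str, float]  # ground truth (post-PSF, noise-free)
    target_pid: dict[str, float]  # pre-blur sampled target
    subject: SubjectRecord
    lesions: dict = field(default_factory=dict)
    #: CT-grid boolean masks of the excluded structures
    #: (pelvis / cyst / stone / tumor)
    structures: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry helpers


def _world_axes(shape, spacing, origin):
    return [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]


def _centered_origin(shape, spacing):
    return tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))


class _Kidney:
    """Analytic kidney: tilted ellipsoid with a medial pelvis ellipsoid."""

    def __init__(self, side: str, center, semi, tilt_deg: float, cfg: PhantomConfig):
        self.side = side
        self.sign = 1.0 if side == "left" else -1.0
        self.center = np.asarray(center, dtype=float)
        self.semi = np.asarray(semi, dtype=float)
        t = math.radians(tilt_deg)
        # rotation about the AP axis (axis 1): coronal tilt of the long axis
        self.rot = np.array(
            [[math.cos(t), 0.0, math.sin(t)], [0.0, 1.0, 0.0], [-math.sin(t), 0.0, math.cos(t)]]
        )
        pf = np.asarray(cfg.pelvis_semi_frac)
        self.pelvis_semi = pf * self.semi
        self.pelvis_center_local = np.array(
            [-self.sign * cfg.pelvis_offset_frac * self.semi[0], 0.0, 0.0]
        )
        self.spheres: list[tuple[np.ndarray, float, str]] = []  # (world center, radius, kind)

    def _local(self, xs, ys, zs):
        # local coordinates on a separable world grid, shape (nx, ny, nz)
        dx = xs - self.center[0]
        dy = ys - self.center[1]
        dz = zs - self.center[2]
        R = self.rot.T
        lx = (
            R[0, 0] * dx[:, None, None] + R[0, 1] * dy[None, :, None] + R[0, 2] * dz[None, None, :]
        )
        ly = (
            R[1, 0] * dx[:, None, None] + R[1, 1] * dy[None, :, None] + R[1, 2] * dz[None, None, :]
        )
        lz = (
            R[2, 0] * dx[:, None, None] + R[2, 1] * dy[None, :, None] + R[2, 2] * dz[None, None, :]
        )
        return lx, ly, lz

    def masks(self, xs, ys, zs) -> dict[str, np.ndarray]:
        lx, ly, lz = self._local(xs, ys, zs)
        a, b, c = self.semi
        whole = (lx / a) ** 2 + (ly / b) ** 2 + (lz / c) ** 2 <= 1.0
        pa, pb, pc = self.pelvis_semi
        px, py, pz = self.pelvis_center_local
        pelvis = ((lx - px) / pa) ** 2 + ((ly - py) / pb) ** 2 + ((lz - pz) / pc) ** 2 <= 1.0
        pelvis &= whole
        out = {"whole": whole, "pelvis": pelvis}
        for kind in ("cyst", "stone", "tumor"):
            m = np.zeros_like(whole)
            for cen, rad, k in self.spheres:
                if k != kind:
                    continue
                d2 = (
                    (xs[:, None, None] - cen[0]) ** 2
                    + (ys[None, :, None] - cen[1]) ** 2
                    + (zs[None, None, :] - cen[2]) ** 2
                )
                m |= d2 <= rad**2
            out[kind] = m & whole
        out["parenchyma"] = whole & ~pelvis & ~out["cyst"] & ~out["stone"] & ~out["tumor"]
        return out

    def local_to_world(self, u) -> np.ndarray:
        return self.center + self.rot @ np.asarray(u, dtype=float)

    def add_sphere(self, frac_pos, diameter_mm: float, kind: str) -> None:
        """Add a lesion at fractional local coordinates (unit-ball)."""
        u = np.asarray(frac_pos) * self.semi
        self.spheres.append((self.local_to_world(u), diameter_mm / 2.0, kind))


def _sample_in_unit_ball(rng, shrink=0.75):
    while True:
        u = rng.uniform(-1, 1, size=3)
        if np.dot(u, u) <= 1.0:
            return u * shrink


def _build_subject(cfg: PhantomConfig, rng, subject_index: int):
    """Sample anatomy, lesions and status labels for one subject."""
    sides = ["left", "right"]
    single = rng.random() < cfg.single_kidney_prob
    if single:
        sides = [sides[int(rng.integers(2))]]

    donor = rng.random() < cfg.donor_prob
    status: dict[str, str] = {}
    lesions: dict[str, dict] = {s: {"renal_stone_mm": 0.0, "ureter_stone_mm": 0.0} for s in sides}
    if donor:
        status = {s: "normal" for s in sides}
    else:
        sympt = sides[int(rng.integers(len(sides)))]
        status[sympt] = "symptomatic"
        if rng.random() < cfg.ureter_stone_prob:
            lesions[sympt]["ureter_stone_mm"] = float(rng.uniform(2.0, 8.0))
        else:
            lesions[sympt]["renal_stone_mm"] = float(rng.uniform(*cfg.large_stone_diameter_mm))
        for s in sides:
            if s == sympt:
                continue
            status[s] = "asymptomatic"
            if rng.random() < cfg.contralateral_small_stone_prob:
                lesions[s]["renal_stone_mm"] = float(rng.uniform(*cfg.small_stone_diameter_mm))

    kidneys: dict[str, _Kidney] = {}
    for s in sides:
        sign = 1.0 if s == "left" else -1.0
        jit = cfg.kidney_center_jitter_mm
        center = (
            sign * rng.uniform(*cfg.kidney_center_x_mm) + rng.uniform(-jit[0], jit[0]),
            rng.uniform(-jit[1], jit[1]),
            rng.uniform(-jit[2], jit[2]),
        )
        semi = (
            rng.uniform(*cfg.kidney_semi_lr_mm),
            rng.uniform(*cfg.kidney_semi_ap_mm),
            rng.uniform(*cfg.kidney_semi_is_mm),
        )
        k = _Kidney(s, center, semi, rng.uniform(*cfg.kidney_tilt_deg), cfg)
        # cysts anywhere in the parenchyma bulk
        for _ in range(int(rng.integers(cfg.cyst_count_range[0], cfg.cyst_count_range[1] + 1))):
            k.add_sphere(_sample_in_unit_ball(rng), rng.uniform(*cfg.cyst_diameter_mm), "cyst")
        if rng.random() < cfg.tumor_prob:
            k.add_sphere(_sample_in_unit_ball(rng), rng.uniform(*cfg.tumor_diameter_mm), "tumor")
        # renal stones sit at the parenchyma/pelvis interface (calyceal)
        d = lesions.get(s, {}).get("renal_stone_mm", 0.0)
        if d:
            u = np.array([-k.sign * 0.35, rng.uniform(-0.2, 0.2), rng.uniform(-0.35, 0.35)])
            k.add_sphere(u, d, "stone")
        kidneys[s] = k

    contrast = rng.random() < cfg.pelvis_contrast_prob
    target_pid = {}
    for s in sides:
        lo, hi = cfg.pid_range
        p = rng.uniform(lo, hi)
        if status.get(s) == "symptomatic":
            p *= cfg.symptomatic_pid_factor
        target_pid[s] = float(p)

    subject = SubjectRecord(
        subject_id=f"phantom_{subject_index:04d}",
        weight_kg=float(np.clip(rng.normal(68.0, 12.0), 40.0, 110.0)),
        height_cm=float(np.clip(rng.normal(166.0, 9.0), 145.0, 192.0)),
        injected_activity_mbq=cfg.injected_activity_mbq,
        sex="F" if rng.random() < 0.5 else "M",
        age=float(np.clip(rng.normal(53.6, 12.6), 18.0, 85.0)),
        kidney_status=status,
    )
    return kidneys, subject, target_pid, lesions, contrast, single


def generate_phantom(cfg: PhantomConfig, subject_index: int = 0) -> PhantomTruth:
    """Generate one paired CT/SPECT phantom with ground truth.

    Deterministic given ``(cfg.seed, subject_index)``.
    """
    rng = np.random.default_rng([cfg.seed, subject_index])
    kidneys, subject, target_pid, lesions, contrast, single = _build_subject(
        cfg, rng, subject_index
    )

    # ---- CT grid -----------------------------------------------------
    ct_origin = _centered_origin(cfg.ct_shape, cfg.ct_spacing_mm)
    xs, ys, zs = _world_axes(cfg.ct_shape, cfg.ct_spacing_mm, ct_origin)
    ct = np.full(cfg.ct_shape, cfg.hu_air, dtype=np.float32)
    body = (xs[:, None, None] / cfg.body_semi_mm[0]) ** 2 + (
        ys[None, :, None] / cfg.body_semi_mm[1]
    ) ** 2 <= 1.0
    body = np.broadcast_to(body, cfg.ct_shape)

    noise_factor = math.sqrt(
        cfg.hu_noise_ref_voxel_mm3 / float(np.prod(cfg.ct_spacing_mm))
    )

    def paint(region, mean, sd, clip_min=None):
        n = int(region.sum())
        if not n:
            return
        vals = rng.normal(mean, sd * noise_factor, size=n).astype(np.float32)
        if clip_min is not None:
            np.maximum(vals, clip_min, out=vals)
        ct[region] = vals

    paint(body, *cfg.hu_soft_tissue)
    truth = np.zeros(cfg.ct_shape, dtype=bool)
    structures = {
        name: np.zeros(cfg.ct_shape, dtype=bool)
        for name in ("pelvis", "cyst", "stone", "tumor")
    }
    for s, k in kidneys.items():
        m = k.masks(xs, ys, zs)
        for name in structures:
            structures[name] |= m[name]
        paint(m["whole"], *cfg.hu_parenchyma)
        if contrast:
            paint(m["pelvis"], *cfg.hu_pelvis_contrast, clip_min=150.0)
        else:
            paint(m["pelvis"], *cfg.hu_pelvis)
        paint(m["cyst"], *cfg.hu_cyst)
        paint(m["tumor"], *cfg.hu_tumor)
        paint(m["stone"], *cfg.hu_stone, clip_min=300.0)
        # ureter stone: small bright sphere inferior-medial of the kidney
        d = lesions.get(s, {}).get("ureter_stone_mm", 0.0)
        if d:
            cen = k.local_to_world([-k.sign * 1.3 * k.semi[0], 0.0, -0.9 * k.semi[2]])
            d2 = (
                (xs[:, None, None] - cen[0]) ** 2
                + (ys[None, :, None] - cen[1]) ** 2
                + (zs[None, None, :] - cen[2]) ** 2
            )
            paint((d2 <= (d / 2) ** 2) & body, *cfg.hu_stone, clip_min=300.0)
        truth |= m["parenchyma"]

    ct_grid = VolumeGrid(ct, cfg.ct_spacing_mm, ct_origin, unit=Unit.HU)
    truth_mask = LabeledMask.from_binary(ct_grid.with_values(truth.astype(np.uint8)))

    # ---- SPECT grid --------------------------------------------------
    sp_origin = _centered_origin(cfg.spect_shape, cfg.spect_spacing_mm)
    sxs, sys_, szs = _world_axes(cfg.spect_shape, cfg.spect_spacing_mm, sp_origin)
    vox_ml = float(np.prod(cfg.spect_spacing_mm)) / 1000.0
    activity = np.zeros(cfg.spect_shape, dtype=np.float64)
    voi_spect = np.zeros(cfg.spect_shape, dtype=bool)
    for s, k in kidneys.items():
        m = k.masks(sxs, sys_, szs)
        par = m["parenchyma"]
        n = int(par.sum())
        if n == 0:
            continue
        act_mbq = target_pid[s] / 100.0 * cfg.injected_activity_mbq
        activity[par] = act_mbq * 1e6 / (n * vox_ml)  # Bq/ml, uniform uptake
        voi_spect |= par

    sigma_vox = cfg.psf_fwhm_mm * FWHM_TO_SIGMA / np.asarray(cfg.spect_spacing_mm)
    ideal = (
        ndimage.gaussian_filter(activity, sigma=sigma_vox) if cfg.psf_fwhm_mm > 0 else activity
    )

    sp_grid_geom = dict(spacing_mm=cfg.spect_spacing_mm, origin_mm=sp_origin)
    voi_spect_mask = LabeledMask.from_binary(
        VolumeGrid(voi_spect.astype(np.uint8), unit=Unit.BINARY, **sp_grid_geom)
    )
    # ground-truth %ID: VOI content of the ideal reconstructed map
    true_pid = {}
    for s in ("left", "right"):
        sel = voi_spect_mask.side_mask(s)
        true_pid[s] = float(
            100.0 * np.sum(ideal[sel]) * vox_ml * 1e-6 / cfg.injected_activity_mbq
        )

    if cfg.noise_scale > 0:
        # Poisson count noise at the calibrated sensitivity (152.5 cpm/uCi)
        cpm_per_bq = 152.5 / 37000.0
        lam = ideal * vox_ml * cpm_per_bq * cfg.acquisition_minutes * cfg.noise_scale
        counts = rng.poisson(lam).astype(np.float64) / cfg.noise_scale
        spect_vals = counts / (vox_ml * cpm_per_bq * cfg.acquisition_minutes)
    else:
        spect_vals = ideal
    spect = VolumeGrid(
        spect_vals.astype(np.float32), unit=Unit.BQ_PER_ML, **sp_grid_geom
    )

    return PhantomTruth(
        ct=ct_grid,
        spect=spect,
        truth_mask=truth_mask,
        truth_mask_spect=voi_spect_mask,
        true_pid=true_pid,
        target_pid=target_pid,
        subject=subject,
        lesions={
            "per_kidney": lesions,
            "contrast_pelvis": bool(contrast),
            "single_kidney": bool(single),
        },
        structures=structures,
    )


def generate_cohort_truths(cfg: PhantomConfig, n: int) -> list[PhantomTruth]:
    """Generate ``n`` phantoms in memory (subject indices 0..n-1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_phantom(cfg, i) for i in range(n)]


def generate_cohort(cfg: PhantomConfig, n: int, out_dir) -> Path:
    """Write ``n`` phantoms as NIfTI plus a TSV manifest; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        ph = generate_phantom(cfg, i)
        sid = ph.subject.subject_id
        write_volume(ph.ct, out / f"{sid}_ct.nii.gz")
        write_volume(ph.spect, out / f"{sid}_spect.nii.gz")
        write_volume(ph.truth_mask.grid, out / f"{sid}_mask.nii.gz")
        row = {
            "subject_id": sid,
            "weight_kg": round(ph.subject.weight_kg, 4),
            "height_cm": round(ph.subject.height_cm, 4),
            "injected_MBq": cfg.injected_activity_mbq,
            "single_kidney": int(ph.lesions["single_kidney"]),
            "contrast_pelvis": int(ph.lesions["contrast_pelvis"]),
        }
        for s in ("left", "right"):
            row[f"status_{s}"] = ph.subject.kidney_status.get(s, "")
            row[f"true_pid_{s}"] = round(ph.true_pid.get(s, 0.0), 6)
            row[f"target_pid_{s}"] = round(ph.target_pid.get(s, 0.0), 6)
            les = ph.lesions["per_kidney"].get(s, {})
            row[f"renal_stone_mm_{s}"] = round(les.get("renal_stone_mm", 0.0), 3)
            row[f"ureter_stone_mm_{s}"] = round(les.get("ureter_stone_mm", 0.0), 3)
        rows.append(row)
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# manual-VOI emulation


def _slice_sdf(roi2d: np.ndarray) -> np.ndarray:
    """Signed distance of a 2D ROI (positive inside)."""
    if roi2d.any():
        inside = ndimage.distance_transform_edt(roi2d)
        outside = ndimage.distance_transform_edt(~roi2d)
        return (inside - outside).astype(np.float32)
    return np.full(roi2d.shape, -1e3, dtype=np.float32)


def emulate_manual_voi(
    truth: PhantomTruth,
    slice_stride: int = 2,
    max_slices: int = 30,
    jitter_vox: int = 1,
    jitter_prob: float = 0.5,
    start_offset: int = 0,
    seed: int = 0,
) -> LabeledMask:
    """Emulate sparse-slice manual ROI drawing with interpolation.

    True 2D parenchyma ROIs are kept on every ``slice_stride``-th coronal
    slice (at most ``max_slices`` per kidney; the effective stride grows
    if needed), optionally jittered in-plane to mimic drawing error.
    Intervening slices are reconstructed by linear interpolation of
    per-slice signed distance fields, then the result is regularized with
    :func:`renoquant.grids.smooth_mask`.  Structures that only appear on
    unsampled slices (e.g. a small stone) are *not* excluded — the
    characteristic error of the interpolated manual reference.
    """
    if slice_stride < 1:
        raise ValueError("slice_stride must be >= 1")
    rng = np.random.default_rng(seed)
    mask = np.asarray(truth.truth_mask.grid.values) > 0.5
    if not mask.any():
        raise ValueError("truth mask is empty")

    out = np.zeros_like(mask)
    sampled_by_side: dict[str, list[int]] = {}
    for side in truth.truth_mask.sides_present:
        m = truth.truth_mask.side_mask(side)
        js = np.where(m.any(axis=(0, 2)))[0]
        j0, j1 = int(js[0]), int(js[-1])
        stride = slice_stride
        while (j1 - j0) // stride + 1 > max_slices:
            stride += 1
        sampled = list(range(j0 + start_offset, j1 + 1, stride))
        if not sampled:
            sampled = [j0]
        if sampled[-1] != j1:
            sampled.append(j1)
        sampled_by_side[side] = sampled

        sdfs = {}
        for j in sampled:
            roi = m[:, j, :].copy()
            if jitter_vox and roi.any() and rng.random() < jitter_prob:
                # drawing error: shift the ROI by one voxel along one
                # random in-plane axis
                axis = int(rng.integers(2))
                roi = np.roll(roi, int(rng.choice((-jitter_vox, jitter_vox))), axis=axis)
            sdfs[j] = _slice_sdf(roi)
            out[:, j, :] |= roi
        for a, b in zip(sampled[:-1], sampled[1:]):
            for j in range(a + 1, b):
                w = (j - a) / (b - a)
                out[:, j, :] |= ((1.0 - w) * sdfs[a] + w * sdfs[b]) > 0.0
    lab = LabeledMask.from_binary(truth.truth_mask.grid.with_values(out.astype(np.uint8)))
    # mild smoothing only: the SDF interpolation already yields slice
    # continuity, and morphological closing would refill the pelvis notch
    # that the per-slice ROIs deliberately exclude
    lab = smooth_mask(
        lab, sigma_mm=0.5 * min(truth.truth_mask.grid.spacing_mm), closing_radius_vox=0
    )
    lab.grid.meta["sampled_slices"] = sampled_by_side
    return lab
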