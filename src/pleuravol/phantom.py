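"""Synthetic thorax phantom with pleural plaques and exact ground truth.

The phantom models an axial chest section as nested ellipses: an outer body
of soft-tissue attenuation, two air-filled lungs, a thin extrapleural fat
layer lining the inner chest wall, short high-attenuation rib arcs near the
outer chest wall, and pleural plaques as crescents hugging the inner chest
wall (the lung boundary, replacing the fat where present).  The
discriminating image property the segmentation task relies on is the
clinical one: plaques attenuate well above the structures that surround
them at the pleural interface (aerated lung and extrapleural fat), far
above them when calcified, and they sit directly on the lung interface,
next to ribs.

Every voxel of every plaque is rasterized deterministically from the spec, so
ground-truth masks and volumes are exact by construction, and the generator
can feed every downstream stage without any external data.

Noise is additive Gaussian truncated at +/-3 sigma, which keeps per-tissue HU
ranges disjoint enough to assert (e.g. plaque pixels never fall below
``plaque_soft_hu - 3 * noise_sd``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .ct_io import BinaryMask, CTVolume, write_manifest, write_mask, write_volume

__all__ = [
    "PlaqueParams",
    "PhantomSpec",
    "PhantomSpecError",
    "generate_exam",
    "generate_longitudinal_pair",
    "sample_spec",
    "generate_cohort_to_dir",
]


class PhantomSpecError(ValueError):
    """Invalid phantom specification; the message names the offending field."""


@dataclass(frozen=True)
class PlaqueParams:
    """One crescent-shaped pleural plaque.

    The crescent is the shell just outside one lung ellipse, between the lung
    boundary and ``thickness_mm`` further out, restricted to an angular arc.
    Angles are in degrees in the lung-centred frame (0 = lateral +x,
    counter-clockwise with +y pointing caudally on screen).
    """

    center_angle_deg: float
    arc_extent_deg: float
    thickness_mm: float
    slice_start: int
    n_slices: int
    calcified: bool = False
    side: str = "left"  # which lung the plaque abuts


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue attenuation and noise model for one synthetic exam."""

    image_size: int = 512
    pixel_spacing: float = 0.7  # mm
    slice_spacing: float = 1.0  # mm, emulating 1-1.25 mm native slices
    n_slices: int = 300
    body_hu: float = 40.0
    lung_hu: float = -800.0
    fat_hu: float = -100.0
    fat_thickness_mm: float = 3.0
    rib_hu: float = 700.0
    plaque_soft_hu: float = 60.0
    plaque_calc_hu: float = 400.0
    noise_sd: float = 10.0
    plaque_params: tuple[PlaqueParams, ...] = ()
    seed: int = 0
    exam_id: str = "exam"
    participant_id: str = "p0"
    round: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "plaque_params", tuple(self.plaque_params))
        self.validate()

    def validate(self) -> None:
        for name in ("image_size", "pixel_spacing", "slice_spacing", "n_slices"):
            if getattr(self, name) <= 0:
                raise PhantomSpecError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if not self.lung_hu < self.body_hu < self.rib_hu:
            raise PhantomSpecError(
                "require lung_hu < body_hu < rib_hu, got "
                f"lung_hu={self.lung_hu}, body_hu={self.body_hu}, rib_hu={self.rib_hu}"
            )
        if not self.lung_hu < self.fat_hu < self.body_hu:
            raise PhantomSpecError(
                "require lung_hu < fat_hu < body_hu, got "
                f"lung_hu={self.lung_hu}, fat_hu={self.fat_hu}, body_hu={self.body_hu}"
            )
        if self.fat_thickness_mm < 0:
            raise PhantomSpecError(f"fat_thickness_mm must be >= 0, got {self.fat_thickness_mm}")
        if not self.plaque_soft_hu < 100 <= self.plaque_calc_hu:
            raise PhantomSpecError(
                "require plaque_soft_hu < 100 <= plaque_calc_hu (calcification threshold), got "
                f"plaque_soft_hu={self.plaque_soft_hu}, plaque_calc_hu={self.plaque_calc_hu}"
            )
        if self.noise_sd < 0:
            raise PhantomSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for i, p in enumerate(self.plaque_params):
            if p.thickness_mm <= 0:
                raise PhantomSpecError(f"plaque_params[{i}].thickness_mm must be > 0, got {p.thickness_mm}")
            if p.arc_extent_deg <= 0:
                raise PhantomSpecError(f"plaque_params[{i}].arc_extent_deg must be > 0, got {p.arc_extent_deg}")
            if p.n_slices <= 0:
                raise PhantomSpecError(f"plaque_params[{i}].n_slices must be > 0, got {p.n_slices}")
            if p.slice_start < 0 or p.slice_start >= self.n_slices:
                raise PhantomSpecError(
                    f"plaque_params[{i}].slice_start out of [0, n_slices), got {p.slice_start}"
                )
            if p.side not in ("left", "right"):
                raise PhantomSpecError(f"plaque_params[{i}].side must be 'left' or 'right', got {p.side!r}")

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "PhantomSpec":
        """Desk-scale preset: a miniature 64 mm thorax at 64x64, 1 mm voxels.

        A miniature (rather than down-sampled) thorax keeps millimetre-scale plaques
        spatially resolved at this matrix size.
        """
        defaults = dict(image_size=64, pixel_spacing=1.0, slice_spacing=1.0, n_slices=20, seed=seed)
        defaults.update(overrides)
        return cls(**defaults)


# --- geometry ---------------------------------------------------------------


def _thorax_geometry(size: int):
    """Body/lung ellipse parameters in pixel units for a given matrix size."""
    cx = cy = (size - 1) / 2.0
    body = (cx, cy, 0.45 * size, 0.37 * size)
    lungs = {
        "left": (cx - 0.21 * size, cy, 0.155 * size, 0.26 * size),
        "right": (cx + 0.21 * size, cy, 0.155 * size, 0.26 * size),
    }
    return body, lungs


def _ellipse_mask(size: int, cx: float, cy: float, sa: float, sb: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / sa) ** 2 + ((yy - cy) / sb) ** 2 <= 1.0


def _shell_arc_mask(
    size: int,
    lung: tuple[float, float, float, float],
    center_angle_deg: float,
    arc_extent_deg: float,
    thickness_px: float,
) -> np.ndarray:
    """Pixels in the shell just outside a lung ellipse, within an angular arc."""
    cx, cy, sa, sb = lung
    yy, xx = np.mgrid[0:size, 0:size]
    u = (xx - cx) / sa
    v = (yy - cy) / sb
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    # local ellipse radius (px) along direction theta
    r_ell = sa * sb / np.hypot(sb * np.cos(theta), sa * np.sin(theta))
    r_px = rho * r_ell
    d_ang = np.angle(np.exp(1j * (theta - np.deg2rad(center_angle_deg))))
    in_arc = np.abs(d_ang) <= np.deg2rad(arc_extent_deg) / 2.0
    return (r_px >= r_ell) & (r_px <= r_ell + thickness_px) & in_arc


def _rib_mask(size: int, body: tuple[float, float, float, float]) -> np.ndarray:
    """Short high-HU arcs near the outer chest wall, mimicking rib sections."""
    cx, cy, sa, sb = body
    yy, xx = np.mgrid[0:size, 0:size]
    u = (xx - cx) / sa
    v = (yy - cy) / sb
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    shell = (rho >= 0.90) & (rho <= 0.96)
    ribs = np.zeros((size, size), dtype=bool)
    for ang in np.deg2rad(np.arange(15, 360, 45)):
        d = np.angle(np.exp(1j * (theta - ang)))
        ribs |= shell & (np.abs(d) <= np.deg2rad(9))
    return ribs


# --- generation -------------------------------------------------------------


def _rasterize_slice(spec: PhantomSpec, z: int):
    """Noise-free HU image plus plaque/calcified boolean masks for slice z."""
    size = spec.image_size
    body, lungs = _thorax_geometry(size)
    hu = np.full((size, size), -1000.0, dtype=np.float64)
    body_m = _ellipse_mask(size, *body)
    hu[body_m] = spec.body_hu
    lung_m = {s: _ellipse_mask(size, *lungs[s]) for s in lungs}
    if spec.fat_thickness_mm > 0:
        # extrapleural fat lining the inner chest wall, replaced by plaque below
        fat_px = spec.fat_thickness_mm / spec.pixel_spacing
        for s in lungs:
            fat = _shell_arc_mask(size, lungs[s], 0.0, 360.0, fat_px)
            hu[fat & body_m] = spec.fat_hu
    for s in lungs:
        hu[lung_m[s]] = spec.lung_hu
    hu[_rib_mask(size, body)] = spec.rib_hu

    pp = np.zeros((size, size), dtype=bool)
    calc = np.zeros((size, size), dtype=bool)
    inside_body = _ellipse_mask(size, body[0], body[1], 0.985 * body[2], 0.985 * body[3])
    for p in spec.plaque_params:
        if not (p.slice_start <= z < p.slice_start + p.n_slices):
            continue
        t_px = p.thickness_mm / spec.pixel_spacing
        m = _shell_arc_mask(size, lungs[p.side], p.center_angle_deg, p.arc_extent_deg, t_px)
        m &= inside_body & ~lung_m[p.side]
        pp |= m
        hu[m] = spec.plaque_calc_hu if p.calcified else spec.plaque_soft_hu
        if p.calcified:
            calc |= m
    return hu, pp, calc


def generate_exam(spec: PhantomSpec) -> tuple[CTVolume, BinaryMask, BinaryMask]:
    """Generate one exam: HU volume plus exact plaque and calcified masks.

    Deterministic given ``spec.seed``; the calcified mask is a subset of the
    plaque mask by construction.
    """
    spec.validate()
    size, n = spec.image_size, spec.n_slices
    hu = np.empty((n, size, size), dtype=np.float32)
    pp = np.zeros((n, size, size), dtype=np.uint8)
    calc = np.zeros((n, size, size), dtype=np.uint8)
    # plaque axial ranges rarely change slice to slice; cache rasterized slices
    cache: dict[tuple, tuple] = {}
    for z in range(n):
        key = tuple(
            (i, True) for i, p in enumerate(spec.plaque_params) if p.slice_start <= z < p.slice_start + p.n_slices
        )
        if key not in cache:
            cache[key] = _rasterize_slice(spec, z)
        hz, pz, cz = cache[key]
        hu[z], pp[z], calc[z] = hz, pz, cz
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        noise = rng.standard_normal(hu.shape).astype(np.float32)
        np.clip(noise, -3.0, 3.0, out=noise)
        hu += spec.noise_sd * noise
    ids = dict(exam_id=spec.exam_id, participant_id=spec.participant_id, round=spec.round)
    vol = CTVolume(hu, (spec.slice_spacing, spec.pixel_spacing, spec.pixel_spacing), **ids)
    return vol, BinaryMask(pp, source="native"), BinaryMask(calc, source="native")


def _gt_pixel_count(spec: PhantomSpec) -> int:
    """Exact plaque-mask voxel count without materialising the volume."""
    counts: dict[tuple, list[int]] = {}
    for z in range(spec.n_slices):
        key = tuple(
            i for i, p in enumerate(spec.plaque_params) if p.slice_start <= z < p.slice_start + p.n_slices
        )
        if key in counts:
            counts[key][0] += 1
        else:
            counts[key] = [1, z]
    total = 0
    for key, (mult, z_repr) in counts.items():
        if not key:
            continue
        _, pp, _ = _rasterize_slice(spec, z_repr)
        total += mult * int(pp.sum())
    return total


def _scaled_spec(spec: PhantomSpec, s: float) -> PhantomSpec:
    """Grow every plaque along the pleural surface by the factor ``s``.

    Growth extends each crescent tangentially (arc extent) and
    cranio-caudally (axial slice span, centred on the original span);
    thickness is left unchanged, modelling plaques spreading over the
    pleura.  Sub-voxel thickening would not be resolvable at phantom
    resolution anyway, whereas surface spread is measured exactly by
    voxel counting.
    """
    plaques = []
    for p in spec.plaque_params:
        n_new = int(np.clip(round(p.n_slices * s), p.n_slices, spec.n_slices))
        center = p.slice_start + p.n_slices / 2.0
        start = int(np.clip(round(center - n_new / 2.0), 0, spec.n_slices - n_new))
        plaques.append(
            dataclasses.replace(
                p,
                arc_extent_deg=min(p.arc_extent_deg * s, 358.0),
                n_slices=n_new,
                slice_start=start,
            )
        )
    return dataclasses.replace(spec, plaque_params=tuple(plaques))


def generate_longitudinal_pair(spec: PhantomSpec, growth_factor: float):
    """Round-2 and round-3 exams for one participant with plaque growth.

    Returns two ``(CTVolume, pp_mask, calc_mask)`` triples sharing the
    participant identifier.  Round-3 plaques are grown in-plane (thickness
    and arc extent); because rasterization, plaque overlap and chest-wall
    clipping make the volume a nonlinear function of the scale factor, the
    factor is calibrated by bisection on exact rasterized pixel counts so the
    ground-truth volume ratio matches ``growth_factor`` up to rasterization
    granularity.
    """
    if growth_factor < 1:
        raise ValueError(f"growth_factor must be >= 1, got {growth_factor}")
    spec2 = dataclasses.replace(spec, round=2, exam_id=spec.exam_id + "_r2")
    n2 = _gt_pixel_count(spec2)
    target = growth_factor * n2
    if n2 == 0 or growth_factor == 1.0:
        s = 1.0
    else:
        lo, hi = 1.0, 1.05
        while _gt_pixel_count(_scaled_spec(spec2, hi)) < target and hi < 4.0:
            hi *= 1.3
        for _ in range(24):
            mid = 0.5 * (lo + hi)
            if _gt_pixel_count(_scaled_spec(spec2, mid)) < target:
                lo = mid
            else:
                hi = mid
        s = 0.5 * (lo + hi)
    spec3 = dataclasses.replace(
        _scaled_spec(spec2, s),
        round=3,
        seed=spec.seed + 1_000_003,
        exam_id=spec.exam_id + "_r3",
    )
    return generate_exam(spec2), generate_exam(spec3)


# --- cohort sampling --------------------------------------------------------


def sample_spec(
    rng: np.random.Generator,
    participant_id: str,
    exam_id: str | None = None,
    image_size: int = 64,
    pixel_spacing: float = 1.0,
    n_slices: int = 20,
    n_plaques: tuple[int, int] = (1, 5),
    thickness_mm: tuple[float, float] = (2.5, 8.0),
    arc_deg: tuple[float, float] = (40.0, 200.0),
    calc_prob: float = 0.5,
) -> PhantomSpec:
    """Draw a random desk-scale exam spec for cohort-style experiments.

    Plaque count, arc position/extent, thickness, axial span, laterality and
    calcification are sampled; the resulting ground-truth volumes spread over
    roughly an order of magnitude, mimicking the clinical spread of plaque
    burden across participants.
    """
    k = int(rng.integers(n_plaques[0], n_plaques[1] + 1))
    plaques = []
    for _ in range(k):
        n_ax = int(rng.integers(max(4, n_slices // 4), n_slices + 1))
        start = int(rng.integers(0, n_slices - n_ax + 1))
        plaques.append(
            PlaqueParams(
                center_angle_deg=float(rng.uniform(0, 360)),
                arc_extent_deg=float(rng.uniform(*arc_deg)),
                thickness_mm=float(rng.uniform(*thickness_mm)),
                slice_start=start,
                n_slices=n_ax,
                calcified=bool(rng.random() < calc_prob),
                side=str(rng.choice(["left", "right"])),
            )
        )
    return PhantomSpec(
        image_size=image_size,
        pixel_spacing=pixel_spacing,
        slice_spacing=1.0,
        n_slices=n_slices,
        plaque_params=tuple(plaques),
        seed=int(rng.integers(0, 2**31 - 1)),
        exam_id=exam_id or f"{participant_id}_r2",
        participant_id=participant_id,
        round=2,
    )


def generate_cohort_to_dir(specs: Iterable[PhantomSpec], out_dir: str | Path) -> Path:
    """Write exams as NIfTI plus a manifest CSV with ground-truth mL volumes."""
    from .mip import native_mask_volume_ml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in specs:
        vol, pp, calc = generate_exam(spec)
        stem = spec.exam_id
        write_volume(vol, out_dir / f"{stem}_ct.nii.gz")
        write_mask(pp, vol.spacing, out_dir / f"{stem}_pp.nii.gz")
        write_mask(calc, vol.spacing, out_dir / f"{stem}_calc.nii.gz")
        rows.append(
            dict(
                exam_id=spec.exam_id,
                participant_id=spec.participant_id,
                round=spec.round,
                seed=spec.seed,
                path=f"{stem}_ct.nii.gz",
                gt_pp_ml=native_mask_volume_ml(pp, vol),
                gt_calc_ml=native_mask_volume_ml(calc, vol),
            )
        )
    return write_manifest(rows, out_dir / "manifest.csv")
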