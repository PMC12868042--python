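"""Synthetic piecewise-constant abdominal phantoms and patient-like degradations.

This module is the desk-scale stand-in for a licensed anthropomorphic phantom
library: it builds paired, perfectly co-registered CT/MRI volumes from one
analytic organ label map (body ellipse, lungs, liver, spine and ribs, aorta,
bowel loops), and produces "patient-like" counterparts by adding correlated
noise, a smooth multiplicative bias field and per-organ texture. The rendered
phantoms are noise-free with a discrete intensity histogram (at most one value
per tissue label) — exactly the property that makes raw digital phantoms
unrealistic and motivates style transfer toward the patient domain.

CT numbers are derived from linear attenuation coefficients at 120 keV via
``HU = 1000 (mu - mu_water) / mu_water``; MRI intensities come from a
per-tissue lookup emulating T1-weighted gradient-echo (VIBE-like) contrast.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .volumes import Modality, LabelVolume, TissueTable, Volume

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "default_tissue_table",
    "make_labels",
    "mu_to_hu",
    "hu_to_mu",
    "render_ct",
    "render_mri",
    "degrade",
    "ORGAN_LABELS",
]

ORGAN_LABELS = {
    "body": 1,
    "lung_left": 2,
    "lung_right": 3,
    "liver": 4,
    "bone": 5,
    "aorta": 6,
    "bowel": 7,
}

#: Default mu_water at 120 keV (1/cm); only the ratio mu/mu_water matters.
MU_WATER_120KEV = 0.1615


def _mu_from_hu(hu: float, mu_water: float = MU_WATER_120KEV) -> float:
    return mu_water * (1.0 + hu / 1000.0)


def default_tissue_table() -> TissueTable:
    """Tissue lookup with textbook-plausible 120 keV attenuation and T1w levels."""
    rows = pd.DataFrame(
        [
            (0, "air", 0.0, 0.0),
            (1, "soft_tissue", _mu_from_hu(40.0), 200.0),
            (2, "lung", _mu_from_hu(-700.0), 40.0),
            (3, "lung", _mu_from_hu(-700.0), 40.0),
            (4, "liver", _mu_from_hu(55.0), 240.0),
            (5, "bone", _mu_from_hu(700.0), 100.0),
            (6, "blood", _mu_from_hu(45.0), 300.0),
            (7, "bowel", _mu_from_hu(-30.0), 160.0),
        ],
        columns=list(TissueTable.COLUMNS),
    )
    return TissueTable(rows, mu_water=MU_WATER_120KEV)


@dataclasses.dataclass
class PhantomSpec:
    """Parametric abdominal geometry on a regular grid.

    ``shape`` is (slices, rows, cols); organ positions and radii are fractions
    of the grid so the same spec scales. ``jitter`` randomly perturbs organ
    centres/radii by up to that fraction (seeded, deterministic).
    """

    shape: tuple[int, int, int] = (20, 160, 160)
    spacing_mm: tuple[float, float, float] = (2.0, 1.0625, 1.0625)
    organs: tuple[str, ...] = tuple(ORGAN_LABELS)
    body_halfaxes: tuple[float, float] = (0.40, 0.46)
    jitter: float = 0.03
    seed: int = 0


@dataclasses.dataclass
class DegradationSpec:
    """Patient-like degradation amplitudes (all >= 0).

    noise_sigma is in HU for CT / a.u. for MRI; ``noise_corr`` is the Gaussian
    correlation length of the noise in voxels (0 = white); the bias field is a
    smooth multiplicative modulation of amplitude ``bias_amplitude`` applied to
    the offset from the background level; ``texture_amplitude`` adds a smooth
    intra-organ modulation.
    """

    noise_sigma: float = 20.0
    noise_corr: float = 1.0
    bias_amplitude: float = 0.05
    bias_smoothness: float = 24.0
    texture_amplitude: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


class SpecError(ValueError):
    pass


def _ellipsoid(shape, center, halfaxes) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    cz, cy, cx = center
    az, ay, ax = halfaxes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _tube(shape, center_rc, radius_rc) -> np.ndarray:
    """Axis-aligned elliptical cylinder running through every slice."""
    yy, xx = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    cy, cx = center_rc
    ry, rx = radius_rc
    disk = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return np.broadcast_to(disk, shape).copy()


def make_labels(spec: PhantomSpec) -> LabelVolume:
    """Deterministic (per seed) analytic organ label map.

    Later organs overwrite earlier ones where they overlap; every declared
    organ is checked to occupy at least one voxel strictly inside the body.
    """
    rng = np.random.default_rng(spec.seed)
    ns, nr, nc = spec.shape

    def jit(x: float) -> float:
        return x * (1.0 + rng.uniform(-spec.jitter, spec.jitter))

    labels = np.zeros(spec.shape, dtype=np.int32)
    body_r, body_c = spec.body_halfaxes[0] * nr, spec.body_halfaxes[1] * nc
    body = _tube(spec.shape, (nr / 2, nc / 2), (jit(body_r), jit(body_c)))
    labels[body] = ORGAN_LABELS["body"]

    def place(name: str, mask: np.ndarray) -> None:
        if name not in spec.organs:
            return
        inside = mask & body
        if not inside.any():
            raise SpecError(f"organ {name!r} fell outside the body")
        if (mask & ~body).mean() > 0.5 * mask.mean():
            raise SpecError(f"organ {name!r} mostly overlaps the body boundary")
        labels[inside] = ORGAN_LABELS[name]

    top = ns * 0.30
    place("lung_left", _ellipsoid(spec.shape, (top, jit(0.38 * nr), jit(0.30 * nc)),
                                  (ns * 0.28, 0.16 * nr, 0.12 * nc)))
    place("lung_right", _ellipsoid(spec.shape, (top, jit(0.38 * nr), jit(0.70 * nc)),
                                   (ns * 0.28, 0.16 * nr, 0.12 * nc)))
    place("liver", _ellipsoid(spec.shape, (ns * 0.62, jit(0.52 * nr), jit(0.62 * nc)),
                              (ns * 0.34, jit(0.20 * nr), jit(0.22 * nc))))
    if "bone" in spec.organs:
        spine = _tube(spec.shape, (jit(0.78 * nr), nc / 2), (0.07 * nr, 0.06 * nc))
        rib_l = _tube(spec.shape, (0.50 * nr, 0.12 * nc), (0.30 * nr, 0.025 * nc))
        rib_r = _tube(spec.shape, (0.50 * nr, 0.88 * nc), (0.30 * nr, 0.025 * nc))
        bones = (spine | rib_l | rib_r) & body
        if not bones.any():
            raise SpecError("organ 'bone' fell outside the body")
        labels[bones] = ORGAN_LABELS["bone"]
    place("aorta", _tube(spec.shape, (jit(0.64 * nr), jit(0.46 * nc)),
                         (0.035 * nr, 0.035 * nc)))
    if "bowel" in spec.organs:
        loops = np.zeros(spec.shape, dtype=bool)
        for _ in range(4):
            cr, cc = rng.uniform(0.35, 0.60) * nr, rng.uniform(0.30, 0.55) * nc
            rr = rng.uniform(0.04, 0.07)
            loops |= _ellipsoid(spec.shape, (rng.uniform(0.4, 0.8) * ns, cr, cc),
                                (ns * 0.25, rr * nr, rr * nc))
        place("bowel", loops)

    return LabelVolume(labels, spec.spacing_mm)


def mu_to_hu(mu: float | np.ndarray, mu_water: float = MU_WATER_120KEV):
    """CT number from linear attenuation: HU = 1000 (mu - mu_water)/mu_water."""
    if mu_water <= 0:
        raise ValueError("mu_water must be > 0")
    return 1000.0 * (np.asarray(mu, dtype=np.float64) - mu_water) / mu_water


def hu_to_mu(hu: float | np.ndarray, mu_water: float = MU_WATER_120KEV):
    if mu_water <= 0:
        raise ValueError("mu_water must be > 0")
    return mu_water * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0)


def _render(labels: LabelVolume, values: dict[int, float], background: float,
            modality: Modality, intensity_range) -> Volume:
    present = labels.present_labels()
    unknown = [int(l) for l in present if l != 0 and l not in values]
    if unknown:
        raise KeyError(f"labels not in tissue table: {unknown}")
    out = np.full(labels.shape, background, dtype=np.float32)
    for lab in present:
        if lab == 0:
            continue
        out[labels.labels == lab] = values[int(lab)]
    return Volume(out, labels.spacing_mm, modality=modality, intensity_range=intensity_range)


def render_ct(labels: LabelVolume, tissues: TissueTable) -> Volume:
    """Piecewise-constant CT volume: per-label HU from mu at 120 keV, air outside."""
    values = {
        int(row.label): float(mu_to_hu(row.mu_120kev, tissues.mu_water))
        for row in tissues.df.itertuples()
    }
    from .volumes import CT_RANGE

    return _render(labels, values, -1000.0, Modality.CT, CT_RANGE)


def render_mri(labels: LabelVolume, tissues: TissueTable) -> Volume:
    """Piecewise-constant MRI volume from the per-tissue intensity column."""
    values = {int(r.label): float(r.mri_intensity) for r in tissues.df.itertuples()}
    return _render(labels, values, 0.0, Modality.MRI, None)


def _smooth_field(shape, smoothness: float, rng) -> np.ndarray:
    field = rng.standard_normal(shape)
    field = ndi.gaussian_filter(field, sigma=smoothness)
    sd = field.std()
    return field / sd if sd > 0 else field


def degrade(vol: Volume, spec: DegradationSpec, seed: int) -> Volume:
    """Create a patient-like counterpart of a noise-free phantom volume.

    Order: multiplicative bias on the offset from the background level, smooth
    texture, then additive correlated Gaussian noise rescaled to noise_sigma.
    Deterministic per seed. An all-zero spec is the identity.
    """
    rng = np.random.default_rng(seed)
    out = vol.data.astype(np.float64).copy()
    background = -1000.0 if vol.modality == Modality.CT else 0.0

    if spec.bias_amplitude > 0:
        bias = _smooth_field(vol.shape, spec.bias_smoothness, rng)
        out = background + (out - background) * (1.0 + spec.bias_amplitude * bias)

    if spec.texture_amplitude > 0:
        tex = _smooth_field(vol.shape, max(spec.bias_smoothness / 8.0, 1.0), rng)
        out = out + spec.texture_amplitude * tex

    if spec.noise_sigma > 0:
        noise = rng.standard_normal(vol.shape)
        if spec.noise_corr > 0:
            noise = ndi.gaussian_filter(noise, sigma=spec.noise_corr)
            noise /= noise.std()
        out = out + spec.noise_sigma * noise

    return vol.with_data(out.astype(np.float32))
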