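"""Synthetic paired FLAIR / diffusion-scalar phantoms.

Each phantom subject is a 3-D "head": concentric smooth tissue shells
(background, CSF-like rim, GM-like band, WM-like core) whose elliptical
cross-section shrinks toward the top and bottom slices, plus randomly
seeded curvilinear "tracts" of distinct intensity inside the WM core.
The FA-like / MD-like target volumes are deterministic intensity maps of
the source volume (plus optional truncated Gaussian noise inside tissue),
so a sufficiently expressive regressor can drive the translation error to
zero on noiseless phantoms — which is what makes the phantoms usable as
ground-truthed stand-ins for clinical cohorts in training tests.

Intensity conventions follow brain-extracted MRI: background is exactly
zero in the raw volumes; intensity normalization to [-1, 1] is a separate
preprocessing step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "PhantomParams",
    "PairedSubject",
    "generate_phantom_subject",
    "generate_cohort",
    "tissue_fraction",
    "mid_volume_slices",
    "apply_mapping",
    "write_cohort",
    "load_manifest",
    "load_subject",
    "MAPPINGS",
]

# Raw class intensity bands of the FLAIR-like source volume (CSF suppressed,
# GM brightest, tracts distinct from surrounding WM).  Bands do not overlap,
# so a voxelwise intensity map is well defined.
_CLASS_BANDS = {
    "csf": (0.06, 0.18),
    "wm": (0.40, 0.54),
    "tract": (0.58, 0.66),
    "gm": (0.70, 0.82),
}

# Deterministic FLAIR -> scalar intensity maps (piecewise linear in source
# intensity).  Band order is CSF < WM < tract < GM: CSF suppressed and GM
# brightest as in FLAIR, with tracts a distinct band between WM and GM.
# "fa-like" enhances tracts and is monotone increasing across the WM band;
# "md-like" enhances the fluid class and is inverted there.  Placing the
# tract band adjacent to (not inside) the WM intensity range keeps the
# FA map's within-WM slope aligned with its local trend, so a smooth
# regressor can recover per-subject WM levels instead of averaging across
# a sawtooth.
MAPPINGS: dict[str, tuple[np.ndarray, np.ndarray]] = {
    "fa-like": (
        np.array([0.00, 0.06, 0.18, 0.40, 0.54, 0.58, 0.66, 0.70, 0.82, 1.00]),
        np.array([0.02, 0.04, 0.06, 0.55, 0.72, 0.92, 0.97, 0.42, 0.24, 0.22]),
    ),
    "md-like": (
        np.array([0.00, 0.06, 0.18, 0.40, 0.54, 0.58, 0.66, 0.70, 0.82, 1.00]),
        np.array([0.97, 0.95, 0.84, 0.30, 0.22, 0.16, 0.15, 0.48, 0.34, 0.32]),
    ),
}


@dataclass
class PhantomParams:
    """Cohort-level phantom configuration.

    ``tissue_fraction_range`` bounds the per-slice tissue fraction
    (nonzero voxels / total voxels) of mid-volume slices; ``noise_sd`` is
    the standard deviation of additive target noise inside tissue;
    ``tract_density`` is the expected number of tracts per subject.
    """

    grid_shape: tuple[int, int, int] = (256, 256, 55)
    n_subjects: int = 10
    tissue_fraction_range: tuple[float, float] = (0.2, 0.6)
    noise_sd: float = 0.02
    mapping_id: str = "fa-like"
    tract_density: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be three positive integers")
        lo, hi = self.tissue_fraction_range
        if not (0 < lo < hi < 1):
            raise ConfigurationError("tissue_fraction_range must be ordered within (0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.mapping_id not in MAPPINGS:
            raise ConfigurationError(
                f"unknown mapping_id {self.mapping_id!r}; available: {sorted(MAPPINGS)}"
            )
        if self.tract_density < 0:
            raise ConfigurationError("tract_density must be nonnegative")


@dataclass
class PairedSubject:
    """One subject's co-registered source volume, targets and region masks."""

    subject_id: str
    source_volume: np.ndarray  # (rows, cols, slices), FLAIR-like
    target_fa: np.ndarray
    target_md: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    slice_spacing: tuple[float, float, float] = (0.9375, 0.9375, 3.0)
    meta: dict = field(default_factory=dict)


def tissue_fraction(slc: np.ndarray) -> float:
    """Nonzero pixels / total pixels of one slice (brain-extracted convention)."""
    slc = np.asarray(slc)
    return float(np.count_nonzero(slc) / slc.size)


def mid_volume_slices(n_slices: int) -> range:
    """Indices of the central third of the volume."""
    lo = n_slices // 3
    hi = n_slices - n_slices // 3
    return range(lo, max(hi, lo + 1))


def apply_mapping(source: np.ndarray, mapping_id: str) -> np.ndarray:
    """Apply the deterministic source->scalar intensity map voxelwise.

    Background (exact zeros) stays zero, as in brain-extracted targets.
    """
    if mapping_id not in MAPPINGS:
        raise ConfigurationError(f"unknown mapping_id {mapping_id!r}")
    knots_x, knots_y = MAPPINGS[mapping_id]
    out = np.interp(np.asarray(source, dtype=float), knots_x, knots_y)
    out[np.asarray(source) == 0] = 0.0
    return out


def _radial_map(m: int, n: int, center: tuple[float, float], axes: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:m, 0:n]
    a, b = axes
    return np.sqrt(((yy - center[0]) / a) ** 2 + ((xx - center[1]) / b) ** 2)


def _rasterize_classes(
    m: int, n: int, s: int, center, axes, z_center, z_half
) -> np.ndarray:
    """Per-voxel class labels: 0 background, 1 CSF, 2 GM, 3 WM.

    The CSF-like class is a thin film (1-2 voxels) at the brain surface,
    as in brain-extracted FLAIR where subarachnoid CSF forms a narrow rim;
    GM and WM fill the interior as concentric shells.
    """
    from scipy.ndimage import binary_dilation

    # ~1 mm subarachnoid film: one voxel at the reference 256-grid resolution
    film_width = max(1, round(min(m, n) / 256))
    labels = np.zeros((m, n, s), dtype=np.uint8)
    for z in range(s):
        scale_sq = 1.0 - 0.5 * ((z - z_center) / z_half) ** 2
        if scale_sq <= 0.05:
            continue
        scale = np.sqrt(scale_sq)
        r = _radial_map(m, n, center, (axes[0] * scale, axes[1] * scale))
        sl = np.zeros((m, n), dtype=np.uint8)
        interior = r < 1.0
        sl[interior] = 2  # GM band
        sl[r < 0.62] = 3  # WM core
        film = interior & binary_dilation(~interior, iterations=film_width)
        sl[film] = 1  # CSF film
        labels[:, :, z] = sl
    return labels


def _draw_tracts(
    labels: np.ndarray, rng: np.random.Generator, n_tracts: int, center, axes
) -> np.ndarray:
    """Curvilinear high-FA structures inside the WM core (boolean volume)."""
    m, n, s = labels.shape
    tract = np.zeros(labels.shape, dtype=bool)
    if n_tracts == 0:
        return tract
    radius = max(1, round(min(m, n) / 48))
    yy, xx = np.mgrid[0:m, 0:n]
    for _ in range(n_tracts):
        # quadratic Bezier with control points inside the WM core
        pts = rng.uniform(-0.45, 0.45, size=(3, 2))
        z0 = rng.integers(0, max(1, s - 1))
        span = int(rng.integers(max(1, s // 3), s)) if s > 1 else 1
        z1 = min(s, z0 + span)
        drift = rng.uniform(-0.1, 0.1, size=2)
        t = np.linspace(0.0, 1.0, 4 * max(m, n))
        for z in range(z0, z1):
            frac = (z - z0) / max(1, z1 - z0)
            p = pts + drift * frac
            curve = (
                (1 - t[:, None]) ** 2 * p[0]
                + 2 * (1 - t[:, None]) * t[:, None] * p[1]
                + t[:, None] ** 2 * p[2]
            )
            cy = center[0] + curve[:, 0] * axes[0]
            cx = center[1] + curve[:, 1] * axes[1]
            sl = np.zeros((m, n), dtype=bool)
            iy = np.clip(np.round(cy).astype(int), 0, m - 1)
            ix = np.clip(np.round(cx).astype(int), 0, n - 1)
            sl[iy, ix] = True
            if radius > 0:
                from scipy.ndimage import binary_dilation

                sl = binary_dilation(sl, iterations=radius)
            tract[:, :, z] |= sl & (labels[:, :, z] == 3)
    return tract


def generate_phantom_subject(params: PhantomParams, subject_index: int) -> PairedSubject:
    """Generate one phantom subject, deterministic in (seed, subject_index)."""
    if subject_index >= params.n_subjects:
        raise ConfigurationError("subject_index must be < n_subjects")
    m, n, s = (int(v) for v in params.grid_shape)
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed) % 2**31, subject_index]))

    lo, hi = params.tissue_fraction_range
    width = hi - lo
    f_target = rng.uniform(lo + 0.25 * width, lo + 0.75 * width)
    aspect = rng.uniform(0.85, 1.0)
    center = (m / 2 + rng.uniform(-0.03, 0.03) * m, n / 2 + rng.uniform(-0.03, 0.03) * n)
    a = np.sqrt(f_target * m * n / (np.pi * aspect))
    axes = (min(a, 0.49 * m), min(a * aspect, 0.49 * n))
    z_center = (s - 1) / 2
    z_half = max(s / 2, 1.0) * 1.01

    labels = _rasterize_classes(m, n, s, center, axes, z_center, z_half)
    # one corrective rescale against rasterization error on the central slice
    achieved = tissue_fraction(labels[:, :, int(round(z_center))])
    if achieved > 0:
        corr = np.sqrt(f_target / achieved)
        axes = (min(axes[0] * corr, 0.49 * m), min(axes[1] * corr, 0.49 * n))
        labels = _rasterize_classes(m, n, s, center, axes, z_center, z_half)

    n_tracts = int(round(params.tract_density))
    tracts = _draw_tracts(labels, rng, n_tracts, center, axes)

    # Smooth intra-class modulation keeps bands non-overlapping.  Each class
    # occupies a per-subject sub-band anchored at the band top: the subject's
    # "width" draw moves the class median without moving the volume maximum,
    # so per-volume min-max normalization stays consistent across subjects
    # while the cohort shows real between-subject variation in regional
    # median intensities (as clinical cohorts do).
    mod = rng.uniform(0.0, 1.0)
    widths = {cls: rng.uniform(0.35, 1.0) for cls in ("csf", "gm", "wm", "tract")}
    yy, xx = np.mgrid[0:m, 0:n]
    texture = 0.5 + 0.5 * np.sin(2 * np.pi * (yy / m + mod)) * np.cos(2 * np.pi * xx / n)

    def band_field(cls):
        lo, hi = _CLASS_BANDS[cls]
        return hi - widths[cls] * (hi - lo) * (1.0 - texture)

    source = np.zeros((m, n, s), dtype=float)
    for z in range(s):
        sl = np.zeros((m, n), dtype=float)
        lab = labels[:, :, z]
        sl[lab == 1] = band_field("csf")[lab == 1]
        sl[lab == 2] = band_field("gm")[lab == 2]
        sl[lab == 3] = band_field("wm")[lab == 3]
        tr = tracts[:, :, z]
        sl[tr] = band_field("tract")[tr]
        source[:, :, z] = sl

    tissue = source > 0
    target_fa = apply_mapping(source, "fa-like")
    target_md = apply_mapping(source, "md-like")
    if params.noise_sd > 0:
        for target in (target_fa, target_md):
            noise = rng.normal(0.0, params.noise_sd, target.shape)
            target[tissue] = np.clip(target[tissue] + noise[tissue], 0.005, 1.0)

    wm_mask = ((labels == 3) | tracts).astype(np.uint8)
    gm_mask = (labels == 2).astype(np.uint8)
    return PairedSubject(
        subject_id=f"phantom-{subject_index:03d}",
        source_volume=source,
        target_fa=target_fa,
        target_md=target_md,
        gm_mask=gm_mask,
        wm_mask=wm_mask,
        meta={"mapping_id": params.mapping_id, "seed": params.seed, "index": subject_index},
    )


def generate_cohort(params: PhantomParams) -> list[PairedSubject]:
    """All ``n_subjects`` phantom subjects, reproducible under a fixed seed."""
    if params.n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    return [generate_phantom_subject(params, i) for i in range(params.n_subjects)]


# ---------------------------------------------------------------------------
# NIfTI + manifest I/O
# ---------------------------------------------------------------------------

def _save_nifti(volume: np.ndarray, spacing, path: Path) -> None:
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def write_cohort(subjects: list[PairedSubject], out_dir: str | Path) -> Path:
    """Write each subject as NIfTI files plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for subj in subjects:
        paths = {}
        for key, vol in (
            ("flair", subj.source_volume),
            ("fa", subj.target_fa),
            ("md", subj.target_md),
            ("gm_mask", subj.gm_mask),
            ("wm_mask", subj.wm_mask),
        ):
            p = out_dir / f"{subj.subject_id}_{key}.nii.gz"
            _save_nifti(vol, subj.slice_spacing, p)
            paths[key] = p.name
        entries.append({"subject_id": subj.subject_id, **paths})
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"subjects": entries}, indent=2))
    return manifest


def load_manifest(manifest_path: str | Path) -> list[dict]:
    manifest_path = Path(manifest_path)
    data = json.loads(manifest_path.read_text())
    return data["subjects"]


def load_subject(entry: dict, base_dir: str | Path) -> PairedSubject:
    base = Path(base_dir)

    def vol(key):
        img = nib.load(str(base / entry[key]))
        return np.asarray(img.dataobj, dtype=np.float64)

    img = nib.load(str(base / entry["flair"]))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PairedSubject(
        subject_id=entry["subject_id"],
        source_volume=vol("flair"),
        target_fa=vol("fa"),
        target_md=vol("md"),
        gm_mask=vol("gm_mask").astype(np.uint8),
        wm_mask=vol("wm_mask").astype(np.uint8),
        slice_spacing=zooms,
    )
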