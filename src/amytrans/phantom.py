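"""Synthetic paired PiB/FBB/MR brain phantoms.

Real paired amyloid-PET datasets (one subject scanned with both [11C]PiB and
[18F]florbetaben) are rare; this module generates template-space triplets
with a *known, parameterized* inter-tracer mapping so every downstream stage
— masking, SUVr normalization, slice extraction, network training, metric and
Centiloid computation — can be exercised and verified against ground truth.

The anatomy is a nested-ellipsoid head: a scalp shell enclosing a cerebrum
with a cortical gray ribbon (partitioned angularly into six named
subregions), a white-matter core, a central ventricle/choroid-plexus region,
and an inferior cerebellar-gray blob (the SUVr reference region). Geometry is
expressed in fractional grid coordinates, so smaller grids can be used for
fast tests.

Noiseless ground-truth SUVr per tissue class, as a function of the latent
amyloid burden ``A`` in [0, 1]:

==================  ==================  ==================
tissue              PiB                 FBB
==================  ==================  ==================
cerebellar gray     1.0                 1.0
cortical gray       1.0 + 2.0 A         1.0 + 1.2 A
white matter        1.3                 1.6
ventricle / CP      0.9 + 0.4 A         0.7 + 0.3 A
background, scalp   0                   0
==================  ==================  ==================

so at full burden cortical PiB reaches 3.0 and cortical FBB 2.2 (the
characteristic dynamic-range difference between the tracers), and FBB shows
nonspecific white-matter binding exceeding its amyloid-negative gray level.
Both volumes are then blurred with a PET-like Gaussian PSF and perturbed with
additive Gaussian noise, clipped at zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Label", "PhantomConfig", "VolumeImage", "TissueMap", "SubjectPhantom",
    "make_tissue_map", "simulate_tracer_pair", "simulate_mr",
    "generate_cohort", "save_cohort", "load_cohort",
    "CORTICAL_LABELS", "BURDEN_RANGES", "DIAGNOSES",
]


class Label:
    """Integer tissue classes of the phantom atlas."""
    BACKGROUND = 0
    SCALP = 1
    WHITE = 2
    VENTRICLE = 3          # ventricle / choroid plexus
    CEREBELLUM = 4         # cerebellar gray: the SUVr reference region
    FRONTAL = 5
    PARIETAL = 6
    TEMPORAL = 7
    MEDIAL_TEMPORAL = 8
    OCCIPITAL = 9
    CINGULATE = 10


CORTICAL_LABELS = (Label.FRONTAL, Label.PARIETAL, Label.TEMPORAL,
                   Label.MEDIAL_TEMPORAL, Label.OCCIPITAL, Label.CINGULATE)

ALL_LABELS = (Label.BACKGROUND, Label.SCALP, Label.WHITE, Label.VENTRICLE,
              Label.CEREBELLUM) + CORTICAL_LABELS

DIAGNOSES = ("YHC", "EHC", "MCI", "AD", "FTD")

# latent amyloid-burden sampling intervals per diagnosis group
BURDEN_RANGES = {
    "YHC": (0.0, 0.15),
    "FTD": (0.0, 0.15),   # FTD is not an amyloid pathology
    "EHC": (0.0, 0.5),
    "MCI": (0.05, 0.9),
    "AD": (0.3, 1.0),
}

# noiseless SUVr maps: label -> (intercept, slope in burden), per tracer
PIB_UPTAKE = {Label.CEREBELLUM: (1.0, 0.0), Label.WHITE: (1.3, 0.0),
              Label.VENTRICLE: (0.9, 0.4),
              **{lab: (1.0, 2.0) for lab in CORTICAL_LABELS}}
FBB_UPTAKE = {Label.CEREBELLUM: (1.0, 0.0), Label.WHITE: (1.6, 0.0),
              Label.VENTRICLE: (0.7, 0.3),
              **{lab: (1.0, 1.2) for lab in CORTICAL_LABELS}}


@dataclass
class VolumeImage:
    """A 3D scalar grid in template space."""
    data: np.ndarray
    voxel_mm: float = 2.0
    role: str = ""

    @property
    def shape(self):
        return self.data.shape


@dataclass
class TissueMap:
    labels: np.ndarray
    voxel_mm: float = 2.0

    def region(self, label) -> np.ndarray:
        """Boolean mask of one label or a tuple of labels."""
        if np.isscalar(label):
            return self.labels == label
        return np.isin(self.labels, label)


@dataclass
class PhantomConfig:
    grid_shape: tuple = (109, 91, 91)
    voxel_mm: float = 2.0
    counts: dict = field(default_factory=lambda: {
        "YHC": 10, "EHC": 6, "MCI": 9, "AD": 8, "FTD": 2})
    psf_fwhm_mm: float = 6.0
    noise_sd: float = 0.05
    mr_noise_sd: float = 0.02
    jitter: float = 0.01       # fractional anatomical jitter per subject
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(d) < 16 for d in self.grid_shape):
            raise ValueError(f"invalid grid_shape {self.grid_shape}: each dim must be >= 16")
        self.grid_shape = tuple(int(d) for d in self.grid_shape)
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if any(int(v) < 0 for v in self.counts.values()):
            raise ValueError("subject counts must be non-negative")
        if self.noise_sd < 0 or self.psf_fwhm_mm < 0:
            raise ValueError("noise_sd and psf_fwhm_mm must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class SubjectPhantom:
    """One synthetic subject: coregistered tracer pair, MR, mask and atlas."""
    id: str
    diagnosis: str
    burden: float
    pib: VolumeImage
    fbb: VolumeImage
    mr: VolumeImage
    mask: VolumeImage
    tissue: TissueMap

    @property
    def atlas(self) -> TissueMap:
        return self.tissue


def _ellipsoid(coords, center_frac, semi_frac, shape) -> np.ndarray:
    """Boolean ellipsoid; center and semi-axes as fractions of the grid."""
    acc = np.zeros(shape, dtype=np.float64)
    for ax in range(3):
        c = center_frac[ax] * (shape[ax] - 1)
        s = max(semi_frac[ax] * shape[ax], 1.0)
        acc = acc + ((coords[ax] - c) / s) ** 2
    return acc <= 1.0


def make_tissue_map(config: PhantomConfig, rng: np.random.Generator) -> TissueMap:
    """Build the nested-ellipsoid head atlas; deterministic given rng state."""
    shape = config.grid_shape
    coords = np.meshgrid(*[np.arange(d, dtype=np.float64) for d in shape],
                         indexing="ij", sparse=True)

    j = config.jitter
    jc = rng.uniform(-j, j, size=3)          # center jitter (fractional)
    js = 1.0 + rng.uniform(-j, j, size=3)    # semi-axis jitter

    def ell(center, semi):
        c = tuple(center[i] + jc[i] for i in range(3))
        s = tuple(semi[i] * js[i] for i in range(3))
        return _ellipsoid(coords, c, s, shape)

    head = ell((0.5, 0.5, 0.5), (0.46, 0.45, 0.46))
    cerebrum = ell((0.47, 0.5, 0.56), (0.36, 0.36, 0.33))
    cerebellum = ell((0.72, 0.5, 0.26), (0.16, 0.20, 0.14)) & head & ~cerebrum
    white = ell((0.47, 0.5, 0.56), (0.245, 0.24, 0.22))
    ventricle = ell((0.47, 0.5, 0.56), (0.085, 0.06, 0.075))

    labels = np.zeros(shape, dtype=np.int16)
    labels[head] = Label.SCALP
    labels[cerebrum] = Label.WHITE  # provisional: gray ribbon assigned below
    gray = cerebrum & ~white

    # partition the gray ribbon into six cortical subregions by position
    # relative to the cerebrum center, normalized by its semi-axes
    cc = [(0.47 + jc[0]) * (shape[0] - 1), (0.5 + jc[1]) * (shape[1] - 1),
          (0.56 + jc[2]) * (shape[2] - 1)]
    ss = [0.36 * js[0] * shape[0], 0.36 * js[1] * shape[1], 0.33 * js[2] * shape[2]]
    u0 = (coords[0] - cc[0]) / ss[0]   # anterior(-)/posterior(+) axis
    u1 = (coords[1] - cc[1]) / ss[1]   # left/right
    u2 = (coords[2] - cc[2]) / ss[2]   # inferior(-)/superior(+)
    u0, u1, u2 = np.broadcast_arrays(u0, u1, u2)

    sub = np.full(shape, Label.TEMPORAL, dtype=np.int16)
    sub[u2 > 0.15] = Label.PARIETAL
    sub[u0 < -0.3] = Label.FRONTAL
    sub[u0 > 0.35] = Label.OCCIPITAL
    sub[(np.abs(u1) < 0.45) & (u2 < -0.25)] = Label.MEDIAL_TEMPORAL
    sub[(np.abs(u1) < 0.2) & (u2 > 0)] = Label.CINGULATE
    labels[gray] = sub[gray]

    labels[white] = Label.WHITE
    labels[ventricle & cerebrum] = Label.VENTRICLE
    labels[cerebellum] = Label.CEREBELLUM

    tissue = TissueMap(labels=labels, voxel_mm=config.voxel_mm)
    for lab in ALL_LABELS:
        if lab != Label.BACKGROUND and not tissue.region(lab).any():
            raise RuntimeError(f"degenerate phantom geometry: empty label {lab}")
    return tissue


def _uptake_volume(tissue: TissueMap, table: dict, burden: float) -> np.ndarray:
    vol = np.zeros(tissue.labels.shape, dtype=np.float64)
    for lab, (a, b) in table.items():
        vol[tissue.labels == lab] = a + b * burden
    return vol


def simulate_tracer_pair(tissue: TissueMap, burden: float, config: PhantomConfig,
                         rng: np.random.Generator):
    """Simulate the paired (PiB, FBB) SUVr volumes for one subject."""
    if not 0.0 <= burden <= 1.0:
        raise ValueError(f"burden must lie in [0, 1], got {burden}")
    from scipy.ndimage import gaussian_filter

    sigma_vox = config.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / config.voxel_mm
    out = []
    for table, role in ((PIB_UPTAKE, "PiB-SUVr"), (FBB_UPTAKE, "FBB-SUVr")):
        vol = _uptake_volume(tissue, table, burden)
        if sigma_vox > 0:
            vol = gaussian_filter(vol, sigma_vox)
        vol = vol + rng.normal(0.0, config.noise_sd, size=vol.shape) \
            if config.noise_sd > 0 else vol
        out.append(VolumeImage(np.clip(vol, 0.0, None), config.voxel_mm, role))
    return out[0], out[1]


# T1-like mean intensities (arbitrary units): WM > GM > CSF > background
_MR_MEANS = {Label.SCALP: 0.4, Label.WHITE: 1.0, Label.VENTRICLE: 0.25,
             Label.CEREBELLUM: 0.6, **{lab: 0.6 for lab in CORTICAL_LABELS}}


def simulate_mr(tissue: TissueMap, rng: np.random.Generator,
                config: PhantomConfig) -> VolumeImage:
    """T1-weighted-like volume; intensities independent of amyloid burden."""
    vol = np.zeros(tissue.labels.shape, dtype=np.float64)
    for lab, mean in _MR_MEANS.items():
        vol[tissue.labels == lab] = mean
    if config.mr_noise_sd > 0:
        vol = vol + rng.normal(0.0, config.mr_noise_sd, size=vol.shape)
    return VolumeImage(np.clip(vol, 0.0, None), config.voxel_mm, "MR")


def generate_cohort(config: PhantomConfig, out_dir=None) -> list:
    """Generate the full cohort; optionally write NIfTI files + manifest.

    Subjects are generated in a fixed diagnosis order, fully reproducible
    from ``config.seed``.
    """
    if config.total < 1:
        raise ValueError("cohort must contain at least one subject")
    rng = np.random.default_rng(config.seed)
    subjects = []
    for dx in DIAGNOSES:
        lo, hi = BURDEN_RANGES[dx]
        for i in range(config.counts.get(dx, 0)):
            tissue = make_tissue_map(config, rng)
            burden = float(rng.uniform(lo, hi))
            pib, fbb = simulate_tracer_pair(tissue, burden, config, rng)
            mr = simulate_mr(tissue, rng, config)
            mask = VolumeImage((tissue.labels > 0).astype(np.uint8),
                               config.voxel_mm, "mask")
            subjects.append(SubjectPhantom(
                id=f"{dx}_{i:03d}", diagnosis=dx, burden=burden,
                pib=pib, fbb=fbb, mr=mr, mask=mask, tissue=tissue))
    if out_dir is not None:
        save_cohort(subjects, out_dir)
    return subjects


def _affine(voxel_mm: float) -> np.ndarray:
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return aff


def save_cohort(subjects, out_dir) -> Path:
    """Write one NIfTI per volume plus a cohort manifest CSV."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        row = {"id": s.id, "diagnosis": s.diagnosis, "burden": s.burden}
        for key in ("pib", "fbb", "mr", "mask"):
            vol = getattr(s, key)
            path = out_dir / f"{s.id}_{key}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32),
                                     _affine(vol.voxel_mm)), path)
            row[key] = path.name
        path = out_dir / f"{s.id}_atlas.nii.gz"
        nib.save(nib.Nifti1Image(s.tissue.labels.astype(np.int16),
                                 _affine(s.tissue.voxel_mm)), path)
        row["atlas"] = path.name
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path) -> list:
    """Read a cohort written by :func:`save_cohort`."""
    import nibabel as nib

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    subjects = []
    for _, row in df.iterrows():
        def vol(key, role=""):
            img = nib.load(base / row[key])
            vmm = float(img.header.get_zooms()[0])
            return np.asarray(img.dataobj), vmm

        pib, vmm = vol("pib")
        fbb, _ = vol("fbb")
        mr, _ = vol("mr")
        mask, _ = vol("mask")
        atlas, _ = vol("atlas")
        subjects.append(SubjectPhantom(
            id=str(row["id"]), diagnosis=str(row["diagnosis"]),
            burden=float(row["burden"]),
            pib=VolumeImage(np.asarray(pib, dtype=np.float64), vmm, "PiB-SUVr"),
            fbb=VolumeImage(np.asarray(fbb, dtype=np.float64), vmm, "FBB-SUVr"),
            mr=VolumeImage(np.asarray(mr, dtype=np.float64), vmm, "MR"),
            mask=VolumeImage(np.asarray(mask, dtype=np.uint8), vmm, "mask"),
            tissue=TissueMap(np.asarray(atlas, dtype=np.int16), vmm)))
    return subjects
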