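"""Preprocessing: head masking, SUVr normalization, slice extraction.

Volumes are assumed already coregistered and template-normalized. The chain
implemented here mirrors the standard 2D training setup for paired-tracer
translation:

1. an MRI-derived binary head mask (threshold + morphology) zeroes
   extracerebral noise in both PET volumes;
2. PET volumes are rescaled to SUVr by the mean over the whole-cerebellum
   reference region;
3. axial slices in a kept range (default slices 10-75, 0-based inclusive, 66
   slices) are zero-padded from (109, 91) to (128, 128) and stacked into
   network samples, PiB (and optionally MR) as input channels, FBB as the
   target;
4. optional paired augmentation applies one sampled geometric transform
   (flip / shift / scale / rotate) and intensity perturbation (blur / noise)
   identically to the input channels and the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import Label, TissueMap, VolumeImage

DEFAULT_KEEP_RANGE = (10, 75)   # 0-based, inclusive
NET_SIZE = (128, 128)


class EmptyMaskError(ValueError):
    pass


class ReferenceRegionError(ValueError):
    pass


@dataclass
class SlicePair:
    """One 2D network sample (channels-last spatial arrays)."""
    input: np.ndarray          # (128, 128, C), C in {1, 2}
    target: np.ndarray         # (128, 128, 1)
    subject_id: str
    slice_index: int
    pad_offsets: tuple         # (top, bottom, left, right)


@dataclass
class AugmentParams:
    """Ranges for paired data augmentation; all transforms optional."""
    flip: bool = True
    shift: float = 3.0            # max |shift| in voxels, per axis
    scale: tuple = (0.95, 1.05)   # multiplicative factor range
    rotate: float = 10.0          # max |angle| in degrees
    blur: tuple = (0.0, 0.8)      # sigma range in voxels
    noise_sd: float = 0.02        # max additive noise sd
    p_geometric: float = 0.5      # probability of applying each transform

    def __post_init__(self):
        if not 0.0 <= self.p_geometric <= 1.0:
            raise ValueError("p_geometric must be in [0, 1]")
        if self.shift < 0 or self.rotate < 0 or self.noise_sd < 0:
            raise ValueError("augmentation ranges must be non-negative")

    @classmethod
    def disabled(cls) -> "AugmentParams":
        return cls(flip=False, shift=0.0, scale=(1.0, 1.0), rotate=0.0,
                   blur=(0.0, 0.0), noise_sd=0.0, p_geometric=0.0)


def make_head_mask(mr: VolumeImage, threshold_quantile: float = 0.4) -> VolumeImage:
    """Binary head mask from an MR volume by thresholding + morphology.

    Threshold at the given quantile of the nonzero-voxel intensities (the
    default separates clipped background noise from tissue), close with a
    3x3x3 structuring element, fill holes slice-by-slice, and keep the
    largest connected component.
    """
    data = np.asarray(mr.data)
    nz = data[data > 0]
    if nz.size == 0:
        raise EmptyMaskError("MR volume is all zero; cannot derive a head mask")
    thr = np.quantile(nz, threshold_quantile)
    mask = data >= thr
    # pad so morphological closing does not erode the volume border
    mask = ndimage.binary_closing(np.pad(mask, 1),
                                  structure=np.ones((3, 3, 3), dtype=bool))[1:-1, 1:-1, 1:-1]
    for z in range(mask.shape[2]):
        mask[:, :, z] = ndimage.binary_fill_holes(mask[:, :, z])
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return VolumeImage(mask.astype(np.uint8), mr.voxel_mm, "mask")


def apply_mask(pet: VolumeImage, mask: VolumeImage) -> VolumeImage:
    if pet.data.shape != mask.data.shape:
        raise ValueError(f"shape mismatch: {pet.data.shape} vs {mask.data.shape}")
    return VolumeImage(pet.data * (mask.data > 0), pet.voxel_mm, pet.role)


def to_suvr(pet: VolumeImage, atlas: TissueMap,
            reference_label=Label.CEREBELLUM) -> VolumeImage:
    """Normalize a PET volume by the mean over the reference region.

    The whole cerebellum is the canonical reference; afterwards the mean of
    the output over the reference region is exactly 1.
    """
    ref = atlas.region(reference_label)
    if not ref.any():
        raise ReferenceRegionError("reference region is empty")
    m = float(pet.data[ref].mean())
    if m <= 0:
        raise ReferenceRegionError(f"reference-region mean must be positive, got {m}")
    return VolumeImage(pet.data / m, pet.voxel_mm, "SUVr")


def _pad_amounts(n: int, target: int) -> tuple:
    """Split ``target - n`` zeros evenly; the extra voxel goes high-index."""
    total = target - n
    if total < 0:
        raise ValueError(f"dimension {n} exceeds target {target}")
    return total // 2, total - total // 2


def pad_slice(slice_2d: np.ndarray):
    """Zero-pad a (109, 91) axial slice to (128, 128).

    Returns the padded array and the pad offsets (top, bottom, left, right);
    for the template grid these are (9, 10, 18, 19).
    """
    if slice_2d.shape != (109, 91):
        raise ValueError(f"expected a (109, 91) slice, got {slice_2d.shape}")
    return _pad_any(slice_2d)


def _pad_any(slice_2d: np.ndarray):
    t, b = _pad_amounts(slice_2d.shape[0], NET_SIZE[0])
    l, r = _pad_amounts(slice_2d.shape[1], NET_SIZE[1])
    return np.pad(slice_2d, ((t, b), (l, r))), (t, b, l, r)


def unpad_slice(padded: np.ndarray, pad_offsets: tuple) -> np.ndarray:
    t, b, l, r = pad_offsets
    return padded[t:padded.shape[0] - b, l:padded.shape[1] - r]


def normalize_mr(mr: VolumeImage) -> VolumeImage:
    """Scale MR intensities so the 99th percentile of nonzero voxels is 1."""
    nz = mr.data[mr.data > 0]
    scale = float(np.quantile(nz, 0.99)) if nz.size else 1.0
    return VolumeImage(mr.data / max(scale, 1e-9), mr.voxel_mm, "MR")


def extract_slices(subject, keep_range=DEFAULT_KEEP_RANGE, with_mr: bool = True,
                   suvr: bool = True) -> list:
    """Build the per-subject list of padded 2D training samples.

    ``subject`` provides ``pib``, ``fbb``, ``mr``, ``mask`` volumes and an
    ``atlas`` label map. ``keep_range`` is inclusive on both ends.
    """
    lo, hi = keep_range
    nz = subject.pib.data.shape[2]
    if not (0 <= lo <= hi < nz):
        raise ValueError(f"keep_range {keep_range} outside volume extent {nz}")

    pib = apply_mask(subject.pib, subject.mask)
    fbb = apply_mask(subject.fbb, subject.mask)
    if suvr:
        pib = to_suvr(pib, subject.atlas)
        fbb = to_suvr(fbb, subject.atlas)
    channels = [pib.data]
    if with_mr:
        channels.append(normalize_mr(subject.mr).data)

    pairs = []
    for z in range(lo, hi + 1):
        ins = []
        for ch in channels:
            padded, off = _pad_any(ch[:, :, z])
            ins.append(padded)
        tgt, off = _pad_any(fbb.data[:, :, z])
        pairs.append(SlicePair(
            input=np.stack(ins, axis=-1), target=tgt[:, :, None],
            subject_id=subject.id, slice_index=z, pad_offsets=off))
    return pairs


# ---------------------------------------------------------------------------
# paired augmentation
# ---------------------------------------------------------------------------

def _geometric(img: np.ndarray, flip: bool, shift, scale: float,
               angle: float) -> np.ndarray:
    """Apply flip, then a single affine (rotate+scale about the center) and
    shift, with bilinear interpolation and zero fill."""
    out = img[:, ::-1] if flip else img
    if scale != 1.0 or angle != 0.0 or np.any(np.asarray(shift) != 0):
        th = np.deg2rad(angle)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        # snap right-angle rotations onto the grid (cos 90deg is ~6e-17,
        # which would push boundary samples out of bounds)
        rot = np.round(rot, 12)
        mat = rot / scale
        center = (np.asarray(out.shape) - 1) / 2.0
        offset = center - mat @ (center + np.asarray(shift))
        out = ndimage.affine_transform(out, mat, offset=offset, order=1,
                                       mode="constant", cval=0.0)
    return out


def augment_pair(pair: SlicePair, params: AugmentParams,
                 rng: np.random.Generator) -> SlicePair:
    """One sampled transform set, applied identically to inputs and target."""
    do_flip = params.flip and rng.random() < 0.5
    do_geo = rng.random() < params.p_geometric
    shift = rng.uniform(-params.shift, params.shift, size=2) if do_geo else np.zeros(2)
    scale = float(rng.uniform(*params.scale)) if do_geo else 1.0
    angle = float(rng.uniform(-params.rotate, params.rotate)) if do_geo else 0.0
    sigma = float(rng.uniform(*params.blur))
    noise = float(rng.uniform(0.0, params.noise_sd))

    if not (do_flip or do_geo or sigma > 0 or noise > 0):
        return pair

    def tf(img2d):
        out = _geometric(img2d, do_flip, shift, scale, angle)
        if sigma > 0:
            out = ndimage.gaussian_filter(out, sigma)
        if noise > 0:
            out = out + rng.normal(0.0, noise, size=out.shape)
        return out

    inp = np.stack([tf(pair.input[:, :, c]) for c in range(pair.input.shape[-1])],
                   axis=-1)
    tgt = tf(pair.target[:, :, 0])[:, :, None]
    return SlicePair(input=inp, target=tgt, subject_id=pair.subject_id,
                     slice_index=pair.slice_index, pad_offsets=pair.pad_offsets)


def downsample_pair(pair: SlicePair, factor: int) -> SlicePair:
    """Average-pool a sample by an integer factor (e.g. 128 -> 64)."""
    if factor == 1:
        return pair

    def pool(a):
        H, W, C = a.shape
        return a.reshape(H // factor, factor, W // factor, factor, C).mean(axis=(1, 3))

    return SlicePair(input=pool(pair.input), target=pool(pair.target),
                     subject_id=pair.subject_id, slice_index=pair.slice_index,
                     pad_offsets=pair.pad_offsets)
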