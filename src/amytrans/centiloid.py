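"""Centiloid quantification: SUVr -> CL scaling and tracer calibration.

The Centiloid (CL) scale linearly maps a tracer's global cortical SUVr onto
0-100, anchored by the mean of a young-control group (YC-0, 0 CL) and the
mean of a typical-AD group (AD-100, 100 CL):

    CL = 100 * (SUVr - mean_YC0) / (mean_AD100 - mean_YC0)

A surrogate tracer (here florbetaben, or a model-predicted FBB-like image)
is calibrated against the reference tracer PiB through a paired cohort: an
OLS fit ``PiB_SUVr = m * surrogate_SUVr + b`` composed with the PiB CL
mapping yields the surrogate's direct CL equation. Scans are classified
amyloid-positive at the conventional 20-CL cutoff (inclusive).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import fit_correlation
from .phantom import CORTICAL_LABELS, Label, TissueMap, VolumeImage
from .preprocess import to_suvr

__all__ = ["CentiloidCalibration", "TracerCalibration", "cortical_suvr",
           "centiloid_from_anchors", "calibration_from_groups",
           "calibrate_tracer", "classify_amyloid", "concordance_table",
           "load_reference_cl_table", "CL_POSITIVITY_CUTOFF"]

CL_POSITIVITY_CUTOFF = 20.0


@dataclass
class CentiloidCalibration:
    """Anchor-group means (YC-0, AD-100) defining a tracer's CL mapping."""
    yc0_mean: float
    ad100_mean: float
    tracer: str = "PiB"

    def __post_init__(self):
        if self.ad100_mean <= self.yc0_mean:
            raise ValueError("AD-100 anchor mean must exceed the YC-0 anchor mean")

    @property
    def slope(self) -> float:
        return 100.0 / (self.ad100_mean - self.yc0_mean)

    @property
    def intercept(self) -> float:
        return -self.slope * self.yc0_mean


@dataclass
class TracerCalibration:
    """Surrogate-to-PiB correlation equation and the composed CL equation."""
    corr_slope: float
    corr_intercept: float
    r2: float
    cl_slope: float
    cl_intercept: float
    tracer: str = "FBB"

    def cl(self, suvr) -> np.ndarray:
        return self.cl_slope * np.asarray(suvr, dtype=np.float64) + self.cl_intercept


def cortical_suvr(volume: VolumeImage, atlas: TissueMap,
                  normalize: bool = True) -> float:
    """Mean over the global-cortex VOI of the cerebellum-normalized volume."""
    cortex = atlas.region(CORTICAL_LABELS)
    if not cortex.any():
        raise ValueError("empty cortical VOI")
    vol = to_suvr(volume, atlas, Label.CEREBELLUM) if normalize else volume
    return float(vol.data[cortex].mean())


def centiloid_from_anchors(suvr, cal: CentiloidCalibration):
    """CL = 100 * (SUVr - YC0) / (AD100 - YC0)."""
    suvr = np.asarray(suvr, dtype=np.float64)
    out = 100.0 * (suvr - cal.yc0_mean) / (cal.ad100_mean - cal.yc0_mean)
    return float(out) if out.ndim == 0 else out


def calibration_from_groups(suvr_by_id: dict, diagnosis_by_id: dict,
                            tracer: str = "PiB") -> CentiloidCalibration:
    """Build anchor means from a cohort's YHC (YC-0) and AD (AD-100) groups."""
    yc = [v for sid, v in suvr_by_id.items() if diagnosis_by_id[sid] == "YHC"]
    ad = [v for sid, v in suvr_by_id.items() if diagnosis_by_id[sid] == "AD"]
    if not yc or not ad:
        raise ValueError("need both YHC and AD subjects for anchoring")
    return CentiloidCalibration(float(np.mean(yc)), float(np.mean(ad)), tracer)


def calibrate_tracer(paired_suvr, pib_cl: CentiloidCalibration,
                     tracer: str = "FBB") -> TracerCalibration:
    """Fit the surrogate->PiB correlation equation and compose the CL map.

    ``paired_suvr`` is a sequence of (surrogate_suvr, pib_suvr) pairs from
    subjects scanned with both tracers.
    """
    arr = np.asarray(paired_suvr, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least three (surrogate, pib) pairs")
    fit = fit_correlation(arr[:, 0], arr[:, 1])
    cl_slope = pib_cl.slope * fit.slope
    cl_intercept = pib_cl.slope * fit.intercept + pib_cl.intercept
    return TracerCalibration(corr_slope=fit.slope, corr_intercept=fit.intercept,
                             r2=fit.r2, cl_slope=cl_slope,
                             cl_intercept=cl_intercept, tracer=tracer)


def classify_amyloid(cl: float, cutoff: float = CL_POSITIVITY_CUTOFF) -> str:
    """'positive' iff CL >= cutoff (inclusive boundary convention)."""
    if not np.isfinite(cl):
        raise ValueError("CL value must be finite")
    return "positive" if cl >= cutoff else "negative"


def concordance_table(cl_a, cl_b, ids=None,
                      cutoff: float = CL_POSITIVITY_CUTOFF) -> dict:
    """Positivity concordance of two CL series (b treated as truth).

    Returns per-subject classifications, the discordant ids, and false
    positive / false negative counts of ``a`` against ``b``.
    """
    cl_a = np.asarray(cl_a, dtype=np.float64)
    cl_b = np.asarray(cl_b, dtype=np.float64)
    if cl_a.shape != cl_b.shape:
        raise ValueError("length mismatch")
    if ids is None:
        ids = [str(i) for i in range(cl_a.size)]
    pos_a = cl_a >= cutoff
    pos_b = cl_b >= cutoff
    discordant = [i for i, (pa, pb) in zip(ids, zip(pos_a, pos_b)) if pa != pb]
    return {
        "ids": list(ids),
        "positive_a": pos_a.tolist(),
        "positive_b": pos_b.tolist(),
        "discordant": discordant,
        "false_positive": int(np.sum(pos_a & ~pos_b)),
        "false_negative": int(np.sum(~pos_a & pos_b)),
    }


def load_reference_cl_table() -> pd.DataFrame:
    """Published per-subject Centiloid values from the paired PiB/FBB cohort.

    Columns: id, diagnosis, cl_fbb (ground truth), cl_pib_only and cl_pib_mr
    (model-predicted FBB-like images trained with PiB alone / PiB+MR), and
    cl_pib (the reference tracer itself).
    """
    with importlib.resources.files("amytrans.data").joinpath(
            "paired_cohort_centiloid.csv").open() as f:
        return pd.read_csv(f)
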