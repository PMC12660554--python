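"""Image-quality metrics and agreement statistics for translated volumes.

Provides the standard comparison battery for voxel-wise tracer translation:
RMSE / PSNR / SSIM within a head mask, voxel-wise relative-change maps,
Bland-Altman limits of agreement, ordinary least-squares correlation fits,
the Wilcoxon signed-rank test for paired per-subject metrics, and VOI-wise
mean SUVr tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import CORTICAL_LABELS, Label, TissueMap, VolumeImage
from .preprocess import DEFAULT_KEEP_RANGE

__all__ = ["BAStats", "RegressionFit", "image_metrics", "relative_change_map",
           "bland_altman", "fit_correlation", "wilcoxon_signed_rank",
           "voi_mean_suvr", "DEFAULT_REGIONS"]

# named VOI sets over the phantom atlas; whole brain = union of brain labels
DEFAULT_REGIONS = {
    "whole_brain": (Label.WHITE, Label.VENTRICLE, Label.CEREBELLUM) + CORTICAL_LABELS,
    "cortex": CORTICAL_LABELS,
    "frontal": (Label.FRONTAL,),
    "parietal": (Label.PARIETAL,),
    "temporal": (Label.TEMPORAL,),
    "medial_temporal": (Label.MEDIAL_TEMPORAL,),
    "occipital": (Label.OCCIPITAL,),
    "cingulate": (Label.CINGULATE,),
    "choroid_plexus": (Label.VENTRICLE,),
}


@dataclass
class BAStats:
    mean_diff: float
    sd_diff: float
    lower: float
    upper: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r2: float


def image_metrics(pred: VolumeImage, gt: VolumeImage, mask,
                  data_range: float | None = None,
                  keep_range=DEFAULT_KEEP_RANGE):
    """(RMSE, PSNR, SSIM) of a predicted volume against ground truth.

    RMSE is computed over the masked voxels; PSNR = 20 log10(R) -
    20 log10(RMSE) with R the ground-truth max inside the mask unless given;
    SSIM is computed per kept axial slice (scikit-image, Gaussian-weighted)
    and averaged.
    """
    from skimage.metrics import structural_similarity

    m = np.asarray(mask.data if isinstance(mask, VolumeImage) else mask) > 0
    if pred.data.shape != gt.data.shape or pred.data.shape != m.shape:
        raise ValueError("volume/mask shapes differ")
    if not m.any():
        raise ValueError("empty mask")

    diff = (pred.data - gt.data)[m]
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    if data_range is None:
        data_range = float(gt.data[m].max())
    psnr = np.inf if rmse == 0 else float(20 * np.log10(data_range) - 20 * np.log10(rmse))

    lo, hi = keep_range
    hi = min(hi, pred.data.shape[2] - 1)
    ssims = []
    for z in range(lo, hi + 1):
        if not m[:, :, z].any():
            continue
        ssims.append(structural_similarity(
            gt.data[:, :, z] * m[:, :, z], pred.data[:, :, z] * m[:, :, z],
            data_range=data_range, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False))
    return rmse, psnr, float(np.mean(ssims))


def relative_change_map(pred: VolumeImage, gt: VolumeImage, mask,
                        floor: float = 0.1) -> VolumeImage:
    """Voxel-wise percent difference 100*(pred-gt)/max(gt, floor) in-mask.

    The denominator floor avoids the division blow-up at near-zero SUVr
    voxels close to the skull.
    """
    if floor < 0:
        raise ValueError("floor must be non-negative")
    m = np.asarray(mask.data if isinstance(mask, VolumeImage) else mask) > 0
    if pred.data.shape != gt.data.shape:
        raise ValueError("volume shapes differ")
    den = np.maximum(gt.data, floor)
    out = np.where(m, 100.0 * (pred.data - gt.data) / den, 0.0)
    return VolumeImage(out, pred.voxel_mm, "relative-change-%")


def bland_altman(a, b) -> BAStats:
    """Bland-Altman agreement: mean difference and 1.96-sd limits."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diffs = a - b
    means = (a + b) / 2.0
    md = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BAStats(mean_diff=md, sd_diff=sd, lower=md - 1.96 * sd,
                   upper=md + 1.96 * sd, means=means, diffs=diffs)


def fit_correlation(x, y) -> RegressionFit:
    """OLS fit y = slope*x + intercept with R^2 (squared Pearson r)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: x is constant")
    res = stats.linregress(x, y)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         r2=float(res.rvalue ** 2))


def _signed_rank_null(ranks: np.ndarray) -> np.ndarray:
    """Exact null pmf of T+ over all 2^n sign assignments (integer ranks).

    Built by polynomial convolution of the (1 + x^r) factors — equivalent to
    exhaustive sign-flip enumeration.
    """
    ranks = np.rint(ranks).astype(int)
    dist = np.zeros(int(ranks.sum()) + 1, dtype=np.float64)
    dist[0] = 1.0
    for r in ranks:
        dist[r:] += dist[:-r].copy()
    return dist / dist.sum()


def wilcoxon_signed_rank(a, b, alternative: str = "two-sided"):
    """Wilcoxon signed-rank test for paired samples.

    Returns ``(statistic, p)`` where the statistic is the *signed* rank sum
    T+ - T- (so swapping the samples flips its sign). Zero differences are
    discarded; the p-value uses the exact permutation distribution for
    n <= 25 without ties, otherwise a normal approximation with tie-corrected
    variance.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n < 1:
        raise ValueError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    t_minus = float(ranks[d < 0].sum())
    statistic = t_plus - t_minus

    has_ties = np.unique(np.abs(d)).size < n
    if n <= 25 and not has_ties:
        dist = _signed_rank_null(ranks)
        t = int(round(t_plus))
        p_greater = float(dist[t:].sum())
        p_less = float(dist[:t + 1].sum())
        p_two = float(min(1.0, 2.0 * min(p_greater, p_less)))
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts ** 3 - tie_counts).sum()) / 48.0
        z = (t_plus - mu) / np.sqrt(var)
        p_greater = float(stats.norm.sf(z))
        p_less = float(stats.norm.cdf(z))
        p_two = float(min(1.0, 2.0 * min(p_greater, p_less)))

    if alternative == "two-sided":
        return statistic, p_two
    if alternative == "greater":
        return statistic, p_greater
    if alternative == "less":
        return statistic, p_less
    raise ValueError(f"unknown alternative {alternative!r}")


def voi_mean_suvr(volume: VolumeImage, atlas: TissueMap,
                  region_set: dict | None = None) -> pd.Series:
    """Mean SUVr over each named VOI of the atlas."""
    regions = region_set or DEFAULT_REGIONS
    out = {}
    for name, labels in regions.items():
        sel = atlas.region(labels)
        if not sel.any():
            raise ValueError(f"empty region: {name}")
        out[name] = float(volume.data[sel].mean())
    return pd.Series(out, name=volume.role or "mean_suvr")


def metrics_table(rows) -> pd.DataFrame:
    """Cohort summary (mean +/- sd) of per-subject metric rows."""
    df = pd.DataFrame(rows)
    return df


def plot_bland_altman(ba: BAStats, path, title: str = "") -> None:
    """Agreement plot: paired means vs differences with the mean-difference
    line and the 1.96-sd limits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=18, alpha=0.8)
    ax.axhline(ba.mean_diff, color="tab:blue")
    ax.axhline(ba.upper, color="tab:red", linestyle="--")
    ax.axhline(ba.lower, color="tab:red", linestyle="--")
    ax.set_xlabel("mean SUVr")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation(x, y, fit: RegressionFit, path, title: str = "") -> None:
    """Scatter with the identity line (dashed) and the fitted line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(x, y, s=18, alpha=0.8)
    lim = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax.plot(lim, lim, "k--", linewidth=1, label="identity")
    xs = np.linspace(lim[0], lim[1], 2)
    ax.plot(xs, fit.slope * xs + fit.intercept, color="tab:blue",
            label=f"y = {fit.slope:.2f}x + {fit.intercept:+.2f} (R$^2$={fit.r2:.2f})")
    ax.set_xlabel("reference SUVr")
    ax.set_ylabel("predicted SUVr")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
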