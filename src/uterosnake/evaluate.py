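"""Agreement and similarity statistics for paired segmentations.

Given measurements from the automatic method and a reference (manual)
segmentation, this module reproduces the standard agreement toolkit:
ordinary least-squares regression with Pearson correlation, root mean
square error against the identity, Bland–Altman limits of agreement with
the fraction of points inside them (r95), Dice/Jaccard overlap of masks,
the image-relative area error, and a one-at-a-time sweep of the snake's
alpha/beta weights against that error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .image_io import BinaryMask, ValidationError
from .snake import SnakeParams, evolve, initial_front

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "SimilarityReport",
    "dice_jaccard",
    "linear_regression",
    "bland_altman",
    "agreement_report",
    "similarity_report",
    "area_error",
    "parameter_sweep",
    "plot_bland_altman",
]

logger = logging.getLogger("uterosnake")


@dataclass
class PairedSeries:
    """Paired automatic/manual values of one measurement across cases."""

    auto: np.ndarray
    manual: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.auto = np.asarray(self.auto, dtype=np.float64)
        self.manual = np.asarray(self.manual, dtype=np.float64)
        if self.auto.shape != self.manual.shape or self.auto.ndim != 1:
            raise ValidationError("paired series must be 1-D arrays of equal length")
        if len(self.auto) < 3:
            raise ValidationError("paired series needs at least 3 pairs")
        if not (np.all(np.isfinite(self.auto)) and np.all(np.isfinite(self.manual))):
            raise ValidationError("paired series must be finite")


@dataclass
class AgreementReport:
    """Regression + Bland–Altman summary for one paired series.

    ``loa_low``/``loa_high`` are the limits of agreement, bias ± 1.96 SD of
    the differences; ``bias_ci_low``/``bias_ci_high`` give the 95% CI of the
    bias itself (bias ± 1.96 SD/sqrt(n)); ``r95`` is the percentage of
    points whose difference falls inside the (closed) limits of agreement.
    """

    label: str
    slope: float
    intercept: float
    r: float
    rmse: float
    bias: float
    loa_low: float
    loa_high: float
    bias_ci_low: float
    bias_ci_high: float
    r95: float
    n: int


@dataclass
class SimilarityReport:
    """Dice/Jaccard summary over a set of mask pairs, in percent."""

    dice: float
    jaccard: float
    dice_sd: float
    jaccard_sd: float
    max_deviation_dice: float
    max_deviation_jaccard: float
    per_case: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# overlap metrics


def dice_jaccard(a: BinaryMask, b: BinaryMask) -> tuple[float, float]:
    """Dice and Jaccard overlap of two congruent masks, in percent.

    dice = 200*|A∩B| / (|A|+|B|); jaccard = 100*|A∩B| / |A∪B|.
    """
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = a.area(), b.area()
    if na == 0 and nb == 0:
        raise ValidationError("overlap of two empty masks is undefined")
    inter = int(np.logical_and(a.pixels, b.pixels).sum())
    union = na + nb - inter
    return 200.0 * inter / (na + nb), 100.0 * inter / union


def area_error(auto_mask: BinaryMask, manual_mask: BinaryMask) -> float:
    """Percentage of the image occupied by the (absolute) area difference."""
    if auto_mask.shape != manual_mask.shape:
        raise ValidationError("mask shapes differ")
    total = auto_mask.pixels.size
    return 100.0 * abs(auto_mask.area() - manual_mask.area()) / total


# ---------------------------------------------------------------------------
# paired statistics


def linear_regression(series: PairedSeries) -> tuple[float, float, float, float]:
    """OLS of auto on manual: (slope, intercept, Pearson r, RMSE).

    RMSE is the agreement error against the identity,
    sqrt(mean((auto - manual)^2)), not the regression residual.
    """
    if np.ptp(series.manual) == 0:
        raise ValidationError("degenerate series: manual values have zero variance")
    res = stats.linregress(series.manual, series.auto)
    rmse = float(np.sqrt(np.mean((series.auto - series.manual) ** 2)))
    return float(res.slope), float(res.intercept), float(res.rvalue), rmse


def bland_altman(series: PairedSeries) -> tuple[float, float, float, float]:
    """Bland–Altman agreement: (bias, loa_low, loa_high, r95).

    Differences d = auto - manual; bias = mean(d); limits = bias ± 1.96 ×
    sample SD (n−1 denominator); r95 = percentage of differences inside the
    closed limits.
    """
    d = series.auto - series.manual
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    r95 = 100.0 * float(np.mean((d >= lo) & (d <= hi)))
    return bias, lo, hi, r95


def agreement_report(series: PairedSeries) -> AgreementReport:
    """Full regression + Bland–Altman report for one measurement series."""
    slope, intercept, r, rmse = linear_regression(series)
    bias, lo, hi, r95 = bland_altman(series)
    n = len(series.auto)
    half_ci = 1.96 * float((series.auto - series.manual).std(ddof=1)) / np.sqrt(n)
    return AgreementReport(
        label=series.label,
        slope=slope,
        intercept=intercept,
        r=r,
        rmse=rmse,
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        bias_ci_low=bias - half_ci,
        bias_ci_high=bias + half_ci,
        r95=r95,
        n=n,
    )


def similarity_report(pairs: list[tuple[BinaryMask, BinaryMask]]) -> SimilarityReport:
    """Per-case and summary Dice/Jaccard over (auto, manual) mask pairs."""
    if not pairs:
        raise ValidationError("similarity report needs at least one mask pair")
    per_case = [dice_jaccard(a, b) for a, b in pairs]
    dice = np.array([p[0] for p in per_case])
    jac = np.array([p[1] for p in per_case])
    ddof = 1 if len(per_case) > 1 else 0
    return SimilarityReport(
        dice=float(dice.mean()),
        jaccard=float(jac.mean()),
        dice_sd=float(dice.std(ddof=ddof)),
        jaccard_sd=float(jac.std(ddof=ddof)),
        max_deviation_dice=float(np.abs(dice - dice.mean()).max()),
        max_deviation_jaccard=float(np.abs(jac - jac.mean()).max()),
        per_case=per_case,
    )


# ---------------------------------------------------------------------------
# parameter sweep


def parameter_sweep(
    phantom_set: list,
    alphas: np.ndarray,
    betas: np.ndarray,
    params: SnakeParams | None = None,
) -> pd.DataFrame:
    """One-at-a-time alpha/beta sweep of the mean area error.

    For each alpha in ``alphas`` the snake runs with beta held at its
    default, and vice versa, over every ``(image, seeds, truth_mask)``
    triple in ``phantom_set``; the mean image-relative area error against
    ground truth is recorded. Returns a long-format table with columns
    ``parameter`` ("alpha"/"beta"), ``value``, ``mean_area_error`` and
    ``n_ok``. A failed evolution leaves its cell as NaN and the sweep
    continues.
    """
    from .image_io import rasterize_contour  # local import to avoid cycle

    if not phantom_set or (len(alphas) == 0 and len(betas) == 0):
        raise ValidationError("sweep needs a nonempty phantom set and grid")
    base = params or SnakeParams()
    rows = []
    grid = [("alpha", float(a)) for a in alphas] + [("beta", float(b)) for b in betas]
    for name, value in grid:
        kwargs = {
            "alpha": base.alpha,
            "beta": base.beta,
            "n_vertices": base.n_vertices,
            "step_size": base.step_size,
            "max_iters": base.max_iters,
            "tol": base.tol,
            "gradient_sigma": base.gradient_sigma,
            "reparam_interval": base.reparam_interval,
            "coarse_sigmas": base.coarse_sigmas,
        }
        kwargs[name] = value
        p = SnakeParams(**kwargs)
        errors = []
        for image, seeds, truth in phantom_set:
            try:
                init = initial_front(seeds, p.n_vertices)
                result = evolve(image, init, p)
                auto = rasterize_contour(result.contour, image.shape)
                errors.append(area_error(auto, truth))
            except Exception as exc:  # record-and-continue per cell
                logger.warning("sweep cell (%s=%.3g) failed: %s", name, value, exc)
        rows.append(
            {
                "parameter": name,
                "value": value,
                "mean_area_error": float(np.mean(errors)) if errors else np.nan,
                "n_ok": len(errors),
            }
        )
    return pd.DataFrame(rows)


def plot_bland_altman(series: PairedSeries, ax=None):
    """Bland–Altman scatter with bias and limits of agreement drawn."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    bias, lo, hi, _ = bland_altman(series)
    mean = (series.auto + series.manual) / 2
    diff = series.auto - series.manual
    ax.scatter(mean, diff, s=12)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=0.8)
    ax.set_xlabel(f"mean of methods ({series.label})")
    ax.set_ylabel("auto − manual")
    return ax
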