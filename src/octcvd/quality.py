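"""Scan-quality scoring and lowest-fraction exclusion.

The quality index (QI) of a [0, 1]-normalised B-scan is the product of two
ingredients, both referenced to the scan's own noise level:

* **intensity ratio** — mean intensity of the pixels at or above the
  saturation-free upper histogram mode, divided by the noise ceiling
  ``mu_bg + 3 sigma_bg``. The noise statistics come from the pre-retinal
  vitreous band (the top rows of the B-scan, dark by acquisition geometry),
  the standard reference region for OCT noise estimation: it is unaffected
  by retinal/choroidal anatomy, so QI ranks acquisition quality rather
  than layer morphology. Saturated pixels (>= 0.98) are excluded from the
  bright set: they carry no signal information.
* **tissue signal ratio** — count of highly reflective pixels (above
  ``TAU_HI + 3 sigma_bg``, unsaturated) over the count of all remaining,
  less reflective ones. The noise-adaptive threshold makes the ratio fall
  as noise or speckle grows; with purely fixed thresholds, noise lifts
  dark pixels across the low threshold and *inflates* the ratio.

Passing ``tau_hi``/``tau_lo`` explicitly switches to the classical
fixed-threshold form (raw count ratio, intensity ratio over the image
mean), which is hand-computable and exposed for calibration.

Higher QI is better. Filtering drops the lowest-QI fraction of scans
(20% by default), ties broken by stable input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from octcvd.errors import ConfigurationError

#: intensities at or above this are treated as saturated
SATURATION = 0.98
#: base high-reflectivity threshold (adaptive form adds 3 sigma of noise)
TAU_HI = 0.55
#: noise multiplier for the adaptive threshold and the noise ceiling
K_NOISE = 3.0
_N_BINS = 256


def _vitreous_stats(img: np.ndarray) -> Tuple[float, float]:
    """Mean and SD of the pre-retinal vitreous band (top rows)."""
    n_rows = max(2, img.shape[0] // 16)
    top = img[:n_rows]
    return float(top.mean()), float(top.std())


@dataclass(frozen=True)
class QualityScore:
    qi: float
    intensity_ratio: float
    tissue_signal_ratio: float
    degenerate: bool = False


def compute_qi(
    image: np.ndarray,
    tau_hi: Optional[float] = None,
    tau_lo: Optional[float] = None,
) -> QualityScore:
    """Quality index of a single [0, 1]-valued B-scan.

    With ``tau_hi``/``tau_lo`` given, the classical fixed-threshold form is
    used: tissue signal ratio = count(> tau_hi) / count(< tau_lo) and
    intensity ratio over the whole-image mean. By default both ingredients
    are referenced to the vitreous noise level (see module docstring).
    A constant image, or one where any denominator vanishes, is degenerate:
    QI is defined as 0 and flagged.
    """
    img = np.asarray(image, dtype=np.float64)
    overall_mean = img.mean() if img.size else 0.0
    if img.size == 0 or np.ptp(img) == 0.0 or overall_mean == 0.0:
        return QualityScore(0.0, 0.0, 0.0, degenerate=True)

    # saturation-free upper histogram mode
    unsaturated = img[img < SATURATION]
    if unsaturated.size == 0:
        return QualityScore(0.0, 0.0, 0.0, degenerate=True)
    hist, edges = np.histogram(unsaturated, bins=_N_BINS, range=(0.0, 1.0))
    upper = hist[_N_BINS // 2 :]
    if upper.sum() > 0:
        mode_bin = _N_BINS // 2 + int(np.argmax(upper))
    else:
        mode_bin = int(np.argmax(hist))
    bright = img[(img >= edges[mode_bin]) & (img < SATURATION)]
    if bright.size == 0:
        return QualityScore(0.0, 0.0, 0.0, degenerate=True)

    if tau_hi is not None and tau_lo is not None:
        # classical fixed-threshold form
        intensity_ratio = float(bright.mean() / overall_mean)
        n_hi = int(np.count_nonzero(img > tau_hi))
        n_lo = int(np.count_nonzero(img < tau_lo))
    else:
        # noise-referenced form
        mu_bg, sd_bg = _vitreous_stats(img)
        ceiling = mu_bg + K_NOISE * sd_bg
        if ceiling == 0.0:
            return QualityScore(0.0, 0.0, 0.0, degenerate=True)
        intensity_ratio = float(bright.mean() / ceiling)
        t_hi = TAU_HI + K_NOISE * sd_bg
        n_hi = int(np.count_nonzero((img > t_hi) & (img < SATURATION)))
        n_lo = img.size - n_hi
    if n_lo == 0:
        return QualityScore(0.0, intensity_ratio, 0.0, degenerate=True)
    tissue_signal_ratio = float(n_hi) / float(n_lo)

    return QualityScore(
        qi=intensity_ratio * tissue_signal_ratio,
        intensity_ratio=intensity_ratio,
        tissue_signal_ratio=tissue_signal_ratio,
    )


def volume_qi(bscans: np.ndarray, **kwargs) -> float:
    """Volume-level QI: median of per-B-scan QIs."""
    return float(np.median([compute_qi(b, **kwargs).qi for b in bscans]))


def filter_lowest_fraction(
    scored_images: Sequence[Tuple[object, float]], fraction: float = 0.2
) -> Tuple[List[Tuple[object, float]], List[Tuple[object, float]]]:
    """Split ``(item, qi)`` pairs into (retained, excluded) sets.

    Excludes the ``floor(fraction * N)`` items with smallest QI; ties are
    broken by stable input order. Both outputs preserve input order.
    """
    items = list(scored_images)
    if not items:
        raise ConfigurationError("cannot filter an empty image set")
    if not 0.0 <= fraction < 1.0:
        raise ConfigurationError("fraction must lie in [0, 1)")
    n_excl = int(np.floor(fraction * len(items)))
    qis = np.array([q for _, q in items], dtype=np.float64)
    order = np.argsort(qis, kind="stable")
    excluded_idx = set(order[:n_excl].tolist())
    retained = [it for i, it in enumerate(items) if i not in excluded_idx]
    excluded = [it for i, it in enumerate(items) if i in excluded_idx]
    return retained, excluded
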