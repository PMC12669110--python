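"""Global and local explanations of the risk classifier.

Global: mean Gini importance per feature from the fitted forest, plus the
share of importance per data channel (left-eye latents, right-eye latents,
metadata). Local: a latent-traversal vector-field method — the most
classifier-important latent dimension z_max is multiplied by its population
standard deviation sigma_max, both latent vectors are decoded, and the
displacement field between the two reconstructions is estimated with a
windowed Lucas-Kanade solver and overlaid on the original B-scan. An
occlusion-based saliency map serves as an independent comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from octcvd.errors import ConfigurationError
from octcvd.phantom import BAND_NAMES, CHOROID_BAND
from octcvd.vae import ConvVAE

#: Lucas-Kanade defaults: window side, structure-tensor eigenvalue gate
LK_WINDOW = 5
LK_LAMBDA_MIN = 1e-4


# ------------------------------ global ------------------------------------


def importance_table(model, feature_names: Sequence[str]) -> pd.DataFrame:
    """Mean Gini importance per feature, ranked (rank 1 = most important)."""
    imp = np.asarray(model.feature_importances_, dtype=float)
    if len(imp) != len(feature_names):
        raise ConfigurationError("feature name list does not match the model")
    order = np.argsort(imp)[::-1]
    ranks = np.empty(len(imp), dtype=int)
    ranks[order] = np.arange(1, len(imp) + 1)
    return pd.DataFrame(
        {"feature_name": list(feature_names), "importance": imp, "rank": ranks}
    )


def feature_channel(name: str) -> str:
    if name.startswith("zl"):
        return "zl"
    if name.startswith("zr"):
        return "zr"
    return "metadata"


def modality_importance(
    table: pd.DataFrame, channel_map: Optional[Dict[str, str]] = None
) -> Dict[str, float]:
    """Share of total importance per data channel, in percent (sums to 100)."""
    shares = {"zl": 0.0, "zr": 0.0, "metadata": 0.0}
    total = float(table["importance"].sum())
    if total <= 0:
        raise ConfigurationError("importance table carries no mass")
    for _, row in table.iterrows():
        name = row["feature_name"]
        ch = channel_map[name] if channel_map is not None else feature_channel(name)
        if ch not in shares:
            raise ConfigurationError(f"feature {name!r} mapped to unknown channel")
        shares[ch] += float(row["importance"])
    return {ch: 100.0 * v / total for ch, v in shares.items()}


@dataclass(frozen=True)
class Perturbation:
    """Latent traversal: multiply dimension ``index`` (z_max) by ``scale``
    (sigma_max, the population SD of that dimension)."""

    index: int
    scale: float

    def __post_init__(self):
        if self.index < 0:
            raise ConfigurationError("latent index must be >= 0")
        if self.scale <= 0:
            raise ConfigurationError("perturbation scale must be positive")


def top_latent_feature(table: pd.DataFrame) -> str:
    """Name of the most important latent-channel feature (z_max).

    Ties break toward the lowest latent index; metadata features are
    ignored. Feature names must follow ``zl###``/``zr###``.
    """
    latents = table[
        table["feature_name"].map(lambda n: feature_channel(n) != "metadata")
    ].copy()
    if latents.empty:
        raise ConfigurationError("model has no latent features")
    latents["idx"] = latents["feature_name"].str[2:].astype(int)
    best = latents.sort_values(
        ["importance", "idx"], ascending=[False, True], kind="stable"
    ).iloc[0]
    return str(best["feature_name"])


def top_latent(table: pd.DataFrame) -> int:
    """Latent dimension index of z_max (see :func:`top_latent_feature`)."""
    return int(top_latent_feature(table)[2:])


def latent_population_sd(latent_frame: pd.DataFrame, column: str) -> float:
    """Brute SD of one latent dimension's posterior means over a population."""
    return float(latent_frame[column].std(ddof=0))


def perturb_and_reconstruct(
    image: np.ndarray, model: ConvVAE, p: Perturbation
) -> Tuple[np.ndarray, np.ndarray]:
    """Decode the posterior mean and its z_max-perturbed copy.

    Returns ``(xhat_base, xhat_pert)``; only component ``p.index`` of the
    latent differs, multiplied by ``p.scale``.
    """
    z = model.encode(image).mean.copy()
    if p.index >= z.shape[-1]:
        raise ConfigurationError("perturbation index exceeds latent dimension")
    z_pert = z.copy()
    z_pert[p.index] = z[p.index] * p.scale
    return model.decode(z), model.decode(z_pert)


# ------------------------------ optical flow -------------------------------


@dataclass
class FlowField:
    u: np.ndarray  # horizontal displacement, pixels
    v: np.ndarray  # vertical displacement, pixels
    valid: np.ndarray  # where the local 2x2 system was well conditioned

    @property
    def magnitude(self) -> np.ndarray:
        mag = np.hypot(self.u, self.v)
        return np.where(self.valid, mag, 0.0)


def lucas_kanade(
    img_a: np.ndarray,
    img_b: np.ndarray,
    window: int = LK_WINDOW,
    lambda_min: float = LK_LAMBDA_MIN,
) -> FlowField:
    """Single-level Lucas-Kanade optical flow from ``img_a`` to ``img_b``.

    Per pixel, solves the optical-flow constraint by least squares over a
    ``window``-sided square: spatial gradients are central differences of
    ``img_a``, the temporal difference is ``img_b - img_a``. Pixels whose
    windowed 2x2 structure tensor has minimum eigenvalue below
    ``lambda_min`` are masked invalid (and their flow set to 0).
    """
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ConfigurationError("images must be two identical-shape 2D arrays")
    if window > min(a.shape):
        raise ConfigurationError("window larger than image")

    Iy, Ix = np.gradient(a)  # central differences; rows are y
    It = b - a

    def wsum(z):
        # uniform_filter is the window mean; scale to the window sum
        return uniform_filter(z, size=window, mode="nearest") * window**2

    sxx, syy, sxy = wsum(Ix * Ix), wsum(Iy * Iy), wsum(Ix * Iy)
    sxt, syt = wsum(Ix * It), wsum(Iy * It)

    # min eigenvalue of [[sxx, sxy], [sxy, syy]]
    tr, det = sxx + syy, sxx * syy - sxy * sxy
    disc = np.sqrt(np.maximum((tr / 2) ** 2 - det, 0.0))
    min_eig = tr / 2 - disc
    valid = min_eig >= lambda_min

    denom = np.where(det == 0.0, 1.0, det)
    u = np.where(valid, -(syy * sxt - sxy * syt) / denom, 0.0)
    v = np.where(valid, -(sxx * syt - sxy * sxt) / denom, 0.0)
    return FlowField(u=u, v=v, valid=valid)


# ------------------------------ local maps ---------------------------------


@dataclass
class VectorFieldExplanation:
    image: np.ndarray  # the ORIGINAL B-scan the overlay refers to
    flow: FlowField
    perturbation: Perturbation
    layer_summary: Optional[pd.DataFrame] = None  # mean |flow| per band

    @property
    def magnitude(self) -> np.ndarray:
        return self.flow.magnitude


def band_masks(boundary_map: np.ndarray, shape: Tuple[int, int]) -> Dict[str, np.ndarray]:
    """Boolean pixel mask per named band from a ground-truth boundary map."""
    H, W = shape
    rows = np.arange(H).reshape(H, 1)
    masks = {}
    for k, band in enumerate(BAND_NAMES):
        top, bot = boundary_map[k], boundary_map[k + 1]
        masks[band] = (rows >= top) & (rows < bot)
    return masks


def layer_magnitude_summary(
    magnitude: np.ndarray, boundary_map: np.ndarray
) -> pd.DataFrame:
    """Mean flow magnitude within each ground-truth retinal band."""
    masks = band_masks(boundary_map, magnitude.shape)
    rows = [
        {
            "band": band,
            "mean_magnitude": float(magnitude[m].mean()) if m.any() else 0.0,
            "area_fraction": float(m.mean()),
        }
        for band, m in masks.items()
    ]
    return pd.DataFrame(rows)


def vector_field_explanation(
    image: np.ndarray,
    model: ConvVAE,
    p: Perturbation,
    boundary_map: Optional[np.ndarray] = None,
    flow_source: str = "reconstruction",
    window: int = LK_WINDOW,
    lambda_min: float = LK_LAMBDA_MIN,
) -> VectorFieldExplanation:
    """Latent-traversal vector field for one B-scan.

    ``flow_source="reconstruction"`` (default) computes flow between the
    base and perturbed reconstructions, so reconstruction error cancels;
    ``"original"`` computes it between the original image and the perturbed
    reconstruction.
    """
    xhat_base, xhat_pert = perturb_and_reconstruct(image, model, p)
    if flow_source == "reconstruction":
        flow = lucas_kanade(xhat_base, xhat_pert, window, lambda_min)
    elif flow_source == "original":
        flow = lucas_kanade(np.asarray(image, dtype=np.float64), xhat_pert,
                            window, lambda_min)
    else:
        raise ConfigurationError(f"unknown flow_source {flow_source!r}")
    summary = (
        layer_magnitude_summary(flow.magnitude, boundary_map)
        if boundary_map is not None
        else None
    )
    return VectorFieldExplanation(
        image=np.asarray(image), flow=flow, perturbation=p, layer_summary=summary
    )


def band_enrichment(
    magnitude: np.ndarray,
    boundary_map: np.ndarray,
    band: str = CHOROID_BAND,
    top_fraction: float = 0.1,
) -> float:
    """Enrichment of top-magnitude pixels in one band vs. its area fraction.

    Takes the top ``top_fraction`` of pixels by flow magnitude and returns
    (fraction of those inside the band) / (the band's area fraction). A
    value of 1 is the no-localisation null; values >> 1 mean the flow
    concentrates in the band.
    """
    masks = band_masks(boundary_map, magnitude.shape)
    m = masks[band]
    n_top = max(1, int(round(top_fraction * magnitude.size)))
    thresh_idx = np.argsort(magnitude.ravel())[::-1][:n_top]
    top_mask = np.zeros(magnitude.size, dtype=bool)
    top_mask[thresh_idx] = True
    top_mask = top_mask.reshape(magnitude.shape)
    frac_in_band = float((top_mask & m).sum()) / n_top
    area_frac = float(m.mean())
    if area_frac == 0:
        raise ConfigurationError(f"band {band!r} has zero area")
    return frac_in_band / area_frac


def quiver_landmarks(
    flow: FlowField, grid: int = 16
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Downsample the flow to a coarse grid for quiver rendering."""
    H, W = flow.u.shape
    ys = np.linspace(0, H - 1, grid).round().astype(int)
    xs = np.linspace(0, W - 1, grid).round().astype(int)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return xx, yy, flow.u[yy, xx], flow.v[yy, xx]


def render_overlay(explanation: VectorFieldExplanation, path, grid: int = 16):
    """Write a PNG overlay: original image, magnitude heat-map, quiver."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(explanation.image, cmap="gray", vmin=0, vmax=1)
    mag = explanation.magnitude
    ax.imshow(np.ma.masked_where(mag <= 0, mag), cmap="inferno", alpha=0.5)
    xx, yy, u, v = quiver_landmarks(explanation.flow, grid)
    ax.quiver(xx, yy, u, -v, color="cyan", scale=20, width=0.003)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


# ------------------------------ occlusion ----------------------------------


def occlusion_explanation(
    image: np.ndarray,
    model: ConvVAE,
    predict_proba,
    patch: int = 16,
    stride: int = 8,
) -> np.ndarray:
    """Occlusion saliency for a classifier consuming this eye's latents.

    ``predict_proba`` maps a latent mean vector to a CVD+ probability.
    A mean-intensity patch slides over the image; saliency at each location
    is the drop in predicted probability, normalised to [0, 1] (all-zero if
    the probability never changes).
    """
    img = np.asarray(image, dtype=np.float32)
    H, W = img.shape
    if patch > H or patch > W:
        raise ConfigurationError("patch larger than image")
    base_prob = float(predict_proba(model.encode(img).mean))
    fill = float(img.mean())

    saliency = np.zeros_like(img, dtype=np.float64)
    counts = np.zeros_like(img, dtype=np.float64)
    tops = list(range(0, H - patch + 1, stride))
    lefts = list(range(0, W - patch + 1, stride))
    if tops[-1] != H - patch:
        tops.append(H - patch)
    if lefts[-1] != W - patch:
        lefts.append(W - patch)
    occluded = []
    positions = [(t, l) for t in tops for l in lefts]
    for t, l in positions:
        im = img.copy()
        im[t : t + patch, l : l + patch] = fill
        occluded.append(im)
    codes = model.encode(np.stack(occluded))
    for (t, l), zmean in zip(positions, np.atleast_2d(codes.mean)):
        drop = base_prob - float(predict_proba(zmean))
        saliency[t : t + patch, l : l + patch] += drop
        counts[t : t + patch, l : l + patch] += 1.0
    saliency = saliency / np.maximum(counts, 1.0)
    lo, hi = saliency.min(), saliency.max()
    if hi - lo == 0:
        return np.zeros_like(saliency)
    return (saliency - lo) / (hi - lo)
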