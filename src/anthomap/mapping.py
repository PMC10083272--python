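"""Per-pixel anthocyanin prediction maps and their rendering.

Every ROI pixel's spectrum passes through the bundle's frozen transform
chain (crop -> per-pixel SNV -> band subset or auto-encoder features ->
model), yielding a concentration map aligned to the fruit mask. Maps of
different scenes rendered under a shared color scale are directly
comparable across varieties and maturity stages.
"""

from __future__ import annotations

import numpy as np

from .bundle import ModelBundle
from .models import r2_score
from .types import FruitMask, GroundTruth, PredictionMap, SpectralCube


def predict_map(
    refl: SpectralCube, mask: FruitMask, bundle: ModelBundle, batch_size: int = 8192
) -> PredictionMap:
    """Apply a trained bundle to every masked pixel.

    Batched and pixel-order independent: each pixel's SNV uses only its
    own spectrum, so any batching yields identical results.
    """
    if mask.shape != refl.shape[:2]:
        raise ValueError("mask shape does not match cube")
    rows, cols = np.nonzero(mask.grid)
    values = np.full(mask.shape, np.nan)
    spectra = refl.values[rows, cols].astype(np.float64)
    preds = np.empty(len(rows))
    for s in range(0, len(rows), batch_size):
        preds[s : s + batch_size] = bundle.predict(
            spectra[s : s + batch_size], refl.wavelengths
        )
    values[rows, cols] = preds
    return PredictionMap(values=values, mask=mask)


def render_map(
    pm: PredictionMap,
    out,
    scale: tuple[float, float] | None = None,
    cmap: str = "plasma",
    title: str | None = None,
):
    """Render a pseudocolor PNG with a colorbar (mg/g).

    The map data itself is never mutated: values outside ``scale`` are
    clipped by the color normalization only. Background (non-ROI) pixels
    render neutral gray. Deterministic: identical inputs give
    byte-identical files.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if scale is None:
        mv = pm.masked_values
        scale = (float(np.percentile(mv, 1)), float(np.percentile(mv, 99)))
    if not scale[0] < scale[1]:
        raise ValueError("scale min must be < scale max")
    masked = np.ma.masked_invalid(pm.values)
    fig, ax = plt.subplots(figsize=(4.2, 4.0), dpi=120)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("0.85")
    im = ax.imshow(masked, cmap=cm, vmin=scale[0], vmax=scale[1], interpolation="nearest")
    fig.colorbar(im, ax=ax, label="anthocyanin content (mg/g)")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.savefig(out, bbox_inches="tight", metadata={"Software": "anthomap"})
    plt.close(fig)
    return out


def map_statistics(pm: PredictionMap, truth: GroundTruth) -> dict:
    """Pixelwise agreement between a prediction map and ground truth over
    the intersection of the prediction mask and the true fruit mask."""
    if pm.values.shape != truth.concentration_map.shape:
        raise ValueError("map and truth shapes differ")
    inter = pm.mask.grid & truth.fruit_mask.grid
    if not inter.any():
        raise ValueError("empty intersection between prediction and truth masks")
    pred = pm.values[inter]
    true = truth.concentration_map[inter]
    return {
        "pixelwise_r2": r2_score(true, pred),
        "pixelwise_rmse": float(np.sqrt(np.mean((true - pred) ** 2))),
        "mean_content_error": float(pred.mean() - true.mean()),
        "n_pixels": int(inter.sum()),
    }
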