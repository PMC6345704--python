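"""End-to-end orchestration: image -> ranked interpretations -> artifacts.

``run_pipeline`` ties the modules together: it loads (or receives) an
image, searches for multiple interpretations with the frozen
configuration, classifies each as illusory or not, optionally extracts
the top-most object mask, and writes everything — ``.bo`` maps, quiver
renderings, a machine-readable ``ranking.json`` and the resolved config —
into a run directory.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np

from . import stimuli
from .bo_core import bo_distance, save_bo
from .config import RunConfig, default_config
from .contour import evolve, seed_contour
from .interpreter import ImageObjective, classify_illusory, find_interpretations

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "render_bo_map"]


def run_pipeline(image, config: RunConfig | None = None, out_dir: str | None = None,
                 extract_mask: bool = True, render: bool = True) -> dict:
    """Run the full interpretation pipeline on an image.

    ``image`` may be a 2-D array or a path to a raster file.  Returns the
    ranking manifest (also written as ``ranking.json`` when ``out_dir`` is
    given): per-interpretation cost, rank, illusory flag and score, and
    pairwise distances.
    """
    config = config or default_config()
    if isinstance(image, (str, os.PathLike)):
        image = stimuli.read_raster(os.fspath(image))
    image = np.asarray(image, dtype=float)

    objective = ImageObjective(image, config.model, config.multipliers)
    interps = find_interpretations(
        objective, seed=config.seed, schedule=config.schedule,
        settings=config.descent, repulsion=config.repulsion,
        final_settings=config.final_descent)

    entries = []
    for it in interps:
        flag, score = classify_illusory(it, image, config.model,
                                        config.illusory_fraction_threshold)
        entries.append({"rank": it.rank, "cost": it.cost, "illusory": bool(flag),
                        "illusory_score": round(score, 6),
                        "provenance": {k: v for k, v in it.provenance.items()}})
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "image_shape": list(image.shape),
        "interpretations": entries,
        "pairwise_distances": [
            [round(bo_distance(a.bo_map, b.bo_map), 6) for b in interps]
            for a in interps
        ],
    }

    if extract_mask and interps:
        # extract from the smoothed map — the representation the functional
        # scores; raw maps carry cost-invisible high-frequency mass that
        # would spuriously stop the contour
        from .bo_core import smooth_bo

        c = smooth_bo(interps[0].bo_map, config.model.sigma_sa,
                      config.model.sigma_sx)
        mask = evolve(seed_contour(c, config.contour), c)
        manifest["top_object_area"] = int(mask.sum())
    else:
        mask = None

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        config.to_yaml(os.path.join(out_dir, "config.yaml"))
        for it in interps:
            save_bo(it.bo_map, it.cost, os.path.join(out_dir, f"interp_{it.rank}.bo"),
                    meta={"seed": config.seed, "config_digest": config.digest(),
                          **{k: v for k, v in it.provenance.items()}})
            if render:
                render_bo_map(it.bo_map, image,
                              os.path.join(out_dir, f"interp_{it.rank}.png"))
        if mask is not None:
            stimuli.write_raster(mask.astype(float),
                                 os.path.join(out_dir, "top_object_mask.png"))
        with open(os.path.join(out_dir, "ranking.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def render_bo_map(b, image, path: str, highlight_fraction: float = 0.8) -> None:
    """Quiver rendering of a BO map over the input image.

    One arrow per site and direction with length proportional to |b|;
    arrows above ``highlight_fraction`` of the map maximum are drawn in
    magenta, the rest in black; image edges are overdrawn in green for
    reference.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    b = np.asarray(b, dtype=float)
    image = np.asarray(image, dtype=float)
    H, W, L = b.shape
    mag = np.abs(b)
    vmax = mag.max()
    fig, ax = plt.subplots(figsize=(max(4, W / 5), max(4, H / 5)))
    ax.imshow(image, cmap="gray", vmin=0, vmax=1, interpolation="nearest")
    # image edges (pixel-difference contours) in green
    gy, gx = np.gradient(image)
    edge = np.hypot(gx, gy)
    if edge.max() > 0:
        ax.contour(edge, levels=[0.5 * edge.max()], colors="lime", linewidths=0.8)
    if vmax > 0:
        a = 2.0 * np.pi * np.arange(L) / L
        scale = 0.9 / vmax
        ys, xs, ls = np.nonzero(mag > 0.05 * vmax)
        u = np.cos(a[ls]) * mag[ys, xs, ls] * scale
        v = np.sin(a[ls]) * mag[ys, xs, ls] * scale  # display y-up; invert_yaxis off
        hi = mag[ys, xs, ls] >= highlight_fraction * vmax
        for sel, color, z in ((~hi, "black", 2), (hi, "magenta", 3)):
            if sel.any():
                ax.quiver(xs[sel], ys[sel], u[sel], -v[sel], color=color,
                          angles="xy", scale_units="xy", scale=1.0,
                          width=0.004, zorder=z)
    ax.set_xlim(-0.5, W - 0.5)
    ax.set_ylim(H - 0.5, -0.5)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
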