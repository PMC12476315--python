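"""Evaluation tables, per-attribute performance breakdown, model comparison.

Tables mirror the usual segmentation-paper style: per-image IoU/Dice with a
mean ± sd summary row (population sd by default, switchable), percentages
to two decimals; the per-attribute breakdown is the tabular twin of a
boxplot (median, quartiles, 1.5·IQR outlier flags per attribute category).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .architectures import MetaUNet, images_to_batch
from .data_model import LesionSample, MetadataSchema
from .training import dice_metric, iou_metric


def evaluate(model: MetaUNet, test_samples: list[LesionSample],
             batch_size: int = 16, population_sd: bool = True) -> pd.DataFrame:
    """Per-image IoU/Dice (as percentages) plus a mean ± sd summary row."""
    if not test_samples:
        raise ValueError("empty test split")
    rows = []
    for i in range(0, len(test_samples), batch_size):
        chunk = test_samples[i:i + batch_size]
        imgs, masks, meta = images_to_batch(chunk)
        meta_arg = meta if model.cfg.fusion_strategy != "none" else None
        probs = model.predict(imgs, meta_arg)
        for s, p, m in zip(chunk, probs, masks):
            rows.append({"id": s.id,
                         "iou": round(100.0 * iou_metric(p, m), 2),
                         "dice": round(100.0 * dice_metric(p, m), 2)})
    df = pd.DataFrame(rows)
    return append_summary(df, population_sd)


def append_summary(per_image: pd.DataFrame, population_sd: bool = True) -> pd.DataFrame:
    ddof = 0 if population_sd else 1
    summary = {"id": "mean±sd"}
    for col in ("iou", "dice"):
        summary[col] = round(float(per_image[col].mean()), 2)
        summary[f"{col}_sd"] = round(float(per_image[col].std(ddof=ddof)), 2)
    out = per_image.copy()
    for col in ("iou_sd", "dice_sd"):
        if col not in out.columns:
            out[col] = np.nan
    out.loc[len(out)] = {**{c: np.nan for c in out.columns}, **summary}
    return out


def report_attributes(per_image_iou: pd.Series, metadata: pd.DataFrame,
                      schema: MetadataSchema) -> pd.DataFrame:
    """IoU distribution per attribute category (boxplot statistics).

    ``per_image_iou`` is indexed by image id; ``metadata`` holds the raw
    29-column vectors with an ``id`` column.  Categories with zero images
    are emitted with count 0 and no statistics.
    """
    meta = metadata.set_index("id") if "id" in metadata.columns else metadata
    missing = set(per_image_iou.index) - set(meta.index)
    if missing:
        raise ValueError(f"metadata missing for ids {sorted(missing)[:5]}")
    rows = []
    for (group, category), col in zip(schema.column_map(), schema.column_names()):
        member_ids = meta.index[meta[col] == 1].intersection(per_image_iou.index)
        vals = per_image_iou.loc[member_ids].to_numpy(dtype=float)
        row = {"group": group, "category": category, "count": len(vals)}
        if len(vals):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            out_lo, out_hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            row.update({"median": med, "q1": q1, "q3": q3,
                        "n_outliers": int(((vals < out_lo) | (vals > out_hi)).sum())})
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(report_a: pd.DataFrame, report_b: pd.DataFrame,
                   eval_a: pd.DataFrame | None = None,
                   eval_b: pd.DataFrame | None = None,
                   names: tuple[str, str] = ("model_A", "model_B")) -> pd.DataFrame:
    """Cohort comparison: mean U_tot per model (+ mean IoU/Dice if given).

    Both uncertainty reports must come from the same cohort definition,
    normalised per model; paired per-image differences require matching ids.
    """
    ids_a, ids_b = set(report_a.index), set(report_b.index)
    if ids_a != ids_b:
        raise ValueError("cohort mismatch: the two reports cover different ids")
    rows = []
    for name, rep, ev in ((names[0], report_a, eval_a), (names[1], report_b, eval_b)):
        row = {"model": name, "mean_u_tot": float(rep["u_tot"].mean())}
        for m in ("C", "H", "MI", "EPKL"):
            row[f"mean_{m}"] = float(rep[f"mean_{m}"].mean())
        if ev is not None:
            per_image = ev[ev["id"] != "mean±sd"]
            row["mean_iou"] = float(per_image["iou"].mean())
            row["mean_dice"] = float(per_image["dice"].mean())
        rows.append(row)
    summary = pd.DataFrame(rows)
    diffs = (report_a["u_tot"] - report_b.loc[report_a.index, "u_tot"])
    summary.attrs["paired_u_tot_diff"] = diffs
    summary.attrs["mean_paired_u_tot_diff"] = float(diffs.mean())
    return summary


# ---------------------------------------------------------------------
# artifact writers
# ---------------------------------------------------------------------

def write_uncertainty_maps(report, out_dir) -> None:
    """Write each map as 32-bit TIFF plus an 8-bit colormapped PNG preview."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cmap = plt.get_cmap("viridis")
    for name, arr in report.maps.items():
        tifffile.imwrite(out_dir / f"{report.sample_id}_{name}.tif",
                         arr.astype(np.float32))
        lo, hi = float(arr.min()), float(arr.max())
        norm = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        rgb = (cmap(norm)[:, :, :3] * 255).astype(np.uint8)
        Image.fromarray(rgb).save(out_dir / f"{report.sample_id}_{name}.png")


def plot_attribute_boxes(per_image_iou: pd.Series, metadata: pd.DataFrame,
                         schema: MetadataSchema, path) -> None:
    """Basic boxplot rendering of the per-attribute IoU breakdown."""
    meta = metadata.set_index("id") if "id" in metadata.columns else metadata
    labels, data = [], []
    for (group, category), col in zip(schema.column_map(), schema.column_names()):
        ids = meta.index[meta[col] == 1].intersection(per_image_iou.index)
        if len(ids):
            labels.append(f"{group}\n{category}")
            data.append(per_image_iou.loc[ids].to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(labels)), 4))
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("IoU")
    ax.tick_params(axis="x", labelsize=6, rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mean_uncertainty(summary: pd.DataFrame, path) -> None:
    """Bar chart of mean aggregate uncertainty score per model."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(summary["model"], summary["mean_u_tot"])
    ax.set_ylabel("mean $U_{tot}$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
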