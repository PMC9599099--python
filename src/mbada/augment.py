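"""Adversarial-training augmentation and degradation tabulation.

Retraining a model on a mix of clean images and moment-attacked copies
over a range of orders makes it robust to the attack.  This module
builds such augmented datasets — attacked copies inherit the source
label or mask unchanged — and tabulates, for any pluggable predictor,
how task performance and SSIM degrade as the attack order drops.
Model training itself is out of scope: the predictor is an opaque
callable, so the protocol can be replayed against anything from a
thresholding baseline to a trained network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .attack import AttackConfig, attack_image
from .image import IntensityImage, as_image
from .metrics import SSIMParams, iou, mean_ssim_percent

__all__ = [
    "AugmentationPlan",
    "build_augmented_set",
    "degradation_table",
    "threshold_segmenter",
]

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["source", "order", "label", "path", "status"]


@dataclass(frozen=True)
class AugmentationPlan:
    """Order grid and inclusion policy for dataset augmentation.

    One attacked copy is emitted per source image and per order in
    ``order_min, order_min + order_step, ..., <= order_max``.  The
    default step of 20 matches the granularity attack orders are usually
    reported at.  Attacked copies always keep the source label
    (``label_policy='inherit'`` is the only policy).
    """

    order_min: int
    order_max: int
    order_step: int = 20
    include_originals: bool = True
    label_policy: str = "inherit"

    def __post_init__(self) -> None:
        if self.order_min > self.order_max:
            raise ValueError("order_min must be <= order_max")
        if self.order_step < 1:
            raise ValueError("order_step must be >= 1")
        if self.order_min < 0:
            raise ValueError("orders must be non-negative")
        if self.label_policy != "inherit":
            raise ValueError("'inherit' is the only label policy")

    @property
    def orders(self) -> list[int]:
        return list(range(self.order_min, self.order_max + 1, self.order_step))


def build_augmented_set(
    sources,
    plan: AugmentationPlan,
    output_sink: str | Path,
    encoding: str = "eight_bit",
) -> pd.DataFrame:
    """Emit attacked copies of every source at every planned order.

    ``sources`` is a non-empty sequence of ``(source_id, image, label)``
    triples; ``image`` may be an :class:`IntensityImage`, an array, or a
    file path, and ``label`` is a class label or a mask path — it is
    copied through untouched.  Orders above an image's cap
    ``min(N, M) - 1`` are skipped and recorded.  Filenames encode the
    order (``<id>__mbada_K<order>``), so a standard training loader can
    consume the output directory unchanged.

    Returns the manifest, also written to ``manifest.csv`` in the sink.
    """
    sources = list(sources)
    if not sources:
        raise ValueError("source set is empty")
    out_dir = Path(output_sink)
    out_dir.mkdir(parents=True, exist_ok=True)
    probe = out_dir / ".write_probe"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output sink {out_dir} is not writable: {exc}") from exc

    suffix = ".png" if encoding == "eight_bit" else ".tif"
    rows = []
    for sid, source, label in sources:
        img = (
            IntensityImage.load(source)
            if isinstance(source, (str, Path))
            else as_image(source)
        )
        if plan.include_originals:
            path = out_dir / f"{sid}__original{suffix}"
            img.save(path, encoding)
            rows.append({"source": sid, "order": "original", "label": label,
                         "path": str(path), "status": "ok"})
        cap = min(img.height, img.width) - 1
        for order in plan.orders:
            if order > cap:
                log.info("skipping order %d for %s (cap %d)", order, sid, cap)
                rows.append({"source": sid, "order": order, "label": label,
                             "path": "", "status": f"skipped: order exceeds cap {cap}"})
                continue
            result = attack_image(
                img, AttackConfig(order=order, output_encoding=encoding)
            )
            path = out_dir / f"{sid}__mbada_K{order}{suffix}"
            result.adversarial.save(path, encoding)
            rows.append({"source": sid, "order": order, "label": label,
                         "path": str(path), "status": "ok"})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _score(prediction, truth) -> float:
    if isinstance(truth, np.ndarray):
        return iou(np.asarray(prediction), truth)
    return 1.0 if prediction == truth else 0.0


def degradation_table(
    predictor,
    evaluation_set,
    orders,
    ssim_params: SSIMParams | None = None,
) -> pd.DataFrame:
    """Tabulate predictor performance and SSIM across attack orders.

    ``evaluation_set`` is a sequence of ``(image, truth)`` pairs where
    ``truth`` is a class label (scored by accuracy) or a binary mask
    array (scored by mean IoU).  The first row is the attack-free
    baseline with SSIM fixed at 100%.  Predictor failures on individual
    items are recorded and excluded from that row's means.

    Returns a table with columns ``order``, ``mean_ssim_pct``, ``score``,
    ``n_items``, ``n_excluded``.
    """
    items = [(as_image(img), truth) for img, truth in evaluation_set]
    if not items:
        raise ValueError("evaluation set is empty")

    def evaluate(attacked_pairs, ssim_pct):
        scores, excluded = [], 0
        for adv, truth in attacked_pairs:
            try:
                scores.append(_score(predictor(adv), truth))
            except Exception as exc:  # noqa: BLE001 — isolate predictor faults
                log.warning("predictor failed: %s", exc)
                excluded += 1
        return {
            "mean_ssim_pct": ssim_pct,
            "score": float(np.mean(scores)) if scores else float("nan"),
            "n_items": len(scores),
            "n_excluded": excluded,
        }

    rows = [{"order": "attack_free",
             **evaluate(items, 100.0)}]
    for order in orders:
        attacked, ssims = [], []
        for img, truth in items:
            cap = min(img.height, img.width) - 1
            res = attack_image(img, AttackConfig(order=min(order, cap),
                                                 output_encoding="float"))
            attacked.append((res.adversarial, truth))
            ssims.append(mean_ssim_percent(img, res.adversarial, ssim_params))
        rows.append({"order": order, **evaluate(attacked, float(np.mean(ssims)))})
    table = pd.DataFrame(rows, columns=["order", "mean_ssim_pct", "score",
                                        "n_items", "n_excluded"])
    return table


def threshold_segmenter(image: IntensityImage | np.ndarray) -> np.ndarray:
    """Otsu-threshold baseline segmenter: bright foreground mask.

    The simplest predictor satisfying the pluggable contract; useful for
    exercising the segmentation protocol on nuclei-like fixtures.
    """
    img = as_image(image)
    gray = img.pixels if img.channels == 1 else img.pixels.mean(axis=-1)
    return gray > threshold_otsu(gray)
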