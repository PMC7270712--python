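"""Overlap metrics for validating segmentations and registrations.

The Dice similarity coefficient 2|A∩B| / (|A| + |B|) is the standard
measure of agreement between two segmentations; ``regional_dice`` applies
it label by label between two atlases on the same grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .images import LabelImage, MaskImage

__all__ = ["dice", "regional_dice"]


def _binary(mask) -> np.ndarray:
    data = mask.data if hasattr(mask, "data") else np.asarray(mask)
    return data.astype(bool)


def dice(mask_a, mask_b) -> float:
    """Dice similarity coefficient of two binary masks on one grid.

    Both masks empty is defined as perfect (trivial) agreement, 1.0;
    exactly one empty gives 0.0 — the set formula is 0/0 there.
    """
    a = _binary(mask_a)
    b = _binary(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks are on different grids")
    if (hasattr(mask_a, "affine") and hasattr(mask_b, "affine")
            and not np.allclose(mask_a.affine, mask_b.affine, atol=1e-6)):
        raise ValueError("masks are on different grids (affines differ)")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int((a & b).sum())
    return 2.0 * inter / (na + nb)


def regional_dice(labels_a: LabelImage, labels_b: LabelImage) -> pd.DataFrame:
    """Per-label Dice between two label images on one grid.

    One row per nonzero label present in either image (a label missing from
    one side scores 0.0); background 0 is excluded.  Columns: label, name
    (when known), dice, n_voxels_a, n_voxels_b.
    """
    if labels_a.shape != labels_b.shape:
        raise ValueError("label images are on different grids")
    if not np.allclose(labels_a.affine, labels_b.affine, atol=1e-6):
        raise ValueError("label images are on different grids (affines "
                         "differ)")
    ids = sorted(set(labels_a.labels()) | set(labels_b.labels()))
    rows = []
    for lid in ids:
        a = labels_a.data == lid
        b = labels_b.data == lid
        na, nb = int(a.sum()), int(b.sum())
        d = 1.0 if na == nb == 0 else 2.0 * int((a & b).sum()) / (na + nb)
        name = None
        for src in (labels_a, labels_b):
            if src.label_names and int(lid) in src.label_names:
                name = src.label_names[int(lid)]
                break
        rows.append({"label": int(lid), "name": name, "dice": float(d),
                     "n_voxels_a": na, "n_voxels_b": nb})
    return pd.DataFrame(rows)
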