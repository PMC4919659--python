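"""Cell segmentation from donor and acceptor intensity images.

Thresholding + connected components: a pixel belongs to a cell when its
donor intensity exceeds ``background + k * sigma`` (robust sigma from the
median absolute deviation of the image) and — for co-transfection
conditions — its acceptor intensity does likewise.  Small objects are
dropped; cells touching the image border are excluded by default since
their per-cell means would be biased.
"""

from __future__ import annotations

import numpy as np
from skimage import measure, morphology, segmentation as sk_seg

__all__ = ["robust_sigma", "segment_cells"]


def robust_sigma(image: np.ndarray) -> float:
    """MAD-based noise scale, consistent for a Gaussian (1.4826 * MAD)."""
    img = np.asarray(image, dtype=float)
    med = np.median(img)
    return float(1.4826 * np.median(np.abs(img - med)))


def segment_cells(
    donor_image: np.ndarray,
    acceptor_image: np.ndarray | None = None,
    donor_background: float = 0.0,
    acceptor_background: float = 0.0,
    k: float = 5.0,
    min_area: int = 100,
    exclude_border: bool = True,
) -> np.ndarray:
    """Label cells from intensity images; 0 = background.

    ``acceptor_image=None`` segments on donor intensity alone (donor-only
    wells); otherwise pixels must clear both channel thresholds, so cells
    expressing only the donor are excluded from co-transfection conditions.
    An empty image yields an empty mask, not an error.
    """
    donor = np.asarray(donor_image, dtype=float)
    mask = donor > donor_background + k * robust_sigma(donor)
    if acceptor_image is not None:
        acc = np.asarray(acceptor_image, dtype=float)
        if acc.shape != donor.shape:
            raise ValueError("donor and acceptor images must be co-registered")
        mask &= acc > acceptor_background + k * robust_sigma(acc)
    mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    if exclude_border:
        mask = sk_seg.clear_border(mask)
    labels = measure.label(mask, connectivity=2)
    return labels.astype(np.int32)
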