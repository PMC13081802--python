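"""Single-cell radial fluorescence profiling and the PNPR statistic.

For a segmented cell (nucleus + whole-cell mask), every cytoplasmic pixel
gets a normalized radial coordinate d in [0, 1] — 0 at the nuclear
boundary, 1 at the cell boundary — computed from two Euclidean distance
transforms (distance to the nucleus edge and to the cell edge), which keeps
the coordinate meaningful for non-circular cells.  Binned intensity means
and standard deviations along d form the radial profile; the
perinuclear-to-peripheral ratio (PNPR) is the mean signal in the inner
band of the cytoplasm (default d < 0.25) divided by the mean in the outer
band (default d >= 0.75).  PNPR > 1 indicates perinuclear enrichment and is
invariant to global intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import disk

__all__ = [
    "CellImage",
    "CellMasks",
    "RadialProfile",
    "PNPRResult",
    "SegmentationError",
    "segment_cell",
    "normalized_distance",
    "radial_profile",
    "compute_pnpr",
    "compare_conditions",
]


class SegmentationError(RuntimeError):
    """Raised when nucleus or cytoplasm cannot be segmented."""


@dataclass(frozen=True)
class CellImage:
    """Two-channel single-cell crop: signal + DNA counterstain."""

    signal_channel: np.ndarray
    dna_channel: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        s, d = np.asarray(self.signal_channel), np.asarray(self.dna_channel)
        if s.ndim != 2 or s.shape != d.shape:
            raise ValueError("channels must be 2-D arrays of equal shape")
        if not (np.isfinite(s).all() and np.isfinite(d).all()):
            raise ValueError("intensities must be finite")
        if (s < 0).any() or (d < 0).any():
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "signal_channel", s.astype(float))
        object.__setattr__(self, "dna_channel", d.astype(float))


@dataclass(frozen=True)
class CellMasks:
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray

    def __post_init__(self) -> None:
        nuc = np.asarray(self.nucleus_mask, dtype=bool)
        cell = np.asarray(self.cell_mask, dtype=bool)
        if nuc.shape != cell.shape:
            raise ValueError("masks must have equal shapes")
        if not nuc.any():
            raise ValueError("nucleus mask is empty")
        if (nuc & ~cell).any():
            raise ValueError("nucleus mask must be contained in cell mask")
        if not (cell & ~nuc).any():
            raise ValueError("cytoplasm (cell minus nucleus) is empty")
        object.__setattr__(self, "nucleus_mask", nuc)
        object.__setattr__(self, "cell_mask", cell)

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        return self.cell_mask & ~self.nucleus_mask


@dataclass(frozen=True)
class RadialProfile:
    """Binned intensity statistics over normalized cytoplasmic distance."""

    bin_edges: np.ndarray  # n_bins + 1 edges over [0, 1]
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.mean)


@dataclass(frozen=True)
class PNPRResult:
    ctrl_values: np.ndarray
    treat_values: np.ndarray
    mean_ctrl: float
    mean_treat: float
    fold_change: float
    p: float


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def segment_cell(image: CellImage, masks: CellMasks | None = None) -> CellMasks:
    """Segment nucleus and whole cell; pass ``masks`` to bypass (identity).

    Nucleus: Otsu threshold on the DNA channel, largest connected
    component, holes filled.  Cell: Otsu threshold on the signal channel,
    morphological closing, holes filled, union with the nucleus, largest
    component containing it.  Raises :class:`SegmentationError` naming the
    failing stage.
    """
    if masks is not None:
        return masks
    dna = image.dna_channel
    if dna.max() <= dna.min():
        raise SegmentationError("nucleus: DNA channel has no contrast")
    nucleus = dna > threshold_otsu(dna)
    nucleus = ndimage.binary_fill_holes(_largest_component(nucleus))
    if not nucleus.any():
        raise SegmentationError("nucleus: empty after thresholding")
    signal = image.signal_channel
    if signal.max() <= signal.min():
        raise SegmentationError("cell: signal channel has no contrast")
    cell = signal > threshold_otsu(signal)
    cell = ndimage.binary_closing(cell, structure=disk(2))
    cell = ndimage.binary_fill_holes(cell | nucleus)
    cell = _largest_component(cell)
    nucleus = nucleus & cell
    if not nucleus.any():
        raise SegmentationError("nucleus: eliminated by cell mask")
    if not (cell & ~nucleus).any():
        raise SegmentationError("cytoplasm: empty after segmentation")
    return CellMasks(nucleus_mask=nucleus, cell_mask=cell)


def normalized_distance(masks: CellMasks) -> np.ndarray:
    """Normalized radial coordinate d for every pixel (NaN outside cytoplasm).

    d = dist_to_nucleus_edge / (dist_to_nucleus_edge + dist_to_cell_edge),
    both distances from Euclidean distance transforms.
    """
    d_nuc = ndimage.distance_transform_edt(~masks.nucleus_mask)
    d_cell = ndimage.distance_transform_edt(masks.cell_mask)
    cyto = masks.cytoplasm_mask
    out = np.full(masks.cell_mask.shape, np.nan)
    denom = d_nuc[cyto] + d_cell[cyto]
    out[cyto] = d_nuc[cyto] / np.where(denom == 0, 1.0, denom)
    return out


def radial_profile(image: CellImage, masks: CellMasks, n_bins: int = 20) -> RadialProfile:
    """Bin cytoplasmic signal intensity by normalized radial distance.

    Every cytoplasmic pixel lands in exactly one of ``n_bins`` equal-width
    bins over [0, 1] (d = 1 joins the last bin); per-bin counts sum to the
    cytoplasm size.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    d = normalized_distance(masks)
    cyto = masks.cytoplasm_mask
    values = image.signal_channel[cyto]
    bins = np.minimum((d[cyto] * n_bins).astype(int), n_bins - 1)
    count = np.bincount(bins, minlength=n_bins)
    total = np.bincount(bins, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        sq = np.bincount(bins, weights=values**2, minlength=n_bins)
        var = np.where(count > 0, sq / np.maximum(count, 1) - mean**2, np.nan)
    sd = np.sqrt(np.maximum(var, 0.0))
    return RadialProfile(
        bin_edges=np.linspace(0.0, 1.0, n_bins + 1),
        mean=mean,
        sd=sd,
        count=count,
    )


def compute_pnpr(
    profile: RadialProfile,
    perinuclear_band: tuple[float, float] = (0.0, 0.25),
    peripheral_band: tuple[float, float] = (0.75, 1.0),
) -> float:
    """Perinuclear-to-peripheral ratio from a radial profile.

    Band means are pixel-count-weighted over the bins whose centers fall in
    the band.  Empty bands or a zero peripheral mean are errors.
    """

    def band_mean(band: tuple[float, float]) -> float:
        lo, hi = band
        centers = (profile.bin_edges[:-1] + profile.bin_edges[1:]) / 2
        inclusive_hi = centers <= hi if hi >= 1.0 else centers < hi
        sel = (centers >= lo) & inclusive_hi & (profile.count > 0)
        if not sel.any():
            raise ValueError(f"band {band} contains no pixels")
        w = profile.count[sel]
        return float(np.sum(profile.mean[sel] * w) / np.sum(w))

    peri = band_mean(perinuclear_band)
    periph = band_mean(peripheral_band)
    if periph <= 0:
        raise ValueError("peripheral band mean is zero; PNPR undefined")
    return peri / periph


def compare_conditions(ctrl_cells, treat_cells) -> PNPRResult:
    """Compare per-cell PNPR values between conditions.

    Fold change is mean(treat)/mean(ctrl); the p-value is a two-tailed
    Welch (unequal-variance) t-test.  Groups with zero variance resolve
    deterministically: equal means give p = 1, unequal means p = 0.
    """
    ctrl = np.asarray(ctrl_cells, dtype=float)
    treat = np.asarray(treat_cells, dtype=float)
    if len(ctrl) < 2 or len(treat) < 2:
        raise ValueError("need >= 2 cells per condition")
    if (ctrl <= 0).any() or (treat <= 0).any():
        raise ValueError("PNPR values must be positive")
    if ctrl.var(ddof=1) == 0 and treat.var(ddof=1) == 0:
        p = 1.0 if ctrl.mean() == treat.mean() else 0.0
    else:
        p = float(stats.ttest_ind(treat, ctrl, equal_var=False).pvalue)
    return PNPRResult(
        ctrl_values=ctrl,
        treat_values=treat,
        mean_ctrl=float(ctrl.mean()),
        mean_treat=float(treat.mean()),
        fold_change=float(treat.mean() / ctrl.mean()),
        p=p,
    )
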