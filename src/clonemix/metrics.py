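"""Summary statistics of clone maps: subclone frequency and the
quadrat-based Shannon mixing score.

The mixing score overlays a regular grid of square quadrats on the
occupied bounding box of a clone map and averages the binary entropy of
the local mutant fraction:

    S = - sum_i [ p_i log2 p_i + (1 - p_i) log2(1 - p_i) ] / n

where p_i is the mutant fraction among tumor positions in quadrat i and
n counts quadrats that contain at least one tumor position. S is 1 when
mutant and wild-type cells are fully mixed (every quadrat half-and-half)
and 0 when the clones are completely spatially separated (every quadrat
pure). Both statistics are computed identically for simulated lattices
and annotated section maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.special import xlogy

from .simulator import WT, MUT

__all__ = [
    "NON_TUMOR",
    "CloneMap",
    "QuadratSpec",
    "SummaryPair",
    "mutant_frequency",
    "shannon_entropy",
    "summarize",
    "quadrat_fractions",
]

#: Label for positions outside the tumor (same code as the simulator's EMPTY).
NON_TUMOR: int = 0


@dataclass
class CloneMap:
    """A labeled 2D raster: 0=NON_TUMOR, 1=WT, 2=MUT.

    ``pixel_size`` is the physical side length of one pixel in microns,
    if known (absent for simulated lattices).
    """

    labels: np.ndarray
    pixel_size: Optional[float] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D array")

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class QuadratSpec:
    """Quadrat overlay: square tiles of ``quadrat_side`` positions,
    anchored at the top-left corner of the occupied bounding box.
    Partial quadrats at the far edges are kept."""

    quadrat_side: int
    origin: str = "bbox"

    def __post_init__(self):
        if self.quadrat_side < 1:
            raise ValueError("quadrat_side must be >= 1")
        if self.origin != "bbox":
            raise ValueError("only 'bbox' anchoring is supported")

    @classmethod
    def for_target_count(cls, cmap: CloneMap, target: int = 100) -> "QuadratSpec":
        """Choose the side so the occupied bounding box yields about
        ``target`` quadrats (the annotated sections averaged 96)."""
        rows, cols = _bbox(cmap)
        area = len(rows) * len(cols)
        side = max(1, int(round(np.sqrt(area / target))))
        return cls(quadrat_side=side)

    @classmethod
    def from_physical(
        cls,
        pixel_size: float,
        area_um2: Optional[float] = 1300.0,
        side_um: Optional[float] = None,
    ) -> "QuadratSpec":
        """Derive the side in pixels from a physical quadrat size.

        Either a target quadrat area in square microns (default 1300)
        or an explicit side length in microns. Both conventions are
        offered because reported physical quadrat sizes are sometimes
        quoted as areas and sometimes as side lengths.
        """
        if pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if side_um is not None:
            side = side_um / pixel_size
        else:
            side = np.sqrt(area_um2) / pixel_size
        return cls(quadrat_side=max(1, int(round(side))))


class SummaryPair(NamedTuple):
    """The (mutant frequency, mixing score) vector matched by ABC."""

    frequency: float
    entropy: float


def _bbox(cmap: CloneMap):
    occ = cmap.labels != NON_TUMOR
    rows = np.flatnonzero(occ.any(axis=1))
    cols = np.flatnonzero(occ.any(axis=0))
    if rows.size == 0:
        raise ValueError("clone map contains no tumor positions")
    return np.arange(rows[0], rows[-1] + 1), np.arange(cols[0], cols[-1] + 1)


def mutant_frequency(cmap: CloneMap) -> float:
    """Mutant pixel count divided by total tumor (WT + MUT) pixel count."""
    labels = cmap.labels
    n_mut = int((labels == MUT).sum())
    n_wt = int((labels == WT).sum())
    if n_mut + n_wt == 0:
        raise ValueError("clone map contains no tumor positions")
    return n_mut / (n_mut + n_wt)


def quadrat_fractions(cmap: CloneMap, spec: QuadratSpec):
    """Per-quadrat mutant fractions p_i over quadrats containing tumor.

    Returns ``(p, tumor_counts)`` for the quadrats kept (tumor count
    > 0); quadrats with no tumor positions are dropped.
    """
    rows, cols = _bbox(cmap)
    sub = cmap.labels[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    s = spec.quadrat_side
    h, w = sub.shape
    ph = (-h) % s
    pw = (-w) % s
    if ph or pw:
        sub = np.pad(sub, ((0, ph), (0, pw)), constant_values=NON_TUMOR)
    H, W = sub.shape
    blocks = sub.reshape(H // s, s, W // s, s)
    mut = (blocks == MUT).sum(axis=(1, 3)).ravel()
    tumor = mut + (blocks == WT).sum(axis=(1, 3)).ravel()
    keep = tumor > 0
    return mut[keep] / tumor[keep], tumor[keep]


def shannon_entropy(cmap: CloneMap, spec: QuadratSpec) -> float:
    """Quadrat-averaged binary Shannon entropy of the mutant fraction.

    Base-2 logarithms; 0*log(0) terms are 0; the result is in [0, 1].
    """
    p, _ = quadrat_fractions(cmap, spec)
    with np.errstate(invalid="ignore"):
        h = -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)) / np.log(2.0)
    return float(h.mean())


def summarize(cmap: CloneMap, spec: QuadratSpec) -> SummaryPair:
    """Bundle the two statistics matched by the inference."""
    return SummaryPair(mutant_frequency(cmap), shannon_entropy(cmap, spec))
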