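"""Reading annotated clone-map rasters and generating synthetic ones.

Annotated lesion maps are two-color rasters (mutant regions filled red,
wild-type yellow, everything else background); this module converts
them to label grids and also fabricates synthetic lesions with a
controlled subclone proportion and spatial mixing, spanning the
spectrum seen in real sections: a single compact subclone blob,
striped or interdigitated clone bands, and highly dispersed subclones.
Synthetic maps make every downstream statistic and the ABC inference
testable without any study material.

Label convention everywhere: 0 = NON_TUMOR/EMPTY, 1 = WT, 2 = MUT;
row-major, origin top-left, 0-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .metrics import CloneMap, NON_TUMOR
from .simulator import WT, MUT, LatticeState

__all__ = [
    "PatternKind",
    "MapPattern",
    "FormatError",
    "read_label_grid",
    "write_label_grid",
    "read_color_raster",
    "write_color_raster",
    "generate",
    "DEFAULT_PALETTE",
    "MAX_DISPERSION",
]

#: Default annotation palette: red fills are mutant, yellow wild-type.
DEFAULT_PALETTE: dict = {(255, 0, 0): MUT, (255, 255, 0): WT}

#: Dispersion knob ceiling; at this value SCATTERED places single
#: pixels stratified over 2x2 tiles (maximal mixing).
MAX_DISPERSION: int = 10


class FormatError(ValueError):
    """A label-grid file violates the 0/1/2 delimited-integer format."""


class PatternKind(enum.Enum):
    BLOB = "blob"
    STRIPED = "striped"
    INTERDIGITATED = "interdigitated"
    SCATTERED = "scattered"
    FROM_SIM = "from_sim"


_DEFAULT_DISPERSION = {
    PatternKind.BLOB: 1,
    PatternKind.STRIPED: 4,
    PatternKind.INTERDIGITATED: 6,
    PatternKind.SCATTERED: MAX_DISPERSION,
}


@dataclass
class MapPattern:
    """Recipe for a synthetic clone map.

    ``dispersion`` (1..10) controls fragmentation: band width for the
    striped kinds, patch count for SCATTERED. ``source`` is only used
    by FROM_SIM (a simulator snapshot, its file path, or a lattice
    state to pass through).
    """

    kind: PatternKind
    target_frequency: float = 0.5
    dispersion: Optional[int] = None
    seed: int = 0
    source: Union[CloneMap, LatticeState, str, Path, None] = None

    def __post_init__(self):
        if isinstance(self.kind, str):
            self.kind = PatternKind(self.kind)
        if self.kind is not PatternKind.FROM_SIM and not 0.0 < self.target_frequency < 1.0:
            raise ValueError("target_frequency must be strictly between 0 and 1")
        if self.dispersion is None:
            self.dispersion = _DEFAULT_DISPERSION.get(self.kind, 1)
        if not 1 <= self.dispersion <= MAX_DISPERSION:
            raise ValueError(f"dispersion must be in [1, {MAX_DISPERSION}]")


# ---------------------------------------------------------------- I/O

def read_label_grid(path) -> CloneMap:
    """Read a whitespace-delimited integer grid over {0, 1, 2}."""
    path = Path(path)
    rows = []
    width = None
    with open(path) as fh:
        for r, line in enumerate(fh):
            toks = line.split()
            if not toks:
                continue
            if width is None:
                width = len(toks)
            elif len(toks) != width:
                raise FormatError(
                    f"{path}: ragged row {r} (expected {width} columns, got {len(toks)})"
                )
            vals = []
            for c, tok in enumerate(toks):
                try:
                    v = int(tok)
                except ValueError:
                    v = -1
                if v not in (NON_TUMOR, WT, MUT):
                    raise FormatError(
                        f"{path}: invalid symbol {tok!r} at row {r}, column {c}"
                    )
                vals.append(v)
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: empty grid")
    return CloneMap(np.array(rows, dtype=np.int8))


def write_label_grid(cmap: CloneMap, path) -> None:
    np.savetxt(path, cmap.labels, fmt="%d", delimiter=" ")


def read_color_raster(path, palette: Optional[dict] = None, tol: int = 60) -> CloneMap:
    """Convert an annotated color raster (PNG/TIFF/...) to a label grid.

    Pixels within ``tol`` of a palette color on every RGB channel take
    that color's label; all other pixels (background, tissue outside
    the annotation) become NON_TUMOR.
    """
    from PIL import Image

    palette = DEFAULT_PALETTE if palette is None else palette
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.int16)
    labels = np.full(arr.shape[:2], NON_TUMOR, dtype=np.int8)
    for color, label in palette.items():
        ref = np.asarray(color, dtype=np.int16)
        match = (np.abs(arr - ref) <= tol).all(axis=2)
        labels[match] = label
    return CloneMap(labels)


def write_color_raster(cmap: CloneMap, path, palette: Optional[dict] = None) -> None:
    """Render a label grid to an RGB image (inverse of read_color_raster)."""
    from PIL import Image

    palette = DEFAULT_PALETTE if palette is None else palette
    rgb = np.zeros(cmap.labels.shape + (3,), dtype=np.uint8)
    for color, label in palette.items():
        rgb[cmap.labels == label] = color
    Image.fromarray(rgb).save(path)


# ---------------------------------------------------------- generator

def generate(pattern: MapPattern, height: int, width: int) -> CloneMap:
    """Generate a synthetic clone map with a controlled subclone
    proportion and mixing geometry.

    The whole ``height x width`` rectangle is tumor; exactly
    ``round(target_frequency * height * width)`` pixels are mutant, so
    the realized frequency is within +/-0.02 of the target whenever the
    map holds at least ~25 pixels.

    BLOB places a single compact disc (low mixing); STRIPED and
    INTERDIGITATED place alternating clone bands (intermediate mixing,
    finer with higher dispersion); SCATTERED fragments the subclone
    into many small patches, down to stratified single pixels at
    maximal dispersion (mixing near 1). FROM_SIM passes a simulator
    snapshot through unchanged.
    """
    if pattern.kind is PatternKind.FROM_SIM:
        return _from_sim(pattern.source)
    n = height * width
    m = int(round(pattern.target_frequency * n))
    if n <= 0 or m == 0 or m == n or abs(m / n - pattern.target_frequency) > 0.02:
        raise ValueError(
            f"cannot realize frequency {pattern.target_frequency} within "
            f"+/-0.02 on a {height}x{width} map"
        )
    rng = np.random.default_rng(pattern.seed)
    kind = pattern.kind
    if kind is PatternKind.BLOB:
        score = _blob_score(height, width, rng)
    elif kind is PatternKind.STRIPED:
        score = _stripe_score(height, width, pattern.dispersion, interdigitate=False)
    elif kind is PatternKind.INTERDIGITATED:
        score = _stripe_score(height, width, pattern.dispersion, interdigitate=True)
    elif kind is PatternKind.SCATTERED:
        if pattern.dispersion >= MAX_DISPERSION:
            return CloneMap(_stratified(height, width, m, rng))
        score = _patch_score(height, width, pattern.dispersion, rng)
    else:  # pragma: no cover
        raise ValueError(f"unknown pattern kind {kind}")
    labels = np.full(n, WT, dtype=np.int8)
    labels[np.argsort(score, kind="stable")[:m]] = MUT
    return CloneMap(labels.reshape(height, width))


def _from_sim(source) -> CloneMap:
    if source is None:
        raise ValueError("FROM_SIM requires a source snapshot")
    if isinstance(source, CloneMap):
        return source
    if isinstance(source, LatticeState):
        return CloneMap(source.copy_grid())
    return read_label_grid(source)


def _grid_coords(height, width):
    r, c = np.indices((height, width))
    return r.ravel().astype(float), c.ravel().astype(float)


def _blob_score(height, width, rng):
    # distance from center, tiny jitter to break ties reproducibly
    r, c = _grid_coords(height, width)
    d = (r - (height - 1) / 2.0) ** 2 + (c - (width - 1) / 2.0) ** 2
    return d + rng.random(d.size) * 1e-6


def _stripe_score(height, width, dispersion, interdigitate):
    # vertical bands; the mutant fills the low-phase part of each period
    r, c = _grid_coords(height, width)
    period = max(2, width // dispersion)
    phase = c % period
    if interdigitate:
        # offset alternate horizontal slabs by half a period so the
        # bands interlock like fingers
        slab = max(1, height // (2 * dispersion))
        phase = (c + (r // slab) * (period // 2)) % period
    # within equal phase, fill columns top to bottom for exact counts
    return phase * height * width + r * width + c


def _patch_score(height, width, dispersion, rng):
    # distance to the nearest of dispersion^2 random patch seeds
    r, c = _grid_coords(height, width)
    k = dispersion ** 2
    sr = rng.uniform(0, height, size=k)
    sc = rng.uniform(0, width, size=k)
    d = (r[:, None] - sr) ** 2 + (c[:, None] - sc) ** 2
    return d.min(axis=1) + rng.random(r.size) * 1e-6


def _stratified(height, width, m, rng):
    """Exactly m mutant pixels spread by error diffusion over 2x2 tiles.

    Every tile receives floor or ceil of its fair share, so any quadrat
    aligned with the tiling sees the target fraction almost exactly —
    the fully-mixed limit of the pattern family.
    """
    labels = np.full((height, width), WT, dtype=np.int8)
    tiles = [
        (r0, c0, min(2, height - r0), min(2, width - c0))
        for r0 in range(0, height, 2)
        for c0 in range(0, width, 2)
    ]
    n = height * width
    acc = 0.0
    placed = 0
    for r0, c0, th, tw in tiles:
        size = th * tw
        acc += m * size / n
        quota = int(round(acc)) - placed
        quota = max(0, min(quota, size))
        if quota:
            flat = rng.permutation(size)[:quota]
            rr, cc = np.unravel_index(flat, (th, tw))
            labels[r0 + rr, c0 + cc] = MUT
            placed += quota
    # error diffusion can be off by a pixel at the end; patch exactly
    diff = m - placed
    if diff > 0:
        wt = np.flatnonzero(labels.ravel() == WT)
        labels.ravel()[rng.choice(wt, size=diff, replace=False)] = MUT
    elif diff < 0:
        mut = np.flatnonzero(labels.ravel() == MUT)
        labels.ravel()[rng.choice(mut, size=-diff, replace=False)] = WT
    return labels
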