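"""Label-map preprocessing: tissue masking, DCIS exclusion, nucleus
rasterization and the patch grid of per-patch layer fractions.

All spatial inputs are single-channel integer label maps with pixel (0, 0)
at the top-left, row-major, 0-based.  Nuclei arrive as point sets in the
coordinates of the full-resolution frame and are rasterized onto a
five-times down-sampled grid, mirroring how whole-slide cell maps are built
from detected nucleus centroids.  Features downstream consume only the
:class:`PatchGrid`: per-patch layer fractions on non-overlapping square
patches of 62 µm side, with patches below 50% tissue coverage or touching
excluded DCIS flagged invalid.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMap",
    "CellPointSet",
    "LayerStack",
    "PatchGrid",
    "tissue_mask",
    "exclude_dcis",
    "rasterize_cells",
    "patchify",
    "assemble_stack",
    "NUCLEUS_CLASSES",
]

#: Nucleus classes emitted by the upstream classifier, with raster codes.
NUCLEUS_CLASSES = {
    "tumor": 1,
    "immune": 2,
    "connective": 3,
    "normal_epithelial": 4,
}


@dataclasses.dataclass
class LabelMap:
    """2D integer class grid; 0 is background."""

    grid: np.ndarray
    pixel_size_um: float
    class_codes: dict[int, str]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or min(self.grid.shape) < 1:
            raise ValueError("label grid must be 2D with positive dimensions")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        present = set(np.unique(self.grid).tolist()) - {0}
        unknown = present - set(self.class_codes)
        if unknown:
            raise ValueError(f"codes {sorted(unknown)} missing from class_codes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclasses.dataclass
class CellPointSet:
    """Nucleus centroids (x, y, class) in full-resolution frame pixels."""

    x_px: np.ndarray
    y_px: np.ndarray
    classes: np.ndarray  # string class names
    frame_shape: tuple[int, int]  # (height, width) of the full-res frame
    frame_pixel_size_um: float

    def __post_init__(self) -> None:
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        if not (self.x_px.size == self.y_px.size == self.classes.size):
            raise ValueError("x, y and class arrays must have equal length")
        bad = set(np.unique(self.classes).tolist()) - set(NUCLEUS_CLASSES)
        if bad:
            raise ValueError(f"unknown nucleus classes: {sorted(bad)}")

    def __len__(self) -> int:
        return self.x_px.size


@dataclasses.dataclass
class LayerStack:
    """Registered binary analysis layers on a common grid.

    ``layers`` maps layer name to a boolean map; all layers, the DCIS mask
    and the tissue mask share one shape and pixel size.  ``graded_groups``
    names ordered groups of mutually exclusive layers (grade 1-3,
    pleomorphism 1-3) that the patch grid summarizes by dominant level.
    """

    layers: dict[str, np.ndarray]
    dcis_mask: np.ndarray
    tissue_mask: np.ndarray
    pixel_size_um: float
    patch_side_um: float = 62.0
    graded_groups: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("layer stack needs at least one layer")
        shapes = {np.asarray(m).shape for m in self.layers.values()}
        shapes |= {np.asarray(self.dcis_mask).shape, np.asarray(self.tissue_mask).shape}
        if len(shapes) != 1:
            raise ValueError(f"layers are not registered: shapes {shapes}")
        self.layers = {k: np.asarray(v, dtype=bool) for k, v in self.layers.items()}
        self.dcis_mask = np.asarray(self.dcis_mask, dtype=bool)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        for group, members in self.graded_groups.items():
            missing = [m for m in members if m not in self.layers]
            if missing:
                raise ValueError(f"graded group {group!r} references missing layers {missing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tissue_mask.shape

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)


@dataclasses.dataclass
class PatchGrid:
    """Per-patch layer fractions on a regular tiling of the stack.

    Attributes
    ----------
    fractions : dict of layer name -> 2D float array
        Labelled-pixel fraction of each patch, in [0, 1].
    tissue_fraction : 2D float array
        Tissue coverage per patch.
    valid : 2D bool array
        Patches with >= ``min_tissue_frac`` tissue and no DCIS overlap.
    levels : dict of group name -> 2D int array
        Dominant ordinal level (1-based) per patch for graded groups;
        0 where no member layer is present.
    """

    fractions: dict[str, np.ndarray]
    tissue_fraction: np.ndarray
    valid: np.ndarray
    levels: dict[str, np.ndarray]
    patch_side_px: int
    patch_side_um: float
    min_tissue_frac: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def layer_fracs(self, name: str, valid_only: bool = True) -> np.ndarray:
        """Fraction vector of one layer, restricted to valid patches."""
        f = self.fractions[name]
        return f[self.valid] if valid_only else f

    def presence_map(self, name: str, threshold: float = 0.1) -> np.ndarray:
        """Binary per-patch presence map at a fraction threshold."""
        return (self.fractions[name] >= threshold).astype(np.int8)


def tissue_mask(label_map: LabelMap, min_object_px: int = 64,
                closing_radius_px: int = 2) -> np.ndarray:
    """Union of non-background labels, morphologically closed and
    small-object filtered.

    Emulates the thresholding + morphology step that isolates tissue from
    background before any feature computation.  An all-background map yields
    an empty mask with a logged warning rather than an error.
    """
    mask = label_map.grid > 0
    if not mask.any():
        logger.warning("tissue_mask: map contains no labelled pixels")
        return mask
    if closing_radius_px > 0:
        mask = ndimage.binary_closing(mask, structure=disk(closing_radius_px))
    if min_object_px > 1:
        labelled, n = ndimage.label(mask)
        if n:
            sizes = np.bincount(labelled.ravel())
            small = np.flatnonzero(sizes < min_object_px)
            mask &= ~np.isin(labelled, small[small > 0])
    return mask


def exclude_dcis(stack: LayerStack) -> LayerStack:
    """Zero every analysis layer inside the DCIS mask.

    The DCIS mask itself is retained so that :func:`patchify` can invalidate
    any patch the excluded region touched.  Idempotent.
    """
    if stack.dcis_mask.shape != stack.shape:
        raise ValueError("dcis_mask is not registered to the layers")
    keep = ~stack.dcis_mask
    return dataclasses.replace(
        stack, layers={k: v & keep for k, v in stack.layers.items()}
    )


def rasterize_cells(cells: CellPointSet, downsample: int = 5) -> LabelMap:
    """Rasterize nucleus centroids onto a down-sampled grid.

    Each nucleus sets the pixel at ``(floor(y/downsample), floor(x/downsample))``
    to its class code.  Collisions resolve last-writer-wins after sorting by
    (y, x, class code), making the output independent of input order.
    """
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    h, w = cells.frame_shape
    out_shape = (math.ceil(h / downsample), math.ceil(w / downsample))
    grid = np.zeros(out_shape, dtype=np.uint8)
    if len(cells):
        oob = (cells.x_px < 0) | (cells.x_px >= w) | (cells.y_px < 0) | (cells.y_px >= h)
        if oob.any():
            k = int(np.flatnonzero(oob)[0])
            raise ValueError(
                f"point {k} at (x={cells.x_px[k]}, y={cells.y_px[k]}) lies "
                f"outside the {h}x{w} frame"
            )
        codes = np.array([NUCLEUS_CLASSES[c] for c in cells.classes])
        ys = np.floor(cells.y_px / downsample).astype(int)
        xs = np.floor(cells.x_px / downsample).astype(int)
        order = np.lexsort((codes, xs, ys))
        grid[ys[order], xs[order]] = codes[order]  # fancy assignment: last wins
    return LabelMap(
        grid=grid,
        pixel_size_um=cells.frame_pixel_size_um * downsample,
        class_codes={v: k for k, v in NUCLEUS_CLASSES.items()},
    )


def assemble_stack(
    region: np.ndarray,
    nuclei: np.ndarray,
    grade: np.ndarray,
    pleomorphism: np.ndarray,
    components: dict[str, np.ndarray],
    dcis_mask: np.ndarray,
    tissue: np.ndarray,
    pixel_size_um: float,
    patch_side_um: float = 62.0,
    assoc_radius_px: int | None = None,
    patient_id: str | None = None,
) -> LayerStack:
    """Assemble the default 18 analysis layers from base label maps.

    ``region`` holds codes 1 = tumor, 2 = stroma, 3 = other tissue;
    ``nuclei`` is a rasterized nucleus class map (codes per
    :data:`NUCLEUS_CLASSES`); ``grade``/``pleomorphism`` hold ordinal levels
    1-3 (0 outside tissue); ``components`` maps the four differentiation
    component names to binary masks.  Tumor-associated stroma is the stroma
    within ``assoc_radius_px`` of tumor (default: two patch widths), the
    remaining stroma and the 'other' class form the other-stroma layer, and
    immune nuclei are split into intratumoral and stromal by the tumor
    region.
    """
    region = np.asarray(region)
    tumor = region == 1
    stroma = region == 2
    other = region == 3
    if assoc_radius_px is None:
        assoc_radius_px = 2 * round(patch_side_um / pixel_size_um)
    dist_to_tumor = ndimage.distance_transform_edt(~tumor)
    near_tumor = dist_to_tumor <= assoc_radius_px
    immune = nuclei == NUCLEUS_CLASSES["immune"]

    layers = {
        "tumor": tumor,
        "tumor_stroma": stroma & near_tumor,
        "other_stroma": (stroma & ~near_tumor) | other,
        "tumor_nuclei": nuclei == NUCLEUS_CLASSES["tumor"],
        "intratumoral_immune": immune & tumor,
        "stromal_immune": immune & ~tumor,
        "connective": nuclei == NUCLEUS_CLASSES["connective"],
        "normal_epithelial": nuclei == NUCLEUS_CLASSES["normal_epithelial"],
        "grade1": grade == 1,
        "grade2": grade == 2,
        "grade3": grade == 3,
        "pleomorphism1": pleomorphism == 1,
        "pleomorphism2": pleomorphism == 2,
        "pleomorphism3": pleomorphism == 3,
        **{name: np.asarray(m, dtype=bool) for name, m in components.items()},
    }
    return LayerStack(
        layers=layers,
        dcis_mask=dcis_mask,
        tissue_mask=tissue,
        pixel_size_um=pixel_size_um,
        patch_side_um=patch_side_um,
        graded_groups={
            "grade": ["grade1", "grade2", "grade3"],
            "pleomorphism": ["pleomorphism1", "pleomorphism2", "pleomorphism3"],
        },
        patient_id=patient_id,
    )


def patchify(stack: LayerStack, min_tissue_frac: float = 0.5) -> PatchGrid:
    """Tile the stack into non-overlapping square patches and compute
    per-patch layer fractions.

    The patch side is ``round(patch_side_um / pixel_size_um)`` pixels; tiling
    starts at the top-left and incomplete edge tiles are dropped.  A patch is
    valid when its tissue coverage is at least ``min_tissue_frac`` and it has
    no overlap with the DCIS mask (any overlap invalidates).  Graded groups
    are summarized by the member layer with the largest fraction, ties broken
    toward the lower level; 0 marks patches where no member is present.
    """
    side = round(stack.patch_side_um / stack.pixel_size_um)
    if side < 1:
        raise ValueError(
            f"patch side {stack.patch_side_um} um is below one pixel at "
            f"{stack.pixel_size_um} um/px"
        )
    H, W = stack.shape
    nr, nc = H // side, W // side
    if nr < 1 or nc < 1:
        raise ValueError("map smaller than one patch")

    def block_mean(arr: np.ndarray) -> np.ndarray:
        a = arr[: nr * side, : nc * side].astype(float)
        return a.reshape(nr, side, nc, side).mean(axis=(1, 3))

    fractions = {name: block_mean(m) for name, m in stack.layers.items()}
    tissue_frac = block_mean(stack.tissue_mask)
    dcis_frac = block_mean(stack.dcis_mask)
    valid = (tissue_frac >= min_tissue_frac) & (dcis_frac == 0)

    levels: dict[str, np.ndarray] = {}
    for group, members in stack.graded_groups.items():
        fr = np.stack([fractions[m] for m in members])  # (L, nr, nc)
        # argmax returns the first (lowest) level on ties
        lev = np.argmax(fr, axis=0) + 1
        lev[fr.max(axis=0) == 0] = 0
        levels[group] = lev.astype(np.int8)

    return PatchGrid(
        fractions=fractions,
        tissue_fraction=tissue_frac,
        valid=valid,
        levels=levels,
        patch_side_px=side,
        patch_side_um=stack.patch_side_um,
        min_tissue_frac=min_tissue_frac,
    )
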