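"""The heterogeneity feature catalogue and per-patient feature extraction.

The default catalogue holds 162 features: 18 spatial layers, each summarized
by the 8 co-occurrence texture statistics (144 features), plus 18 designated
layer-pair colocalization statistics.  Every feature belongs to exactly one
family — tumor differentiation, stroma (tumor microenvironment), or TILs —
used downstream to form the three family heterogeneity scores.

Texture statistics are computed on the per-patch *presence* map of a layer,
so that levels 0/1 encode local absence or presence and the co-occurrence
matrix measures how intermixed the layer is across neighbouring 62 µm
patches.  Area layers (regions, grade, pleomorphism, differentiation
components) use a presence threshold of 0.1 patch fraction; nuclei layers
are rasterized points covering a vanishing pixel fraction, so their presence
means "at least one labelled pixel in the patch".  Colocalization compares
the raw fraction vectors of two layers over the valid patches.

Degenerate statistics (a layer with fewer than two valid patches, or
correlation of a constant map) are recorded as missing values, never errors.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .preprocess import LayerStack, PatchGrid, patchify
from .texture import (
    TEXTURE_STATISTICS,
    UndefinedCMError,
    build_cm,
    texture_stats,
)

__all__ = [
    "FeatureDef",
    "FeatureCatalogue",
    "default_catalogue",
    "default_layer_names",
    "compute_features",
    "compute_feature_matrix",
]

FAMILIES = ("differentiation", "stroma", "tils")

#: The 18 default layers with their family assignment.
DEFAULT_LAYERS: dict[str, str] = {
    # region layers -> stroma / TME family
    "tumor": "stroma",
    "tumor_stroma": "stroma",
    "other_stroma": "stroma",
    # nuclei layers
    "tumor_nuclei": "differentiation",
    "intratumoral_immune": "tils",
    "stromal_immune": "tils",
    "connective": "stroma",
    "normal_epithelial": "stroma",
    # digital grade
    "grade1": "differentiation",
    "grade2": "differentiation",
    "grade3": "differentiation",
    # nuclear pleomorphism
    "pleomorphism1": "differentiation",
    "pleomorphism2": "differentiation",
    "pleomorphism3": "differentiation",
    # differentiation components
    "tubule_forming": "differentiation",
    "mitosis_rich": "differentiation",
    "high_cellularity": "differentiation",
    "discohesive": "differentiation",
}

#: The 18 default colocalization pairs with their family.
DEFAULT_COLOC_PAIRS: list[tuple[str, str, str]] = [
    ("tumor", "tumor_stroma", "stroma"),
    ("tumor", "connective", "stroma"),
    ("tumor_stroma", "connective", "stroma"),
    ("tumor", "normal_epithelial", "stroma"),
    ("tumor", "stromal_immune", "tils"),
    ("tumor", "intratumoral_immune", "tils"),
    ("tumor_stroma", "stromal_immune", "tils"),
    ("grade3", "intratumoral_immune", "tils"),
    ("grade3", "stromal_immune", "tils"),
    ("intratumoral_immune", "stromal_immune", "tils"),
    ("tumor", "tumor_nuclei", "differentiation"),
    ("grade1", "grade3", "differentiation"),
    ("grade2", "grade3", "differentiation"),
    ("pleomorphism1", "pleomorphism3", "differentiation"),
    ("grade3", "pleomorphism3", "differentiation"),
    ("tubule_forming", "grade1", "differentiation"),
    ("mitosis_rich", "grade3", "differentiation"),
    ("high_cellularity", "discohesive", "differentiation"),
]


@dataclasses.dataclass(frozen=True)
class FeatureDef:
    """One catalogue entry: a named statistic on a layer or layer pair."""

    name: str
    kind: str  # "texture" | "colocalization"
    statistic: str
    layers: tuple[str, ...]
    family: str

    def __post_init__(self) -> None:
        if self.kind not in ("texture", "colocalization"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


#: nuclei layers are point rasters: a single labelled pixel marks presence
POINT_LAYERS = frozenset({
    "tumor_nuclei", "intratumoral_immune", "stromal_immune",
    "connective", "normal_epithelial",
})
_POINT_EPS = 1e-12


class FeatureCatalogue:
    """Ordered, named feature definitions with a family partition.

    ``presence_threshold`` applies to area layers; layers listed in
    ``point_layers`` binarize at any non-zero fraction instead.
    """

    def __init__(self, features: Sequence[FeatureDef],
                 presence_threshold: float = 0.1,
                 point_layers: frozenset[str] | set[str] = POINT_LAYERS):
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        self.features = list(features)
        self.presence_threshold = float(presence_threshold)
        self.point_layers = frozenset(point_layers)

    def layer_threshold(self, layer: str) -> float:
        return _POINT_EPS if layer in self.point_layers else self.presence_threshold

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def family_members(self, family: str) -> list[str]:
        return [f.name for f in self.features if f.family == family]

    @property
    def families(self) -> dict[str, str]:
        return {f.name: f.family for f in self.features}

    def to_yaml(self, path) -> None:
        payload = {
            "presence_threshold": self.presence_threshold,
            "point_layers": sorted(self.point_layers),
            "features": [
                {"name": f.name, "kind": f.kind, "statistic": f.statistic,
                 "layers": list(f.layers), "family": f.family}
                for f in self.features
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureCatalogue":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        feats = [
            FeatureDef(name=d["name"], kind=d["kind"], statistic=d["statistic"],
                       layers=tuple(d["layers"]), family=d["family"])
            for d in payload["features"]
        ]
        return cls(feats,
                   presence_threshold=payload.get("presence_threshold", 0.1),
                   point_layers=frozenset(payload.get("point_layers",
                                                      POINT_LAYERS)))


def default_layer_names() -> list[str]:
    return list(DEFAULT_LAYERS)


def default_catalogue(presence_threshold: float = 0.1) -> FeatureCatalogue:
    """The default 162-feature catalogue: 18 layers x 8 texture statistics
    plus 18 colocalization pairs."""
    feats: list[FeatureDef] = []
    for layer, family in DEFAULT_LAYERS.items():
        for stat in TEXTURE_STATISTICS:
            feats.append(FeatureDef(
                name=f"{layer}__{stat}", kind="texture", statistic=stat,
                layers=(layer,), family=family,
            ))
    for a, b, family in DEFAULT_COLOC_PAIRS:
        feats.append(FeatureDef(
            name=f"coloc__{a}__{b}", kind="colocalization",
            statistic="colocalization", layers=(a, b), family=family,
        ))
    return FeatureCatalogue(feats, presence_threshold=presence_threshold)


def compute_features(grid: PatchGrid, catalogue: FeatureCatalogue | None = None,
                     ) -> pd.Series:
    """Evaluate every catalogue feature on one patch grid.

    Returns a Series aligned to the catalogue, with NaN where a statistic is
    undefined (no valid neighbouring pair, constant-map correlation, or an
    empty colocalization pair).
    """
    from .texture import colocalization  # local import keeps module load light

    if catalogue is None:
        catalogue = default_catalogue()

    # one CM + stats per referenced layer, shared across its 8 statistics
    stats_cache: dict[str, dict[str, float] | None] = {}

    def layer_stats(layer: str) -> dict[str, float] | None:
        if layer not in stats_cache:
            try:
                thr = catalogue.layer_threshold(layer)
                cm = build_cm(grid.presence_map(layer, thr), valid=grid.valid)
                ts = texture_stats(cm)
                d = ts.as_dict()
                if not ts.correlation_defined:
                    d["correlation"] = np.nan
                stats_cache[layer] = d
            except UndefinedCMError:
                stats_cache[layer] = None
        return stats_cache[layer]

    values: dict[str, float] = {}
    for f in catalogue:
        if f.kind == "texture":
            d = layer_stats(f.layers[0])
            values[f.name] = np.nan if d is None else d[f.statistic]
        else:
            a = grid.layer_fracs(f.layers[0])
            b = grid.layer_fracs(f.layers[1])
            if a.size == 0 or float(np.maximum(a, b).sum()) == 0.0:
                values[f.name] = np.nan  # undefined: neither layer present
            else:
                values[f.name] = colocalization(a, b)
    return pd.Series(values, index=catalogue.names, dtype=float)


def compute_feature_matrix(stacks: Iterable[LayerStack],
                           catalogue: FeatureCatalogue | None = None,
                           min_tissue_frac: float = 0.5) -> pd.DataFrame:
    """Patients x features value table for a cohort of layer stacks.

    Each stack is patchified after DCIS exclusion is assumed applied by the
    caller (use :func:`ithquant.preprocess.exclude_dcis`).  Row index is the
    stack's patient id (or its position when unnamed).
    """
    if catalogue is None:
        catalogue = default_catalogue()
    rows, index = [], []
    for i, stack in enumerate(stacks):
        grid = patchify(stack, min_tissue_frac=min_tissue_frac)
        rows.append(compute_features(grid, catalogue))
        index.append(stack.patient_id if stack.patient_id is not None else i)
    return pd.DataFrame(rows, index=pd.Index(index, name="patient_id"),
                        columns=catalogue.names)
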