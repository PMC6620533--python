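"""Desikan–Killiany cortical parcellation used throughout the pipeline.

Every feature matrix in the package is indexed by the 68 cortical regions of
the Desikan–Killiany (DK) atlas: 34 labels per hemisphere, in the standard
FreeSurfer ``aparc`` order, left hemisphere first.  The atlas object carries
the canonical region order so that feature tables, connectivity matrices and
delta tensors loaded from different files always line up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["AtlasDefinition", "dk_atlas", "DK_REGION_BASENAMES"]

# FreeSurfer aparc cortical labels (corpus callosum excluded), in the order
# the annotation color table lists them.  34 per hemisphere.
DK_REGION_BASENAMES: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

# aparc+aseg integer codes: 1000/2000 blocks with corpus callosum (offset 4)
# skipped, i.e. lh 1001..1035 \ {1004}, rh 2001..2035 \ {2004}.
_APARC_OFFSETS: tuple[int, ...] = tuple(
    k for k in range(1, 36) if k != 4
)


@dataclass(frozen=True)
class AtlasDefinition:
    """Ordered definition of a cortical parcellation.

    Attributes
    ----------
    region_ids:
        Integer label codes, one per region, in canonical order.
    region_names:
        Region names such as ``"lh-bankssts"``, same order as ``region_ids``.
    hemisphere:
        ``"left"`` or ``"right"`` per region.
    """

    region_ids: tuple[int, ...]
    region_names: tuple[str, ...]
    hemisphere: tuple[str, ...]
    _name_to_index: dict[str, int] = field(init=False, repr=False, compare=False)
    _id_to_index: dict[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        if not (len(self.region_names) == len(self.hemisphere) == n):
            raise ValueError("region_ids, region_names, hemisphere must align")
        if n != 68:
            raise ValueError(f"atlas must define exactly 68 regions, got {n}")
        if len(set(self.region_ids)) != n:
            raise ValueError("region ids must be unique")
        if len(set(self.region_names)) != n:
            raise ValueError("region names must be unique")
        for hemi in ("left", "right"):
            count = sum(1 for h in self.hemisphere if h == hemi)
            if count != 34:
                raise ValueError(f"expected 34 {hemi}-hemisphere regions, got {count}")
        object.__setattr__(
            self, "_name_to_index", {nm: i for i, nm in enumerate(self.region_names)}
        )
        object.__setattr__(
            self, "_id_to_index", {rid: i for i, rid in enumerate(self.region_ids)}
        )

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index_of(self, region: str | int) -> int:
        """Position of a region (by name or integer code) in canonical order."""
        if isinstance(region, str):
            try:
                return self._name_to_index[region]
            except KeyError:
                raise KeyError(f"unknown region name: {region!r}") from None
        try:
            return self._id_to_index[int(region)]
        except (KeyError, ValueError):
            raise KeyError(f"unknown region id: {region!r}") from None

    def __contains__(self, region: object) -> bool:
        try:
            self.index_of(region)  # type: ignore[arg-type]
        except KeyError:
            return False
        return True


def dk_atlas() -> AtlasDefinition:
    """The default Desikan–Killiany atlas: lh regions 1–34, then rh 35–68."""
    names: list[str] = []
    ids: list[int] = []
    hemis: list[str] = []
    for hemi, prefix, block in (("left", "lh", 1000), ("right", "rh", 2000)):
        for offset, base in zip(_APARC_OFFSETS, DK_REGION_BASENAMES):
            names.append(f"{prefix}-{base}")
            ids.append(block + offset)
            hemis.append(hemi)
    return AtlasDefinition(tuple(ids), tuple(names), tuple(hemis))


def region_order(atlas: AtlasDefinition, regions: Sequence[str | int]) -> list[int]:
    """Map arbitrary region identifiers to canonical positions, erroring on unknowns."""
    return [atlas.index_of(r) for r in regions]
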