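"""Province canon and the eastern/central/western region partition.

Mainland China's 31 provincial administrative units (provinces, autonomous
regions and municipalities; Hong Kong, Macao and Taiwan excluded) are grouped
into three macro-regions by geography and level of economic development.  All
regional aggregation in this package runs through a :class:`RegionScheme`,
which is simply a validated province -> region mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

REGIONS = ("eastern", "central", "western")

#: The 31 provincial units in official administrative-division order.
PROVINCE_ORDER = (
    "Beijing", "Tianjin", "Hebei", "Shanxi", "Inner Mongolia",
    "Liaoning", "Jilin", "Heilongjiang",
    "Shanghai", "Jiangsu", "Zhejiang", "Anhui", "Fujian", "Jiangxi", "Shandong",
    "Henan", "Hubei", "Hunan", "Guangdong", "Guangxi", "Hainan",
    "Chongqing", "Sichuan", "Guizhou", "Yunnan", "Tibet",
    "Shaanxi", "Gansu", "Qinghai", "Ningxia", "Xinjiang",
)

_EASTERN = (
    "Beijing", "Tianjin", "Hebei", "Liaoning", "Shanghai", "Jiangsu",
    "Zhejiang", "Fujian", "Shandong", "Guangdong", "Hainan",
)
_CENTRAL = (
    "Shanxi", "Jilin", "Heilongjiang", "Anhui", "Jiangxi", "Henan",
    "Hubei", "Hunan",
)
# Chongqing belongs to the western group in this scheme.
_WESTERN = (
    "Inner Mongolia", "Guangxi", "Chongqing", "Sichuan", "Guizhou", "Yunnan",
    "Tibet", "Shaanxi", "Gansu", "Qinghai", "Ningxia", "Xinjiang",
)

#: Alternative spellings accepted on input, mapped to the canonical name.
ALIASES = {
    "xizang": "Tibet",
    "tibet": "Tibet",
    "nei mongol": "Inner Mongolia",
    "neimenggu": "Inner Mongolia",
}


class RegionMappingError(ValueError):
    """A province is missing from, or duplicated in, the region scheme."""


def canonical_province(name: str) -> str:
    """Normalise a province name: trim, case-fold, resolve known aliases.

    Unknown names are returned title-stripped as given (the panel may carry
    synthetic province labels); known names always come back in canonical
    spelling.
    """
    key = " ".join(str(name).split()).lower()
    if key in ALIASES:
        return ALIASES[key]
    for canon in PROVINCE_ORDER:
        if key == canon.lower():
            return canon
    return " ".join(str(name).split())


@dataclass(frozen=True)
class RegionScheme:
    """A partition of provinces into region labels.

    Parameters
    ----------
    mapping
        province name -> region label.  Names are canonicalised; each
        province must appear exactly once and every label must be one of
        ``REGIONS``.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon: dict[str, str] = {}
        for prov, region in self.mapping.items():
            name = canonical_province(prov)
            if name in canon:
                raise RegionMappingError(f"province {name!r} appears twice in scheme")
            if region not in REGIONS:
                raise RegionMappingError(
                    f"unknown region {region!r} for {name!r}; expected one of {REGIONS}"
                )
            canon[name] = region
        object.__setattr__(self, "mapping", canon)

    def __contains__(self, province: str) -> bool:
        return canonical_province(province) in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    def region_of(self, province: str) -> str:
        name = canonical_province(province)
        try:
            return self.mapping[name]
        except KeyError:
            raise RegionMappingError(f"province {name!r} not in region scheme") from None

    def provinces(self, region: str | None = None) -> tuple[str, ...]:
        """Provinces in the scheme, optionally restricted to one region,
        in canonical administrative order (unknown names last, sorted)."""
        names = [p for p, r in self.mapping.items() if region is None or r == region]
        order = {p: i for i, p in enumerate(PROVINCE_ORDER)}
        return tuple(sorted(names, key=lambda p: (order.get(p, len(order)), p)))

    def region_sizes(self) -> dict[str, int]:
        sizes = {r: 0 for r in REGIONS}
        for r in self.mapping.values():
            sizes[r] += 1
        return sizes


def default_scheme() -> RegionScheme:
    """The standard 11 eastern / 8 central / 12 western partition."""
    mapping: dict[str, str] = {}
    for prov in _EASTERN:
        mapping[prov] = "eastern"
    for prov in _CENTRAL:
        mapping[prov] = "central"
    for prov in _WESTERN:
        mapping[prov] = "western"
    return RegionScheme(mapping)
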