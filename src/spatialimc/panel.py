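"""Antibody panel: the ordered mapping from acquisition channels to markers.

Every channel of an IMC acquisition corresponds to one metal-tagged
antibody.  The panel records, per channel, the metal tag, the marker name
and the marker's *role* in the analysis:

``nuclear`` / ``membrane`` / ``cytoplasm``
    segmentation-support channels, excluded from clustering features;
``phenotyping``
    immune/lineage markers used as clustering features;
``tumor`` / ``stroma``
    markers identifying the malignant-epithelial and connective-tissue
    compartments; used both as clustering features and to derive the
    parenchyma/stroma compartment map;
``ignore``
    acquired but unused.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

VALID_ROLES = frozenset(
    {"nuclear", "membrane", "cytoplasm", "phenotyping", "tumor", "stroma", "ignore"}
)

#: roles whose per-cell mean intensities feed the clustering feature matrix
FEATURE_ROLES = frozenset({"phenotyping", "tumor", "stroma"})


@dataclass(frozen=True)
class PanelEntry:
    channel_index: int
    metal_tag: str
    marker_name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(
                f"invalid role {self.role!r} for marker {self.marker_name!r}; "
                f"expected one of {sorted(VALID_ROLES)}"
            )


@dataclass(frozen=True)
class Panel:
    """Ordered list of channel descriptors; channel order is acquisition order."""

    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        idx = [e.channel_index for e in self.entries]
        if idx != list(range(len(idx))):
            raise ValueError(
                f"channel indices must be unique and contiguous from 0, got {idx}"
            )
        names = [e.marker_name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate marker names in panel: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PanelEntry]:
        return iter(self.entries)

    @property
    def markers(self) -> list[str]:
        return [e.marker_name for e in self.entries]

    @property
    def metals(self) -> list[str]:
        return [e.metal_tag for e in self.entries]

    def markers_with_role(self, role: str | Iterable[str]) -> list[str]:
        roles = {role} if isinstance(role, str) else set(role)
        unknown = roles - VALID_ROLES
        if unknown:
            raise ValueError(f"unknown roles: {sorted(unknown)}")
        return [e.marker_name for e in self.entries if e.role in roles]

    @property
    def feature_markers(self) -> list[str]:
        """Markers used as clustering features (phenotyping + tumor + stroma)."""
        return self.markers_with_role(FEATURE_ROLES)

    @property
    def measured_markers(self) -> list[str]:
        """All markers whose per-cell means are extracted (every role but ignore)."""
        return [e.marker_name for e in self.entries if e.role != "ignore"]

    def index_of(self, marker: str) -> int:
        for e in self.entries:
            if e.marker_name == marker:
                return e.channel_index
        raise KeyError(f"marker {marker!r} not in panel")

    @classmethod
    def from_records(cls, records: Iterable[tuple[int, str, str, str]]) -> "Panel":
        return cls(tuple(PanelEntry(*r) for r in records))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": [e.channel_index for e in self.entries],
                "metal": [e.metal_tag for e in self.entries],
                "marker": [e.marker_name for e in self.entries],
                "role": [e.role for e in self.entries],
            }
        )


def default_panel() -> Panel:
    """The 12-marker reduced panel used throughout the synthetic studies.

    A desk-scale subset of a full 40+ marker IMC panel: one nuclear and one
    membrane channel, the canonical adaptive/innate immune lineage markers,
    a tumor-cell marker (CA19-9, the biliary/pancreatic epithelial antigen)
    and two stromal markers (collagen, alpha-smooth-muscle actin).
    """
    rows = [
        (0, "Ir191", "DNA1", "nuclear"),
        (1, "Gd158", "E-cadherin", "membrane"),
        (2, "Nd148", "CD3", "phenotyping"),
        (3, "Nd145", "CD4", "phenotyping"),
        (4, "Dy162", "CD8a", "phenotyping"),
        (5, "Dy161", "CD20", "phenotyping"),
        (6, "Yb176", "CD7", "phenotyping"),
        (7, "Tb159", "CD68", "phenotyping"),
        (8, "Nd150", "CD204", "phenotyping"),
        (9, "Nd142", "CA19-9", "tumor"),
        (10, "Pr141", "aSMA", "stroma"),
        (11, "Tm169", "collagen", "stroma"),
    ]
    return Panel.from_records(rows)
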