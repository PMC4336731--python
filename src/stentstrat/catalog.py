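"""Catalogue of predictive variables and their grouping into feature sets.

Predictive variables fall into two families: clinical variables (demographics,
history, angiographic measurements) and in vitro diagnostic (IVD) biomarkers
(lipid panel and cardiac markers). Because the source registries collected
data over several years with changing protocols, not every variable exists
for every patient; each family is therefore organised into overlapping
feature *sets* (C1/C2/C3 for clinical, B1/B2/B3 for biomarkers) reflecting
which variables were recorded together in a given era. Classifiers are built
from one clinical set and one biomarker set (either of which may be NONE).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

CLINICAL_SET_IDS = ("C1", "C2", "C3")
BIOMARKER_SET_IDS = ("B1", "B2", "B3")
#: Sentinel set id for "use no features from this family".
NONE_SET = "NONE"

#: Options per family entering the exhaustive feature-set search: the three
#: catalogued sets plus the no-feature option, i.e. 4 x 4 = 16 combinations.
CLINICAL_OPTIONS = CLINICAL_SET_IDS + (NONE_SET,)
BIOMARKER_OPTIONS = BIOMARKER_SET_IDS + (NONE_SET,)


@dataclass(frozen=True)
class FeatureInfo:
    name: str
    family: str  # "clinical" | "biomarkers"
    kind: str  # "continuous" | "binary" | "categorical"
    levels: tuple[str, ...] = ()
    sets: tuple[str, ...] = ()


@dataclass
class FeatureCatalog:
    """Feature names, types and set membership for both variable families."""

    features: dict[str, FeatureInfo] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "FeatureCatalog":
        """Load the packaged catalogue (Tables of predictive variables)."""
        text = resources.files("stentstrat").joinpath("data/feature_catalog.json").read_text()
        return cls.from_mapping(json.loads(text))

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureCatalog":
        """Load a user-supplied catalogue override (same JSON layout)."""
        return cls.from_mapping(json.loads(Path(path).read_text()))

    @classmethod
    def from_mapping(cls, raw: dict) -> "FeatureCatalog":
        feats: dict[str, FeatureInfo] = {}
        for family in ("clinical", "biomarkers"):
            for name, meta in raw[family].items():
                feats[name] = FeatureInfo(
                    name=name,
                    family=family,
                    kind=meta["kind"],
                    levels=tuple(meta.get("levels", ())),
                    sets=tuple(meta["sets"]),
                )
        return cls(features=feats)

    # -- set accessors ----------------------------------------------------
    def family_names(self, family: str) -> list[str]:
        return [f.name for f in self.features.values() if f.family == family]

    @property
    def clinical_names(self) -> list[str]:
        return self.family_names("clinical")

    @property
    def biomarker_names(self) -> list[str]:
        return self.family_names("biomarkers")

    @property
    def clinical_sets(self) -> dict[str, list[str]]:
        return {s: self.set_members(s) for s in CLINICAL_SET_IDS}

    @property
    def biomarker_sets(self) -> dict[str, list[str]]:
        return {s: self.set_members(s) for s in BIOMARKER_SET_IDS}

    def set_members(self, set_id: str) -> list[str]:
        """Feature names belonging to a set id; NONE yields the empty list."""
        if set_id == NONE_SET:
            return []
        if set_id not in CLINICAL_SET_IDS + BIOMARKER_SET_IDS:
            raise KeyError(f"unknown feature set id: {set_id!r}")
        return [f.name for f in self.features.values() if set_id in f.sets]

    def pair_members(self, pair: tuple[str, str]) -> list[str]:
        """Union of features for a (clinical set, biomarker set) pair."""
        ci, bj = pair
        if ci not in CLINICAL_OPTIONS:
            raise KeyError(f"clinical set id must be one of {CLINICAL_OPTIONS}, got {ci!r}")
        if bj not in BIOMARKER_OPTIONS:
            raise KeyError(f"biomarker set id must be one of {BIOMARKER_OPTIONS}, got {bj!r}")
        return self.set_members(ci) + self.set_members(bj)

    def kind(self, name: str) -> str:
        return self.features[name].kind

    def levels(self, name: str) -> tuple[str, ...]:
        return self.features[name].levels

    def __contains__(self, name: str) -> bool:
        return name in self.features
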