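"""Domain containers shared by every stage of the pipeline.

Relative abundances are stored as fractions of 1 throughout; thresholds
quoted as percentages elsewhere (e.g. a 0.01% detection floor) are held
internally as fractions (1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional

import numpy as np
import pandas as pd


class FeatureKind(str, Enum):
    taxon = "taxon"
    pathway = "pathway"


class Rank(str, Enum):
    phylum = "phylum"
    genus = "genus"
    species = "species"
    unknown = "unknown"


#: MetaPhlAn-style rank prefixes, most specific last.
RANK_PREFIXES = {
    "p__": Rank.phylum,
    "g__": Rank.genus,
    "s__": Rank.species,
}


class ValidationError(ValueError):
    """Input data violates a container invariant."""


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class AbundanceTable:
    """Samples x features matrix of non-negative relative abundances.

    ``data`` is indexed by sample id with one column per feature.  ``rank``
    carries the taxonomy rank parsed from MetaPhlAn-style prefixes; features
    without a prefix are rank-unknown.  When ``normalized`` is set, every
    sample row sums to 1 within 1e-6.
    """

    data: pd.DataFrame
    feature_kind: FeatureKind = FeatureKind.taxon
    rank: Optional[pd.Series] = None  # feature -> Rank
    normalized: bool = False

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValidationError("abundance values must be non-negative")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate feature ids")
        if self.rank is not None:
            self.rank = self.rank.reindex(self.data.columns).fillna(Rank.unknown)
        if self.normalized:
            sums = vals.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValidationError("normalized flag set but sample sums differ from 1")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def normalize(self) -> "AbundanceTable":
        """Rescale every sample to sum 1.  Idempotent; all-zero samples rejected."""
        vals = self.data.to_numpy(dtype=float)
        sums = vals.sum(axis=1)
        if np.any(sums <= 0):
            bad = self.data.index[sums <= 0][0]
            raise ValidationError(f"sample {bad!r} has zero total abundance")
        out = self.data.div(sums, axis=0)
        return AbundanceTable(out, self.feature_kind, self.rank, normalized=True)

    def subset_samples(self, ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(ids)], self.feature_kind, self.rank,
                              normalized=self.normalized)

    def subset_features(self, ids) -> "AbundanceTable":
        rank = self.rank.loc[list(ids)] if self.rank is not None else None
        return AbundanceTable(self.data[list(ids)], self.feature_kind, rank,
                              normalized=False)


class Compartment(str, Enum):
    plasma = "plasma"
    tissue = "tissue"


class MetabMode(str, Enum):
    untargeted = "untargeted"
    targeted = "targeted"


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites matrix of intensities (untargeted) or
    concentrations (targeted), tagged with the sampled compartment."""

    data: pd.DataFrame
    compartment: Compartment
    mode: MetabMode = MetabMode.untargeted

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValidationError("metabolite values must be finite")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValidationError("duplicate sample or metabolite ids")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> List[str]:
        return list(self.data.columns)


class Group(str, Enum):
    MK = "MK"  # multiple-keloid patients
    NS = "NS"  # normal-scar controls


@dataclass
class SampleMetadata:
    """Two-group sample labels (MK = multiple keloid, NS = normal scar)."""

    group: pd.Series  # sample id -> "MK" | "NS"

    def __post_init__(self) -> None:
        self.group = self.group.astype(str)
        bad = set(self.group.unique()) - {g.value for g in Group}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if self.group.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        for g in Group:
            if (self.group == g.value).sum() == 0:
                raise ValidationError(f"group {g.value} is empty")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.group.index)

    def ids_in(self, group: str) -> List[str]:
        return list(self.group.index[self.group == str(group)])

    def labels_for(self, ids) -> np.ndarray:
        return self.group.loc[list(ids)].to_numpy()


@dataclass
class GeneSetCollection:
    """Named gene sets (pathway -> member genes), e.g. metabolic pathways."""

    sets: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> List[str]:
        return self.sets[name]
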