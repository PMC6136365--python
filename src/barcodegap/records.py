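"""Domain record types: checklist species, barcode accessions, surveys."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .markers import MarkerRegion
from .names import ParsedTaxon


class GrowthForm(str, Enum):
    TREE = "tree"
    TALL_SHRUB = "tall_shrub"
    PALM = "palm"
    FERN = "fern"
    CACTUS = "cactus"
    BAMBOO = "bamboo"
    HEMIEPIPHYTE = "hemiepiphyte"


class ThreatClass(str, Enum):
    """IUCN red-list categories plus NONE for unassessed species."""

    LC = "LC"
    NT = "NT"
    DD = "DD"
    VU = "VU"
    EN = "EN"
    CR = "CR"
    EW = "EW"
    EX = "EX"
    NONE = "NONE"


#: Categories counted as "threatened": vulnerable, endangered, critically
#: endangered, extinct in the wild, extinct.
THREATENED_CLASSES = frozenset(
    {ThreatClass.VU, ThreatClass.EN, ThreatClass.CR, ThreatClass.EW, ThreatClass.EX}
)


class DistributionClass(str, Enum):
    """Geographical-distribution classes, from widespread to most restricted."""

    NON_ENDEMIC = "non_endemic"
    EASTERN_SA_ENDEMIC = "eastern_sa_endemic"
    REGIONAL_ENDEMIC = "regional_endemic"
    LOCAL_ENDEMIC = "local_endemic"


#: Classes counted as "endemic" for priority scoring: regional + local.
ENDEMIC_CLASSES = frozenset(
    {DistributionClass.REGIONAL_ENDEMIC, DistributionClass.LOCAL_ENDEMIC}
)


class Source(str, Enum):
    GENBANK = "genbank"
    LOCAL_STUDY = "local_study"


class TaxLevel(str, Enum):
    SPECIES = "species"
    GENUS = "genus"
    FAMILY = "family"
    ORDER = "order"


UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class SpeciesRecord:
    """One checklist entry with taxonomy and conservation attributes."""

    binomial: str
    genus: str
    family: str
    order: str
    growth_form: GrowthForm
    naturalized: bool
    threat_class: ThreatClass
    distribution_class: DistributionClass

    @property
    def threatened(self) -> bool:
        return self.threat_class in THREATENED_CLASSES

    @property
    def endemic(self) -> bool:
        return self.distribution_class in ENDEMIC_CLASSES


@dataclass(frozen=True)
class AccessionRecord:
    """Metadata for one deposited barcode sequence.

    ``species`` is the checklist binomial the raw label resolved to, or
    :data:`UNRESOLVED`.  ``marker`` is ``None`` for non-barcode regions;
    such rows are retained but excluded from all barcode statistics.
    """

    accession_id: str
    raw_taxon: str
    species: str
    marker: Optional[MarkerRegion]
    submission_date: dt.date
    source: Source

    @property
    def resolved(self) -> bool:
        return self.species != UNRESOLVED

    @property
    def is_barcode(self) -> bool:
        return self.marker is not None


@dataclass
class CommunitySurvey:
    """One site's abundance records: (determination, individual count)."""

    survey_id: str
    records: list[tuple[ParsedTaxon, int]]
    sampled_area_ha: Optional[float] = None

    @property
    def total_individuals(self) -> int:
        return sum(n for _, n in self.records)


@dataclass
class LoadReport:
    """Accounting for an accession-table load: every input row is either
    resolved, unresolved, or skipped (bad date)."""

    n_rows: int = 0
    n_resolved: int = 0
    n_unresolved: int = 0
    n_skipped: int = 0
    unresolved_names: dict[str, int] = field(default_factory=dict)
    skipped_rows: list[str] = field(default_factory=list)
    n_trinomial: int = 0

    def check(self) -> None:
        assert self.n_resolved + self.n_unresolved + self.n_skipped == self.n_rows
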