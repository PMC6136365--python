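"""Parsing of taxon determination strings.

Community-survey and accession tables carry raw determinations such as
``"Trema micrantha"``, ``"Ocotea aff. puberula"``, ``"Eugenia cf.
pyriformis"``, ``"Myrcia sp."`` or bare family names.  The matching rules
follow standard floristic practice: *aff.* (affinis) records are reliable
only to genus, *cf.* (confer) records are attributed to the suggested
species, and *sp.* marks an indeterminate member of a genus.
Infraspecific ranks (var., subsp., f.) are folded into the parent binomial.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import MalformedNameError


class Qualifier(Enum):
    NONE = "none"
    AFF = "aff"
    CF = "cf"
    INDET = "indet"


class MatchLevel(Enum):
    """How far down the taxonomy a determination can be trusted."""

    NONE = 0
    FAMILY = 1
    GENUS = 2
    SPECIES = 3

    def __ge__(self, other: "MatchLevel") -> bool:
        return self.value >= other.value

    def __le__(self, other: "MatchLevel") -> bool:
        return self.value <= other.value

    def __gt__(self, other: "MatchLevel") -> bool:
        return self.value > other.value

    def __lt__(self, other: "MatchLevel") -> bool:
        return self.value < other.value


_QUALIFIER_TOKENS = {
    "aff": Qualifier.AFF,
    "affinis": Qualifier.AFF,
    "cf": Qualifier.CF,
    "cfr": Qualifier.CF,
    "confer": Qualifier.CF,
    "sp": Qualifier.INDET,
    "spp": Qualifier.INDET,
}

_INFRA_TOKENS = {"var", "subsp", "ssp", "f", "fo", "forma", "subvar"}

_UNKNOWN_TOKENS = {"indet", "indeterminada", "unknown", "ni", "na", "morta", "dead"}


@dataclass(frozen=True)
class ParsedTaxon:
    """A parsed determination with its usable taxonomic resolution."""

    genus: str
    epithet: Optional[str]
    qualifier: Qualifier
    match_level: MatchLevel
    family: Optional[str] = None
    infraspecific: bool = False

    @property
    def binomial(self) -> Optional[str]:
        """Canonical ``Genus epithet`` when a species-level name exists."""
        if self.genus and self.epithet:
            return f"{self.genus} {self.epithet}"
        return None

    def canonical(self) -> str:
        """Render the canonical string form; ``parse_taxon_name`` is
        idempotent on this rendering."""
        if self.match_level is MatchLevel.NONE:
            return "Indet."
        if self.match_level is MatchLevel.FAMILY:
            return self.family or "Indet."
        if self.qualifier is Qualifier.AFF:
            return f"{self.genus} aff. {self.epithet}" if self.epithet else f"{self.genus} sp."
        if self.qualifier is Qualifier.CF:
            return f"{self.genus} cf. {self.epithet}"
        if self.qualifier is Qualifier.INDET or not self.epithet:
            return f"{self.genus} sp."
        return f"{self.genus} {self.epithet}"


def _clean_token(tok: str) -> str:
    return tok.rstrip(".").lower()


def parse_taxon_name(raw: str) -> ParsedTaxon:
    """Parse a raw determination into a :class:`ParsedTaxon`.

    Rules
    -----
    * plain binomial -> species-level match;
    * ``aff.`` forces the match down to genus level;
    * ``cf.`` keeps the species-level match (suggested species accepted);
    * ``sp.``/``spp.`` -> indeterminate, genus-level match;
    * a single token ending in ``-aceae`` -> family-level determination;
    * trinomials are folded into the parent binomial (``infraspecific=True``);
    * recognisably unidentifiable strings (``Indet.``, ``NI`` ...) -> no match.

    Raises
    ------
    MalformedNameError
        If the string is empty after trimming.
    """
    if raw is None or not str(raw).strip():
        raise MalformedNameError("empty taxon name")
    tokens = re.split(r"\s+", str(raw).strip())

    first = _clean_token(tokens[0])
    if first in _UNKNOWN_TOKENS:
        return ParsedTaxon("", None, Qualifier.NONE, MatchLevel.NONE)
    if len(tokens) == 1 and first.endswith("aceae"):
        return ParsedTaxon("", None, Qualifier.NONE, MatchLevel.FAMILY,
                           family=tokens[0].capitalize())

    genus = tokens[0].capitalize()
    qualifier = Qualifier.NONE
    epithet: Optional[str] = None
    infraspecific = False

    rest = tokens[1:]
    i = 0
    while i < len(rest):
        tok = _clean_token(rest[i])
        if tok in _QUALIFIER_TOKENS:
            q = _QUALIFIER_TOKENS[tok]
            # first qualifier wins; "sp." after an epithet is noise
            if qualifier is Qualifier.NONE and epithet is None:
                qualifier = q
            i += 1
            continue
        if tok in _INFRA_TOKENS:
            # infraspecific rank: drop the rank and its epithet
            infraspecific = True
            i += 2
            continue
        if epithet is None and re.match(r"^[a-zA-Z-]+$", rest[i]):
            epithet = rest[i].lower()
        elif epithet is not None:
            # bare trinomial ("Genus epithet subepithet"): fold to binomial
            infraspecific = True
        i += 1

    if qualifier is Qualifier.AFF:
        level = MatchLevel.GENUS
    elif qualifier is Qualifier.INDET:
        level = MatchLevel.GENUS
        epithet = None
    elif epithet is None:
        # bare genus name: usable at genus level only
        qualifier = Qualifier.INDET
        level = MatchLevel.GENUS
    else:
        level = MatchLevel.SPECIES
    return ParsedTaxon(genus, epithet, qualifier, level,
                       infraspecific=infraspecific)
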