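"""Canonical plant DNA-barcode marker regions and label normalization.

Ten candidate plant barcoding regions are tracked: the two core plastid
barcodes (rbcL, matK), the nuclear ribosomal ITS region (the composite
18S|ITS1|5.8S|ITS2|26S cistron), psbA-trnH, and the supplementary plastid
regions atpF-atpH, psbK-psbI, rpoB, rpoC1, trnL and ycf1.  Everything else
(COI, whole plastomes, microsatellites, ...) normalizes to ``None`` —
retained in accession tables but excluded from all barcode statistics.
"""

from __future__ import annotations

import re
from enum import Enum
from typing import Optional


class MarkerRegion(str, Enum):
    """The ten candidate plant barcode regions."""

    ATPF_ATPH = "atpF-atpH"
    ITS = "ITS"
    MATK = "matK"
    PSBA_TRNH = "psbA-trnH"
    PSBK_PSBI = "psbK-psbI"
    RBCL = "rbcL"
    RPOB = "rpoB"
    RPOC1 = "rpoC1"
    TRNL = "trnL"
    YCF1 = "ycf1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Core two-marker set used for the endemism presence/absence contrast.
CORE_MARKERS = (MarkerRegion.RBCL, MarkerRegion.MATK)

#: The five regions that dominate current libraries.
TOP5_MARKERS = (
    MarkerRegion.ITS,
    MarkerRegion.RBCL,
    MarkerRegion.PSBA_TRNH,
    MarkerRegion.MATK,
    MarkerRegion.TRNL,
)

ALL_MARKERS = tuple(MarkerRegion)


def _key(label: str) -> str:
    """Collapse a raw marker label to a lookup key: lowercase alphanumerics."""
    return re.sub(r"[^a-z0-9]+", "", label.lower())


# Synonym dictionary: lookup key -> canonical region.  ITS is composite, so
# any of its components map to it.
_SYNONYMS: dict[str, MarkerRegion] = {}


def _add(marker: MarkerRegion, *labels: str) -> None:
    for label in labels:
        _SYNONYMS[_key(label)] = marker


_add(
    MarkerRegion.ITS,
    "ITS",
    "ITS1",
    "ITS2",
    "ITS region",
    "5.8S",
    "18S",
    "26S",
    "internal transcribed spacer",
    "internal transcribed spacer 1",
    "internal transcribed spacer 2",
    "ITS1-5.8S-ITS2",
    "nrITS",
)
_add(
    MarkerRegion.RBCL,
    "rbcL",
    "rbcL gene",
    "rbcLa",
    "ribulose-1,5-bisphosphate carboxylase/oxygenase large subunit",
    "ribulose 1 5 bisphosphate carboxylase large subunit",
)
_add(MarkerRegion.MATK, "matK", "matK gene", "maturase K", "trnK-matK")
_add(
    MarkerRegion.PSBA_TRNH,
    "psbA-trnH",
    "trnH-psbA",
    "psbA-trnH intergenic spacer",
    "trnH-psbA intergenic spacer",
    "psbA trnH spacer",
)
_add(
    MarkerRegion.ATPF_ATPH,
    "atpF-atpH",
    "atpF-atpH intergenic spacer",
    "atpH-atpF",
)
_add(
    MarkerRegion.PSBK_PSBI,
    "psbK-psbI",
    "psbK-psbI intergenic spacer",
    "psbI-psbK",
)
_add(MarkerRegion.RPOB, "rpoB", "rpoB gene", "RNA polymerase beta subunit")
_add(MarkerRegion.RPOC1, "rpoC1", "rpoC1 gene")
_add(
    MarkerRegion.TRNL,
    "trnL",
    "trnL intron",
    "trnL-trnF",
    "trnL-F",
    "trnL (UAA) intron",
    "trnL P6 loop",
)
_add(MarkerRegion.YCF1, "ycf1", "ycf1 gene")


def normalize_marker(raw_label: str) -> Optional[MarkerRegion]:
    """Map a raw marker/gene label to a canonical :class:`MarkerRegion`.

    Unknown labels (non-barcode regions such as COI) return ``None``;
    normalization never raises.
    """
    if raw_label is None:
        return None
    return _SYNONYMS.get(_key(str(raw_label)))


def parse_marker_set(spec: str) -> tuple[MarkerRegion, ...]:
    """Parse a user marker-set spec: ``all``, ``top5``, ``core`` or a
    comma-separated list of labels (e.g. ``rbcL,matK``)."""
    s = spec.strip().lower()
    if s == "all":
        return ALL_MARKERS
    if s == "top5":
        return TOP5_MARKERS
    if s == "core":
        return CORE_MARKERS
    out = []
    for part in spec.split(","):
        m = normalize_marker(part)
        if m is None:
            raise ValueError(f"unknown marker label: {part!r}")
        out.append(m)
    return tuple(dict.fromkeys(out))
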