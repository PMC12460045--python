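"""The 14 ribosomal universal single-copy gene (USCG) families.

Ribosomal large- and small-subunit proteins are present in essentially every
bacterial and archaeal genome in a single copy, which makes their summed
per-family RPKM a per-sample proxy for "one genome's worth" of sequence.
Each family carries one or two KEGG Orthology identifiers and one COG.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class USCGFamily:
    """One marker family: its name, orthology labels and member reference ids.

    ``member_seq_ids`` is filled when a reference database is loaded; the
    bundled metadata ships with it empty.
    """

    family_name: str
    ko_ids: list[str]
    cog_id: str
    member_seq_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ko_ids:
            raise ValueError(f"family {self.family_name!r} has no KO ids")


# name, KO id(s), COG, prevalence in bacteria (%), prevalence in archaea (%)
_FAMILY_TABLE: list[tuple[str, tuple[str, ...], str, float, float]] = [
    ("S2_rpsB", ("K02967",), "COG0052", 99.50, 100.0),
    ("S10_rpsJ", ("K02946",), "COG0051", 98.51, 100.0),
    ("L6_rplF", ("K02933",), "COG0097", 99.50, 100.0),
    ("S12_S23", ("K02950", "K02973"), "COG0048", 99.17, 100.0),
    ("S15P_S13e", ("K02956", "K02953"), "COG0184", 99.84, 100.0),
    ("S19_rpsS", ("K02965",), "COG0185", 99.17, 100.0),
    ("L5_rplE", ("K02931",), "COG0094", 99.83, 100.0),
    ("L11_rplK", ("K02867",), "COG0080", 99.83, 100.0),
    ("L14b_L23e_rplN", ("K02874", "K02894"), "COG0093", 99.34, 100.0),
    ("L16_L10E_rplP", ("K02878", "K02866"), "COG0197", 99.67, 100.0),
    ("S7", ("K01316",), "COG0049", 99.67, 100.0),
    ("L3_rplC", ("K02906",), "COG0087", 99.50, 100.0),
    ("S5", ("K02988",), "COG0098", 99.50, 100.0),
    ("L2_rplB", ("K02886",), "COG0090", 99.50, 100.0),
]

#: Canonical family names, in the bundled order.
FAMILY_NAMES: tuple[str, ...] = tuple(row[0] for row in _FAMILY_TABLE)

N_FAMILIES: int = len(FAMILY_NAMES)

#: Typical mature-protein lengths (amino acids) for each family, used as the
#: defaults of the community simulator. Values are round figures for bacterial
#: ribosomal proteins (e.g. L2 ~275 aa, S15 ~89 aa).
DEFAULT_FAMILY_LENGTHS_AA: dict[str, int] = {
    "S2_rpsB": 240,
    "S10_rpsJ": 103,
    "L6_rplF": 178,
    "S12_S23": 124,
    "S15P_S13e": 89,
    "S19_rpsS": 92,
    "L5_rplE": 179,
    "L11_rplK": 141,
    "L14b_L23e_rplN": 122,
    "L16_L10E_rplP": 136,
    "S7": 156,
    "L3_rplC": 209,
    "S5": 166,
    "L2_rplB": 275,
}


def uscg_families() -> list[USCGFamily]:
    """Fresh ``USCGFamily`` objects for the bundled 14-family marker set."""
    return [
        USCGFamily(family_name=name, ko_ids=list(kos), cog_id=cog)
        for name, kos, cog, _, _ in _FAMILY_TABLE
    ]


def family_prevalence() -> dict[str, tuple[float, float]]:
    """Per-family (bacteria %, archaea %) genome prevalence of the marker."""
    return {name: (bact, arch) for name, _, _, bact, arch in _FAMILY_TABLE}
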