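"""Census summary statistics over the annotated DUB inventory.

The fission-yeast genome encodes 20 putative deubiquitinating enzymes across
four subfamilies (USP, UCH, OTU, JAMM). The packaged fixture records, per
enzyme, its domains, subcellular localization codes, stable interactors from
the AP-MS screen, budding-yeast and human orthologs, and whether the complex
membership is conserved in each organism. The summary reduces that table to
the census headline counts: how many DUBs have stable interactors, how many
are nuclear versus on specific cytoplasmic structures, how many have human
orthologs and human-conserved complexes, and how many distinct complexes
(total and small, i.e. excluding the proteasome and SAGA) were recovered.

Localization codes: N nucleus, NE nuclear envelope, No nucleolus,
C cytoplasm, CS cytoplasmic structure, M mitochondria; a parenthesised
qualifier names the structure (ER, endosomes, Golgi, cell tips/septum).
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from fractions import Fraction
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

LOCALIZATION_CODES = frozenset({"N", "NE", "No", "C", "CS", "M"})
NUCLEAR_CODES = frozenset({"N", "NE", "No"})
CYTOPLASMIC_STRUCTURE_CODES = frozenset({"CS", "M"})
SUBFAMILIES = frozenset({"USP", "UCH", "OTU", "JAMM"})
MACROMOLECULAR_COMPLEXES = frozenset({"26S proteasome", "SAGA"})

_LOC_TOKEN = re.compile(r"^(?P<code>[A-Za-z]+)(?:\((?P<qual>[^)]*)\))?$")


@dataclass(frozen=True)
class CensusRow:
    """One annotated DUB record."""

    dub: str
    uniprot: str
    subfamily: str
    domains: tuple[str, ...]
    localization: frozenset[str]
    localization_qualifiers: tuple[str, ...]
    interactors: tuple[str, ...]
    ortholog_sc: str | None
    ortholog_hs: str | None
    complex_conserved_sc: bool
    complex_conserved_hs: bool

    def __post_init__(self):
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"{self.dub}: unknown subfamily {self.subfamily!r}")
        if not self.localization:
            raise ValueError(f"{self.dub}: localization must be nonempty")
        unknown = self.localization - LOCALIZATION_CODES
        if unknown:
            raise ValueError(f"{self.dub}: unknown localization codes {sorted(unknown)}")


@dataclass(frozen=True)
class CensusSummary:
    """Headline counts and percentages over an annotation table."""

    n_dubs: int
    n_with_interactors: int
    pct_with_interactors: float
    n_nuclear: int
    pct_nuclear: float
    n_cytoplasmic_structures: int
    pct_cytoplasmic_structures: float
    n_hs_orthologs: int
    n_hs_complex_conserved: int
    n_complexes_total: int
    n_small_complexes: int

    def to_dict(self) -> dict:
        return asdict(self)


def _parse_localization(text: str) -> tuple[frozenset[str], tuple[str, ...]]:
    codes: set[str] = set()
    quals: list[str] = []
    for token in filter(None, (t.strip() for t in text.split("|"))):
        m = _LOC_TOKEN.match(token)
        if m is None:
            raise ValueError(f"malformed localization token: {token!r}")
        codes.add(m.group("code"))
        if m.group("qual"):
            quals.append(m.group("qual"))
    return frozenset(codes), tuple(quals)


def _split(text, sep: str = ";") -> tuple[str, ...]:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return ()
    return tuple(t.strip() for t in str(text).split(sep) if t.strip())


def rows_from_table(df: pd.DataFrame) -> list[CensusRow]:
    required = {
        "dub", "subfamily", "domains", "localization", "interactors",
        "ortholog_sc", "ortholog_hs", "complex_conserved_sc", "complex_conserved_hs",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        codes, quals = _parse_localization(str(rec.localization))
        ortho_sc = None if str(rec.ortholog_sc) in ("NA", "nan", "") else str(rec.ortholog_sc)
        ortho_hs = None if str(rec.ortholog_hs) in ("NA", "nan", "") else str(rec.ortholog_hs)
        rows.append(
            CensusRow(
                dub=str(rec.dub),
                uniprot=str(getattr(rec, "uniprot", "")),
                subfamily=str(rec.subfamily),
                domains=_split(rec.domains),
                localization=codes,
                localization_qualifiers=quals,
                interactors=_split(rec.interactors),
                ortholog_sc=ortho_sc,
                ortholog_hs=ortho_hs,
                complex_conserved_sc=bool(int(rec.complex_conserved_sc)),
                complex_conserved_hs=bool(int(rec.complex_conserved_hs)),
            )
        )
    return rows


def load_census_fixture() -> list[CensusRow]:
    """The packaged 20-row annotation table."""
    with resources.files("dubcensus.data").joinpath("table1_census.csv").open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    rows = rows_from_table(df)
    if len(rows) != 20:
        raise ValueError(f"fixture must hold 20 rows, found {len(rows)}")
    return rows


def load_complex_map() -> dict[str, str]:
    with resources.files("dubcensus.data").joinpath("complex_map.json").open() as fh:
        return json.load(fh)


def load_validated_partners() -> dict[str, list[str]]:
    with resources.files("dubcensus.data").joinpath("validated_partners.json").open() as fh:
        return json.load(fh)


def summarize_census(
    rows: Sequence[CensusRow],
    complex_map: Mapping[str, str] | None = None,
    macromolecular: frozenset[str] = MACROMOLECULAR_COMPLEXES,
) -> CensusSummary:
    """Reduce an annotation table to the census headline statistics.

    ``complex_map`` groups interactor names into complex identities (e.g. the
    three proteasomal baits share the 26S proteasome); every listed
    interactor must be mapped. Percentages are exact rationals rendered as
    floats.
    """
    if complex_map is None:
        complex_map = load_complex_map()
    n = len(rows)
    n_with = sum(1 for r in rows if r.interactors)
    n_nuc = sum(1 for r in rows if r.localization & NUCLEAR_CODES)
    n_cs = sum(1 for r in rows if r.localization & CYTOPLASMIC_STRUCTURE_CODES)
    n_hs = sum(1 for r in rows if r.ortholog_hs is not None)
    n_hs_cons = sum(1 for r in rows if r.complex_conserved_hs)

    complexes: set[str] = set()
    for r in rows:
        for interactor in r.interactors:
            if interactor not in complex_map:
                raise KeyError(f"interactor {interactor!r} missing from complex map")
            complexes.add(complex_map[interactor])

    def pct(count: int) -> float:
        return float(100 * Fraction(count, n)) if n else 0.0

    return CensusSummary(
        n_dubs=n,
        n_with_interactors=n_with,
        pct_with_interactors=pct(n_with),
        n_nuclear=n_nuc,
        pct_nuclear=pct(n_nuc),
        n_cytoplasmic_structures=n_cs,
        pct_cytoplasmic_structures=pct(n_cs),
        n_hs_orthologs=n_hs,
        n_hs_complex_conserved=n_hs_cons,
        n_complexes_total=len(complexes),
        n_small_complexes=len(complexes - macromolecular),
    )


def validated_partner_counts(
    bait: str, validated_lists: Mapping[str, Sequence[str]] | None = None
) -> int:
    """Number of named validated partners recorded for a bait."""
    if validated_lists is None:
        validated_lists = load_validated_partners()
    if bait not in validated_lists:
        raise KeyError(f"unknown bait: {bait!r}")
    return len(validated_lists[bait])
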