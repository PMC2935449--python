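"""Shared data model for the DUB interactome census pipeline.

The atomic evidence unit is the peptide-spectrum match (PSM); a purification
run is a bag of PSMs tied to a bait, a tag terminus, and a replicate index.
Protein entries live in a :class:`ProteinDB`, which is also the search space
for target-decoy protein inference.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DECOY_PREFIX = "rev_"

#: average residue mass, kDa; used to approximate protein mass from length
RESIDUE_MASS_KDA = 0.110


@dataclass(frozen=True)
class ProteinEntry:
    """One database entry: a target, a contaminant, or a reversed decoy."""

    accession: str
    sequence: str
    is_decoy: bool = False
    is_contaminant: bool = False
    species: str = "S. pombe"

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mass_kda(self) -> float:
        return self.length * RESIDUE_MASS_KDA

    def reversed_decoy(self) -> "ProteinEntry":
        return replace(
            self,
            accession=DECOY_PREFIX + self.accession,
            sequence=self.sequence[::-1],
            is_decoy=True,
        )


class ProteinDB:
    """Ordered, accession-unique collection of protein entries."""

    def __init__(self, entries: Iterable[ProteinEntry] = ()):
        self._entries: dict[str, ProteinEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: ProteinEntry) -> None:
        if entry.accession in self._entries:
            raise ValueError(f"duplicate accession: {entry.accession!r}")
        self._entries[entry.accession] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[ProteinEntry]:
        return iter(self._entries.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self._entries

    def __getitem__(self, accession: str) -> ProteinEntry:
        try:
            return self._entries[accession]
        except KeyError:
            raise KeyError(f"unknown accession: {accession!r}") from None

    def get(self, accession: str) -> ProteinEntry | None:
        return self._entries.get(accession)

    @property
    def targets(self) -> list[ProteinEntry]:
        return [e for e in self if not e.is_decoy and not e.is_contaminant]

    @property
    def contaminants(self) -> list[ProteinEntry]:
        return [e for e in self if e.is_contaminant and not e.is_decoy]

    @property
    def decoys(self) -> list[ProteinEntry]:
        return [e for e in self if e.is_decoy]

    # ---- FASTA I/O (decoys carry the ``rev_`` accession prefix) ----

    def to_fasta(self, path) -> None:
        records = []
        for e in self:
            desc = []
            if e.is_contaminant:
                desc.append("contaminant")
            desc.append(f"species={e.species}")
            records.append(
                SeqRecord(Seq(e.sequence), id=e.accession, description=" ".join(desc))
            )
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path) -> "ProteinDB":
        db = cls()
        for rec in SeqIO.parse(path, "fasta"):
            desc = rec.description
            species = "S. pombe"
            for tok in desc.split():
                if tok.startswith("species="):
                    species = tok.split("=", 1)[1]
            db.add(
                ProteinEntry(
                    accession=rec.id,
                    sequence=str(rec.seq),
                    is_decoy=rec.id.startswith(DECOY_PREFIX),
                    is_contaminant="contaminant" in desc.split(),
                    species=species,
                )
            )
        return db


@dataclass(frozen=True)
class PSM:
    """One peptide-spectrum match.

    ``interpretations`` counts the distinct peptide readings proposed for the
    spectrum (the "ambiguous IDs per result" of the identification filters);
    ``accessions`` is the set of database proteins containing the peptide.
    """

    run_id: str
    spectrum_id: str
    peptide: str
    charge: int
    score: float
    accessions: frozenset[str]
    interpretations: int = 1

    def __post_init__(self):
        if not self.peptide:
            raise ValueError("empty peptide")
        if not self.accessions:
            raise ValueError("PSM must map to at least one accession")
        if self.interpretations < 1:
            raise ValueError("interpretations must be >= 1")

    @property
    def is_decoy(self) -> bool:
        return all(a.startswith(DECOY_PREFIX) for a in self.accessions)


@dataclass
class Run:
    """One purification: a bait (or a negative control) with its PSMs."""

    run_id: str
    bait: str | None
    tag_terminus: str = "C"  # {C, N}
    replicate: int = 1  # {1, 2}
    is_control: bool = False
    psms: list[PSM] = field(default_factory=list)

    def __post_init__(self):
        if self.is_control and self.bait is not None:
            raise ValueError("control runs carry no bait")
        if self.tag_terminus not in ("C", "N"):
            raise ValueError("tag_terminus must be 'C' or 'N'")

    def tsc_by_protein(self) -> dict[str, int]:
        """Total spectral counts per accession (shared PSMs count for each)."""
        counts: dict[str, int] = {}
        for psm in self.psms:
            for acc in psm.accessions:
                counts[acc] = counts.get(acc, 0) + 1
        return counts


def run_index(run_id: str) -> int:
    """Stable 32-bit index for a run id, for per-run RNG stream derivation."""
    return zlib.crc32(run_id.encode())


def psms_to_table(psms: Iterable[PSM]) -> pd.DataFrame:
    rows = [
        {
            "run_id": p.run_id,
            "spectrum_id": p.spectrum_id,
            "peptide": p.peptide,
            "charge": p.charge,
            "score": p.score,
            "interpretations": p.interpretations,
            "accessions": ";".join(sorted(p.accessions)),
        }
        for p in psms
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "run_id",
            "spectrum_id",
            "peptide",
            "charge",
            "score",
            "interpretations",
            "accessions",
        ],
    )


def psms_from_table(df: pd.DataFrame) -> list[PSM]:
    return [
        PSM(
            run_id=str(r.run_id),
            spectrum_id=str(r.spectrum_id),
            peptide=str(r.peptide),
            charge=int(r.charge),
            score=float(r.score),
            interpretations=int(getattr(r, "interpretations", 1)),
            accessions=frozenset(str(r.accessions).split(";")),
        )
        for r in df.itertuples(index=False)
    ]


def manifest_to_table(runs: Iterable[Run]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "run_id": r.run_id,
                "bait": r.bait if r.bait is not None else "",
                "tag_terminus": r.tag_terminus,
                "replicate": r.replicate,
                "is_control": int(r.is_control),
            }
            for r in runs
        ],
        columns=["run_id", "bait", "tag_terminus", "replicate", "is_control"],
    )


def runs_from_manifest(
    df: pd.DataFrame, psms_by_run: Mapping[str, list[PSM]] | None = None
) -> list[Run]:
    runs = []
    for r in df.itertuples(index=False):
        bait = str(r.bait) if str(r.bait) not in ("", "nan") else None
        run = Run(
            run_id=str(r.run_id),
            bait=bait,
            tag_terminus=str(r.tag_terminus),
            replicate=int(r.replicate),
            is_control=bool(int(r.is_control)),
        )
        if psms_by_run is not None:
            run.psms = list(psms_by_run.get(run.run_id, []))
        runs.append(run)
    return runs
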