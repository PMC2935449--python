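"""Target-decoy filtering and parsimony protein inference.

The search database concatenates every target and contaminant sequence with
its exact reversal (decoy), so the rate at which decoys pass the score filter
estimates the false-discovery rate among accepted matches. PSMs are filtered
by peptide length, spectrum ambiguity, and a decoy-calibrated score cutoff;
surviving peptides are then explained by a minimal (parsimonious) list of
protein groups built by greedy set cover, with proteins sharing identical
peptide evidence merged into a single indistinguishable group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import DECOY_PREFIX, PSM, ProteinDB, ProteinEntry


@dataclass(frozen=True)
class FilterParams:
    """Identification filter thresholds (defaults match the census analysis)."""

    max_fdr: float = 0.01
    max_ambiguous_ids: int = 2
    min_peptide_length: int = 5
    min_distinct_peptides: int = 5
    min_additional_peptides: int = 2

    def __post_init__(self):
        if not (0 < self.max_fdr <= 1):
            raise ValueError("max_fdr must lie in (0, 1]")
        for name in (
            "max_ambiguous_ids",
            "min_peptide_length",
            "min_distinct_peptides",
            "min_additional_peptides",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ProteinGroup:
    """A set of indistinguishable proteins explaining a shared peptide set."""

    accessions: tuple[str, ...]
    peptides: frozenset[str]
    tsc: int
    coverage: float  # fraction of residues of the representative accession
    contains_decoy: bool
    contains_contaminant: bool = False

    @property
    def representative(self) -> str:
        return self.accessions[0]

    @property
    def distinct_peptides(self) -> int:
        return len(self.peptides)


def build_target_decoy_db(
    targets: list[ProteinEntry], contaminants: list[ProteinEntry] = ()
) -> ProteinDB:
    """Concatenate targets + contaminants with their reversed decoys.

    Output size is exactly twice the forward database; decoy accessions carry
    the ``rev_`` prefix and reversed sequences.
    """
    db = ProteinDB()
    forward = list(targets) + list(contaminants)
    for entry in forward:
        if entry.is_decoy:
            raise ValueError(f"decoy entry in forward database: {entry.accession}")
        db.add(entry)
    for entry in forward:
        db.add(entry.reversed_decoy())
    return db


def estimate_fdr(n_target_psms: int, n_decoy_psms: int) -> float:
    """Concatenated-search FDR estimate 2D/(T+D), clamped to [0, 1]."""
    if n_target_psms < 0 or n_decoy_psms < 0:
        raise ValueError("counts must be nonnegative")
    total = n_target_psms + n_decoy_psms
    if total == 0:
        raise ValueError("FDR undefined: no PSMs")
    return min(1.0, 2.0 * n_decoy_psms / total)


def filter_psms(psms: list[PSM], params: FilterParams = FilterParams()) -> list[PSM]:
    """Apply length, ambiguity, and decoy-calibrated score filters.

    After dropping short peptides and over-ambiguous spectra, the lowest score
    cutoff is chosen such that the estimated FDR among PSMs at or above it
    stays within ``params.max_fdr``; input order is preserved in the output.
    """
    eligible = [
        p
        for p in psms
        if len(p.peptide) >= params.min_peptide_length
        and p.interpretations <= params.max_ambiguous_ids
    ]
    if not eligible:
        return []

    # scan score thresholds from the top; equal scores enter together
    ranked = sorted(eligible, key=lambda p: -p.score)
    best_cutoff: float | None = None
    t = d = 0
    i = 0
    n = len(ranked)
    while i < n:
        j = i
        while j < n and ranked[j].score == ranked[i].score:
            if ranked[j].is_decoy:
                d += 1
            else:
                t += 1
            j += 1
        if estimate_fdr(t, d) <= params.max_fdr:
            best_cutoff = ranked[i].score
        i = j
    if best_cutoff is None:
        return []
    return [p for p in eligible if p.score >= best_cutoff]


def _peptide_positions(peptide: str, sequence: str) -> list[tuple[int, int]]:
    """All (start, end) occurrences of a peptide in a protein sequence."""
    spans = []
    start = sequence.find(peptide)
    while start != -1:
        spans.append((start, start + len(peptide)))
        start = sequence.find(peptide, start + 1)
    return spans


def infer_protein_groups(
    psms: list[PSM],
    db: ProteinDB,
    params: FilterParams = FilterParams(),
) -> tuple[list[ProteinGroup], set[str]]:
    """Greedy parsimonious protein grouping over filtered PSMs.

    Proteins with identical evidence-peptide sets are merged into one group.
    Groups are then accepted greedily: each accepted group must carry at least
    ``min_distinct_peptides`` distinct peptides overall and explain at least
    ``min_additional_peptides`` peptides not already explained. Ties break on
    most new peptides, then highest TSC, then smallest accession.

    Returns the accepted groups plus the set of orphaned peptides (peptides
    whose only candidate proteins failed the acceptance thresholds).
    """
    pep_to_psms: dict[str, list[PSM]] = {}
    acc_to_peps: dict[str, set[str]] = {}
    for psm in psms:
        pep_to_psms.setdefault(psm.peptide, []).append(psm)
        for acc in psm.accessions:
            acc_to_peps.setdefault(acc, set()).add(psm.peptide)

    # merge indistinguishable proteins (identical peptide evidence)
    by_evidence: dict[frozenset[str], list[str]] = {}
    for acc, peps in acc_to_peps.items():
        by_evidence.setdefault(frozenset(peps), []).append(acc)

    candidates = []
    for peps, accs in by_evidence.items():
        accs = tuple(sorted(accs))
        tsc = len({(p.run_id, p.spectrum_id) for pep in peps for p in pep_to_psms[pep]})
        candidates.append((accs, peps, tsc))

    accepted: list[ProteinGroup] = []
    explained: set[str] = set()
    all_peptides = set(pep_to_psms)
    remaining = list(candidates)
    while True:
        best = None
        best_key = None
        for accs, peps, tsc in remaining:
            if len(peps) < params.min_distinct_peptides:
                continue
            new = len(peps - explained)
            if new < params.min_additional_peptides:
                continue
            key = (-new, -tsc, accs[0])
            if best_key is None or key < best_key:
                best_key = key
                best = (accs, peps, tsc)
        if best is None:
            break
        accs, peps, tsc = best
        remaining = [c for c in remaining if c[0] != accs]
        explained |= peps
        entry = db.get(accs[0])
        coverage = 0.0
        if entry is not None and entry.length > 0:
            covered: set[int] = set()
            for pep in peps:
                for start, end in _peptide_positions(pep, entry.sequence):
                    covered.update(range(start, end))
            coverage = len(covered) / entry.length
        accepted.append(
            ProteinGroup(
                accessions=accs,
                peptides=peps,
                tsc=tsc,
                coverage=coverage,
                contains_decoy=any(a.startswith(DECOY_PREFIX) for a in accs),
                contains_contaminant=any(
                    (db.get(a) is not None and db[a].is_contaminant) for a in accs
                ),
            )
        )
    orphans = all_peptides - explained
    return accepted, orphans


def compute_run_summary(groups: list[ProteinGroup]) -> tuple[pd.DataFrame, float]:
    """Per-run protein table plus the decoy-estimated protein-level FDR (%).

    Columns mirror the published per-run tables: accession(s), sequence
    coverage percent, unique peptide count, and TSC. The protein FDR applies
    the same concatenated-search estimator at the group level.
    """
    rows = [
        {
            "accessions": ";".join(g.accessions),
            "seq_cov_pct": round(100.0 * g.coverage, 1),
            "uniq_seq": g.distinct_peptides,
            "tsc": g.tsc,
            "is_decoy": int(g.contains_decoy),
            "is_contaminant": int(g.contains_contaminant),
        }
        for g in sorted(groups, key=lambda g: -g.tsc)
    ]
    table = pd.DataFrame(
        rows,
        columns=["accessions", "seq_cov_pct", "uniq_seq", "tsc", "is_decoy", "is_contaminant"],
    )
    if not groups:
        fdr_pct = 0.0
    else:
        n_decoy = sum(1 for g in groups if g.contains_decoy)
        fdr_pct = 100.0 * estimate_fdr(len(groups) - n_decoy, n_decoy)
    return table, fdr_pct
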