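"""Replicate- and frequency-based interaction calling with spectral-count
stoichiometry classification.

A protein is considered a candidate interactor of a bait only if it appears
in both biological replicates of that bait's purification. Candidates are
then shaded by provenance: gray for proteins seen in negative controls or in
over half of unrelated purifications (likely background), blue for proteins
recurring in over half of all bait purifications (or in every N-terminal
purification), orange for gray-flagged proteins rescued by high abundance
relative to the bait, and yellow for the top-ranked specific candidate per
bait. Prey abundance relative to bait — the TSC ratio, mass-normalized by
default — classifies each call as stoichiometric (comparable amounts),
substoichiometric (a few percent of the bait), or intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .core import ProteinDB, Run

SHADES = ("unshaded", "gray", "blue", "orange", "yellow")
STOICH_CLASSES = ("stoichiometric", "intermediate", "substoichiometric")


@dataclass(frozen=True)
class CallParams:
    """Thresholds for shading and stoichiometry classification."""

    gray_frequency_threshold: float = 0.5
    blue_frequency_threshold: float = 0.5
    orange_ratio_threshold: float = 0.5
    stoichiometric_ratio: float = 0.5
    substoichiometric_ratio: float = 0.1
    normalize_by_mass: bool = True


@dataclass(frozen=True)
class InteractionCall:
    """One bait-prey call with its shade label and stoichiometry class."""

    bait: str
    prey: str
    mean_tsc: float
    tsc_ratio: float
    shade: str
    stoichiometry_class: str

    def __post_init__(self):
        if self.shade not in SHADES:
            raise ValueError(f"unknown shade: {self.shade!r}")
        if self.stoichiometry_class not in STOICH_CLASSES:
            raise ValueError(f"unknown class: {self.stoichiometry_class!r}")


ProteinTable = Mapping[str, float]  # accession -> TSC for one run


def intersect_replicates(
    rep1: ProteinTable, rep2: ProteinTable
) -> dict[str, float]:
    """Proteins present in both replicates, with replicate-mean TSC."""
    return {
        acc: (rep1[acc] + rep2[acc]) / 2.0 for acc in rep1.keys() & rep2.keys()
    }


def flag_gray(
    protein: str,
    control_sets: Sequence[frozenset[str] | set[str]],
    unrelated_sets: Sequence[frozenset[str] | set[str]],
    threshold: float = 0.5,
) -> bool:
    """Background flag: in any negative control, or in strictly more than
    ``threshold`` of the unrelated purifications."""
    if not control_sets and not unrelated_sets:
        raise ValueError("no controls and no unrelated panel configured")
    if any(protein in s for s in control_sets):
        return True
    if unrelated_sets:
        frac = sum(protein in s for s in unrelated_sets) / len(unrelated_sets)
        return frac > threshold
    return False


def flag_blue(
    protein: str,
    all_bait_sets: Sequence[frozenset[str] | set[str]],
    n_terminal_sets: Sequence[frozenset[str] | set[str]] = (),
    threshold: float = 0.5,
) -> bool:
    """Promiscuity flag: in strictly more than ``threshold`` of all bait
    purifications, or in every N-terminal purification.

    The frequency rule needs at least two purifications to be meaningful; a
    panel of one is skipped (any prey would trivially sit at 100%).
    """
    if len(all_bait_sets) > 1:
        frac = sum(protein in s for s in all_bait_sets) / len(all_bait_sets)
        if frac > threshold:
            return True
    if n_terminal_sets and all(protein in s for s in n_terminal_sets):
        return True
    return False


def rescue_orange(
    call: InteractionCall, high_ratio_threshold: float = 0.5
) -> InteractionCall:
    """Rescue a gray call whose abundance relative to bait is high."""
    if call.shade == "gray" and call.tsc_ratio >= high_ratio_threshold:
        return replace(call, shade="orange")
    return call


def classify_stoichiometry(
    prey_tsc: float,
    bait_tsc: float,
    prey_mass: float = 1.0,
    bait_mass: float = 1.0,
    normalize_by_mass: bool = True,
    high: float = 0.5,
    low: float = 0.1,
) -> str:
    """Classify a prey by its (optionally mass-normalized) TSC ratio to bait."""
    if bait_tsc <= 0:
        raise ZeroDivisionError("bait TSC must be positive for a ratio")
    r = tsc_ratio(prey_tsc, bait_tsc, prey_mass, bait_mass, normalize_by_mass)
    if r >= high:
        return "stoichiometric"
    if r <= low:
        return "substoichiometric"
    return "intermediate"


def tsc_ratio(
    prey_tsc: float,
    bait_tsc: float,
    prey_mass: float = 1.0,
    bait_mass: float = 1.0,
    normalize_by_mass: bool = True,
) -> float:
    if bait_tsc <= 0:
        raise ZeroDivisionError("bait TSC must be positive for a ratio")
    if normalize_by_mass:
        if prey_mass <= 0 or bait_mass <= 0:
            raise ValueError("masses must be positive for normalization")
        return (prey_tsc / prey_mass) / (bait_tsc / bait_mass)
    return prey_tsc / bait_tsc


def _presence(tables: Mapping[str, ProteinTable], run_ids: Sequence[str]) -> set[str]:
    present: set[str] = set()
    for rid in run_ids:
        present |= set(tables.get(rid, {}))
    return present


def call_interactions(
    runs: Sequence[Run],
    tables: Mapping[str, ProteinTable] | None = None,
    db: ProteinDB | None = None,
    params: CallParams = CallParams(),
    unrelated_panel: Sequence[frozenset[str] | set[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full shading pipeline over a set of purification runs.

    ``tables`` maps run_id to a protein->TSC table (defaults to raw per-run
    spectral counts); ``unrelated_panel`` is a list of presence sets from
    unrelated purifications (defaults, for each bait, to the other baits'
    purifications, duplicates collapsed). Returns the full shaded call table
    and the validated (yellow) sub-table.
    """
    if tables is None:
        tables = {r.run_id: r.tsc_by_protein() for r in runs}

    by_bait: dict[tuple[str, str], dict[int, Run]] = {}
    controls: list[Run] = []
    for r in runs:
        if r.is_control:
            controls.append(r)
        else:
            reps = by_bait.setdefault((r.bait, r.tag_terminus), {})
            if r.replicate in reps:
                raise ValueError(f"duplicate replicate {r.replicate} for bait {r.bait}")
            reps[r.replicate] = r

    control_sets = [frozenset(tables.get(r.run_id, {})) for r in controls]

    # bait-level presence sets (duplicates collapsed), for gray/blue panels
    bait_presence: dict[tuple[str, str], set[str]] = {
        key: _presence(tables, [r.run_id for r in reps.values()])
        for key, reps in by_bait.items()
    }
    all_bait_sets = list(bait_presence.values())
    n_terminal_sets = [s for (b, term), s in bait_presence.items() if term == "N"]

    calls: list[InteractionCall] = []
    for (bait, terminus), reps in sorted(by_bait.items()):
        if set(reps) != {1, 2}:
            raise ValueError(
                f"bait {bait} ({terminus}-terminal) lacks a replicate pair"
            )
        merged = intersect_replicates(
            tables.get(reps[1].run_id, {}), tables.get(reps[2].run_id, {})
        )
        if bait not in merged:
            continue  # bait itself failed replication; nothing to ratio against
        bait_tsc = merged[bait]
        bait_mass = db[bait].mass_kda if (db is not None and bait in db) else 1.0

        if unrelated_panel is not None:
            panel = list(unrelated_panel)
        else:
            panel = [s for key, s in bait_presence.items() if key[0] != bait]

        bait_calls: list[InteractionCall] = []
        for prey in sorted(merged):
            if prey == bait:
                continue
            if db is not None and prey in db and db[prey].is_contaminant:
                continue  # cross-species contaminants removed from ID lists
            prey_mass = db[prey].mass_kda if (db is not None and prey in db) else 1.0
            ratio = tsc_ratio(
                merged[prey], bait_tsc, prey_mass, bait_mass, params.normalize_by_mass
            )
            stoich = classify_stoichiometry(
                merged[prey],
                bait_tsc,
                prey_mass,
                bait_mass,
                params.normalize_by_mass,
                high=params.stoichiometric_ratio,
                low=params.substoichiometric_ratio,
            )
            shade = "unshaded"
            if (control_sets or panel) and flag_gray(
                prey, control_sets, panel, params.gray_frequency_threshold
            ):
                shade = "gray"
            elif flag_blue(
                prey,
                all_bait_sets,
                n_terminal_sets if terminus == "N" else (),
                params.blue_frequency_threshold,
            ):
                shade = "blue"
            call = InteractionCall(
                bait=bait,
                prey=prey,
                mean_tsc=merged[prey],
                tsc_ratio=ratio,
                shade=shade,
                stoichiometry_class=stoich,
            )
            bait_calls.append(rescue_orange(call, params.orange_ratio_threshold))

        # yellow: top-ranked specific (unshaded) prey by TSC ratio
        unshaded = [c for c in bait_calls if c.shade == "unshaded"]
        if unshaded:
            top = max(unshaded, key=lambda c: c.tsc_ratio)
            bait_calls = [
                replace(c, shade="yellow") if c is top else c for c in bait_calls
            ]
        calls.extend(bait_calls)

    cols = ["bait", "prey", "mean_tsc", "tsc_ratio", "shade", "stoichiometry_class"]
    full = pd.DataFrame([c.__dict__ for c in calls], columns=cols)
    validated = full[full["shade"] == "yellow"].reset_index(drop=True)
    return full, validated
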