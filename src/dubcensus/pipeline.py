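"""End-to-end convenience wrappers: simulated runs -> PSM filtering ->
parsimony inference -> per-run protein tables -> interaction calls."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .core import ProteinDB, Run
from .inference import FilterParams, compute_run_summary, filter_psms, infer_protein_groups
from .interactions import CallParams, call_interactions


def infer_run_table(
    run: Run, db: ProteinDB, params: FilterParams = FilterParams()
) -> tuple[dict[str, float], pd.DataFrame, float]:
    """Filter one run's PSMs and infer its protein table.

    Returns (protein->TSC table keyed by group representative, the full
    summary table, protein-level FDR percent). Decoy groups are excluded
    from the TSC table but counted in the FDR.
    """
    kept = filter_psms(run.psms, params)
    groups, _orphans = infer_protein_groups(kept, db, params)
    summary, fdr_pct = compute_run_summary(groups)
    table = {g.representative: float(g.tsc) for g in groups if not g.contains_decoy}
    return table, summary, fdr_pct


def run_census_pipeline(
    runs: Sequence[Run],
    db: ProteinDB,
    filter_params: FilterParams = FilterParams(),
    call_params: CallParams = CallParams(),
    unrelated_panel=None,
) -> tuple[pd.DataFrame, pd.DataFrame, Mapping[str, float]]:
    """Full pipeline over a run set.

    Returns (shaded call table, validated sub-table, per-run protein FDR %).
    """
    tables: dict[str, dict[str, float]] = {}
    fdrs: dict[str, float] = {}
    for run in runs:
        table, _summary, fdr = infer_run_table(run, db, filter_params)
        tables[run.run_id] = table
        fdrs[run.run_id] = fdr
    calls, validated = call_interactions(
        runs, tables=tables, db=db, params=call_params, unrelated_panel=unrelated_panel
    )
    return calls, validated, fdrs
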