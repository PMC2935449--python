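"""Quantifying DUB enzymatic activity and in vivo ubiquitination levels.

Activity comes from Ub-AMC hydrolysis traces: fluorescence released by
cleavage of the ubiquitin-AMC reporter, with a matched control trace (from
untagged cells or a catalytically dead point mutant) subtracted and the
result normalized to the amount of immunoprecipitated enzyme. Ubiquitinated-
protein levels come from blot quantifications: anti-ubiquitin signal divided
by a total-protein loading stain, with mutant/reference fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KineticTrace:
    """A fluorescence time course with its matched control and enzyme amount.

    ``timepoints`` in minutes (strictly increasing); fluorescence in
    arbitrary AMC units; ``protein_amount`` in arbitrary quantitative-imaging
    units (must be positive).
    """

    sample_id: str
    timepoints: np.ndarray
    fluorescence: np.ndarray
    control_fluorescence: np.ndarray
    protein_amount: float = 1.0

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.control_fluorescence = np.asarray(self.control_fluorescence, dtype=float)
        n = len(self.timepoints)
        if len(self.fluorescence) != n or len(self.control_fluorescence) != n:
            raise ValueError(f"{self.sample_id}: trace lengths do not align")
        if n < 2:
            raise ValueError(f"{self.sample_id}: need at least two timepoints")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError(f"{self.sample_id}: timepoints must strictly increase")
        if self.protein_amount <= 0:
            raise ValueError(f"{self.sample_id}: protein_amount must be positive")

    def corrected(self) -> np.ndarray:
        """Control-subtracted fluorescence, clipped at zero per timepoint."""
        return np.clip(self.fluorescence - self.control_fluorescence, 0.0, None)


@dataclass(frozen=True)
class BlotQuant:
    """One lane's anti-ubiquitin and total-protein integrated intensities."""

    sample_id: str
    ub_signal: float
    loading_signal: float

    def __post_init__(self):
        if self.loading_signal <= 0:
            raise ValueError(f"{self.sample_id}: loading signal must be positive")

    @property
    def ratio(self) -> float:
        return self.ub_signal / self.loading_signal


def corrected_activity(trace: KineticTrace, mode: str = "slope") -> float:
    """Control-subtracted, amount-normalized activity of one trace.

    ``slope`` (default) fits a least-squares line to the corrected trace and
    reports its slope per unit enzyme; ``endpoint`` reports the final
    corrected fluorescence per unit enzyme.
    """
    corrected = trace.corrected()
    if mode == "slope":
        fit = stats.linregress(trace.timepoints, corrected)
        value = float(fit.slope)
    elif mode == "endpoint":
        value = float(corrected[-1])
    else:
        raise ValueError(f"unknown activity mode: {mode!r}")
    return value / trace.protein_amount


def compare_activities(
    activities: Mapping[str, Sequence[float]], reference: str = "wild-type"
) -> pd.DataFrame:
    """Per-genotype activity ratios to the reference, with mean +/- SEM.

    SEM uses the n-1 replicate standard deviation; single-replicate
    genotypes report a NaN SEM.
    """
    if reference not in activities:
        raise KeyError(f"reference genotype {reference!r} missing")
    ref_mean = float(np.mean(activities[reference]))
    if ref_mean == 0:
        raise ZeroDivisionError("reference activity is zero")
    rows = []
    for genotype, values in activities.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 1:
            raise ValueError(f"{genotype}: needs at least one replicate")
        ratios = arr / ref_mean
        sem = float(np.std(ratios, ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
        rows.append(
            {
                "genotype": genotype,
                "n": arr.size,
                "mean_activity": float(arr.mean()),
                "ratio_to_reference": float(ratios.mean()),
                "sem": sem,
            }
        )
    return pd.DataFrame(rows, columns=["genotype", "n", "mean_activity", "ratio_to_reference", "sem"])


def ub_fold_change(mutant: BlotQuant, reference: BlotQuant) -> float:
    """Loading-normalized ubiquitin-signal fold change, mutant over reference."""
    if reference.ratio == 0:
        raise ZeroDivisionError("reference ubiquitin/loading ratio is zero")
    return mutant.ratio / reference.ratio


def traces_from_table(
    df: pd.DataFrame, amounts: Mapping[str, float] | None = None
) -> list[KineticTrace]:
    """Build traces from a long-form table with columns sample_id, time_min,
    fluorescence, control_fluorescence."""
    traces = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_min")
        traces.append(
            KineticTrace(
                sample_id=str(sample_id),
                timepoints=grp["time_min"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                control_fluorescence=grp["control_fluorescence"].to_numpy(),
                protein_amount=float(amounts.get(str(sample_id), 1.0)) if amounts else 1.0,
            )
        )
    return traces
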