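"""Spectrum-level preprocessing: minimum-peak exclusion and precursor-charge
assignment.

Two rules run before any database search. Spectra with fewer than six peaks
are discarded outright. For the rest, the precursor charge is inferred from
where the fragment intensity lies relative to the precursor m/z: a singly
charged precursor cannot yield fragments above its own m/z, so if 90% or less
of the total fragment intensity falls strictly below the precursor m/z the
spectrum is treated as +1; otherwise it is ambiguous between +2 and +3 and
both interpretations are carried forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from pyteomics import mgf as _mgf


@dataclass
class SpectrumRecord:
    """One MS2 spectrum: precursor m/z plus a centroided peak list.

    Peaks are kept sorted ascending by m/z; intensities must be nonnegative.
    """

    spectrum_id: str
    precursor_mz: float
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        for mz, inten in self.peaks:
            if mz <= 0:
                raise ValueError("peak m/z must be positive")
            if inten < 0:
                raise ValueError("peak intensity must be nonnegative")
        self.peaks = sorted(self.peaks, key=lambda p: p[0])

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def total_intensity(self) -> float:
        return float(sum(i for _, i in self.peaks))


@dataclass(frozen=True)
class ChargeAssignment:
    """Charge-state call for one spectrum: exactly {+1} or {+2, +3}."""

    spectrum_id: str
    charges: frozenset[int]

    def __post_init__(self):
        if self.charges not in (frozenset({1}), frozenset({2, 3})):
            raise ValueError("charges must be {+1} or {+2,+3}")


def filter_min_peaks(
    spectra: list[SpectrumRecord], min_peaks: int = 6
) -> list[SpectrumRecord]:
    """Drop spectra with fewer than ``min_peaks`` peaks, preserving order."""
    return [s for s in spectra if s.n_peaks >= min_peaks]


def assign_precursor_charges(
    spectrum: SpectrumRecord, intensity_fraction_threshold: float = 0.90
) -> ChargeAssignment:
    """Assign precursor charge(s) from the sub-precursor intensity fraction.

    Let f be the fraction of total intensity at m/z strictly below the
    precursor. f <= threshold -> {+1}; f > threshold -> {+2, +3}. Peaks at
    exactly the precursor m/z are not "lower than" it.
    """
    total = spectrum.total_intensity
    if total <= 0:
        raise ValueError(f"degenerate spectrum {spectrum.spectrum_id!r}: zero total intensity")
    below = sum(i for mz, i in spectrum.peaks if mz < spectrum.precursor_mz)
    f = below / total
    if f <= intensity_fraction_threshold:
        charges = frozenset({1})
    else:
        charges = frozenset({2, 3})
    return ChargeAssignment(spectrum_id=spectrum.spectrum_id, charges=charges)


def assign_all(
    spectra: list[SpectrumRecord], intensity_fraction_threshold: float = 0.90
) -> list[ChargeAssignment]:
    return [assign_precursor_charges(s, intensity_fraction_threshold) for s in spectra]


# ---- MGF I/O (TITLE is the spectrum id; first PEPMASS field is m/z) ----


def read_mgf(path) -> list[SpectrumRecord]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            title = str(params.get("title", ""))
            pepmass = params["pepmass"]
            mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            peaks = list(
                zip((float(x) for x in entry["m/z array"]),
                    (float(y) for y in entry["intensity array"]))
            )
            spectra.append(SpectrumRecord(spectrum_id=title, precursor_mz=mz, peaks=peaks))
    return spectra


def write_mgf(spectra: list[SpectrumRecord], path) -> None:
    entries = [
        {
            "m/z array": [mz for mz, _ in s.peaks],
            "intensity array": [i for _, i in s.peaks],
            "params": {"title": s.spectrum_id, "pepmass": s.precursor_mz},
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


def charges_to_table(assignments: list[ChargeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spectrum_id": a.spectrum_id,
                "charges": ";".join(f"+{c}" for c in sorted(a.charges)),
            }
            for a in assignments
        ],
        columns=["spectrum_id", "charges"],
    )
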