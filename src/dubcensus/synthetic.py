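"""Seeded generator for synthetic AP-MS purification data.

Emulates the statistical structure the census analysis assumes: duplicate
bait purifications with negative controls, prey spectral counts proportional
to bait abundance scaled by interaction stoichiometry and protein length,
frequency-structured background proteins recurring across unrelated runs,
decoy identifications injected at a tunable rate, and MS2 spectra whose peak
counts and sub-precursor intensity fraction are controllable so both
branches of the precursor-charge rule can be exercised.

Spectral counts follow a Poisson model with mean proportional to
stoichiometry x bait abundance x length ratio, reflecting the empirical
concordance of spectral counts with relative molecular mass. Every stream of
randomness derives from (master seed, run id), so identical configuration
plus seed reproduces byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from pyteomics import mass as _pmass

from .core import PSM, ProteinDB, ProteinEntry, Run, run_index
from .spectra import SpectrumRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Counts are entity counts; probabilities are per run; ``bait_tsc_mean`` is
    the expected spectral count of the bait itself;
    ``peptides_per_protein_rate`` is the expected number of distinct peptides
    per 100 residues.
    """

    n_target_proteins: int = 300
    n_contaminants: int = 20
    n_baits: int = 5
    complex_size_distribution: tuple[tuple[int, float], ...] = ((2, 0.5), (3, 0.5))
    stoichiometry_levels: tuple[float, ...] = (1.0, 0.5, 0.3)
    background_pool_size: int = 30
    background_occurrence_prob: float = 0.6
    decoy_psm_rate: float = 0.01
    bait_tsc_mean: float = 100.0
    peptides_per_protein_rate: float = 6.0
    seed: int = 0
    # secondary knobs
    background_tsc_mean: float = 2.0
    sequence_length_median: float = 450.0
    sequence_length_sigma: float = 0.35
    target_score_mean: float = 3.0
    decoy_score_mean: float = 1.0
    score_sd: float = 0.4
    peptide_length_range: tuple[int, int] = (7, 20)
    n_unrelated_panel: int = 20
    junk_spectrum_fraction: float = 0.0
    spectrum_peak_count: int = 30
    below_precursor_intensity_fraction: float = 0.95

    def __post_init__(self):
        for name in ("n_target_proteins", "n_contaminants", "n_baits",
                     "background_pool_size", "n_unrelated_panel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("background_occurrence_prob", "decoy_psm_rate",
                     "junk_spectrum_fraction"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for level in self.stoichiometry_levels:
            if not (0.0 < level <= 1.0):
                raise ValueError("stoichiometry levels must lie in (0, 1]")
        total = sum(p for _, p in self.complex_size_distribution)
        if self.complex_size_distribution and not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("complex size probabilities must sum to 1")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_mapping(cls, data: dict) -> "SimConfig":
        if "complex_size_distribution" in data:
            data["complex_size_distribution"] = tuple(
                (int(k), float(v)) for k, v in data["complex_size_distribution"]
            )
        if "stoichiometry_levels" in data:
            data["stoichiometry_levels"] = tuple(float(x) for x in data["stoichiometry_levels"])
        if "peptide_length_range" in data:
            data["peptide_length_range"] = tuple(int(x) for x in data["peptide_length_range"])
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text)
        return cls.from_mapping(data)


@dataclass
class GroundTruth:
    """True interactome: per-bait partner stoichiometries plus background."""

    complexes: dict[str, dict[str, float]] = field(default_factory=dict)
    background_set: frozenset[str] = frozenset()
    contaminant_set: frozenset[str] = frozenset()

    def partners(self, bait: str) -> dict[str, float]:
        if bait not in self.complexes:
            raise KeyError(f"unknown bait: {bait!r}")
        return self.complexes[bait]


def _rng_for(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *stream])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def generate_proteome(config: SimConfig) -> ProteinDB:
    """Draw target + contaminant proteins with lognormal sequence lengths."""
    rng = _rng_for(config, 1)
    db = ProteinDB()
    mu = math.log(config.sequence_length_median)
    for i in range(config.n_target_proteins):
        length = max(50, int(round(rng.lognormal(mu, config.sequence_length_sigma))))
        db.add(ProteinEntry(f"SPT{i + 1:04d}", _random_sequence(rng, length)))
    for i in range(config.n_contaminants):
        length = max(50, int(round(rng.lognormal(mu, config.sequence_length_sigma))))
        db.add(
            ProteinEntry(
                f"CONT{i + 1:03d}",
                _random_sequence(rng, length),
                is_contaminant=True,
                species="H. sapiens",
            )
        )
    return db


def generate_interactome(db: ProteinDB, config: SimConfig) -> GroundTruth:
    """Assign each bait a complex and designate a recurring background pool.

    Complex membership and the background pool are disjoint, so background
    occurrences are unambiguous false positives for the downstream filters.
    """
    rng = _rng_for(config, 2)
    targets = [e.accession for e in db.targets]
    if len(targets) < config.n_baits:
        raise ValueError(
            f"need at least {config.n_baits} target proteins, have {len(targets)}"
        )
    order = [str(a) for a in rng.permutation(targets)]
    baits = order[: config.n_baits]
    pool_cursor = config.n_baits

    sizes = [s for s, _ in config.complex_size_distribution]
    probs = [p for _, p in config.complex_size_distribution]
    complexes: dict[str, dict[str, float]] = {}
    for bait in baits:
        size = int(rng.choice(sizes, p=probs)) if sizes else 2
        n_partners = max(0, size - 1)
        partners = order[pool_cursor : pool_cursor + n_partners]
        pool_cursor += n_partners
        complexes[bait] = {
            p: float(rng.choice(config.stoichiometry_levels)) for p in partners
        }
    background = order[pool_cursor : pool_cursor + config.background_pool_size]
    if len(background) < config.background_pool_size:
        raise ValueError("not enough target proteins for the background pool")
    return GroundTruth(
        complexes=complexes,
        background_set=frozenset(background),
        contaminant_set=frozenset(e.accession for e in db.contaminants),
    )


def _sample_peptides(
    rng: np.random.Generator, entry: ProteinEntry, config: SimConfig, n_spectra: int
) -> list[str]:
    """Draw ``n_spectra`` peptide occurrences from a per-protein peptide pool."""
    lo, hi = config.peptide_length_range
    expected = config.peptides_per_protein_rate * entry.length / 100.0
    pool_size = max(1, int(rng.poisson(expected)))
    pool = []
    for _ in range(pool_size):
        plen = int(rng.integers(lo, hi + 1))
        plen = min(plen, entry.length)
        start = int(rng.integers(0, entry.length - plen + 1))
        pool.append(entry.sequence[start : start + plen])
    picks = rng.integers(0, len(pool), size=n_spectra)
    return [pool[i] for i in picks]


def simulate_run(
    truth: GroundTruth,
    db: ProteinDB,
    bait: str | None,
    replicate: int,
    is_control: bool,
    config: SimConfig,
    run_id: str | None = None,
    tag_terminus: str = "C",
) -> Run:
    """Simulate one purification run's PSM table.

    Bait TSC ~ Poisson(bait_tsc_mean); each true partner's TSC ~
    Poisson(stoichiometry x bait_tsc_mean x length ratio); each background
    protein appears independently with ``background_occurrence_prob`` at low
    TSC; decoy PSMs are injected at ``decoy_psm_rate``. Control runs carry
    only background and decoys.
    """
    if is_control:
        bait = None
    elif bait is None:
        raise ValueError("non-control runs require a bait")
    elif bait not in truth.complexes:
        raise KeyError(f"unknown bait: {bait!r}")

    if run_id is None:
        stem = "control" if is_control else bait
        run_id = f"{stem}_{tag_terminus}_rep{replicate}"
    rng = _rng_for(config, 3, run_index(run_id))
    run = Run(
        run_id=run_id,
        bait=bait,
        tag_terminus=tag_terminus,
        replicate=replicate,
        is_control=is_control,
    )

    counter = 0

    def emit(entry: ProteinEntry, n: int, score_mean: float) -> None:
        nonlocal counter
        for pep in _sample_peptides(rng, entry, config, n):
            counter += 1
            run.psms.append(
                PSM(
                    run_id=run_id,
                    spectrum_id=f"{run_id}.{counter:05d}",
                    peptide=pep,
                    charge=int(rng.choice([2, 3])),
                    score=float(rng.normal(score_mean, config.score_sd)),
                    accessions=frozenset({entry.accession}),
                )
            )

    if bait is not None:
        bait_entry = db[bait]
        bait_tsc = int(rng.poisson(config.bait_tsc_mean))
        emit(bait_entry, bait_tsc, config.target_score_mean)
        for partner, fraction in truth.partners(bait).items():
            partner_entry = db[partner]
            mean = (
                fraction
                * config.bait_tsc_mean
                * partner_entry.length
                / bait_entry.length
            )
            emit(partner_entry, int(rng.poisson(mean)), config.target_score_mean)

    for acc in sorted(truth.background_set):
        if rng.random() < config.background_occurrence_prob:
            n = max(1, int(rng.poisson(config.background_tsc_mean)))
            emit(db[acc], n, config.target_score_mean)

    n_true = len(run.psms)
    decoy_pool = db.decoys or [e.reversed_decoy() for e in db.targets]
    n_decoy = int(rng.binomial(max(n_true, 1), config.decoy_psm_rate))
    for _ in range(n_decoy):
        entry = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
        emit(entry, 1, config.decoy_score_mean)
    return run


def simulate_runset(
    truth: GroundTruth, db: ProteinDB, config: SimConfig
) -> list[Run]:
    """Duplicate purifications for every bait plus duplicate negative controls."""
    runs = []
    for bait in truth.complexes:
        for rep in (1, 2):
            runs.append(simulate_run(truth, db, bait, rep, False, config))
    for rep in (1, 2):
        runs.append(simulate_run(truth, db, None, rep, True, config))
    return runs


def simulate_spectra(run: Run, config: SimConfig) -> list[SpectrumRecord]:
    """One MS2 spectrum per PSM, plus optional junk spectra.

    The fraction of total intensity below the precursor m/z equals
    ``below_precursor_intensity_fraction`` and the peak count equals
    ``spectrum_peak_count``, so the downstream prefilter rules see exactly
    the configured regime.
    """
    rng = _rng_for(config, 4, run_index(run.run_id))
    spectra = []

    def build(spectrum_id: str, precursor_mz: float) -> SpectrumRecord:
        k = config.spectrum_peak_count
        f = config.below_precursor_intensity_fraction
        k_below = max(1, k // 2) if f > 0 else 0
        k_above = k - k_below
        peaks: list[tuple[float, float]] = []
        if k_below:
            mzs = rng.uniform(0.2 * precursor_mz, 0.999 * precursor_mz, size=k_below)
            weights = rng.uniform(0.5, 1.5, size=k_below)
            weights *= f / weights.sum()
            peaks += list(zip(map(float, mzs), map(float, weights)))
        if k_above:
            mzs = rng.uniform(1.001 * precursor_mz, 2.0 * precursor_mz, size=k_above)
            weights = rng.uniform(0.5, 1.5, size=k_above)
            weights *= (1.0 - f) / weights.sum()
            peaks += list(zip(map(float, mzs), map(float, weights)))
        return SpectrumRecord(spectrum_id=spectrum_id, precursor_mz=precursor_mz, peaks=peaks)

    for psm in run.psms:
        mz = _pmass.fast_mass(psm.peptide, charge=psm.charge)
        spectra.append(build(psm.spectrum_id, float(mz)))
    n_junk = int(round(config.junk_spectrum_fraction * len(run.psms)))
    for i in range(n_junk):
        spectra.append(build(f"{run.run_id}.junk{i + 1:04d}", float(rng.uniform(400, 2000))))
    return spectra
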