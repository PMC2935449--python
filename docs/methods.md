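# Methods

## Problem setting

Tandem affinity purification of a tagged bait followed by LC-MS/MS recovers
the bait, its stable partners, and a reproducible layer of background
proteins (resin binders, abundant cytoplasmic proteins, cross-species
contaminants such as keratin). Total spectral counts (TSC) — the number of
peptide-spectrum matches (PSMs) attributed to a protein — serve as a
semi-quantitative abundance proxy. The pipeline turns raw per-run evidence
into bait–prey calls with a stoichiometry class, merges them with curated
interactions, and summarizes a family-wide census.

## Spectrum prefiltering

Two rules run before any identification. Spectra with fewer than
`min_peaks = 6` peaks are removed. For the rest, let f be the fraction of
total fragment intensity at m/z strictly below the precursor m/z (a peak at
exactly the precursor m/z does not count as below). If f ≤ 0.90 the
precursor is called +1; otherwise both +2 and +3 interpretations are carried
forward as a set (not duplicated rows). The comparison uses summed
intensity, not peak counts, and both thresholds use the literal boundary
semantics (strict `<` for "below", `≤` at 90%). The rule is invariant to
uniform intensity rescaling; a spectrum with zero total intensity is a
degenerate-input error.

## Target-decoy filtering and parsimony inference

The search space concatenates every target and contaminant sequence with its
exact reversal, accession-prefixed `rev_`; output size is exactly twice the
forward database. The FDR among accepted PSMs is estimated with the standard
concatenated-search estimator FDR = 2D/(T+D), clamped to [0, 1] (undefined
when T = D = 0).

PSM filtering drops peptides shorter than 5 residues and spectra with more
than 2 distinct peptide interpretations, then chooses the lowest score
cutoff such that the estimated FDR among PSMs at or above it stays ≤ 1%
(equal scores enter or leave together). Raising the FDR ceiling can only
grow the retained set.

Protein grouping merges proteins with identical evidence-peptide sets into a
single indistinguishable group, then accepts groups greedily: each accepted
group must carry ≥ 5 distinct peptides overall and explain ≥ 2 peptides not
explained by previously accepted groups. Ties break on most new peptides,
then highest TSC, then lexicographically smallest accession, so output is
deterministic. Peptides whose only candidates fail these thresholds are
returned as orphans. Sequence coverage is the union of peptide-occurrence
intervals on the group's first accession. The run summary reports
accession(s), coverage %, unique peptides, and TSC per group, plus a
protein-level FDR using the same estimator over decoy-containing groups.

Greedy set cover is exactly minimal whenever the evidence family has the
subset/duplicate structure parsimony rules actually confront — maximal
proteins owning disjoint peptide blocks plus nested subset and duplicate
proteins — and the test suite proves equality against an exhaustive
minimal-cover oracle on 500 such instances. On arbitrary overlapping set
systems greedy can exceed the optimum (the classic ln n worst case); a
dedicated test generates unstructured instances, verifies any discrepancy is
one-sided (greedy ≥ optimum, still a valid cover), and records it. This is a
deliberate scope statement, not a defect: minimal-cover protein inference is
NP-hard in general, and practical tools use the same greedy accretion.

## Interaction calling

Per bait and tag terminus, exactly two biological replicates are required; a
prey must appear in both, and its TSC is the replicate mean. Cross-species
contaminants and the bait itself are removed. Shading then partitions the
calls:

- **gray** — in ≥ 1 negative-control run, or in strictly more than 50% of
  unrelated purifications (default panel: the other baits' purifications,
  duplicates collapsed to bait-level presence);
- **blue** — in strictly more than 50% of all bait purifications
  (bait-level, duplicates collapsed), or, for N-terminal purifications, in
  every N-terminal purification. A frequency rule over a single purification
  is vacuous (any prey would sit at 100%), so the >50% test requires at
  least two purifications;
- **orange** — formerly gray, rescued because its TSC ratio to bait is
  ≥ 0.5 (high relative abundance);
- **yellow** — the top-ranked remaining (specific) prey per bait by TSC
  ratio. Yellow is a rank, not a wet-lab truth claim;
- **unshaded** — everything else, the specific-candidate pool.

The TSC ratio is mass-normalized by default,
r = (prey_TSC/prey_mass)/(bait_TSC/bait_mass), since spectral counts scale
with protein size; classification uses r ≥ 0.5 → stoichiometric and
r ≤ 0.1 → substoichiometric, with intermediate between. The 0.5/0.1 cutoffs
are calibrated to the two qualitative poles seen in real data — partners
detected "in similar amounts" versus proteasome subunits at ~1–3% of the
bait — and are exposed as configuration.

## Network merging

Calls (after background exclusion) become a multigraph: nodes carry roles
(bait, validated partner, other); AP-MS edges carry mean TSC; curated edges
are added only between already-called proteins (induced-subgraph semantics)
and kept parallel to AP-MS edges rather than merged. Display width for AP-MS
edges is 1 + log(1 + TSC) — the data only constrain the mapping to be
monotone, and the log keeps hub baits readable. GraphML export is lossless
on this data model; SIF carries topology plus provenance only.

## Census statistics

The packaged fixture is a machine-readable 20-row annotation table of the
fission-yeast DUB family (subfamily, domains, localization codes,
interactors, orthologs, complex-conservation flags), shipped with a map from
interactor names to complex identities and with per-bait validated-partner
lists. "Nuclear" means any of the codes {N, NE, No}; "specific cytoplasmic
structures" means any of {CS, M} — the only readings that reproduce the
published 55%/35% pair simultaneously, documented here as a reconstruction.
Small complexes are the distinct complexes minus the macromolecular entries
(26S proteasome, SAGA). Percentages are computed as exact rationals.

## Kinetics

DUB activity on the fluorogenic substrate Ub-AMC is quantified per trace as
(fluorescence − matched control), clipped at zero per timepoint (signal
below control is noise), summarized either by the least-squares slope
(default; robust to a late plateau) or the endpoint, and divided by the
enzyme amount from quantitative imaging. Genotype comparisons report ratios
to a wild-type reference with mean ± SEM (n−1 standard deviation); with two
replicates the SEM equals half the absolute difference. Ubiquitination fold
change is the ratio of loading-normalized anti-ubiquitin intensities and is
invariant to per-lane rescaling. Band intensities are assumed linear; no
enzyme kinetic model (Km/kcat) is fitted.

## Synthetic data generator

The generator emulates the study design: per bait, two replicate
purifications plus duplicate negative controls. Counts follow a Poisson
model — bait TSC ~ Poisson(100); each partner ~ Poisson(stoichiometry ×
bait mean × length ratio), reflecting the concordance of spectral counts
with molecular mass; background-pool proteins occur independently per run
with probability 0.6 at low counts, implemented as max(1, Poisson(2)) so the
occurrence probability is honored exactly; decoy PSMs are injected at 1% of
the true PSM count with lower scores. Sequences are uniform over the 20
amino acids with lognormal lengths (median 450 aa), sufficient for
reversal-based decoys. Distinct peptides per protein are drawn from a
per-protein pool of expected size 6 per 100 residues — chosen to match the
tens of unique peptides that abundant baits show in real per-run tables; at
this rate abundant true proteins clear the 5-distinct-peptide filter while
background at 1–3 spectra cannot. Every run derives its own RNG stream from
(master seed, CRC32 of run id), so identical configuration and seed give
byte-identical outputs, including FASTA/MGF/TSV writers.

Defaults (the study conditions of the test suite): 300 target proteins, 20
contaminants, 5 baits, complex sizes 2–3, stoichiometry levels
{1.0, 0.5, 0.3}, background pool 30, unrelated-panel size follows the run
set itself (the real panel size is a laboratory-specific unknown; the
generator exposes it as a parameter, default 20). Spectra get a
configurable peak count (default 30) and sub-precursor intensity fraction
(default 0.95) so both precursor-charge branches and the minimum-peak rule
can be exercised.

What the generator does **not** model: fragment-ion physics, retention time,
isotope envelopes, intensity-based quantitation, correlated background
structure (real backgrounds co-occur in modules), shared peptides between
homologous targets (random sequences make peptide-to-protein maps nearly
injective), and score distributions of real search engines. Passing tests
therefore demonstrate correctness of the filtering logic and calibration
machinery under the stated statistical model, not performance on real
spectra.

## Problem sizes and numerical choices

The test suite and the acceptance script run purifications of a few hundred
PSMs over a ~640-entry concatenated database — large enough for every filter
to bind, small enough that the whole suite runs in seconds. The replicate-
recovery and FDR-calibration properties average over 20 and 50 seeds
respectively. Score ties in the FDR cutoff are resolved by moving whole
tie-groups; stoichiometry classification refuses bait TSC ≤ 0; replicate
pairing requires exactly replicates {1, 2} per bait and terminus; an empty
curated list, empty panels, and partnerless baits are all well-defined
degenerate inputs.

## Known limitations

- The decoy estimator assumes targets and decoys are exchangeable under the
  null; the synthetic score model makes them so by construction.
- The orange-rescue threshold (ratio ≥ 0.5) has no published quantitative
  anchor; it is a configuration default.
- Whether "over 50% of purifications" counts runs or baits is ambiguous in
  the source convention; baits (duplicates collapsed) is implemented.
- The FDR filter is applied at PSM level, pooled across charge states.
- Yellow/validated status in the original census additionally reflected
  co-IP and reciprocal-TAP experiments; here it is a computable rank only.
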