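"""Target-decoy construction, FDR-calibrated PSM filtering, and greedy
parsimony protein grouping, checked against small exhaustive oracles."""

import itertools

import numpy as np
import pytest

from dubcensus.core import PSM, ProteinDB, ProteinEntry
from dubcensus.inference import (
    FilterParams,
    build_target_decoy_db,
    compute_run_summary,
    estimate_fdr,
    filter_psms,
    infer_protein_groups,
)
from tests.conftest import make_psm


class TestBuildTargetDecoyDb:
    def test_published_entry_total(self):
        targets = [ProteinEntry(f"T{i}", "MKAVLLDE") for i in range(5020)]
        contams = [ProteinEntry(f"C{i}", "MKAVLLDE", is_contaminant=True) for i in range(73)]
        db = build_target_decoy_db(targets, contams)
        assert len(db) == 10186

    def test_empty_db(self):
        assert len(build_target_decoy_db([], [])) == 0

    def test_decoy_is_exact_reversal(self):
        db = build_target_decoy_db([ProteinEntry("A", "MKAV")])
        assert db["rev_A"].sequence == "VAKM"
        assert db["rev_A"].is_decoy

    def test_duplicate_accession_rejected(self):
        with pytest.raises(ValueError):
            build_target_decoy_db([ProteinEntry("A", "MK"), ProteinEntry("A", "AV")])


class TestEstimateFdr:
    @pytest.mark.parametrize(
        "t,d,expected", [(100, 0, 0.0), (199, 1, 0.01), (50, 50, 1.0), (10, 90, 1.0)]
    )
    def test_concatenated_estimator(self, t, d, expected):
        assert estimate_fdr(t, d) == pytest.approx(expected)

    def test_undefined_without_psms(self):
        with pytest.raises(ValueError):
            estimate_fdr(0, 0)


class TestFilterPsms:
    def test_short_peptide_removed(self):
        psms = [make_psm(peptide="PEPT")]  # length 4 < 5
        assert filter_psms(psms) == []

    def test_ambiguous_spectrum_removed(self):
        psms = [make_psm(interpretations=3)]
        assert filter_psms(psms) == []

    def test_clean_psm_retained(self):
        psms = [make_psm(peptide="PEPTI", interpretations=1)]
        assert filter_psms(psms) == psms

    def test_score_cutoff_calibrated_by_decoys(self):
        # 199 targets above one decoy: full set passes at 2*1/200 = 0.01
        psms = [make_psm(spectrum_id=f"s{i}", score=2.0 + i * 0.01) for i in range(199)]
        psms.append(make_psm(spectrum_id="d", score=1.0, accessions=("rev_P1",)))
        kept = filter_psms(psms, FilterParams(max_fdr=0.01))
        assert len(kept) == 200
        # a second decoy pushes the estimate to 2*2/201 > 0.01: tail trimmed
        psms.append(make_psm(spectrum_id="d2", score=0.5, accessions=("rev_P2",)))
        kept2 = filter_psms(psms, FilterParams(max_fdr=0.01))
        assert len(kept2) < len(psms)
        assert all(p.score >= min(q.score for q in kept2) for q in kept2 for p in kept2)

    def test_monotone_in_max_fdr(self):
        rng = np.random.default_rng(0)
        psms = []
        for i in range(100):
            decoy = rng.random() < 0.3
            acc = "rev_P" if decoy else "P"
            psms.append(
                make_psm(spectrum_id=f"s{i}", score=float(rng.normal(2 - decoy, 1)),
                         accessions=(f"{acc}{i}",))
            )
        sizes = [
            len(filter_psms(psms, FilterParams(max_fdr=f)))
            for f in (0.01, 0.05, 0.1, 0.5, 1.0)
        ]
        assert sizes == sorted(sizes)


def _psms_from_membership(membership: dict[str, set[int]], n_peptides: int):
    """One PSM per peptide index, mapped to every protein containing it."""
    peptides = [f"PEPTI{i:02d}X" for i in range(n_peptides)]
    psms = []
    for i, pep in enumerate(peptides):
        accs = {acc for acc, peps in membership.items() if i in peps}
        if accs:
            psms.append(make_psm(peptide=pep, spectrum_id=f"s{i}", accessions=tuple(accs)))
    return psms


def _structured_instance(rng, n_pep: int = 20) -> dict[str, set[int]]:
    """Random instance with real-data evidence structure: maximal proteins
    with disjoint peptide blocks, plus subset and duplicate proteins."""
    n_max = int(rng.integers(1, 5))
    cuts = sorted(rng.choice(range(1, n_pep), size=n_max - 1, replace=False)) if n_max > 1 else []
    bounds = [0, *map(int, cuts), n_pep]
    membership = {
        f"M{j}": set(range(bounds[j], bounds[j + 1])) for j in range(n_max)
    }
    for j in range(int(rng.integers(0, 8))):
        parent = membership[f"M{int(rng.integers(0, n_max))}"]
        if rng.random() < 0.3:
            membership[f"D{j}"] = set(parent)  # indistinguishable duplicate
        else:
            size = int(rng.integers(1, len(parent) + 1))
            membership[f"S{j}"] = {
                int(i) for i in rng.choice(sorted(parent), size=size, replace=False)
            }
    return membership


def _exhaustive_min_cover(membership: dict[str, set[int]]) -> int:
    """Smallest number of evidence-distinct groups covering all peptides."""
    groups: dict[frozenset[int], None] = {}
    for peps in membership.values():
        groups.setdefault(frozenset(peps))
    sets = list(groups)
    universe = frozenset().union(*sets) if sets else frozenset()
    for k in range(len(sets) + 1):
        for combo in itertools.combinations(sets, k):
            if frozenset().union(*combo, frozenset()) == universe:
                return k
    return len(sets)


class TestInferProteinGroups:
    loose = FilterParams(min_distinct_peptides=1, min_additional_peptides=1)

    def test_subset_protein_not_reported(self):
        membership = {"A": {0, 1, 2, 3, 4}, "B": {0, 1}}
        psms = _psms_from_membership(membership, 5)
        groups, orphans = infer_protein_groups(psms, ProteinDB())
        assert [g.accessions for g in groups] == [("A",)]
        assert not orphans

    def test_protein_below_five_distinct_peptides_not_reported(self):
        membership = {"A": {0, 1, 2, 3}}
        psms = _psms_from_membership(membership, 4)
        groups, orphans = infer_protein_groups(psms, ProteinDB())
        assert groups == []
        assert len(orphans) == 4

    def test_indistinguishable_proteins_share_one_group(self):
        membership = {"A": {0, 1, 2, 3, 4}, "B": {0, 1, 2, 3, 4}}
        psms = _psms_from_membership(membership, 5)
        groups, _ = infer_protein_groups(psms, ProteinDB())
        assert len(groups) == 1
        assert groups[0].accessions == ("A", "B")

    def test_min_additional_peptides_constraint(self):
        # B has 5 distinct peptides but only one novel after A is accepted
        membership = {"A": {0, 1, 2, 3, 4, 5}, "B": {0, 1, 2, 3, 6}}
        psms = _psms_from_membership(membership, 7)
        groups, orphans = infer_protein_groups(psms, ProteinDB())
        assert [g.accessions for g in groups] == [("A",)]
        assert orphans == {"PEPTI06X"}

    def test_every_peptide_explained_or_orphaned(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            membership = {
                f"P{j}": {int(i) for i in rng.choice(15, size=rng.integers(1, 8), replace=False)}
                for j in range(8)
            }
            psms = _psms_from_membership(membership, 15)
            groups, orphans = infer_protein_groups(psms, ProteinDB(), self.loose)
            explained = set().union(*(g.peptides for g in groups)) if groups else set()
            assert explained | orphans == {p.peptide for p in psms}
            assert not explained & orphans

    def test_greedy_matches_exhaustive_oracle_on_structured_instances(self):
        # evidence structured as real peptide maps are: distinct proteins own
        # disjoint peptide blocks, plus subset (shared-evidence) and duplicate
        # proteins — the regime parsimony rules are designed for
        rng = np.random.default_rng(12345)
        for trial in range(100):
            membership = _structured_instance(rng)
            psms = _psms_from_membership(membership, 20)
            groups, orphans = infer_protein_groups(psms, ProteinDB(), self.loose)
            assert not orphans  # no acceptance thresholds in loose mode
            assert len(groups) == _exhaustive_min_cover(membership)

    def test_greedy_suboptimality_detected_on_unstructured_instances(self):
        # with arbitrary overlapping sets greedy cover may exceed the true
        # minimum; any discrepancy must be one-sided (never below the optimum)
        # and the greedy output must still be a valid cover
        rng = np.random.default_rng(777)
        recorded = []
        for trial in range(100):
            n_prot = int(rng.integers(2, 13))
            n_pep = int(rng.integers(5, 21))
            membership = {
                f"P{j:02d}": {
                    int(i)
                    for i in rng.choice(
                        n_pep, size=int(rng.integers(1, max(2, n_pep // 2))), replace=False
                    )
                }
                for j in range(n_prot)
            }
            psms = _psms_from_membership(membership, n_pep)
            groups, orphans = infer_protein_groups(psms, ProteinDB(), self.loose)
            assert not orphans
            opt = _exhaustive_min_cover(membership)
            assert len(groups) >= opt
            if len(groups) != opt:
                recorded.append((trial, len(groups), opt))
        assert all(g > o for _, g, o in recorded)


class TestComputeRunSummary:
    def test_no_decoy_groups_means_zero_protein_fdr(self):
        membership = {"A": {0, 1, 2, 3, 4}}
        psms = _psms_from_membership(membership, 5)
        groups, _ = infer_protein_groups(psms, ProteinDB())
        table, fdr = compute_run_summary(groups)
        assert fdr == 0.0
        assert list(table["accessions"]) == ["A"]

    def test_full_coverage_is_100_percent(self):
        seq = "AAAAABBBBB"
        db = ProteinDB([ProteinEntry("A", seq)])
        psms = [
            make_psm(peptide="AAAAA", spectrum_id="s1", accessions=("A",)),
            make_psm(peptide="BBBBB", spectrum_id="s2", accessions=("A",)),
            make_psm(peptide="AAABB", spectrum_id="s3", accessions=("A",)),
            make_psm(peptide="AABBB", spectrum_id="s4", accessions=("A",)),
            make_psm(peptide="ABBBB", spectrum_id="s5", accessions=("A",)),
        ]
        groups, _ = infer_protein_groups(psms, db)
        table, _ = compute_run_summary(groups)
        assert table.loc[0, "seq_cov_pct"] == 100.0

    def test_overlapping_interval_coverage(self):
        # peptides spanning residues 1-10 and 6-20 of a 100-residue protein: 20%
        seq = "ABCDEFGHIJKLMNOPQRST" + "Z" * 80
        db = ProteinDB([ProteinEntry("A", seq)])
        params = FilterParams(min_distinct_peptides=1, min_additional_peptides=1)
        psms = [
            make_psm(peptide=seq[0:10], spectrum_id="s1", accessions=("A",)),
            make_psm(peptide=seq[5:20], spectrum_id="s2", accessions=("A",)),
        ]
        groups, _ = infer_protein_groups(psms, db, params)
        assert groups[0].coverage == pytest.approx(0.20)

    def test_decoy_group_fraction_reported(self):
        membership = {"A": {0, 1, 2, 3, 4}, "rev_B": {5, 6, 7, 8, 9}}
        psms = _psms_from_membership(membership, 10)
        groups, _ = infer_protein_groups(psms, ProteinDB())
        _, fdr = compute_run_summary(groups)
        assert fdr == pytest.approx(100.0)  # 2*1/2 at the group level
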