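"""dS/dN estimators: alignment threading, NG86 vs an exact enumeration
oracle, YN00 parameter recovery, and the Ks filters."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wgdkit import ks as wks
from wgdkit.simulate import evolve_codon_pair


# ---------------------------------------------------------------------------
# Independent NG86 oracle: plain enumeration, exact rational arithmetic.

def _oracle_syn_sites(codon):
    aa = wks.CODON_TO_AA[codon]
    syn = Fraction(0)
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            new = codon[:pos] + alt + codon[pos + 1 :]
            if new not in wks.STOP_CODONS and wks.CODON_TO_AA.get(new) == aa:
                syn += Fraction(1, 3)
    return syn


def _oracle_step_syn(before, after):
    if before in wks.STOP_CODONS or after in wks.STOP_CODONS:
        return False
    return wks.CODON_TO_AA[before] == wks.CODON_TO_AA[after]


def _oracle_pair_diffs(ca, cb):
    if ca == cb:
        return Fraction(0), Fraction(0)
    positions = [i for i in range(3) if ca[i] != cb[i]]
    paths = []
    for order in itertools.permutations(positions):
        current, steps = ca, []
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1 :]
            steps.append((current, nxt))
            current = nxt
        paths.append(steps)
    usable = [p for p in paths if all(s[1] not in wks.STOP_CODONS for s in p[:-1])]
    if not usable:
        usable = paths
    sd = nd = Fraction(0)
    for steps in usable:
        for before, after in steps:
            if _oracle_step_syn(before, after):
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def _oracle_ng86(pairs):
    n = len(pairs)
    S = (
        sum(_oracle_syn_sites(a) for a, _ in pairs)
        + sum(_oracle_syn_sites(b) for _, b in pairs)
    ) / 2
    N = 3 * n - S
    Sd = sum(_oracle_pair_diffs(a, b)[0] for a, b in pairs)
    Nd = sum(_oracle_pair_diffs(a, b)[1] for a, b in pairs)
    ds = dn = None
    if S > 0:
        arg = 1 - Fraction(4, 3) * Sd / S
        ds = -0.75 * math.log(arg) if arg > 0 else None
    if N > 0:
        arg = 1 - Fraction(4, 3) * Nd / N
        dn = -0.75 * math.log(arg) if arg > 0 else None
    return float(S), float(N), float(Sd), float(Nd), ds, dn


def _random_alignment(rng, n_codons):
    codons = [wks.SENSE_CODONS[i] for i in rng.integers(0, 61, size=2 * n_codons)]
    pairs = list(zip(codons[:n_codons], codons[n_codons:]))
    return wks.CodonAlignment("a", "b", pairs)


class TestBackthread:
    def test_gap_column_excluded(self):
        aln = wks.backthread_codon_alignment("M-K", "MAK", "ATGAAA", "ATGGCTAAA")
        assert aln.pairs == [("ATG", "ATG"), ("AAA", "AAA")]
        assert aln.n_excluded == 1

    def test_identical_sequences_no_exclusions(self):
        aln = wks.backthread_codon_alignment("MKW", "MKW", "ATGAAATGG", "ATGAAATGG")
        assert len(aln) == 3 and aln.n_excluded == 0

    def test_length_mismatch_names_gene(self):
        with pytest.raises(wks.KsError, match="geneY"):
            wks.backthread_codon_alignment(
                "MK", "MK", "ATGAAA", "ATGAAAGGG", name_a="geneX", name_b="geneY"
            )

    def test_translation_mismatch_rejected(self):
        with pytest.raises(wks.KsError):
            wks.backthread_codon_alignment("MK", "MK", "ATGCCC", "ATGAAA")

    def test_stop_and_ambiguous_columns_dropped(self):
        aln = wks.backthread_codon_alignment(
            "M*K", "M*K", "ATGTAAAAA", "ATGTGAAAA"
        )
        assert aln.pairs == [("ATG", "ATG"), ("AAA", "AAA")]


class TestNG86:
    def test_identical_pair_is_zero(self):
        aln = _random_alignment(np.random.default_rng(0), 100)
        aln.pairs = [(a, a) for a, _ in aln.pairs]
        est = wks.ng86(aln)
        assert est.Sd == est.Nd == 0 and est.ds == 0 and est.dn == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        aln = _random_alignment(rng, int(rng.integers(1, 21)))
        est = wks.ng86(aln)
        S, N, Sd, Nd, ds, dn = _oracle_ng86(aln.pairs)
        assert est.S == pytest.approx(S, abs=1e-9)
        assert est.N == pytest.approx(N, abs=1e-9)
        assert est.Sd == pytest.approx(Sd, abs=1e-9)
        assert est.Nd == pytest.approx(Nd, abs=1e-9)
        if ds is not None and est.valid:
            assert est.ds == pytest.approx(ds, abs=1e-9)

    def test_site_counts_sum_exactly(self):
        for seed in range(5):
            aln = _random_alignment(np.random.default_rng(seed), 40)
            est = wks.ng86(aln)
            assert est.S + est.N == pytest.approx(3 * len(aln), abs=1e-9)

    def test_simulator_consistency(self):
        # 500-codon pairs at true dS 0.3; the mean estimate recovers it
        values = [
            wks.pair_ks(*evolve_codon_pair(500, 0.3, 0.06, kappa=1.0, seed=s),
                        method="NG86").ds
            for s in range(100)
        ]
        assert np.mean(values) == pytest.approx(0.3, abs=0.04)

    def test_symmetry(self):
        a, b = evolve_codon_pair(80, 0.4, 0.1, seed=3)
        e1 = wks.pair_ks(a, b, method="NG86")
        e2 = wks.pair_ks(b, a, method="NG86")
        assert (e1.S, e1.N, e1.Sd, e1.Nd, e1.ds) == (e2.S, e2.N, e2.Sd, e2.Nd, e2.ds)

    def test_empty_alignment_rejected(self):
        with pytest.raises(wks.KsError):
            wks.ng86(wks.CodonAlignment("a", "b", []))

    def test_monotone_in_divergence(self):
        # mean ds rises with simulated divergence until saturation
        means = []
        for target in (0.05, 0.2, 0.5, 0.9):
            vals = [
                wks.pair_ks(*evolve_codon_pair(300, target, 0.0, kappa=1.0, seed=s),
                            method="NG86").ds
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert means == sorted(means)


class TestYN00:
    def test_identical_pair_is_zero(self):
        a, _ = evolve_codon_pair(100, 0.0, 0.0, seed=0)
        est = wks.pair_ks(a, a, method="YN00")
        assert est.ds == 0 and est.dn == 0 and est.valid

    def test_kappa_recovery(self):
        kappas = [
            wks.pair_ks(*evolve_codon_pair(500, 0.3, 0.06, kappa=2.0, seed=s),
                        method="YN00").kappa
            for s in range(100)
        ]
        assert 1.5 <= np.mean(kappas) <= 2.5

    def test_agrees_with_ng86_when_kappa_one(self):
        # with kappa = 1 and near-uniform codon usage the methods coincide
        diffs = []
        for s in range(40):
            a, b = evolve_codon_pair(500, 0.2, 0.04, kappa=1.0, seed=s)
            diffs.append(
                wks.pair_ks(a, b, method="YN00").ds
                - wks.pair_ks(a, b, method="NG86").ds
            )
        assert abs(np.mean(diffs)) < 0.02

    def test_symmetry(self):
        a, b = evolve_codon_pair(80, 0.4, 0.1, seed=5)
        e1, e2 = wks.pair_ks(a, b, method="YN00"), wks.pair_ks(b, a, method="YN00")
        assert e1.ds == pytest.approx(e2.ds, abs=1e-12)
        assert e1.kappa == pytest.approx(e2.kappa, abs=1e-12)

    def test_too_few_codons_rejected(self):
        aln = _random_alignment(np.random.default_rng(0), 5)
        with pytest.raises(wks.KsError, match="10"):
            wks.yn00(aln)


class TestFilterKs:
    def test_boundary_semantics(self):
        ests = [
            wks.KsEstimate("a", "b", "NG86", 1, 1, 0, 0, ds, 0.0)
            for ds in (0.04, 0.05, 0.06, 1.50, 1.49)
        ]
        kept = {e.ds for e in wks.filter_ks(ests)}
        assert kept == {0.06, 1.49}

    def test_empty_input(self):
        assert wks.filter_ks([]) == []

    def test_invalid_bounds_rejected(self):
        with pytest.raises(wks.KsError):
            wks.filter_ks([], lo=1.0, hi=0.5)

    def test_saturated_estimates_removed(self):
        bad = wks.KsEstimate("a", "b", "NG86", 1, 1, 1, 0, math.nan, 0.0, valid=False)
        assert wks.filter_ks([bad]) == []

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=2.0, allow_nan=False), max_size=30
        )
    )
    def test_matches_comprehension_oracle(self, values):
        ests = [
            wks.KsEstimate("a", "b", "NG86", 1, 1, 0, 0, ds, 0.0) for ds in values
        ]
        expected = [e for e in ests if 0.05 < e.ds < 1.50]
        assert wks.filter_ks(ests) == expected


class TestSingleCopyOrthologs:
    def test_single_copy_only(self):
        seqs = {
            "g1": "ATGAAACCC", "g2": "ATGAAACCC", "g3": "ATGAAACCC", "g4": "ATGAAACCC"
        }
        ogs = {
            "OG1": {"A": ["g1"], "B": ["g2"]},
            "OG2": {"A": ["g3", "g4"], "B": ["g3"]},
        }
        # OG2 is multi-copy in A and contributes nothing; OG1's pair has ds=0,
        # excluded by the strict lower bound 0 only if ds == 0 exactly
        out = wks.single_copy_ortholog_ks(ogs, ("A", "B"), seqs, method="NG86")
        assert out == []  # identical pair: ds 0 is outside the open interval

    def test_recovers_true_divergence(self):
        rng_pairs = [evolve_codon_pair(200, 0.25, 0.05, seed=s) for s in range(30)]
        seqs = {}
        ogs = {}
        for i, (a, b) in enumerate(rng_pairs):
            seqs[f"a{i}"] = a
            seqs[f"b{i}"] = b
            ogs[f"OG{i}"] = {"A": [f"a{i}"], "B": [f"b{i}"]}
        ests = wks.single_copy_ortholog_ks(ogs, ("A", "B"), seqs, method="NG86")
        assert len(ests) == 30
        assert np.median([e.ds for e in ests]) == pytest.approx(0.25, abs=0.05)
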