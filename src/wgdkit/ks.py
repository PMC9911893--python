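"""Codon-level dS/dN estimation for gene pairs.

Two counting estimators are provided:

* NG86 — Nei–Gojobori (1986) counting with Jukes–Cantor correction.  Each
  codon position contributes one site split among its three possible
  single-nucleotide changes; multi-substitution codon pairs are averaged
  over all substitution orders.
* YN00 — a Yang–Nielsen (2000)-style approximate method: codon frequencies
  from the F3x4 model, a transition/transversion ratio (kappa) estimated
  from fourfold-degenerate sites with a K80 correction, kappa- and
  frequency-weighted site counting, likelihood-weighted paths for
  multi-substitution codons, and iterative update of omega until the
  difference counts converge.  dS and dN are corrected per class with the
  K80 formula using their transition/transversion split.

Conventions (documented, applied consistently in both estimators and in
their oracles): a single-nucleotide change that produces a stop codon
counts as nonsynonymous when counting sites, so S + N = 3 x counted codons
holds exactly; substitution paths that pass through a stop codon are
excluded from averaging, falling back to all paths (stop steps counted
nonsynonymous) in the rare case every path is blocked.  Columns containing
a gap, an N, or a stop codon are excluded from counting entirely.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
NUCLEOTIDES = "ACGT"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class KsError(ValueError):
    """Invalid input to a dS/dN computation."""


def is_transition(nt1: str, nt2: str) -> bool:
    return (nt1 in _PURINES and nt2 in _PURINES) or (
        nt1 in _PYRIMIDINES and nt2 in _PYRIMIDINES
    )


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; '*' for stops, 'X' if any N/ambiguity."""
    if codon in CODON_TO_AA:
        return CODON_TO_AA[codon]
    if codon in STOP_CODONS:
        return "*"
    return "X"


def translate_cds(cds: str) -> str:
    if len(cds) % 3:
        raise KsError(f"CDS length {len(cds)} is not a multiple of 3")
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


# single-nucleotide neighbours of each codon: (position, alt codon, is_transition)
_NEIGHBOURS: dict[str, list[tuple[int, str, bool]]] = {}
for _c in itertools.product(NUCLEOTIDES, repeat=3):
    codon = "".join(_c)
    nbs = []
    for pos in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            new = codon[:pos] + alt + codon[pos + 1 :]
            nbs.append((pos, new, is_transition(codon[pos], alt)))
    _NEIGHBOURS[codon] = nbs


@dataclass
class KsEstimate:
    """Synonymous/nonsynonymous site and difference counts for one pair."""

    gene_a: str
    gene_b: str
    method: str
    S: float
    N: float
    Sd: float
    Nd: float
    ds: float
    dn: float
    kappa: float | None = None
    valid: bool = True
    note: str = ""


@dataclass
class CodonAlignment:
    """A paired codon alignment; ``pairs`` holds the counted columns only."""

    name_a: str
    name_b: str
    pairs: list[tuple[str, str]]
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.pairs)


def _column_counted(codon_a: str, codon_b: str) -> bool:
    for codon in (codon_a, codon_b):
        if "N" in codon or codon in STOP_CODONS:
            return False
    return True


def backthread_codon_alignment(
    protein_aln_a: str,
    protein_aln_b: str,
    cds_a: str,
    cds_b: str,
    name_a: str = "a",
    name_b: str = "b",
) -> CodonAlignment:
    """Thread CDS codons onto an aligned protein pair (pal2nal-style).

    Each amino acid is replaced by its source codon and protein gaps become
    codon gaps.  Columns with a gap on either side, an ambiguous codon, or
    a stop codon are excluded from site counting.
    """
    if len(protein_aln_a) != len(protein_aln_b):
        raise KsError("protein alignments differ in length")
    for name, prot, cds in ((name_a, protein_aln_a, cds_a), (name_b, protein_aln_b, cds_b)):
        n_res = sum(1 for aa in prot if aa != "-")
        if n_res * 3 != len(cds):
            raise KsError(
                f"{name}: ungapped protein length {n_res} x 3 != CDS length {len(cds)}"
            )
    pairs: list[tuple[str, str]] = []
    n_excluded = 0
    ia = ib = 0
    for aa_a, aa_b in zip(protein_aln_a, protein_aln_b):
        codon_a = codon_b = None
        if aa_a != "-":
            codon_a = cds_a[3 * ia : 3 * ia + 3]
            if translate_codon(codon_a) not in (aa_a, "X"):
                raise KsError(
                    f"{name_a}: codon {codon_a} at residue {ia} does not encode {aa_a!r}"
                )
            ia += 1
        if aa_b != "-":
            codon_b = cds_b[3 * ib : 3 * ib + 3]
            if translate_codon(codon_b) not in (aa_b, "X"):
                raise KsError(
                    f"{name_b}: codon {codon_b} at residue {ib} does not encode {aa_b!r}"
                )
            ib += 1
        if codon_a is None or codon_b is None or not _column_counted(codon_a, codon_b):
            n_excluded += 1
            continue
        pairs.append((codon_a, codon_b))
    return CodonAlignment(name_a, name_b, pairs, n_excluded)


def codon_alignment_from_cds(
    cds_a: str, cds_b: str, name_a: str = "a", name_b: str = "b"
) -> CodonAlignment:
    """Gap-free codon pairing of two equal-length CDS (trivial back-translation)."""
    if len(cds_a) != len(cds_b):
        raise KsError(
            f"CDS lengths differ ({len(cds_a)} vs {len(cds_b)}); align proteins first"
        )
    prot_a = translate_cds(cds_a)
    prot_b = translate_cds(cds_b)
    return backthread_codon_alignment(prot_a, prot_b, cds_a, cds_b, name_a, name_b)


# ---------------------------------------------------------------------------
# NG86

_NG86_SITES: dict[str, float] = {}
_NG86_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}


def _ng86_syn_sites(codon: str) -> float:
    cached = _NG86_SITES.get(codon)
    if cached is not None:
        return cached
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for _pos, alt, _ts in _NEIGHBOURS[codon]:
        # change to a stop codon counts as nonsynonymous
        if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
            syn += 1.0 / 3.0
    _NG86_SITES[codon] = syn
    return syn


def _enumerate_paths(codon_a: str, codon_b: str) -> list[list[tuple[str, str]]]:
    """All substitution orders from codon_a to codon_b as lists of steps."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    paths = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        steps = []
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            steps.append((current, nxt))
            current = nxt
        paths.append(steps)
    return paths


def _step_is_syn(before: str, after: str) -> bool:
    if before in STOP_CODONS or after in STOP_CODONS:
        return False
    return CODON_TO_AA[before] == CODON_TO_AA[after]


def _ng86_pair_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    cached = _NG86_DIFFS.get((codon_a, codon_b))
    if cached is not None:
        return cached
    if codon_a == codon_b:
        result = (0.0, 0.0)
    else:
        paths = _enumerate_paths(codon_a, codon_b)
        # paths through a stop intermediate are excluded
        usable = [
            p for p in paths if all(s[1] not in STOP_CODONS for s in p[:-1])
        ]
        if not usable:
            usable = paths
        sd = nd = 0.0
        for steps in usable:
            for before, after in steps:
                if _step_is_syn(before, after):
                    sd += 1.0
                else:
                    nd += 1.0
        sd /= len(usable)
        nd /= len(usable)
        result = (sd, nd)
    _NG86_DIFFS[(codon_a, codon_b)] = result
    return result


def jukes_cantor(p: float) -> tuple[float, bool]:
    """JC69 multiple-hit correction of a proportion of differences."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return math.nan, False
    return max(0.0, -0.75 * math.log(arg)), True


def ng86(alignment: CodonAlignment) -> KsEstimate:
    """Nei–Gojobori (1986) counting estimate with Jukes–Cantor correction."""
    n = len(alignment.pairs)
    if n < 1:
        raise KsError("alignment has no counted codons")
    s_a = sum(_ng86_syn_sites(ca) for ca, _ in alignment.pairs)
    s_b = sum(_ng86_syn_sites(cb) for _, cb in alignment.pairs)
    S = 0.5 * (s_a + s_b)
    N = 3.0 * n - S
    Sd = Nd = 0.0
    for ca, cb in alignment.pairs:
        sd, nd = _ng86_pair_diffs(ca, cb)
        Sd += sd
        Nd += nd
    note = ""
    valid = True
    if Sd == 0.0:
        ds = 0.0
    elif S == 0.0:
        ds, valid, note = math.nan, False, "no synonymous sites"
    else:
        ds, ok = jukes_cantor(Sd / S)
        if not ok:
            valid, note = False, "synonymous saturation (pS >= 3/4)"
    if Nd == 0.0:
        dn = 0.0
    elif N == 0.0:
        dn, valid, note = math.nan, False, "no nonsynonymous sites"
    else:
        dn, ok = jukes_cantor(Nd / N)
        if not ok:
            valid, note = False, note or "nonsynonymous saturation"
    return KsEstimate(
        alignment.name_a, alignment.name_b, "NG86", S, N, Sd, Nd, ds, dn,
        kappa=None, valid=valid, note=note,
    )


# ---------------------------------------------------------------------------
# YN00

_FOURFOLD: dict[str, bool] = {}
for codon in SENSE_CODONS:
    aa = CODON_TO_AA[codon]
    _FOURFOLD[codon] = all(
        (codon[:2] + alt) in CODON_TO_AA and CODON_TO_AA[codon[:2] + alt] == aa
        for alt in NUCLEOTIDES
        if alt != codon[2]
    )


def kimura_two_parameter(P: float, Q: float) -> tuple[float, bool]:
    """K80 distance from transition (P) and transversion (Q) proportions."""
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return math.nan, False
    return max(0.0, -0.5 * math.log(arg1) - 0.25 * math.log(arg2)), True


def _estimate_kappa(pairs: Sequence[tuple[str, str]]) -> float:
    """Kappa from fourfold-degenerate third positions via K80, fallback 1."""
    L = ts = tv = 0
    for ca, cb in pairs:
        if _FOURFOLD[ca] and _FOURFOLD[cb]:
            L += 1
            if ca[2] != cb[2]:
                if is_transition(ca[2], cb[2]):
                    ts += 1
                else:
                    tv += 1
    if L < 10:
        return 1.0
    P, Q = ts / L, tv / L
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return 20.0
    if Q == 0.0:
        return 20.0 if P > 0.0 else 1.0
    d_ts = -0.5 * math.log(arg1) + 0.25 * math.log(arg2)
    d_tv = -0.5 * math.log(arg2)
    if d_tv <= 0.0 or d_ts <= 0.0:
        return 1.0
    return min(20.0, max(0.1, 2.0 * d_ts / d_tv))


def _f3x4_frequencies(pairs: Sequence[tuple[str, str]]) -> dict[str, float]:
    counts = [dict.fromkeys(NUCLEOTIDES, 0.0) for _ in range(3)]
    for ca, cb in pairs:
        for codon in (ca, cb):
            for pos in range(3):
                counts[pos][codon[pos]] += 1.0
    freqs = []
    for pos in range(3):
        total = sum(counts[pos].values())
        freqs.append({nt: counts[pos][nt] / total for nt in NUCLEOTIDES})
    pi = {
        codon: freqs[0][codon[0]] * freqs[1][codon[1]] * freqs[2][codon[2]]
        for codon in SENSE_CODONS
    }
    total = sum(pi.values())
    return {codon: p / total for codon, p in pi.items()}


def _yn00_codon_sites(codon: str, kappa: float, pi: Mapping[str, float]) -> float:
    """Synonymous site count of one codon under kappa/frequency weighting."""
    syn_total = 0.0
    aa = CODON_TO_AA[codon]
    by_pos: dict[int, list[tuple[str, bool]]] = {0: [], 1: [], 2: []}
    for pos, alt, ts in _NEIGHBOURS[codon]:
        by_pos[pos].append((alt, ts))
    for pos in range(3):
        weights = []
        syn_flags = []
        for alt, ts in by_pos[pos]:
            w = (kappa if ts else 1.0) * pi.get(alt, 0.0)
            weights.append(w)
            syn_flags.append(alt in CODON_TO_AA and CODON_TO_AA[alt] == aa)
        total = sum(weights)
        if total <= 0.0:
            # no sense target has positive frequency: kappa-only weighting
            weights = [(kappa if ts else 1.0) for _, ts in by_pos[pos]]
            total = sum(weights)
        syn_total += sum(w for w, s in zip(weights, syn_flags) if s) / total
    return syn_total


def _yn00_pair_diffs(
    codon_a: str,
    codon_b: str,
    kappa: float,
    omega: float,
    pi: Mapping[str, float],
) -> tuple[float, float, float, float]:
    """Weighted (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv) differences for one column."""
    if codon_a == codon_b:
        return 0.0, 0.0, 0.0, 0.0
    paths = _enumerate_paths(codon_a, codon_b)
    weighted: list[tuple[float, tuple[float, float, float, float]]] = []
    for steps in paths:
        if any(step[1] in STOP_CODONS for step in steps[:-1]):
            continue
        w = 1.0
        counts = [0.0, 0.0, 0.0, 0.0]
        for before, after in steps:
            pos = next(i for i in range(3) if before[i] != after[i])
            ts = is_transition(before[pos], after[pos])
            syn = _step_is_syn(before, after)
            w *= (kappa if ts else 1.0) * pi.get(after, 0.0) * (1.0 if syn else omega)
            idx = (0 if syn else 2) + (0 if ts else 1)
            counts[idx] += 1.0
        weighted.append((w, tuple(counts)))
    total = sum(w for w, _ in weighted)
    if not weighted or total <= 0.0:
        # all paths blocked or zero-weighted: average all orders unweighted
        fallback = [(1.0, c) for _, c in (weighted or [])]
        if not fallback:
            for steps in paths:
                counts = [0.0, 0.0, 0.0, 0.0]
                for before, after in steps:
                    pos = next(i for i in range(3) if before[i] != after[i])
                    ts = is_transition(before[pos], after[pos])
                    syn = _step_is_syn(before, after)
                    idx = (0 if syn else 2) + (0 if ts else 1)
                    counts[idx] += 1.0
                fallback.append((1.0, tuple(counts)))
        weighted, total = fallback, float(len(fallback))
    out = [0.0, 0.0, 0.0, 0.0]
    for w, counts in weighted:
        for i in range(4):
            out[i] += w * counts[i] / total
    return tuple(out)


def yn00(
    alignment: CodonAlignment,
    max_iter: int = 100,
    tol: float = 1e-6,
    initial_omega: float = 0.5,
) -> KsEstimate:
    """Yang–Nielsen (2000)-style counting estimate of dS, dN and kappa."""
    n = len(alignment.pairs)
    if n < 10:
        raise KsError(f"YN00 needs >= 10 counted codons, got {n}")
    pairs = alignment.pairs
    kappa = _estimate_kappa(pairs)
    pi = _f3x4_frequencies(pairs)
    site_cache: dict[str, float] = {}

    def syn_sites(codon: str) -> float:
        if codon not in site_cache:
            site_cache[codon] = _yn00_codon_sites(codon, kappa, pi)
        return site_cache[codon]

    s_a = sum(syn_sites(ca) for ca, _ in pairs)
    s_b = sum(syn_sites(cb) for _, cb in pairs)
    S = 0.5 * (s_a + s_b)
    N = 3.0 * n - S

    omega = initial_omega
    prev = (math.inf, math.inf)
    converged = False
    Sd = Nd = 0.0
    sd_ts = sd_tv = nd_ts = nd_tv = 0.0
    differing = [(ca, cb) for ca, cb in pairs if ca != cb]
    for _ in range(max_iter):
        sd_ts = sd_tv = nd_ts = nd_tv = 0.0
        for ca, cb in differing:
            a, b, c, d = _yn00_pair_diffs(ca, cb, kappa, omega, pi)
            sd_ts += a
            sd_tv += b
            nd_ts += c
            nd_tv += d
        Sd = sd_ts + sd_tv
        Nd = nd_ts + nd_tv
        if (
            abs(Sd - prev[0]) <= tol * max(1.0, abs(Sd))
            and abs(Nd - prev[1]) <= tol * max(1.0, abs(Nd))
        ):
            converged = True
            break
        prev = (Sd, Nd)
        ds_it, ok_s = kimura_two_parameter(sd_ts / S, sd_tv / S) if S > 0 else (math.nan, False)
        dn_it, ok_n = kimura_two_parameter(nd_ts / N, nd_tv / N) if N > 0 else (math.nan, False)
        if ok_s and ok_n and ds_it > 1e-9:
            omega = min(10.0, max(1e-4, dn_it / ds_it))

    valid = True
    note = ""
    if not converged and differing:
        valid, note = False, f"no convergence after {max_iter} iterations"
    if Sd == 0.0:
        ds = 0.0
    elif S == 0.0:
        ds, valid, note = math.nan, False, "no synonymous sites"
    else:
        ds, ok = kimura_two_parameter(sd_ts / S, sd_tv / S)
        if not ok:
            valid, note = False, "synonymous saturation"
    if Nd == 0.0:
        dn = 0.0
    elif N == 0.0:
        dn, valid, note = math.nan, False, "no nonsynonymous sites"
    else:
        dn, ok = kimura_two_parameter(nd_ts / N, nd_tv / N)
        if not ok:
            valid, note = False, note or "nonsynonymous saturation"
    return KsEstimate(
        alignment.name_a, alignment.name_b, "YN00", S, N, Sd, Nd, ds, dn,
        kappa=kappa, valid=valid, note=note,
    )


# ---------------------------------------------------------------------------
# Convenience drivers

METHODS = {"NG86": ng86, "YN00": yn00}


def pair_ks(
    cds_a: str,
    cds_b: str,
    name_a: str = "a",
    name_b: str = "b",
    method: str = "YN00",
) -> KsEstimate:
    """Estimate dS/dN for two equal-length CDS via trivial back-translation."""
    if method not in METHODS:
        raise KsError(f"unknown method {method!r}; expected one of {sorted(METHODS)}")
    alignment = codon_alignment_from_cds(cds_a, cds_b, name_a, name_b)
    return METHODS[method](alignment)


def filter_ks(
    estimates: Iterable[KsEstimate], lo: float = 0.05, hi: float = 1.50
) -> list[KsEstimate]:
    """Keep valid estimates with lo < ds < hi (strictly exclusive bounds)."""
    if lo >= hi:
        raise KsError(f"lower bound {lo} must be below upper bound {hi}")
    return [e for e in estimates if e.valid and lo < e.ds < hi]


def single_copy_ortholog_ks(
    orthogroups: Mapping[str, Mapping[str, list[str]]],
    species_pair: tuple[str, str],
    sequences: Mapping[str, str],
    method: str = "YN00",
    bounds: tuple[float, float] = (0.0, 1.5),
) -> list[KsEstimate]:
    """Pairwise Ks over orthogroups single-copy in both species of the pair.

    Interspecies orthologs can be much younger than paralog pairs, so this
    workflow takes its own bounds (default (0, 1.5)) instead of the paralog
    filter's 0.05 lower cutoff.
    """
    sp_a, sp_b = species_pair
    estimates: list[KsEstimate] = []
    for og in sorted(orthogroups):
        members = orthogroups[og]
        genes_a = members.get(sp_a, [])
        genes_b = members.get(sp_b, [])
        if len(genes_a) == 1 and len(genes_b) == 1:
            ga, gb = genes_a[0], genes_b[0]
            estimates.append(pair_ks(sequences[ga], sequences[gb], ga, gb, method))
    return filter_ks(estimates, *bounds) if estimates else []
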