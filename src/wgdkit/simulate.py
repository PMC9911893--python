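"""Synthetic genome evolution with nested whole-genome duplications.

The generator emulates the statistical structure the retention analysis
assumes: an ancestral gene order duplicated once per WGD event (duplicated
chromosomes appended as new chromosomes, so collinear blocks exist), each
duplicate retained with a family-dependent probability (elevated for
designated TF families), recent tandem duplications in the focal genome,
close interspecies orthologs, and deeper outgroup species without the
WGDs.  Coding sequences diverge under a single-nucleotide
mutation-selection codon process with transition/transversion bias
(kappa) and omega scaling of the nonsynonymous rate, so the realized
synonymous divergence of a duplicate pair matches its event's Ks depth in
expectation and is estimable by the NG86/YN00 counting methods.

Every labeled pair, gene tree, annotation table and truth record is fully
determined by the seed.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as wio
from .ks import (
    CODON_TO_AA,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    _NEIGHBOURS,
    is_transition,
)


class SimulationError(ValueError):
    """Invalid simulation parameters."""


class SaturationError(SimulationError):
    """Requested divergence exceeds one expected substitution per site per lineage."""


@dataclass(frozen=True)
class WgdEvent:
    """One whole-genome duplication: its Ks depth and retention probabilities."""

    ks_depth: float
    retention_prob_background: float
    retention_prob_tf: float


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic genome.

    Defaults emulate two nested WGDs at Ks depths 0.27 (younger, sigma-like)
    and 0.97 (older, rho-like) with background duplicate retention 0.25 and
    0.10 and TF-family retention 0.5 at both events, interspecies orthologs
    at Ks 0.02, and a deep outgroup without the WGDs.
    """

    n_species: int = 3
    n_chromosomes: int = 4
    genes_per_chromosome: int = 150
    wgd_events: tuple[WgdEvent, ...] = (
        WgdEvent(0.27, 0.25, 0.5),
        WgdEvent(0.97, 0.10, 0.5),
    )
    tandem_rate: float = 0.05
    ortholog_ks: float = 0.02
    kappa: float = 2.0
    omega: float = 0.2
    n_tf_families: int = 5
    seed: int = 0
    cds_length_codons: int = 200
    tf_gene_fraction: float = 0.15
    outgroup_ks: float = 1.3
    tandem_ks: float = 0.01
    low_support_fraction: float = 0.1
    outgroup_loss_rate: float = 0.05
    n_go_terms: int = 40

    def __post_init__(self) -> None:
        probs = [self.tandem_rate, self.tf_gene_fraction, self.low_support_fraction,
                 self.outgroup_loss_rate]
        for e in self.wgd_events:
            probs += [e.retention_prob_background, e.retention_prob_tf]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SimulationError("all probabilities must lie in [0, 1]")
        depths = [e.ks_depth for e in self.wgd_events]
        if any(d < 0 for d in depths):
            raise SimulationError("Ks depths must be non-negative")
        if any(b >= a for a, b in zip(depths[1:], depths)):
            raise SimulationError("WGD Ks depths must be strictly increasing")
        if self.genes_per_chromosome < 10:
            raise SimulationError(
                "genes_per_chromosome < 10: syntenic blocks of >= 5 anchors "
                "would be unreachable"
            )
        if self.n_species < 1:
            raise SimulationError("need at least one species")
        if self.n_species >= 2 and depths and self.ortholog_ks > min(depths):
            raise SimulationError("ortholog_ks must not exceed the youngest WGD depth")
        if self.n_species >= 3 and depths and self.outgroup_ks <= max(depths):
            raise SimulationError("outgroup_ks must exceed the oldest WGD depth")
        if self.n_species >= 2 and self.tandem_ks > self.ortholog_ks:
            raise SimulationError(
                "tandem_ks must not exceed ortholog_ks (tandem duplications "
                "postdate the focal-genus speciation)"
            )
        if self.omega < 0 or self.kappa <= 0:
            raise SimulationError("omega must be >= 0 and kappa > 0")


FOCAL_SPECIES = "MCA"
SISTER_SPECIES = "MDO"
FOCAL_GENUS = (FOCAL_SPECIES, SISTER_SPECIES)
TF_MARKER_TERM = "GO:0000999"


# ---------------------------------------------------------------------------
# Codon evolution engine

_CODON_TABLES: dict[tuple[str, float], tuple] = {}


def _codon_mutation_table(codon: str, kappa: float):
    """Per-codon mutation opportunities under kappa bias.

    Returns (syn_weight, syn_choices, nonsyn_weight, nonsyn_choices) where
    weights are per-position-normalized so each position carries one site
    and choices are lists of (alt_codon, weight).
    """
    key = (codon, kappa)
    cached = _CODON_TABLES.get(key)
    if cached is not None:
        return cached
    aa = CODON_TO_AA.get(codon)
    norm = kappa + 2.0
    syn_choices: list[tuple[str, float]] = []
    nonsyn_choices: list[tuple[str, float]] = []
    for _pos, alt, ts in _NEIGHBOURS[codon]:
        w = (kappa if ts else 1.0) / norm
        if alt in STOP_CODONS:
            continue  # stop codons are never introduced
        if CODON_TO_AA[alt] == aa:
            syn_choices.append((alt, w))
        else:
            nonsyn_choices.append((alt, w))
    result = (
        sum(w for _, w in syn_choices),
        syn_choices,
        sum(w for _, w in nonsyn_choices),
        nonsyn_choices,
    )
    _CODON_TABLES[key] = result
    return result


def _weighted_pick(choices: Sequence[tuple[str, float]], total: float, rng) -> str:
    u = rng.random() * total
    acc = 0.0
    for alt, w in choices:
        acc += w
        if u <= acc:
            return alt
    return choices[-1][0]


def _apply_substitutions(
    codons: list[str], target_ds: float, target_dn: float, kappa: float, rng
) -> list[str]:
    """Evolve one lineage in place-copy by expected per-site divergences."""
    seq = list(codons)
    if target_ds == 0.0 and target_dn == 0.0:
        return seq
    syn_w = np.empty(len(seq))
    nonsyn_w = np.empty(len(seq))
    for i, codon in enumerate(seq):
        s, _, n, _ = _codon_mutation_table(codon, kappa)
        syn_w[i] = s
        nonsyn_w[i] = n
    S = float(syn_w.sum())
    N = float(nonsyn_w.sum())
    if S <= 0.0 and target_ds > 0.0:
        raise SaturationError("sequence has no synonymous substitution opportunity")
    if N <= 0.0 and target_dn > 0.0:
        raise SaturationError("sequence has no nonsynonymous substitution opportunity")
    n_syn = int(rng.poisson(target_ds * S)) if target_ds > 0 else 0
    n_nonsyn = int(rng.poisson(target_dn * N)) if target_dn > 0 else 0
    events = ["s"] * n_syn + ["n"] * n_nonsyn
    rng.shuffle(events)
    for kind in events:
        weights = syn_w if kind == "s" else nonsyn_w
        w_max = 3.0
        for _ in range(10000):
            i = int(rng.integers(len(seq)))
            if rng.random() * w_max <= weights[i]:
                break
        else:  # pragma: no cover - defensive
            continue
        s, syn_choices, n, nonsyn_choices = _codon_mutation_table(seq[i], kappa)
        choices, total = (syn_choices, s) if kind == "s" else (nonsyn_choices, n)
        if not choices:
            continue
        seq[i] = _weighted_pick(choices, total, rng)
        s2, _, n2, _ = _codon_mutation_table(seq[i], kappa)
        syn_w[i] = s2
        nonsyn_w[i] = n2
    return seq


def random_cds(length_codons: int, rng) -> list[str]:
    """A random sense-codon sequence starting with ATG."""
    if length_codons < 1:
        raise SimulationError("length must be >= 1 codon")
    idx = rng.integers(0, len(SENSE_CODONS), size=length_codons)
    codons = [SENSE_CODONS[i] for i in idx]
    codons[0] = "ATG"
    return codons


def evolve_codon_pair(
    length_codons: int,
    target_ds: float,
    target_dn: float,
    kappa: float = 2.0,
    seed: int = 0,
) -> tuple[str, str]:
    """Generate a codon-sequence pair with expected dS and dN divergence.

    A random ancestor evolves along two independent lineages, each by half
    the target per-site divergence, under the kappa-biased
    mutation-selection sampler.  Raises :class:`SaturationError` when a
    lineage would need more than one expected substitution per site
    (target > 2) or when the sequence offers no opportunity of the
    requested class.
    """
    if length_codons < 1:
        raise SimulationError("length must be >= 1 codon")
    if target_ds < 0 or target_dn < 0:
        raise SimulationError("targets must be non-negative")
    if target_ds / 2.0 > 1.0 or target_dn / 2.0 > 1.0:
        raise SaturationError(
            f"per-site substitution probability exceeds 1 "
            f"(target_ds={target_ds}, target_dn={target_dn})"
        )
    rng = np.random.default_rng(seed)
    ancestor = random_cds(length_codons, rng)
    a = _apply_substitutions(ancestor, target_ds / 2, target_dn / 2, kappa, rng)
    b = _apply_substitutions(ancestor, target_ds / 2, target_dn / 2, kappa, rng)
    return "".join(a), "".join(b)


# ---------------------------------------------------------------------------
# Genealogy bookkeeping

class _TreeNode:
    """Mutable gene-genealogy node; pending tips are converted in place."""

    __slots__ = ("depth", "kind", "children", "support", "species", "gene_id",
                 "event_idx")

    def __init__(self) -> None:
        self.depth = 0.0
        self.kind = "tip"
        self.children: list[_TreeNode] = []
        self.support: float | None = None
        self.species: str | None = None
        self.gene_id: str | None = None
        self.event_idx: int | None = None

    def split(self, depth: float, kind: str, support: float,
              event_idx: int | None = None) -> tuple["_TreeNode", "_TreeNode"]:
        left, right = _TreeNode(), _TreeNode()
        self.depth = depth
        self.kind = kind
        self.support = support
        self.event_idx = event_idx
        self.children = [left, right]
        return left, right

    def leaves(self) -> list["_TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out


class _Lineage:
    __slots__ = ("family", "node")

    def __init__(self, family: int, node: _TreeNode) -> None:
        self.family = family
        self.node = node


@dataclass
class SyntheticDataset:
    """A simulated multi-species dataset with ground-truth labels."""

    params: SimulationParams
    species: list[str]
    focal_species: str
    focal_genus: tuple[str, ...]
    genes: dict[str, list[wio.GeneModel]]
    orthogroups: dict[str, dict[str, list[str]]]
    gene_trees: dict[str, str]
    species_tree: str
    tf_family_table: dict[str, str]
    go_table: dict[str, set[str]]
    go_edges: list[tuple[str, str]]
    homology_pairs: list[wio.HomologyPair]
    true_pair_labels: dict[frozenset, str]
    truth: dict

    @property
    def sequences(self) -> dict[str, str]:
        return {
            g.gene_id: g.cds for genes in self.genes.values() for g in genes
        }

    def focal_genes(self) -> list[wio.GeneModel]:
        return self.genes[self.focal_species]

    def write(self, outdir: str | Path) -> None:
        """Emit the dataset in the same plain-text formats the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        wio.write_fasta(outdir / "cds.fasta", self.sequences)
        all_genes = [g for sp in self.species for g in self.genes[sp]]
        wio.write_gene_positions(outdir / "genes.tsv", all_genes)
        wio.write_homology_pairs(outdir / "pairs.tsv", self.homology_pairs)
        wio.write_gene_trees(outdir / "gene_trees.tsv", self.gene_trees)
        (outdir / "species_tree.nwk").write_text(self.species_tree + "\n")
        wio.write_tf_families(outdir / "tf_families.tsv", self.tf_family_table)
        wio.write_go_annotations(outdir / "go_annotations.tsv", self.go_table)
        wio.write_go_edges(outdir / "go_edges.tsv", self.go_edges)
        wio.write_orthogroups(outdir / "orthogroups.tsv", self.orthogroups)
        with open(outdir / "truth_pairs.tsv", "w") as fh:
            for pair in sorted(self.true_pair_labels, key=sorted):
                a, b = sorted(pair)
                fh.write(f"{a}\t{b}\t{self.true_pair_labels[pair]}\n")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2) + "\n")


def _event_label(event_idx: int) -> str:
    # youngest event is the sigma-like WGD, the next the rho-like one
    return {0: "sigma", 1: "rho"}.get(event_idx, f"wgd{event_idx}")


def simulate_genome(params: SimulationParams) -> SyntheticDataset:
    """Simulate the full multi-species dataset under ``params``."""
    rng = np.random.default_rng(params.seed)
    n_families = params.n_chromosomes * params.genes_per_chromosome

    def draw_support() -> float:
        if rng.random() < params.low_support_fraction:
            return float(rng.uniform(0.0, 0.5))
        return float(rng.uniform(0.5, 1.0))

    # family -> TF family label (or None for background)
    tf_label: list[str | None] = []
    for _ in range(n_families):
        if rng.random() < params.tf_gene_fraction:
            tf_label.append(f"TF{1 + int(rng.integers(params.n_tf_families)):02d}")
        else:
            tf_label.append(None)

    # ancestral ingroup genome: chromosomes of lineages
    roots: list[_TreeNode] = []
    genome: list[list[_Lineage]] = []
    fam = 0
    for _c in range(params.n_chromosomes):
        chrom = []
        for _g in range(params.genes_per_chromosome):
            node = _TreeNode()
            roots.append(node)
            chrom.append(_Lineage(fam, node))
            fam += 1
        genome.append(chrom)

    # WGDs, oldest first
    events_desc = sorted(
        enumerate(params.wgd_events), key=lambda t: -t[1].ks_depth
    )
    truth_events = {}
    for event_idx, event in events_desc:
        depth = event.ks_depth / 2.0
        new_chroms: list[list[_Lineage]] = []
        n_opp = n_ret = 0
        n_opp_tf = n_ret_tf = 0
        for chrom in list(genome):
            dup_chrom: list[_Lineage] = []
            for lineage in chrom:
                is_tf = tf_label[lineage.family] is not None
                p = (
                    event.retention_prob_tf
                    if is_tf
                    else event.retention_prob_background
                )
                n_opp += 1
                n_opp_tf += is_tf
                if rng.random() < p:
                    n_ret += 1
                    n_ret_tf += is_tf
                    orig, dup = lineage.node.split(
                        depth, "dup", draw_support(), event_idx
                    )
                    lineage.node = orig
                    dup_chrom.append(_Lineage(lineage.family, dup))
            if dup_chrom:
                new_chroms.append(dup_chrom)
        genome.extend(new_chroms)
        truth_events[_event_label(event_idx)] = {
            "ks_depth": event.ks_depth,
            "n_duplication_opportunities": n_opp,
            "n_retained_duplicates": n_ret,
            "retained_fraction": n_ret / n_opp if n_opp else 0.0,
            "retained_fraction_tf": n_ret_tf / n_opp_tf if n_opp_tf else 0.0,
            "retained_fraction_background": (
                (n_ret - n_ret_tf) / (n_opp - n_opp_tf) if n_opp > n_opp_tf else 0.0
            ),
        }

    # speciation of the focal genus
    species = [FOCAL_SPECIES]
    genomes: dict[str, list[list[_Lineage]]] = {}
    if params.n_species >= 2:
        species.append(SISTER_SPECIES)
        depth = params.ortholog_ks / 2.0
        focal_genome: list[list[_Lineage]] = []
        sister_genome: list[list[_Lineage]] = []
        for chrom in genome:
            fchrom, schrom = [], []
            for lineage in chrom:
                tip_a, tip_b = lineage.node.split(depth, "spec", draw_support())
                fchrom.append(_Lineage(lineage.family, tip_a))
                schrom.append(_Lineage(lineage.family, tip_b))
            focal_genome.append(fchrom)
            sister_genome.append(schrom)
        genomes[FOCAL_SPECIES] = focal_genome
        genomes[SISTER_SPECIES] = sister_genome
    else:
        genomes[FOCAL_SPECIES] = genome

    # tandem duplications in the focal genome
    tandem_depth = params.tandem_ks / 2.0
    focal_genome = genomes[FOCAL_SPECIES]
    for ci, chrom in enumerate(focal_genome):
        expanded: list[_Lineage] = []
        for lineage in chrom:
            expanded.append(lineage)
            if rng.random() < params.tandem_rate:
                orig, dup = lineage.node.split(tandem_depth, "tandem", draw_support())
                lineage.node = orig
                expanded.append(_Lineage(lineage.family, dup))
        focal_genome[ci] = expanded

    # outgroup species: single copy per family, ancestral order, no WGDs
    outgroup_depths: dict[str, float] = {}
    for j in range(max(0, params.n_species - 2)):
        name = f"OUT{j + 1}"
        species.append(name)
        outgroup_depths[name] = params.outgroup_ks / 2.0 * (1.0 + 0.25 * j)
        out_genome: list[list[_Lineage]] = []
        fam = 0
        for _c in range(params.n_chromosomes):
            chrom = []
            for _g in range(params.genes_per_chromosome):
                if rng.random() >= params.outgroup_loss_rate:
                    chrom.append(_Lineage(fam, _TreeNode()))
                fam += 1
            out_genome.append(chrom)
        genomes[name] = out_genome

    # wrap family roots with outgroup splits, shallowest innermost
    family_roots: list[_TreeNode] = list(roots)
    for name in sorted(outgroup_depths, key=outgroup_depths.get):
        depth = outgroup_depths[name]
        out_tips = {lin.family: lin.node for chrom in genomes[name] for lin in chrom}
        for f in range(n_families):
            tip = out_tips.get(f)
            if tip is None:
                continue
            parent = _TreeNode()
            parent.depth = depth
            parent.kind = "spec"
            parent.support = draw_support()
            parent.children = [family_roots[f], tip]
            family_roots[f] = parent

    # assign gene ids, ranks, coordinates
    genes: dict[str, list[wio.GeneModel]] = {}
    cds_nt_len = 3 * params.cds_length_codons
    for sp in species:
        sp_genes: list[wio.GeneModel] = []
        counter = 0
        for ci, chrom in enumerate(genomes[sp]):
            for rank, lineage in enumerate(chrom):
                gene_id = f"{sp}g{counter:05d}"
                counter += 1
                node = lineage.node
                node.kind = "leaf"
                node.species = sp
                node.gene_id = gene_id
                node.depth = 0.0
                start = rank * (cds_nt_len + 500)
                sp_genes.append(
                    wio.GeneModel(
                        gene_id=gene_id,
                        species=sp,
                        chromosome=f"chr{ci + 1}",
                        rank=rank,
                        start=start,
                        end=start + cds_nt_len,
                        strand="+" if rng.random() < 0.5 else "-",
                    )
                )
        genes[sp] = sp_genes

    # evolve sequences down each family tree
    sequences: dict[str, str] = {}

    def _evolve(node: _TreeNode, codons: list[str]) -> None:
        if node.kind == "leaf":
            sequences[node.gene_id] = "".join(codons)
            return
        for child in node.children:
            blen = node.depth - child.depth
            if blen < -1e-12:
                raise SimulationError("negative branch length in genealogy")
            evolved = _apply_substitutions(
                codons, max(0.0, blen), max(0.0, blen) * params.omega,
                params.kappa, rng,
            )
            _evolve(child, evolved)

    for f in range(n_families):
        ancestor = random_cds(params.cds_length_codons, rng)
        _evolve(family_roots[f], ancestor)

    gene_lookup = {g.gene_id: g for sp in species for g in genes[sp]}
    for sp in species:
        for g in genes[sp]:
            g.cds = sequences[g.gene_id]

    # orthogroups, gene trees, true labels
    orthogroups: dict[str, dict[str, list[str]]] = {}
    gene_trees: dict[str, str] = {}
    true_pair_labels: dict[frozenset, str] = {}
    sigma_like = _event_label(0)
    true_retained: dict[str, set[str]] = {
        _event_label(i): set() for i in range(len(params.wgd_events))
    }

    def _newick(node: _TreeNode, parent_depth: float) -> str:
        blen = max(0.0, parent_depth - node.depth)
        if node.kind == "leaf":
            return f"{node.species}|{node.gene_id}:{blen:.4f}"
        inner = ",".join(_newick(c, node.depth) for c in node.children)
        return f"({inner}){node.support:.3f}:{blen:.4f}"

    for f in range(n_families):
        root = family_roots[f]
        leaves = root.leaves()
        og_id = f"OG{f:05d}"
        members: dict[str, list[str]] = {}
        for leaf in leaves:
            members.setdefault(leaf.species, []).append(leaf.gene_id)
        orthogroups[og_id] = members
        if len(leaves) >= 2:
            # strip the root's zero-length branch
            gene_trees[og_id] = _newick(root, root.depth).rsplit(":", 1)[0] + ";"

        # true pair labels via MRCA kind
        paths: dict[str, list[_TreeNode]] = {}

        def _collect(node: _TreeNode, path: list[_TreeNode]) -> None:
            path = path + [node]
            if node.kind == "leaf":
                paths[node.gene_id] = path
                return
            for child in node.children:
                _collect(child, path)

        _collect(root, [])
        for la, lb in itertools.combinations(leaves, 2):
            pa, pb = paths[la.gene_id], paths[lb.gene_id]
            mrca = None
            for x, y in zip(pa, pb):
                if x is y:
                    mrca = x
                else:
                    break
            if mrca is None:
                continue
            key = frozenset((la.gene_id, lb.gene_id))
            if la.species == lb.species == FOCAL_SPECIES:
                if mrca.kind == "tandem":
                    true_pair_labels[key] = "tandem"
                elif mrca.kind == "dup":
                    true_pair_labels[key] = _event_label(mrca.event_idx)
            elif {la.species, lb.species} == set(FOCAL_GENUS[: min(2, params.n_species)]) \
                    and len({la.species, lb.species}) == 2:
                if mrca.kind == "spec" and abs(
                    mrca.depth - params.ortholog_ks / 2.0
                ) < 1e-12:
                    true_pair_labels[key] = "ortholog"

        # true retained focal gene sets per event
        def _focal_leaves(node: _TreeNode) -> list[str]:
            return [
                leaf.gene_id for leaf in node.leaves() if leaf.species == FOCAL_SPECIES
            ]

        def _collect_retained(node: _TreeNode) -> None:
            if node.kind == "dup":
                label = _event_label(node.event_idx)
                left = _focal_leaves(node.children[0])
                right = _focal_leaves(node.children[1])
                if left and right:
                    true_retained[label].update(left + right)
            for child in node.children:
                _collect_retained(child)

        _collect_retained(root)

    # homology pairs: intra-focal-genome true paralogs plus spurious noise
    pairs: list[wio.HomologyPair] = []
    for f in range(n_families):
        og = orthogroups[f"OG{f:05d}"]
        focal = og.get(FOCAL_SPECIES, [])
        for ga, gb in itertools.combinations(focal, 2):
            key = frozenset((ga, gb))
            label = true_pair_labels.get(key)
            if label == "tandem":
                depth = params.tandem_ks
            elif label in true_retained:
                depth = params.wgd_events[
                    [_event_label(i) for i in range(len(params.wgd_events))].index(label)
                ].ks_depth
            else:
                depth = params.wgd_events[-1].ks_depth if params.wgd_events else 0.1
            evalue = 10 ** (-(50.0 - 20.0 * min(depth, 1.5)))
            bitscore = max(50.0, 600.0 * (1.1 - depth / 2.0))
            pairs.append(wio.HomologyPair(ga, gb, evalue, round(bitscore, 1)))
    n_spurious = max(1, len(pairs) // 50)
    focal_ids = [g.gene_id for g in genes[FOCAL_SPECIES]]
    existing = {p.key for p in pairs}
    for _ in range(n_spurious):
        ga, gb = (focal_ids[int(i)] for i in rng.integers(0, len(focal_ids), size=2))
        if ga == gb or frozenset((ga, gb)) in existing:
            continue
        if gene_lookup[ga].species != gene_lookup[gb].species:
            continue
        evalue = 10 ** float(rng.uniform(-7, -2))
        pairs.append(wio.HomologyPair(ga, gb, evalue, 60.0))

    # TF-family and GO annotation tables (all species)
    tf_table: dict[str, str] = {}
    for sp in species:
        for chrom in genomes[sp]:
            for lineage in chrom:
                label = tf_label[lineage.family]
                if label is not None:
                    tf_table[lineage.node.gene_id] = label

    n_parents = max(1, params.n_go_terms // 8)
    parent_terms = [f"GO:{7000000 + i:07d}" for i in range(n_parents)]
    child_terms = [
        f"GO:{1000000 + i:07d}" for i in range(params.n_go_terms - n_parents)
    ]
    go_edges = [
        (term, parent_terms[int(rng.integers(n_parents))]) for term in child_terms
    ]
    go_edges.append((TF_MARKER_TERM, parent_terms[0]))
    family_terms: list[list[str]] = []
    for f in range(n_families):
        k = 1 + int(rng.integers(3))
        terms = [child_terms[int(i)] for i in rng.integers(0, len(child_terms), size=k)]
        if tf_label[f] is not None:
            terms.append(TF_MARKER_TERM)
        family_terms.append(sorted(set(terms)))
    go_table: dict[str, set[str]] = {}
    for sp in species:
        for chrom in genomes[sp]:
            for lineage in chrom:
                go_table[lineage.node.gene_id] = set(family_terms[lineage.family])

    # species tree
    sp_tree = FOCAL_SPECIES
    if params.n_species >= 2:
        sp_tree = f"({FOCAL_SPECIES}:{params.ortholog_ks / 2:.4f},{SISTER_SPECIES}:{params.ortholog_ks / 2:.4f})1.0"
        prev_depth = params.ortholog_ks / 2
        for name in sorted(outgroup_depths, key=outgroup_depths.get):
            d = outgroup_depths[name]
            sp_tree = f"({sp_tree}:{d - prev_depth:.4f},{name}:{d:.4f})1.0"
            prev_depth = d
    sp_tree += ";"

    n_focal = len(genes[FOCAL_SPECIES])
    truth = {
        "events": truth_events,
        "true_retained_genes": {k: sorted(v) for k, v in true_retained.items()},
        "n_focal_genes": n_focal,
        "n_families": n_families,
        "tf_families": sorted({t for t in tf_label if t is not None}),
    }

    return SyntheticDataset(
        params=params,
        species=species,
        focal_species=FOCAL_SPECIES,
        focal_genus=tuple(s for s in FOCAL_GENUS if s in species),
        genes=genes,
        orthogroups=orthogroups,
        gene_trees=gene_trees,
        species_tree=sp_tree,
        tf_family_table=tf_table,
        go_table=go_table,
        go_edges=go_edges,
        homology_pairs=pairs,
        true_pair_labels=true_pair_labels,
        truth=truth,
    )
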