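"""Gene-tree duplication events and their assignment to WGDs.

A gene-tree node is a duplication when the species sets of its child
clades overlap (the species-overlap criterion used by OrthoFinder-style
reconciliation).  Candidate events are filtered by the analysis criteria:
the orthogroup must have at least four genes and at least one gene from
outside the focal genus, both child branches must contain focal-species
genes, branch support must be at least 0.5, tandem duplicates (within the
5-gene rank window) are excluded, and the event's mean cross-child Ks
must lie strictly inside (0.05, 1.50).  Surviving events are assigned to
the younger (sigma) or older (rho) WGD through the age class of the
syntenic block their duplicate pairs anchor in.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Iterable, Mapping

import dendropy

from .io import leaf_gene, leaf_species


class RetentionError(ValueError):
    pass


ACCEPTED = "accepted"
REJECTED_SUPPORT = "rejected_support"
REJECTED_TANDEM = "rejected_tandem"
REJECTED_KS = "rejected_ks"
REJECTED_COMPOSITION = "rejected_composition"
REJECTED_NONSYNTENIC = "rejected_nonsyntenic"


@dataclass
class DuplicationEvent:
    """A supported gene-tree duplication node and its WGD assignment."""

    orthogroup_id: str
    node_id: str
    support: float
    child_a_genes: frozenset[str]
    child_b_genes: frozenset[str]
    species_a: frozenset[str]
    species_b: frozenset[str]
    mean_ks: float | None = None
    wgd: str = "unassigned"
    status: str = "candidate"
    is_polytomy: bool = False

    def focal_cross_pairs(self, focal_species: str) -> list[tuple[str, str]]:
        """Cross-child pairs of focal-species genes (one from each branch)."""
        fa = sorted(
            leaf_gene(lbl) for lbl in self.child_a_genes
            if leaf_species(lbl) == focal_species
        )
        fb = sorted(
            leaf_gene(lbl) for lbl in self.child_b_genes
            if leaf_species(lbl) == focal_species
        )
        return [(a, b) for a in fa for b in fb]

    def focal_genes(self, focal_species: str) -> set[str]:
        out = set()
        for label in self.child_a_genes | self.child_b_genes:
            sp, gene = label.split("|", 1)
            if sp == focal_species:
                out.add(gene)
        return out


def _node_support(node: dendropy.Node) -> float:
    if node.label is None or node.label == "":
        return 1.0  # unassessed supports do not count against the node
    return float(node.label)


def find_duplication_nodes(
    tree: dendropy.Tree, orthogroup_id: str = ""
) -> list[DuplicationEvent]:
    """Candidate duplication events by the species-overlap criterion."""
    if not tree.is_rooted:
        raise RetentionError(
            "tree is unrooted; root it (e.g. midpoint rooting) before "
            "duplication inference"
        )
    candidates: list[DuplicationEvent] = []
    for idx, node in enumerate(tree.preorder_internal_node_iter()):
        children = node.child_nodes()
        if len(children) < 2:
            continue
        clades = []
        for child in children:
            labels = frozenset(
                leaf.taxon.label for leaf in child.leaf_iter()
            )
            species = frozenset(leaf_species(lbl) for lbl in labels)
            clades.append((labels, species))
        overlap = False
        for (_, sa), (_, sb) in itertools.combinations(clades, 2):
            if sa & sb:
                overlap = True
                break
        if not overlap:
            continue
        (genes_a, species_a), (genes_b, species_b) = clades[0], clades[1]
        candidates.append(
            DuplicationEvent(
                orthogroup_id=orthogroup_id,
                node_id=f"n{idx}",
                support=_node_support(node),
                child_a_genes=genes_a,
                child_b_genes=genes_b,
                species_a=species_a,
                species_b=species_b,
                is_polytomy=len(children) > 2,
            )
        )
    return candidates


def filter_events(
    candidates: Iterable[DuplicationEvent],
    orthogroup_members: Mapping[str, Mapping[str, list[str]]],
    focal_species: str,
    focal_genus: Iterable[str],
    min_genes: int = 4,
    require_outgroup: bool = True,
    min_support: float = 0.5,
) -> list[DuplicationEvent]:
    """Apply the composition and support criteria, setting statuses.

    Composition rejects: orthogroups with fewer than ``min_genes`` genes,
    orthogroups without a gene from outside the focal genus (when
    ``require_outgroup``), events where either child branch lacks a
    focal-species gene, and polytomies.  Support of exactly
    ``min_support`` is kept ("not less than").
    """
    genus = set(focal_genus)
    out = []
    for event in candidates:
        members = orthogroup_members.get(event.orthogroup_id, {})
        og_size = sum(len(v) for v in members.values())
        has_outgroup = any(sp not in genus for sp in members)
        if (
            event.is_polytomy
            or og_size < min_genes
            or (require_outgroup and not has_outgroup)
            or focal_species not in event.species_a
            or focal_species not in event.species_b
        ):
            event.status = REJECTED_COMPOSITION
        elif event.support < min_support:
            event.status = REJECTED_SUPPORT
        else:
            event.status = "candidate"
        out.append(event)
    return out


def drop_tandem_events(
    events: Iterable[DuplicationEvent],
    tandem_pairs: set[frozenset],
    focal_species: str,
) -> list[DuplicationEvent]:
    """Reject events whose focal cross-child pair set touches a tandem pair."""
    out = []
    for event in events:
        if event.status == "candidate":
            for a, b in event.focal_cross_pairs(focal_species):
                if frozenset((a, b)) in tandem_pairs:
                    event.status = REJECTED_TANDEM
                    break
        out.append(event)
    return out


def event_mean_ks(
    events: Iterable[DuplicationEvent],
    ks_lookup: Callable[[str, str], float | None],
    focal_species: str,
    lo: float = 0.05,
    hi: float = 1.50,
) -> list[DuplicationEvent]:
    """Mean Ks over valid focal cross-child pairs; reject outside (lo, hi)."""
    out = []
    for event in events:
        if event.status == "candidate":
            values = []
            for a, b in event.focal_cross_pairs(focal_species):
                ks = ks_lookup(a, b)
                if ks is not None:
                    values.append(ks)
            if not values:
                event.status = REJECTED_KS
            else:
                event.mean_ks = sum(values) / len(values)
                if not lo < event.mean_ks < hi:
                    event.status = REJECTED_KS
        out.append(event)
    return out


def assign_to_wgd(
    events: Iterable[DuplicationEvent],
    anchor_classes: Mapping[frozenset, tuple[str, float | None]],
    focal_species: str,
) -> list[DuplicationEvent]:
    """Assign events to sigma/rho via their pairs' syntenic-block classes.

    ``anchor_classes`` maps anchored pairs to (block class, pair Ks).  An
    event anchored only in young blocks is sigma, only in old blocks rho;
    when both occur, the class of the pair whose Ks is nearest the event
    mean wins.  Events with no anchored pair are rejected as nonsyntenic.
    """
    class_to_wgd = {"young": "sigma", "old": "rho"}
    out = []
    for event in events:
        if event.status == "candidate":
            hits: list[tuple[str, float | None]] = []
            for a, b in event.focal_cross_pairs(focal_species):
                hit = anchor_classes.get(frozenset((a, b)))
                if hit is not None:
                    hits.append(hit)
            classes = {cls for cls, _ in hits}
            if not hits:
                event.status = REJECTED_NONSYNTENIC
            elif len(classes) == 1:
                event.wgd = class_to_wgd[classes.pop()]
                event.status = ACCEPTED
            else:
                mean = event.mean_ks if event.mean_ks is not None else 0.0
                scored = [
                    (abs((ks if ks is not None else mean) - mean), cls)
                    for cls, ks in hits
                ]
                event.wgd = class_to_wgd[min(scored)[1]]
                event.status = ACCEPTED
        out.append(event)
    return out


def round_half_up_percent(part: int, whole: int) -> float:
    """100 * part / whole, rounded half-up to one decimal."""
    if whole <= 0:
        raise RetentionError("whole must be positive")
    if part > whole:
        raise RetentionError("part exceeds whole")
    pct = Decimal(100 * part) / Decimal(whole)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class RetentionSummary:
    sigma_genes: set[str]
    rho_genes: set[str]
    n_total_genes: int

    @property
    def union_genes(self) -> set[str]:
        return self.sigma_genes | self.rho_genes

    def to_dict(self) -> dict:
        n = self.n_total_genes
        return {
            "n_total_genes": n,
            "sigma": {
                "count": len(self.sigma_genes),
                "percent": round_half_up_percent(len(self.sigma_genes), n),
            },
            "rho": {
                "count": len(self.rho_genes),
                "percent": round_half_up_percent(len(self.rho_genes), n),
            },
            "union_deduplicated": {
                "count": len(self.union_genes),
                "percent": round_half_up_percent(len(self.union_genes), n),
            },
        }


def retained_gene_sets(
    events: Iterable[DuplicationEvent],
    focal_species: str,
    n_total_genes: int,
) -> RetentionSummary:
    """Union focal genes of accepted events per WGD, with percentages.

    A gene may join events of both ages, so the sigma and rho sets can
    overlap; the summary reports both raw and deduplicated counts.
    """
    sigma: set[str] = set()
    rho: set[str] = set()
    for event in events:
        if event.status != ACCEPTED:
            continue
        genes = event.focal_genes(focal_species)
        if event.wgd == "sigma":
            sigma |= genes
        elif event.wgd == "rho":
            rho |= genes
    return RetentionSummary(sigma, rho, n_total_genes)


def events_table_rows(events: Iterable[DuplicationEvent], focal_species: str):
    """Rows for the events TSV output."""
    for e in events:
        yield {
            "orthogroup": e.orthogroup_id,
            "node": e.node_id,
            "support": e.support,
            "mean_ks": "" if e.mean_ks is None else f"{e.mean_ks:.4f}",
            "wgd": e.wgd,
            "status": e.status,
            "genes_a": ",".join(sorted(e.child_a_genes)),
            "genes_b": ",".join(sorted(e.child_b_genes)),
        }
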