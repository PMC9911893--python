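"""Collinear (syntenic) block detection and Ks-based age classification.

Blocks are maximal chains of anchor pairs found by dynamic programming
within each chromosome pair: successive anchors must advance by a gene-rank
gap in (0, max_gap] on both chromosomes, monotonically increasing on the
first and consistently increasing or decreasing on the second (block
orientation).  Chains score by anchor count; chains shorter than
``min_pairs`` are discarded, and anchors join at most one block
(best-chain-first greedy extraction with a deterministic lexicographic
tie-break).  Tandem-flagged anchors and self-pairs are removed before
chaining.  A block's WGD age class is the window its median anchor Ks
falls in: young for the recent (sigma-like) event, old for the ancient
(rho-like) one.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import GeneModel, HomologyPair

logger = logging.getLogger(__name__)


class SyntenyError(ValueError):
    pass


@dataclass
class Anchor:
    """A homology pair placed on the rank grid of its chromosome pair."""

    pair: HomologyPair
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int

    @property
    def key(self) -> tuple[int, int]:
        return (self.rank_a, self.rank_b)


@dataclass
class SyntenyBlock:
    """An ordered chain of collinear anchors with a median-Ks age class."""

    block_id: int
    anchors: list[Anchor]
    orientation: str  # "same" | "inverted"
    median_ks: float | None = None
    ks_class: str = "unclassified"

    @property
    def chrom_a(self) -> str:
        return self.anchors[0].chrom_a

    @property
    def chrom_b(self) -> str:
        return self.anchors[0].chrom_b

    def __len__(self) -> int:
        return len(self.anchors)


def detect_tandem(
    pairs: Iterable[HomologyPair],
    genes: Sequence[GeneModel],
    window: int = 5,
) -> set[frozenset]:
    """Flag pairs on the same chromosome within ``window`` gene ranks.

    The window is inclusive: a rank distance of exactly ``window`` is
    tandem.  Unknown gene ids are an error.
    """
    lookup = {g.gene_id: g for g in genes}
    tandem: set[frozenset] = set()
    for pair in pairs:
        try:
            a, b = lookup[pair.gene_a], lookup[pair.gene_b]
        except KeyError as exc:
            raise SyntenyError(f"unknown gene id {exc.args[0]!r} in pair table") from exc
        if (
            a.species == b.species
            and a.chromosome == b.chromosome
            and abs(a.rank - b.rank) <= window
        ):
            tandem.add(pair.key)
    return tandem


def make_anchors(
    pairs: Iterable[HomologyPair],
    genes: Sequence[GeneModel],
    evalue_max: float = 1e-5,
    exclude: set[frozenset] | None = None,
) -> list[Anchor]:
    """Place pairs on the rank grid, dropping weak, excluded and self pairs.

    Intra-genome pairs are canonicalised so chrom_a/rank_a is the
    lexicographically smaller end, and symmetric duplicates collapse.
    """
    lookup = {g.gene_id: g for g in genes}
    exclude = exclude or set()
    seen: set[frozenset] = set()
    anchors: list[Anchor] = []
    for pair in pairs:
        if pair.evalue > evalue_max:
            continue
        if pair.key in exclude or pair.key in seen:
            continue
        try:
            a, b = lookup[pair.gene_a], lookup[pair.gene_b]
        except KeyError as exc:
            raise SyntenyError(f"unknown gene id {exc.args[0]!r} in pair table") from exc
        seen.add(pair.key)
        if (b.chromosome, b.rank) < (a.chromosome, a.rank):
            a, b = b, a
        anchors.append(Anchor(pair, a.chromosome, b.chromosome, a.rank, b.rank))
    return anchors


def _best_chain(
    anchors: list[Anchor], max_gap: int
) -> tuple[list[int], str] | None:
    """Longest valid chain over ``anchors`` (indices into the sorted list).

    Among maximum-length chains the lexicographically smallest sequence of
    (rank_a, rank_b) keys wins; orientation "same" beats "inverted" on a
    full tie.
    """
    n = len(anchors)
    if n == 0:
        return None
    order = sorted(range(n), key=lambda i: anchors[i].key)

    def allowed(i: int, j: int, sign: int) -> bool:
        da = anchors[j].rank_a - anchors[i].rank_a
        db = (anchors[j].rank_b - anchors[i].rank_b) * sign
        return 0 < da <= max_gap and 0 < db <= max_gap

    best: tuple[int, list[tuple[int, int]], int, list[int]] | None = None
    for sign, orient_rank in ((1, 0), (-1, 1)):
        # suffix DP: longest chain starting at each anchor
        length = {i: 1 for i in order}
        for pos in range(len(order) - 1, -1, -1):
            i = order[pos]
            for j in order[pos + 1 :]:
                if allowed(i, j, sign) and 1 + length[j] > length[i]:
                    length[i] = 1 + length[j]
        top = max(length.values())
        # greedy reconstruction of the lexicographically smallest max chain
        start = min(
            (i for i in order if length[i] == top), key=lambda i: anchors[i].key
        )
        chain = [start]
        while length[chain[-1]] > 1:
            i = chain[-1]
            nxt = min(
                (
                    j
                    for j in order
                    if length[j] == length[i] - 1 and allowed(i, j, sign)
                ),
                key=lambda j: anchors[j].key,
            )
            chain.append(nxt)
        keyseq = [anchors[i].key for i in chain]
        cand = (-top, keyseq, orient_rank, chain)
        if best is None or cand[:3] < best[:3]:
            best = cand
    assert best is not None
    return best[3], ("same" if best[2] == 0 else "inverted")


def chain_blocks(
    anchors: Iterable[Anchor],
    min_pairs: int = 5,
    max_gap: int = 25,
    evalue_max: float = 1e-5,
) -> list[SyntenyBlock]:
    """Chain anchors into syntenic blocks of at least ``min_pairs`` anchors."""
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for anchor in anchors:
        if anchor.pair.evalue > evalue_max:
            continue
        groups.setdefault((anchor.chrom_a, anchor.chrom_b), []).append(anchor)
    blocks: list[SyntenyBlock] = []
    block_id = 0
    for chrom_pair in sorted(groups):
        remaining = groups[chrom_pair]
        while True:
            found = _best_chain(remaining, max_gap)
            if found is None:
                break
            chain, orientation = found
            if len(chain) < min_pairs:
                break
            members = [remaining[i] for i in chain]
            blocks.append(SyntenyBlock(block_id, members, orientation))
            block_id += 1
            used = set(chain)
            remaining = [a for i, a in enumerate(remaining) if i not in used]
    for block in blocks:
        _assert_monotone(block)
    return blocks


def _assert_monotone(block: SyntenyBlock) -> None:
    sign = 1 if block.orientation == "same" else -1
    for prev, cur in zip(block.anchors, block.anchors[1:]):
        if not (cur.rank_a > prev.rank_a and (cur.rank_b - prev.rank_b) * sign > 0):
            raise SyntenyError(
                f"block {block.block_id}: anchors violate rank monotonicity"
            )


def classify_blocks(
    blocks: Iterable[SyntenyBlock],
    ks_table: Mapping[frozenset, float],
    young_range: tuple[float, float] = (0.05, 0.6),
    old_range: tuple[float, float] = (0.6, 1.5),
) -> list[SyntenyBlock]:
    """Set each block's median Ks and its WGD age class.

    ``ks_table`` maps the frozenset of a pair's gene ids to a valid Ks.
    A median of exactly ``old_range[0]`` classifies old (left-closed
    convention); blocks with no valid anchor Ks stay unclassified.
    """
    blocks = list(blocks)
    for block in blocks:
        values = [
            ks_table[a.pair.key] for a in block.anchors if a.pair.key in ks_table
        ]
        if not values:
            logger.warning(
                "block %d has no anchor with a valid Ks; left unclassified",
                block.block_id,
            )
            block.median_ks = None
            block.ks_class = "unclassified"
            continue
        med = statistics.median(values)
        block.median_ks = med
        if young_range[0] < med < young_range[1]:
            block.ks_class = "young"
        elif old_range[0] <= med <= old_range[1]:
            block.ks_class = "old"
        else:
            block.ks_class = "unclassified"
    return blocks


def anchor_class_table(
    blocks: Iterable[SyntenyBlock],
    ks_table: Mapping[frozenset, float],
) -> dict[frozenset, tuple[str, float | None]]:
    """Map each anchored pair to its block's age class and the pair's Ks."""
    out: dict[frozenset, tuple[str, float | None]] = {}
    for block in blocks:
        if block.ks_class not in ("young", "old"):
            continue
        for anchor in block.anchors:
            out[anchor.pair.key] = (block.ks_class, ks_table.get(anchor.pair.key))
    return out
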