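"""End-to-end orchestration: ks -> synteny -> peaks -> retention -> tfstats -> enrichment.

The :class:`Pipeline` runs the stages in dependency order against one
output directory, writing every intermediate as TSV/JSON and a final
``report.json`` whose numbers are all derived from the stage outputs.
A :class:`PipelineConfig` holds every analysis constant; identical config
and inputs reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import io as wio
from . import ks as wks
from . import mixture, retention, synteny, tfstats, enrichment
from .simulate import SimulationParams, WgdEvent, simulate_genome

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All analysis constants, defaulting to the published procedure."""

    input_dir: str | None = None
    simulate: SimulationParams | None = None
    focal_species: str = "MCA"
    focal_genus: tuple[str, ...] = ("MCA", "MDO")
    ks_method: str = "YN00"
    ks_bounds: tuple[float, float] = (0.05, 1.5)
    ortholog_ks_bounds: tuple[float, float] = (0.0, 1.5)
    trough: float = 0.6
    n_bins: int = 200
    min_block_pairs: int = 5
    max_gap: int = 25
    evalue_max: float = 1e-5
    tandem_window: int = 5
    min_support: float = 0.5
    min_orthogroup_genes: int = 4
    require_outgroup: bool = True
    enrichment_p_adj_cutoff: float = 0.05
    enrichment_q_cutoff: float = 0.2
    propagate_go: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dir is None and self.simulate is None:
            raise PipelineError("config needs either input_dir or a simulate block")
        if self.ks_method not in wks.METHODS:
            raise PipelineError(f"unknown ks_method {self.ks_method!r}")
        if not self.ks_bounds[0] < self.ks_bounds[1]:
            raise PipelineError("ks_bounds must be (lo, hi) with lo < hi")
        if not self.ks_bounds[0] <= self.trough <= self.ks_bounds[1]:
            raise PipelineError("trough must lie inside ks_bounds")
        for name in ("n_bins", "min_block_pairs", "max_gap", "tandem_window",
                     "min_orthogroup_genes"):
            if getattr(self, name) < 1:
                raise PipelineError(f"{name} must be a positive integer")
        if not 0.0 <= self.min_support <= 1.0:
            raise PipelineError("min_support must lie in [0, 1]")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(data.get("simulate"), dict):
            sim = dict(data["simulate"])
            if "wgd_events" in sim:
                sim["wgd_events"] = tuple(
                    WgdEvent(**e) if isinstance(e, dict) else WgdEvent(*e)
                    for e in sim["wgd_events"]
                )
            data["simulate"] = SimulationParams(**sim)
        for key in ("ks_bounds", "ortholog_ks_bounds", "focal_genus"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def echo(self) -> dict:
        out = asdict(self)
        return out


def summary_percentages(part: int, whole: int) -> float:
    """100 * part / whole rounded half-up to one decimal (reporting rule)."""
    return retention.round_half_up_percent(part, whole)


@dataclass
class InputBundle:
    sequences: dict[str, str]
    genes: list[wio.GeneModel]
    pairs: list[wio.HomologyPair]
    gene_trees: dict[str, Any]
    orthogroups: dict[str, dict[str, list[str]]]
    tf_table: dict[str, str]
    go_table: dict[str, set[str]]
    go_edges: list[tuple[str, str]] | None

    def genes_of(self, species: str) -> list[wio.GeneModel]:
        return [g for g in self.genes if g.species == species]


def load_inputs(input_dir: str | Path) -> InputBundle:
    d = Path(input_dir)
    for required in ("cds.fasta", "genes.tsv", "pairs.tsv"):
        if not (d / required).exists():
            raise PipelineError(f"missing input file: {d / required}")
    genes = wio.read_gene_positions(d / "genes.tsv")
    sequences = wio.read_fasta(d / "cds.fasta")
    for g in genes:
        g.cds = sequences.get(g.gene_id, "")
    edges_path = d / "go_edges.tsv"
    return InputBundle(
        sequences=sequences,
        genes=genes,
        pairs=wio.read_homology_pairs(d / "pairs.tsv"),
        gene_trees=(
            wio.read_gene_trees(d / "gene_trees.tsv")
            if (d / "gene_trees.tsv").exists()
            else {}
        ),
        orthogroups=(
            wio.read_orthogroups(d / "orthogroups.tsv")
            if (d / "orthogroups.tsv").exists()
            else {}
        ),
        tf_table=(
            wio.read_tf_families(d / "tf_families.tsv")
            if (d / "tf_families.tsv").exists()
            else {}
        ),
        go_table=(
            wio.read_go_annotations(d / "go_annotations.tsv")
            if (d / "go_annotations.tsv").exists()
            else {}
        ),
        go_edges=wio.read_go_edges(edges_path) if edges_path.exists() else None,
    )


class Pipeline:
    """Stage runner over one output directory."""

    def __init__(self, config: PipelineConfig, outdir: str | Path) -> None:
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._inputs: InputBundle | None = None
        self._estimates: list[wks.KsEstimate] | None = None
        self._blocks: list[synteny.SyntenyBlock] | None = None
        self._tandem: set[frozenset] | None = None
        self._mixture: mixture.KsMixtureResults | None = None
        self._events: list[retention.DuplicationEvent] | None = None
        self._summary: retention.RetentionSummary | None = None
        self._pair_cache: dict[frozenset, wks.KsEstimate] = {}

    # -- inputs -----------------------------------------------------------
    def inputs(self) -> InputBundle:
        if self._inputs is None:
            cfg = self.config
            if cfg.simulate is not None:
                dataset = simulate_genome(cfg.simulate)
                input_dir = self.outdir / "inputs"
                dataset.write(input_dir)
                logger.info("simulated dataset written to %s", input_dir)
                self._inputs = load_inputs(input_dir)
            else:
                self._inputs = load_inputs(cfg.input_dir)
        return self._inputs

    # -- ks ---------------------------------------------------------------
    def ks(self) -> list[wks.KsEstimate]:
        if self._estimates is not None:
            return self._estimates
        bundle = self.inputs()
        cfg = self.config
        species_of = {g.gene_id: g.species for g in bundle.genes}
        focal = cfg.focal_species
        estimates = []
        for pair in bundle.pairs:
            if species_of.get(pair.gene_a) != focal or species_of.get(pair.gene_b) != focal:
                continue
            estimates.append(self._pair_estimate(pair.gene_a, pair.gene_b))
        self._estimates = estimates
        frame = pd.DataFrame(
            [
                {
                    "gene_a": e.gene_a, "gene_b": e.gene_b, "method": e.method,
                    "S": e.S, "N": e.N, "Sd": e.Sd, "Nd": e.Nd,
                    "kappa": "" if e.kappa is None else e.kappa,
                    "ka": e.dn, "ks": e.ds, "valid": e.valid,
                }
                for e in estimates
            ]
        )
        frame.to_csv(self.outdir / "ks.tsv", sep="\t", index=False)
        return estimates

    def _pair_estimate(self, gene_a: str, gene_b: str) -> wks.KsEstimate:
        key = frozenset((gene_a, gene_b))
        if key not in self._pair_cache:
            bundle = self.inputs()
            self._pair_cache[key] = wks.pair_ks(
                bundle.sequences[gene_a],
                bundle.sequences[gene_b],
                gene_a,
                gene_b,
                self.config.ks_method,
            )
        return self._pair_cache[key]

    def ks_table(self) -> dict[frozenset, float]:
        return {
            frozenset((e.gene_a, e.gene_b)): e.ds for e in self.ks() if e.valid
        }

    # -- synteny ----------------------------------------------------------
    def tandem_flags(self) -> set[frozenset]:
        if self._tandem is None:
            bundle = self.inputs()
            self._tandem = synteny.detect_tandem(
                [
                    p
                    for p in bundle.pairs
                    if p.gene_a in bundle.sequences and p.gene_b in bundle.sequences
                ],
                bundle.genes,
                self.config.tandem_window,
            )
        return self._tandem

    def blocks(self) -> list[synteny.SyntenyBlock]:
        if self._blocks is not None:
            return self._blocks
        bundle = self.inputs()
        cfg = self.config
        focal_genes = bundle.genes_of(cfg.focal_species)
        focal_ids = {g.gene_id for g in focal_genes}
        focal_pairs = [
            p for p in bundle.pairs if p.gene_a in focal_ids and p.gene_b in focal_ids
        ]
        anchors = synteny.make_anchors(
            focal_pairs, focal_genes, cfg.evalue_max, exclude=self.tandem_flags()
        )
        blocks = synteny.chain_blocks(
            anchors, cfg.min_block_pairs, cfg.max_gap, cfg.evalue_max
        )
        ks_table = self.ks_table()
        blocks = synteny.classify_blocks(
            blocks,
            ks_table,
            young_range=(cfg.ks_bounds[0], cfg.trough),
            old_range=(cfg.trough, cfg.ks_bounds[1]),
        )
        self._blocks = blocks
        pd.DataFrame(
            [
                {
                    "block_id": b.block_id, "chrom_a": b.chrom_a, "chrom_b": b.chrom_b,
                    "n_anchors": len(b), "orientation": b.orientation,
                    "median_ks": "" if b.median_ks is None else f"{b.median_ks:.4f}",
                    "ks_class": b.ks_class,
                }
                for b in blocks
            ]
        ).to_csv(self.outdir / "blocks.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "block_id": b.block_id,
                    "gene_a": a.pair.gene_a,
                    "gene_b": a.pair.gene_b,
                    "ks": ks_table.get(a.pair.key, float("nan")),
                }
                for b in blocks
                for a in b.anchors
            ]
        ).to_csv(self.outdir / "anchors.tsv", sep="\t", index=False)
        return blocks

    # -- peaks ------------------------------------------------------------
    def peaks(self) -> mixture.KsMixtureResults:
        if self._mixture is not None:
            return self._mixture
        cfg = self.config
        ks_table = self.ks_table()
        lo, hi = cfg.ks_bounds
        values = [
            ks_table[a.pair.key]
            for b in self.blocks()
            for a in b.anchors
            if a.pair.key in ks_table and lo < ks_table[a.pair.key] < hi
        ]
        model = mixture.KsMixtureModel(values, cfg.trough, cfg.n_bins, cfg.ks_bounds)
        results = model.fit(on_small="skip")
        self._mixture = results
        (self.outdir / "peaks.json").write_text(results.to_json() + "\n")
        results.density_table().to_csv(
            self.outdir / "densities.tsv", sep="\t", index=False
        )
        return results

    # -- retention --------------------------------------------------------
    def events(self) -> list[retention.DuplicationEvent]:
        if self._events is not None:
            return self._events
        bundle = self.inputs()
        cfg = self.config
        candidates: list[retention.DuplicationEvent] = []
        for og_id in sorted(bundle.gene_trees):
            candidates.extend(
                retention.find_duplication_nodes(bundle.gene_trees[og_id], og_id)
            )
        events = retention.filter_events(
            candidates,
            bundle.orthogroups,
            cfg.focal_species,
            cfg.focal_genus,
            cfg.min_orthogroup_genes,
            cfg.require_outgroup,
            cfg.min_support,
        )
        events = retention.drop_tandem_events(
            events, self.tandem_flags(), cfg.focal_species
        )

        def ks_lookup(a: str, b: str) -> float | None:
            est = self._pair_estimate(a, b)
            return est.ds if est.valid else None

        events = retention.event_mean_ks(
            events, ks_lookup, cfg.focal_species, *cfg.ks_bounds
        )
        anchor_classes = synteny.anchor_class_table(self.blocks(), self.ks_table())
        events = retention.assign_to_wgd(events, anchor_classes, cfg.focal_species)
        self._events = events
        pd.DataFrame(
            list(retention.events_table_rows(events, cfg.focal_species))
        ).to_csv(self.outdir / "events.tsv", sep="\t", index=False)
        return events

    def retention_summary(self) -> retention.RetentionSummary:
        if self._summary is None:
            bundle = self.inputs()
            cfg = self.config
            n_total = len(bundle.genes_of(cfg.focal_species))
            self._summary = retention.retained_gene_sets(
                self.events(), cfg.focal_species, n_total
            )
            (self.outdir / "sigma_retained.txt").write_text(
                "\n".join(sorted(self._summary.sigma_genes)) + "\n"
            )
            (self.outdir / "rho_retained.txt").write_text(
                "\n".join(sorted(self._summary.rho_genes)) + "\n"
            )
        return self._summary

    # -- tf stats ---------------------------------------------------------
    def tf_stats(self) -> tuple[pd.DataFrame | None, pd.DataFrame]:
        bundle = self.inputs()
        cfg = self.config
        species_of = {g.gene_id: g.species for g in bundle.genes}
        per_species: dict[str, dict[str, str]] = {}
        for gene, family in bundle.tf_table.items():
            sp = species_of.get(gene)
            if sp is not None:
                per_species.setdefault(sp, {})[gene] = family
        ztable = None
        if len(per_species) >= 3 and cfg.focal_species in per_species:
            matrix = tfstats.family_count_matrix(per_species)
            ztable = tfstats.tf_zscore_table(matrix, cfg.focal_species)
            ztable.to_csv(self.outdir / "tf_stats.tsv", sep="\t")
        summary = self.retention_summary()
        focal_tf = per_species.get(cfg.focal_species, {})
        rows = tfstats.retention_table(
            focal_tf, summary.sigma_genes, summary.rho_genes
        )
        frame = tfstats.retention_table_frame(rows)
        frame.to_csv(self.outdir / "tf_retention.tsv", sep="\t", index=False)
        return ztable, frame

    # -- enrichment -------------------------------------------------------
    def enrichment(self) -> dict[str, pd.DataFrame]:
        bundle = self.inputs()
        cfg = self.config
        summary = self.retention_summary()
        background = {
            g.gene_id for g in bundle.genes_of(cfg.focal_species)
        }
        edges = bundle.go_edges if cfg.propagate_go else None
        out = {}
        for name, gene_set in (
            ("sigma", summary.sigma_genes),
            ("rho", summary.rho_genes),
        ):
            frame = enrichment.enrich(
                gene_set,
                bundle.go_table,
                background,
                cfg.enrichment_p_adj_cutoff,
                cfg.enrichment_q_cutoff,
                parent_edges=edges,
            )
            frame.to_csv(self.outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
            out[name] = frame
        return out

    # -- report -----------------------------------------------------------
    def run(self) -> dict:
        """Run every stage in dependency order and write report.json."""
        bundle = self.inputs()
        cfg = self.config
        estimates = self.ks()
        blocks = self.blocks()
        peaks = self.peaks()
        events = self.events()
        summary = self.retention_summary()
        ztable, tf_frame = self.tf_stats()
        enrich_frames = self.enrichment()
        status_counts: dict[str, int] = {}
        for e in events:
            status_counts[e.status] = status_counts.get(e.status, 0) + 1
        report = {
            "version": __version__,
            "config": cfg.echo(),
            "counts": {
                "species": sorted({g.species for g in bundle.genes}),
                "genes_total": len(bundle.genes),
                "genes_focal": len(bundle.genes_of(cfg.focal_species)),
                "homology_pairs": len(bundle.pairs),
                "ks_estimates": len(estimates),
                "ks_valid": sum(e.valid for e in estimates),
                "tandem_pairs": len(self.tandem_flags()),
                "blocks": len(blocks),
                "blocks_young": sum(b.ks_class == "young" for b in blocks),
                "blocks_old": sum(b.ks_class == "old" for b in blocks),
                "anchors_in_blocks": sum(len(b) for b in blocks),
                "duplication_candidates": len(events),
                "event_status": status_counts,
            },
            "wgd_peaks": peaks.mixture.to_dict(),
            "retention": summary.to_dict(),
            "tf_retention_fraction_range": (
                list(tfstats.retention_fraction_range(
                    tfstats.retention_table(
                        {
                            g: f
                            for g, f in bundle.tf_table.items()
                            if g in {x.gene_id for x in bundle.genes_of(cfg.focal_species)}
                        },
                        summary.sigma_genes,
                        summary.rho_genes,
                    )
                ))
                if bundle.tf_table
                else None
            ),
            "enrichment_significant": {
                name: int(frame["significant"].sum()) if len(frame) else 0
                for name, frame in enrich_frames.items()
            },
        }
        (self.outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        return report


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Convenience wrapper: build a :class:`Pipeline` and run every stage."""
    return Pipeline(config, outdir).run()
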