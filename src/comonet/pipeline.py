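"""End-to-end orchestration of the cross-disease workflow.

One declarative config drives the whole chain: expression → fold
changes → feature selection → subject signatures → distance matrix and
similarity graph → consensus signature per group → probe-to-gene
translation → 1-step disease networks for the chosen groups → network
overlap → gene-set over-representation; plus, when a Ct table is
supplied, the qPCR branch (ΔΔCt → rank product).  Every stage writes a
tab-separated output and records its counts in a run manifest that is
written on success and on failure alike.  A run is a pure function of
config + seed: re-running reproduces every output byte-identically
(manifest timestamps are off by default for that reason).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from . import io_formats as iof
from . import signature as sig
from . import network as net
from . import enrichment as enr
from . import qpcr

logger = logging.getLogger("comonet")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    # input paths
    expression: str
    groups: str
    annotation: str
    interactions: str
    gene_sets: list[str]
    ct_table: str | None = None
    output_dir: str = "out"
    # signature parameters
    contrasts: list[list[str]] = field(
        default_factory=lambda: [["t2dm_ctrl", "ctrl"], ["t2dm_ad", "ad"]]
    )
    n1: int = 100
    n2: int = 100
    k: float = 10.0
    alpha: float = 0.01
    scale: str = "log2"
    # network / enrichment parameters
    network_groups: list[str] | None = None
    taxon: int = 9606
    universe: str = "annotation"  # or "interactome"
    fdr: float = 0.05
    min_set_size: int = 5
    max_set_size: int = 2000
    # qPCR parameters
    reference_genes: list[str] = field(default_factory=list)
    control_group: str | None = None
    qpcr_contrast: list[str] | None = None
    n_perm: int = 10000
    seed: int = 0
    record_timestamps: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for p in [self.expression, self.groups, self.annotation, self.interactions,
                  *self.gene_sets, *( [self.ct_table] if self.ct_table else [] )]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("n1 and n2 must be positive")
        if not 0 < self.k <= 100:
            raise ValueError("percentile k must be in (0, 100]")
        if not 0 < self.alpha < 1 or not 0 < self.fdr < 1:
            raise ValueError("alpha and fdr must be in (0, 1)")

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    status: str = "running"
    failed_stage: str | None = None
    counts: dict = field(default_factory=dict)
    timestamps: dict | None = None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def _safe(label: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in label)


def _write_enrichment(results: list[enr.EnrichmentResult], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tN\tK\tn\tk\tp\tq\tsignificant\toverlap_symbols\n")
        for r in results:
            fh.write(
                f"{r.name}\t{r.universe_size}\t{r.set_size}\t{r.query_size}\t"
                f"{r.overlap}\t{r.p_value:.6g}\t{r.q_value:.6g}\t"
                f"{int(r.significant)}\t{','.join(r.overlap_symbols)}\n"
            )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage, writing outputs and a manifest under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot())
    if config.record_timestamps:
        manifest.timestamps = {"started": _now()}
    stage = "config"

    def finish(status: str, failed: str | None = None) -> None:
        manifest.status = status
        manifest.failed_stage = failed
        if config.record_timestamps:
            manifest.timestamps["finished"] = _now()
        manifest.write(out / "manifest.json")

    try:
        config.validate()

        stage = "load_inputs"
        expr = iof.read_expression_matrix(config.expression)
        groups = iof.read_sample_groups(config.groups)
        groups.validate_against(expr)
        ann = iof.read_probe_annotation(config.annotation)
        manifest.counts["probes"] = expr.shape[0]
        manifest.counts["samples"] = expr.shape[1]

        stage = "fold_changes"
        fc = sig.fold_change_profiles(expr, scale=config.scale)

        stage = "feature_selection"
        contrasts = [tuple(c) for c in config.contrasts]
        features = sig.select_features(fc, groups, contrasts, alpha=config.alpha)
        manifest.counts["selected_features"] = len(features)
        (out / "selected_features.tsv").write_text(
            "feature\n" + "".join(f"{f}\n" for f in features)
        )

        stage = "signatures"
        signatures = sig.extract_signatures(fc, features, config.n1, config.n2)
        with open(out / "signatures.tsv", "w") as fh:
            fh.write("sample\tdirection\trank\tfeature\n")
            for s in signatures:
                for r, f in enumerate(s.up, 1):
                    fh.write(f"{s.sample_id}\tup\t{r}\t{f}\n")
                for r, f in enumerate(s.down, 1):
                    fh.write(f"{s.sample_id}\tdown\t{r}\t{f}\n")
        manifest.counts["signatures"] = len(signatures)

        stage = "distance_matrix"
        dm = sig.distance_matrix(signatures)
        dm.to_csv(out / "distance_matrix.tsv", sep="\t", index_label="sample",
                  float_format="%.10g")

        stage = "similarity_graph"
        graph = sig.similarity_graph(dm, k=config.k)
        with open(out / "graph_edges.tsv", "w") as fh:
            fh.write("node_a\tnode_b\tdistance\n")
            for a, b, d in sorted(graph.edges(data="distance")):
                fh.write(f"{a}\t{b}\t{d:.10g}\n")
        manifest.counts["graph_edges"] = graph.number_of_edges()

        stage = "consensus"
        consensus: dict[str, sig.ConsensusSignature] = {}
        by_sample = {s.sample_id: s for s in signatures}
        for g in groups.groups:
            members = [by_sample[x] for x in groups.samples_in(g)]
            cs = sig.consensus_signature(members, config.n1, config.n2, group=g)
            consensus[g] = cs
            with open(out / f"consensus_{_safe(g)}.tsv", "w") as fh:
                fh.write("feature\tdirection\trank\tpopularity\n")
                for r, f in enumerate(cs.up, 1):
                    fh.write(f"{f}\tup\t{r}\t{cs.up_popularity[f]}\n")
                for r, f in enumerate(cs.down, 1):
                    fh.write(f"{f}\tdown\t{r}\t{cs.down_popularity[f]}\n")
            manifest.counts[f"consensus_size_{g}"] = len(cs.up) + len(cs.down)

        stage = "probe_translation"
        consensus_genes: dict[str, list[str]] = {}
        for g, cs in consensus.items():
            genes = iof.map_probes_to_genes(list(cs.up) + list(cs.down), ann)
            consensus_genes[g] = genes
            (out / f"consensus_genes_{_safe(g)}.txt").write_text(
                "".join(f"{x}\n" for x in genes)
            )
            manifest.counts[f"consensus_genes_{g}"] = len(genes)

        stage = "interactome"
        records = iof.read_interactions(config.interactions)
        interactome = net.build_interactome(records, taxon=config.taxon)
        manifest.counts["interactome_edges"] = len(interactome.edges)
        manifest.counts["interactions_skipped_rows"] = records.n_skipped

        stage = "disease_networks"
        net_groups = config.network_groups or groups.groups[:2]
        networks: dict[str, net.DiseaseNetwork] = {}
        for g in net_groups:
            dn = net.expand_seed_network(interactome, consensus_genes[g], label=g)
            networks[g] = dn
            tag = _safe(g)
            with open(out / f"network_{tag}_edges.tsv", "w") as fh:
                fh.write("node_a\tnode_b\n")
                for a, b in sorted(dn.edges):
                    fh.write(f"{a}\t{b}\n")
            with open(out / f"network_{tag}_nodes.tsv", "w") as fh:
                fh.write("symbol\tis_seed\tdegree\tprovenance\n")
                for node in sorted(dn.nodes):
                    fh.write(f"{node}\t{int(node in dn.seeds)}\t{dn.degree(node)}\t{g}\n")
            (out / f"unmapped_seeds_{tag}.txt").write_text(
                "".join(f"{s}\n" for s in sorted(dn.unmapped_seeds))
            )
            manifest.counts[f"network_nodes_{g}"] = len(dn.nodes)
            manifest.counts[f"network_edges_{g}"] = len(dn.edges)

        stage = "overlap"
        overlap_nodes: set[str] = set()
        if len(net_groups) == 2:
            a, b = net_groups
            overlap_nodes, overlap_edges = net.overlap_network(networks[a], networks[b])
            (out / "overlap_nodes.txt").write_text(
                "".join(f"{x}\n" for x in sorted(overlap_nodes))
            )
            with open(out / "overlap_edges.tsv", "w") as fh:
                fh.write("node_a\tnode_b\n")
                for x, y in sorted(overlap_edges):
                    fh.write(f"{x}\t{y}\n")
            manifest.counts["overlap_nodes"] = len(overlap_nodes)
            manifest.counts["overlap_edges"] = len(overlap_edges)

        stage = "enrichment"
        if config.universe == "interactome":
            universe = sorted(interactome.nodes)
        else:
            universe = sorted({s for s in ann.mapping.values() if s})
        collection = iof.GeneSetCollection()
        for path in config.gene_sets:
            for gs in iof.read_gene_sets(path):
                collection.add(gs)
        queries = {f"network_{g}": sorted(networks[g].nodes) for g in networks}
        if overlap_nodes:
            queries["overlap"] = sorted(overlap_nodes)
        for name, query in queries.items():
            results = enr.enrich(
                query, collection, universe, fdr=config.fdr,
                min_set_size=config.min_set_size, max_set_size=config.max_set_size,
            )
            _write_enrichment(results, out / f"enrichment_{_safe(name)}.tsv")
            manifest.counts[f"enrichment_tested_{name}"] = len(results)
            manifest.counts[f"enrichment_significant_{name}"] = sum(
                r.significant for r in results
            )

        if config.ct_table:
            stage = "qpcr_ddct"
            ct = iof.read_ct_table(config.ct_table, config.reference_genes)
            control = config.control_group or next(iter(ct.groups.values()))
            rel = qpcr.ddct_relative_expression(ct, control)
            rel.data.to_csv(out / "qpcr_relative_expression.tsv", sep="\t",
                            index_label="gene", float_format="%.10g")
            manifest.counts["qpcr_genes"] = rel.data.shape[0]

            stage = "qpcr_rank_product"
            if config.qpcr_contrast:
                ga, gb = config.qpcr_contrast
            else:
                labels = [g for g in dict.fromkeys(ct.groups.values())]
                ga, gb = labels[0], labels[1]
            rp = qpcr.rank_product_test(rel, ga, gb, n_perm=config.n_perm,
                                        seed=config.seed)
            rp.table.to_csv(out / "qpcr_rank_product.tsv", sep="\t",
                            float_format="%.10g")
            manifest.counts["qpcr_comparisons"] = rp.n_comparisons
    except Exception as exc:  # record the failing stage, then re-raise
        finish("failed", stage)
        raise PipelineError(stage, exc) from exc

    finish("ok")
    return manifest
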