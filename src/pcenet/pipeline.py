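"""End-to-end orchestration: ingest -> modules -> gate -> hubs -> enrichment
-> multivariate correlation -> regulator calls, driven by one config.

Every stage is deterministic given the config (the only randomness is the
synthetic-data seed), so re-running a config reproduces result tables
byte-for-byte. Structured log lines record the counts at every filter so a
run narrative (N proteins -> M modules -> K significant) can be
reconstructed from the log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, enrichment, hubs, mva, regulators, wgcna
from .io import (
    read_edge_list,
    read_expression,
    read_gene_sets,
    read_traits,
    write_table,
)
from .simulate import SyntheticConfig, generate_dataset

logger = logging.getLogger("pcenet")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All run parameters for the full analysis.

    Either ``counts``/``traits`` paths or a ``simulate`` block must be
    given. Defaults follow the published analysis: soft power 25, minimum
    module size 15, deep-split 4, significance gate |r| > 0.5 with BH
    q < 0.05, top-20 hubs, enrichment p < 0.05, regulator overlap
    p < 0.005.
    """

    out_dir: str = "pcenet_out"
    counts: str | None = None
    traits: str | None = None
    edges: str | None = None
    gene_sets: str | None = None
    causal_network: str | None = None
    simulate: dict | None = None  # SyntheticConfig fields
    transform: str = "log2p1"
    power: int = 25
    auto_power: bool = False
    signed: bool = False
    min_module_size: int = 15
    deep_split: int = 4
    r_min: float = 0.5
    q_max: float = 0.05
    hub_k: int = 20
    enrich_p_max: float = 0.05
    regulator_p_max: float = 0.005
    mva_n_clusters: int = 5
    min_edge_confidence: float = 0.400
    merge_cut_height: float | None = None  # optional eigenprotein merge, off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deep_split not in wgcna.DEEP_SPLIT_CUT_FRACTION:
            raise ValueError("deep_split must be in 0..4")
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not (self.counts and self.traits) and self.simulate is None:
            raise ValueError("provide counts+traits paths or a simulate block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All result tables of one run plus metadata sufficient to re-run."""

    partition: wgcna.ModulePartition
    eigenproteins: wgcna.EigenproteinSet
    module_membership: pd.DataFrame
    module_trait: pd.DataFrame
    significant_modules: list[int]
    hub_tables: dict[int, pd.DataFrame] = field(default_factory=dict)
    enrichment_tables: dict[int, pd.DataFrame] = field(default_factory=dict)
    key_proteins: list[str] = field(default_factory=list)
    mva_clustering: mva.CorrelationClustering | None = None
    regulator_calls: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the cause."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage in order and write the report bundle.

    Stage errors abort the run after writing a FAILED marker naming the
    stage; identical configs produce byte-identical result tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        bundle = _run_stages(config, out)
    except StageError as exc:
        (out / "FAILED").write_text(str(exc) + "\n", encoding="utf-8")
        raise
    return bundle


def _run_stages(config: PipelineConfig, out: Path) -> ReportBundle:
    # ---- ingest / simulate -------------------------------------------------
    if config.counts:
        X = _stage("ingest")(read_expression)(config.counts, transform="none")
        traits = read_traits(config.traits).aligned_to(X)
        truth = None
    else:
        sim_cfg = SyntheticConfig(**{**(config.simulate or {}), "seed": config.seed})
        X, traits, truth = _stage("simulate")(generate_dataset)(sim_cfg)
    logger.info("stage=ingest proteins=%d samples=%d", X.n_proteins, X.n_samples)

    net = None
    if config.edges:
        net = _stage("read_edges")(read_edge_list)(
            config.edges, config.min_edge_confidence
        )
        logger.info("stage=read_edges kept_edges=%d", net.n_edges)
    annotations = None
    if config.gene_sets:
        annotations = _stage("read_gene_sets")(read_gene_sets)(config.gene_sets)
    causal = None
    if config.causal_network:
        causal = _stage("read_causal")(regulators.CausalNetwork.from_tsv)(
            config.causal_network
        )

    # ---- co-expression network + modules -----------------------------------
    Xt = X.log2p1() if config.transform == "log2p1" else X

    def _wgcna():
        S = wgcna.correlation_matrix(Xt)
        if config.auto_power:
            power, _fits = wgcna.pick_soft_power(S)
        else:
            power = config.power
        A = wgcna.adjacency(S, power, signed=config.signed)
        T = wgcna.tom_similarity(A)
        dend = wgcna.cluster_dendrogram(T.dissimilarity, T.protein_ids)
        part = wgcna.dynamic_tree_cut(
            dend, config.min_module_size, config.deep_split
        )
        return power, part

    power_used, partition = _stage("wgcna")(_wgcna)()
    logger.info(
        "stage=wgcna power=%d modules=%d unassigned=%d",
        power_used,
        len(partition.module_ids),
        int((partition.labels == 0).sum()),
    )

    E = _stage("eigenproteins")(wgcna.eigenproteins)(Xt, partition)
    kme = _stage("module_membership")(wgcna.module_membership)(Xt, E)
    mt = _stage("module_trait")(wgcna.module_trait_association)(
        E, traits, config.r_min, config.q_max
    )
    significant = sorted(set(mt.loc[mt["significant"], "module"].astype(int)))
    logger.info("stage=gate significant_modules=%s", significant)

    # ---- hubs on significant modules ---------------------------------------
    hub_tables: dict[int, pd.DataFrame] = {}
    if net is not None:
        for m in significant:
            g = hubs.build_module_network(partition, net, m)
            hub_tables[m] = hubs.top_hubs(hubs.mcc_scores(g), config.hub_k)

    # ---- enrichment ---------------------------------------------------------
    enrich_tables: dict[int, pd.DataFrame] = {}
    if annotations is not None:
        for m in significant:
            query = set(partition.members(m)) & set(annotations.background)
            if query:
                enrich_tables[m] = enrichment.enrich(
                    query, annotations, config.enrich_p_max
                )

    # ---- multivariate correlation of key proteins ---------------------------
    # key set: the top-kME member of each significant module (the module's
    # representative protein) plus its top-k hubs, de-duplicated
    key: set[str] = set()
    for m in significant:
        members = partition.members(m)
        key.add(kme.loc[members, m].idxmax())
        if m in hub_tables and len(hub_tables[m]):
            key |= set(hub_tables[m]["protein"])
    key_proteins = sorted(key)
    clustering = None
    if key_proteins:
        Xq = _stage("quantile_normalize")(mva.quantile_normalize)(X)
        n_clusters = min(config.mva_n_clusters, len(key_proteins))
        clustering = _stage("mva")(mva.correlation_cluster)(
            Xq.log2p1(), key_proteins, n_clusters=n_clusters
        )
    logger.info("stage=mva key_proteins=%d", len(key_proteins))

    # ---- regulator calls -----------------------------------------------------
    calls = None
    if causal is not None:
        trait = traits.usable_traits()[0]
        Xq = mva.quantile_normalize(X)
        calls = _stage("regulators")(regulators.call_regulators)(
            causal, Xq, traits, trait, p_max=config.regulator_p_max
        )
        logger.info(
            "stage=regulators called=%d",
            int((calls["state"] != "none").sum()) if len(calls) else 0,
        )

    bundle = ReportBundle(
        partition=partition,
        eigenproteins=E,
        module_membership=kme,
        module_trait=mt,
        significant_modules=significant,
        hub_tables=hub_tables,
        enrichment_tables=enrich_tables,
        key_proteins=key_proteins,
        mva_clustering=clustering,
        regulator_calls=calls,
        metadata={
            "version": __version__,
            "config_hash": config.config_hash(),
            "power_used": int(power_used),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "n_proteins": X.n_proteins,
            "n_samples": X.n_samples,
            "n_modules": len(partition.module_ids),
            "significant_modules": significant,
        },
    )
    if truth is not None:
        bundle.metadata["planted_trait_modules"] = sorted(
            truth.trait_module_ids
        )
    _stage("write")(_write_bundle)(bundle, out, config)
    return bundle


def _write_bundle(bundle: ReportBundle, out: Path, config: PipelineConfig) -> None:
    part = bundle.partition.labels.rename("module").rename_axis("protein")
    write_table(part.reset_index(), out / "module_partition.tsv")
    ep = bundle.eigenproteins.profiles.rename_axis("sample")
    ep.columns = [f"M{m}" for m in ep.columns]
    write_table(ep.reset_index(), out / "eigenproteins.tsv")
    kme = bundle.module_membership.rename_axis("protein")
    kme.columns = [f"M{m}" for m in kme.columns]
    write_table(kme.reset_index(), out / "module_membership.tsv")
    write_table(bundle.module_trait, out / "module_trait.tsv")
    for m, t in bundle.hub_tables.items():
        write_table(t, out / f"hubs_M{m}.tsv")
    for m, t in bundle.enrichment_tables.items():
        write_table(t, out / f"enrichment_M{m}.tsv")
    if bundle.mva_clustering is not None:
        labels = bundle.mva_clustering.labels.rename_axis("protein").reset_index()
        write_table(labels, out / "mva_clusters.tsv")
    if bundle.regulator_calls is not None:
        write_table(bundle.regulator_calls, out / "regulator_calls.tsv")
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.metadata, fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config_used.yaml")
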