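"""Synthetic scenarios with planted ground truth for pipeline validation.

Real inputs to the pipeline are a curated PPI background, two DEG
contrasts, and the implicit fact that disease genes cluster in the
network.  This module emulates all three so every stage is testable
without external downloads:

* a connected scale-free network (preferential attachment), with
  synthetic Entrez-style numeric node ids;
* a planted disease module drawn as a connected neighbourhood
  (breadth-first from a random root) — network proximity, which RWR
  measures, then carries signal beyond raw set overlap, as it does for
  real disease genes;
* drug seed sets sharing a controllable fraction of the disease module;
* DE tables in which planted genes carry large |log2FC| and small
  p-values against a null background, so top-k selection approximately
  recovers the planted sets.

One master seed derives every sub-seed (network, planting, DE noise,
permutations) through ``numpy.random.SeedSequence``, so a scenario is a
pure function of its configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .deg import DEGRecord, DEGTable, filter_degs, rank_and_select, write_de_table
from .exceptions import ConfigurationError, InputDataError
from .ppi import Network, write_alias_map, write_string_links
from .relevance import assess_drug
from .rwr import RWRConfig, build_transition

logger = logging.getLogger(__name__)

#: taxon-style prefix for synthetic protein ids in STRING-dialect exports
SYNTHETIC_TAXON = "99999"
#: confidence score attached to synthetic edges (above any common cutoff)
SYNTHETIC_SCORE = 900


def _subseed(master: int, *tags: int) -> int:
    """Deterministic 31-bit sub-seed derived from the master seed."""
    return int(np.random.SeedSequence([master, *tags]).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one planted drug/disease scenario.

    ``overlap_fraction`` controls how many drug seeds are shared with the
    disease module: round(overlap_fraction * n_drug) seeds are drawn from
    the disease module, the rest uniformly from non-disease nodes.
    """

    n_nodes: int = 1000
    attachment_m: int = 3
    n_disease: int = 50
    n_drug: int = 50
    overlap_fraction: float = 0.5
    effect_lfc: float = 2.0
    null_lfc_sd: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes <= self.attachment_m or self.attachment_m < 1:
            raise ConfigurationError(
                f"need n_nodes > attachment_m >= 1, got "
                f"{self.n_nodes}, {self.attachment_m}"
            )
        if self.n_disease + self.n_drug > self.n_nodes:
            raise ConfigurationError("n_disease + n_drug exceeds n_nodes")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ConfigurationError("overlap_fraction must be in [0, 1]")

    @property
    def n_shared(self) -> int:
        return int(round(self.overlap_fraction * self.n_drug))


@dataclass
class PlantedScenario:
    """A fully materialized scenario with its ground truth."""

    config: ScenarioConfig
    network: Network
    disease_seeds: list[str]
    drug_seeds: list[str]
    de_table_disease: DEGTable
    de_table_drug: DEGTable

    @property
    def truth(self) -> dict:
        return {
            "disease_seeds": sorted(self.disease_seeds),
            "drug_seeds": sorted(self.drug_seeds),
            "n_shared": len(set(self.disease_seeds) & set(self.drug_seeds)),
        }


def _node_id(i: int) -> str:
    # fixed-width numeric ids: lexicographic order == numeric order
    return str(100000 + i)


def generate_network(n_nodes: int, attachment_m: int, rng_seed: int) -> Network:
    """Connected scale-free network by preferential attachment.

    Node ids are synthetic Entrez-style numeric strings of equal width so
    the canonical (lexicographic) ordering is stable.
    """
    if n_nodes <= attachment_m or attachment_m < 1:
        raise ConfigurationError(
            f"need n_nodes > attachment_m >= 1, got {n_nodes}, {attachment_m}"
        )
    g = nx.barabasi_albert_graph(n_nodes, attachment_m, seed=rng_seed)
    g = nx.relabel_nodes(g, {i: _node_id(i) for i in g.nodes})
    nx.set_edge_attributes(g, SYNTHETIC_SCORE, "score")
    return Network(g)


def plant_seed_sets(
    network: Network,
    n_disease: int,
    n_drug: int,
    overlap_fraction: float,
    rng_seed: int,
) -> tuple[list[str], list[str]]:
    """Plant a disease module and a partially overlapping drug seed set.

    The disease module is a connected neighbourhood grown breadth-first
    from a random root (neighbours visited in random order).  Drug seeds
    are round(overlap_fraction * n_drug) nodes sampled from the disease
    module plus the remainder sampled uniformly from non-disease nodes.
    """
    n = network.n_nodes
    if n_disease < 1 or n_drug < 1 or n_disease + n_drug > n:
        raise InputDataError(
            f"infeasible seed sizes: n_disease={n_disease}, n_drug={n_drug}, "
            f"network has {n} nodes"
        )
    n_shared = int(round(overlap_fraction * n_drug))
    if n_shared > n_disease:
        raise InputDataError(
            f"overlap requires {n_shared} shared seeds but the disease "
            f"module has only {n_disease}"
        )
    if n_drug - n_shared > n - n_disease:
        raise InputDataError("not enough non-disease nodes for the drug set")

    rng = np.random.default_rng(rng_seed)
    nodes = list(network.node_order)
    root = nodes[rng.integers(len(nodes))]

    # breadth-first growth with randomized neighbour order
    disease: list[str] = [root]
    member = {root}
    frontier = [root]
    while len(disease) < n_disease:
        if not frontier:  # cannot happen on a connected network with
            raise InputDataError("disease module exhausted the component")
        nxt: list[str] = []
        for node in frontier:
            nbrs = [v for v in network.graph.neighbors(node) if v not in member]
            rng.shuffle(nbrs)
            for v in nbrs:
                if v in member:
                    continue
                disease.append(v)
                member.add(v)
                nxt.append(v)
                if len(disease) == n_disease:
                    break
            if len(disease) == n_disease:
                break
        frontier = nxt

    shared = list(rng.choice(disease, size=n_shared, replace=False)) if n_shared else []
    outside = [v for v in nodes if v not in member]
    extra = (
        list(rng.choice(outside, size=n_drug - n_shared, replace=False))
        if n_drug - n_shared
        else []
    )
    drug = [str(v) for v in shared + extra]
    return disease, drug


def generate_de_table(
    network: Network,
    affected_genes: Sequence[str],
    effect_lfc: float = 2.0,
    null_lfc_sd: float = 0.2,
    rng_seed: int = 0,
    contrast_label: str = "synthetic",
) -> DEGTable:
    """DE table over all network genes with planted effects.

    Affected genes get ``log2fc = ±(effect_lfc + |N(0, null_lfc_sd)|)``
    (random sign) and ``p ~ U(0, 0.01)``; background genes get
    ``log2fc ~ N(0, null_lfc_sd)`` and ``p ~ U(0, 1)``.
    """
    affected = set(affected_genes)
    if not affected <= set(network.node_order):
        raise InputDataError("affected_genes must be a subset of network nodes")
    rng = np.random.default_rng(rng_seed)
    records = []
    for g in network.node_order:
        if g in affected:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc = sign * (effect_lfc + abs(rng.normal(0.0, null_lfc_sd)))
            p = rng.uniform(0.0, 0.01)
        else:
            lfc = rng.normal(0.0, null_lfc_sd)
            p = rng.uniform(0.0, 1.0)
        records.append(DEGRecord(g, float(lfc), float(p)))
    return DEGTable(records, contrast_label)


def build_scenario(config: ScenarioConfig) -> PlantedScenario:
    """Materialize a scenario from its configuration (pure function)."""
    net = generate_network(
        config.n_nodes, config.attachment_m, _subseed(config.rng_seed, 0)
    )
    disease, drug = plant_seed_sets(
        net,
        config.n_disease,
        config.n_drug,
        config.overlap_fraction,
        _subseed(config.rng_seed, 1),
    )
    de_disease = generate_de_table(
        net,
        disease,
        config.effect_lfc,
        config.null_lfc_sd,
        _subseed(config.rng_seed, 2),
        "disease-vs-normal",
    )
    de_drug = generate_de_table(
        net,
        drug,
        config.effect_lfc,
        config.null_lfc_sd,
        _subseed(config.rng_seed, 3),
        "drug-vs-disease",
    )
    return PlantedScenario(config, net, disease, drug, de_disease, de_drug)


def write_scenario(scenario: PlantedScenario, out_dir: str | Path) -> dict[str, Path]:
    """Write a scenario as pipeline-readable text files.

    Emits a STRING-dialect edge list (synthetic taxon prefix), an
    identity alias map, both DE tables, and a truth JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = f"{SYNTHETIC_TAXON}."
    edges = {
        (f"{prefix}{a}", f"{prefix}{b}"): (
            SYNTHETIC_SCORE if s is None else s
        )
        for (a, b), s in scenario.network.edge_dict().items()
    }
    paths = {
        "links": out / "network.links.txt",
        "aliases": out / "aliases.tsv",
        "de_disease": out / "de_disease.tsv",
        "de_drug": out / "de_drug.tsv",
        "truth": out / "truth.json",
    }
    write_string_links(edges, paths["links"])
    write_alias_map(
        {f"{prefix}{g}": g for g in scenario.network.node_order}, paths["aliases"]
    )
    write_de_table(scenario.de_table_disease, paths["de_disease"])
    write_de_table(scenario.de_table_drug, paths["de_drug"])
    truth = dict(scenario.truth)
    truth["config"] = {
        k: getattr(scenario.config, k)
        for k in (
            "n_nodes",
            "attachment_m",
            "n_disease",
            "n_drug",
            "overlap_fraction",
            "effect_lfc",
            "null_lfc_sd",
            "rng_seed",
        )
    }
    paths["truth"].write_text(json.dumps(truth, sort_keys=True, indent=2) + "\n")
    return paths


def _assess_scenario(
    scenario: PlantedScenario,
    rwr_config: RWRConfig,
    n_perm: int,
    rng_seed: int,
    transition=None,
):
    """Full pipeline on a scenario: DEG selection from both tables, then
    the drug-vs-disease assessment."""
    cfg = scenario.config
    drug_list = rank_and_select(filter_degs(scenario.de_table_drug), k=cfg.n_drug)
    disease_list = rank_and_select(
        filter_degs(scenario.de_table_disease), k=cfg.n_disease
    )
    return assess_drug(
        drug_list,
        disease_list,
        scenario.network,
        rwr_config=rwr_config,
        n_perm=n_perm,
        rng_seed=rng_seed,
        transition=transition,
    )


def calibration_experiment(
    overlap_fractions: Sequence[float] = (0.0, 0.25, 0.5, 1.0),
    n_replicates: int = 20,
    base_config: ScenarioConfig = ScenarioConfig(),
    rwr_config: RWRConfig = RWRConfig(),
    n_perm: int = 100,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Run the full pipeline across an overlap grid on one fixed network.

    The network is generated once from ``base_config``; each replicate
    replants seed sets and DE noise, runs the complete assessment, and
    records the relevance and Z-score.  Returns a tidy table with one
    row per (overlap_fraction, replicate).
    """
    net = generate_network(
        base_config.n_nodes, base_config.attachment_m, _subseed(master_seed, 0)
    )
    transition = build_transition(net)
    rows = []
    for fi, frac in enumerate(overlap_fractions):
        for rep in range(n_replicates):
            seed = _subseed(master_seed, 1, fi, rep)
            disease, drug = plant_seed_sets(
                net,
                base_config.n_disease,
                base_config.n_drug,
                frac,
                _subseed(seed, 0),
            )
            de_disease = generate_de_table(
                net,
                disease,
                base_config.effect_lfc,
                base_config.null_lfc_sd,
                _subseed(seed, 1),
                "disease-vs-normal",
            )
            de_drug = generate_de_table(
                net,
                drug,
                base_config.effect_lfc,
                base_config.null_lfc_sd,
                _subseed(seed, 2),
                "drug-vs-disease",
            )
            scenario = PlantedScenario(
                ScenarioConfig(
                    n_nodes=base_config.n_nodes,
                    attachment_m=base_config.attachment_m,
                    n_disease=base_config.n_disease,
                    n_drug=base_config.n_drug,
                    overlap_fraction=frac,
                    effect_lfc=base_config.effect_lfc,
                    null_lfc_sd=base_config.null_lfc_sd,
                    rng_seed=seed,
                ),
                net,
                disease,
                drug,
                de_disease,
                de_drug,
            )
            report = _assess_scenario(
                scenario, rwr_config, n_perm, _subseed(seed, 3), transition
            )
            rows.append(
                {
                    "overlap_fraction": frac,
                    "replicate": rep,
                    "relevance": report.relevance,
                    "z": report.z_score,
                    "significant": report.significant,
                }
            )
    return pd.DataFrame(rows)


def summarize_calibration(table: pd.DataFrame) -> pd.DataFrame:
    """Per-overlap mean Z and fraction of significant calls."""
    return (
        table.groupby("overlap_fraction")
        .agg(
            mean_relevance=("relevance", "mean"),
            mean_z=("z", "mean"),
            frac_significant=("significant", "mean"),
            n=("z", "size"),
        )
        .reset_index()
    )


def write_calibration(table: pd.DataFrame, path: str | Path) -> None:
    """Tidy TSV with deterministic float formatting."""
    path = Path(path)
    cols = ["overlap_fraction", "replicate", "relevance", "z", "significant"]
    lines = ["\t".join(cols)]
    for row in table.itertuples(index=False):
        lines.append(
            f"{float(row.overlap_fraction)!r}\t{int(row.replicate)}"
            f"\t{float(row.relevance)!r}\t{float(row.z)!r}\t{bool(row.significant)}"
        )
    path.write_text("\n".join(lines) + "\n")


def type_one_error_experiment(
    n_nodes: int = 500,
    attachment_m: int = 3,
    n_disease: int = 50,
    n_drug: int = 50,
    n_trials: int = 200,
    n_perm: int = 100,
    rwr_config: RWRConfig = RWRConfig(),
    master_seed: int = 0,
) -> pd.DataFrame:
    """False-positive calibration under a true null.

    One fixed network and one fixed planted disease module; each trial
    draws the "drug" seed set uniformly at random from all network nodes
    (the same process that generates the permutation null) and runs the
    assessment.  The fraction of trials with Z > 3 estimates the
    procedure's type-I error at the conventional cutoff.
    """
    from .relevance import assess_seed_sets

    net = generate_network(n_nodes, attachment_m, _subseed(master_seed, 0))
    transition = build_transition(net)
    disease, _ = plant_seed_sets(net, n_disease, 1, 0.0, _subseed(master_seed, 1))
    nodes = list(net.node_order)
    rows = []
    for trial in range(n_trials):
        rng = np.random.default_rng([_subseed(master_seed, 2), trial])
        drug = [str(g) for g in rng.choice(nodes, size=n_drug, replace=False)]
        report = assess_seed_sets(
            drug,
            disease,
            net,
            rwr_config=rwr_config,
            n_perm=n_perm,
            rng_seed=_subseed(master_seed, 3, trial),
            transition=transition,
        )
        rows.append(
            {
                "trial": trial,
                "relevance": report.relevance,
                "z": report.z_score,
                "significant": report.significant,
            }
        )
    return pd.DataFrame(rows)
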