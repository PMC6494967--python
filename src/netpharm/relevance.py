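"""Relevance statistic, permutation null, and the drug-effect Z-score.

The drug's and the disease's seed sets each induce an RWR score field
over the whole background network.  Their agreement is the

    Relevance = cor(Scores_drug, Scores_disease)

(Pearson, over all network nodes).  Significance comes from a
permutation null: gene sets of the same size as the drug's mapped seeds
are drawn uniformly at random (without replacement, no degree matching)
from the network, scored with identical RWR settings, and correlated
with the disease field; 100 repetitions by default.  With null mean mu
and standard deviation sigma,

    Z = |Relevance - mu| / sigma

and Z > 3 is called significant.  sigma uses the population (n)
denominator; with 100 repetitions the n vs n-1 choice moves Z by under
1%, and the convention is echoed in every report.

A single integer seed governs the whole assessment.  Each repetition
draws from its own deterministic substream keyed by (seed, repetition),
so enlarging ``n_perm`` extends the sample without reshuffling earlier
draws.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .deg import RankedGeneList
from .exceptions import DegenerateNullError, InputDataError, NetpharmError
from .ppi import Network, restrict_seeds
from .rwr import (
    RWRConfig,
    ScoreVector,
    _power_iterate,
    build_transition,
    run_rwr,
    seed_distribution,
)

logger = logging.getLogger(__name__)

Z_THRESHOLD = 3.0
DEFAULT_N_PERM = 100
#: numerical floor below which a null's spread counts as degenerate
SIGMA_FLOOR = 1e-12


def relevance(
    scores_drug: ScoreVector,
    scores_disease: ScoreVector,
    exclude_indices: Sequence[int] | None = None,
) -> float:
    """Pearson correlation of two score fields over all network nodes.

    ``exclude_indices`` optionally drops positions (e.g. the seed nodes
    themselves) before correlating; by default every node counts.
    """
    if scores_drug.nodes != scores_disease.nodes:
        raise InputDataError("score vectors are on different node orderings")
    x, y = scores_drug.values, scores_disease.values
    if exclude_indices is not None and len(exclude_indices) > 0:
        mask = np.ones(len(x), dtype=bool)
        mask[np.asarray(exclude_indices, dtype=int)] = False
        x, y = x[mask], y[mask]
    return _pearson(x, y)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        raise InputDataError("constant score field: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class NullDistribution:
    """Empirical relevance distribution from random size-matched seed sets."""

    samples: list[float]
    mu: float
    sigma: float
    n_perm: int
    rng_seed: int
    n_random_genes: int

    @classmethod
    def from_samples(
        cls, samples: np.ndarray, rng_seed: int, n_random_genes: int
    ) -> "NullDistribution":
        samples = np.asarray(samples, dtype=float)
        return cls(
            samples=[float(s) for s in samples],
            mu=float(samples.mean()),
            sigma=float(samples.std(ddof=0)),  # population denominator
            n_perm=len(samples),
            rng_seed=rng_seed,
            n_random_genes=n_random_genes,
        )


def sample_null(
    network: Network,
    scores_disease: ScoreVector,
    n_random_genes: int,
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int = 0,
    rwr_config: RWRConfig = RWRConfig(),
    transition: sp.csr_array | None = None,
    exclude_indices: Sequence[int] | None = None,
) -> NullDistribution:
    """Relevance null from uniformly random seed sets of fixed size.

    Each repetition draws ``n_random_genes`` nodes without replacement,
    uniformly over the network (size matching only, no degree matching),
    seeds an RWR with the same configuration as the observed run, and
    records the Pearson correlation with the disease score field.
    """
    n = network.n_nodes
    if not (1 <= n_random_genes <= n):
        raise InputDataError(
            f"n_random_genes must be in [1, {n}], got {n_random_genes}"
        )
    if transition is None:
        transition = build_transition(network)

    # all repetitions propagate together: columns are independent walks
    e = np.zeros((n, n_perm))
    for rep in range(n_perm):
        rng = np.random.default_rng([rng_seed, rep])
        idx = rng.choice(n, size=n_random_genes, replace=False)
        e[idx, rep] = 1.0 / n_random_genes
    scores, _ = _power_iterate(
        transition, e, rwr_config.restart_prob, rwr_config.tol, rwr_config.max_iter
    )

    y = scores_disease.values
    if exclude_indices is not None and len(exclude_indices) > 0:
        mask = np.ones(n, dtype=bool)
        mask[np.asarray(exclude_indices, dtype=int)] = False
        scores, y = scores[mask], y[mask]
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    xc = scores - scores.mean(axis=0)
    x_ss = (xc * xc).sum(axis=0)
    if y_ss == 0 or (x_ss == 0).any():
        samples = np.full(n_perm, np.nan)
        if y_ss > 0:
            ok = x_ss > 0
            samples[ok] = (xc[:, ok].T @ yc) / np.sqrt(x_ss[ok] * y_ss)
        if np.isnan(samples).all():
            raise InputDataError("constant score field in every repetition")
        samples = np.nan_to_num(samples, nan=0.0)
    else:
        samples = (xc.T @ yc) / np.sqrt(x_ss * y_ss)

    null = NullDistribution.from_samples(samples, rng_seed, n_random_genes)
    if null.sigma <= SIGMA_FLOOR:
        logger.warning(
            "degenerate null: all %d permutation samples identical", n_perm
        )
    return null


def z_score(relevance_value: float, null: NullDistribution) -> float:
    """Absolute deviation of the observed relevance from the null mean,
    in units of the null standard deviation."""
    if null.sigma <= SIGMA_FLOOR:
        raise DegenerateNullError(
            "degenerate null: sigma = 0, Z-score undefined"
        )
    return abs(relevance_value - null.mu) / null.sigma


@dataclass
class DrugEffectReport:
    """Machine-readable result of one drug-vs-disease assessment."""

    drug_label: str
    disease_label: str
    overlap_drug: int
    overlap_disease: int
    relevance: float
    null: NullDistribution
    z_score: float
    significant: bool
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "drug_label": self.drug_label,
            "disease_label": self.disease_label,
            "overlap_drug": self.overlap_drug,
            "overlap_disease": self.overlap_disease,
            "relevance": self.relevance,
            "z_score": self.z_score,
            "significant": self.significant,
            "null": {
                "mu": self.null.mu,
                "sigma": self.null.sigma,
                "n_perm": self.null.n_perm,
                "rng_seed": self.null.rng_seed,
                "n_random_genes": self.null.n_random_genes,
                "samples": self.null.samples,
            },
            "config": self.config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    def to_table(self) -> str:
        """One-row TSV with the headline columns (drug, overlap,
        relevance, Z-score, significance call)."""
        header = "Drug\tOverlap\tRelevance\tZ-score\tSignificant"
        row = (
            f"{self.drug_label}\t{self.overlap_drug}\t{self.relevance!r}"
            f"\t{self.z_score!r}\t{self.significant}"
        )
        return header + "\n" + row + "\n"

    def write_table(self, path: str | Path) -> None:
        Path(path).write_text(self.to_table())


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, NetpharmError):
                raise type(exc)(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def assess_seed_sets(
    drug_genes: Sequence[str],
    disease_genes: Sequence[str],
    network: Network,
    rwr_config: RWRConfig = RWRConfig(),
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int = 0,
    drug_label: str = "drug",
    disease_label: str = "disease",
    exclude_seeds: bool = False,
    config_echo: dict | None = None,
    transition: sp.csr_array | None = None,
) -> DrugEffectReport:
    """Assess a drug gene list against a disease gene list.

    Runs seed restriction, RWR for both seed sets, the relevance
    statistic, the size-matched permutation null (matching the drug
    overlap), and the Z-score.  Any stage failure aborts with the stage
    name in the message.
    """
    with _stage("restrict_seeds"):
        drug_seeds = restrict_seeds(drug_genes, network, drug_label)
        disease_seeds = restrict_seeds(disease_genes, network, disease_label)
    if transition is None:
        with _stage("build_transition"):
            transition = build_transition(network)
    with _stage("rwr"):
        scores_drug = run_rwr(
            transition, seed_distribution(drug_seeds, network), rwr_config
        )
        scores_disease = run_rwr(
            transition, seed_distribution(disease_seeds, network), rwr_config
        )
    exclude = None
    if exclude_seeds:
        exclude = sorted(
            {network.index_of(g) for g in drug_seeds.mapped}
            | {network.index_of(g) for g in disease_seeds.mapped}
        )
    with _stage("relevance"):
        rel = relevance(scores_drug, scores_disease, exclude_indices=exclude)
    with _stage("sample_null"):
        null = sample_null(
            network,
            scores_disease,
            n_random_genes=drug_seeds.overlap,
            n_perm=n_perm,
            rng_seed=rng_seed,
            rwr_config=rwr_config,
            transition=transition,
            exclude_indices=exclude,
        )
    with _stage("z_score"):
        z = z_score(rel, null)

    config = {
        "restart_prob": rwr_config.restart_prob,
        "tol": rwr_config.tol,
        "max_iter": rwr_config.max_iter,
        "n_perm": n_perm,
        "rng_seed": rng_seed,
        "exclude_seeds": exclude_seeds,
        "sigma_denominator": "population (n)",
        "z_threshold": Z_THRESHOLD,
    }
    if config_echo:
        config.update(config_echo)
    return DrugEffectReport(
        drug_label=drug_label,
        disease_label=disease_label,
        overlap_drug=drug_seeds.overlap,
        overlap_disease=disease_seeds.overlap,
        relevance=rel,
        null=null,
        z_score=z,
        significant=z > Z_THRESHOLD,
        config=config,
    )


def assess_drug(
    drug_degs: RankedGeneList,
    disease_degs: RankedGeneList,
    network: Network,
    rwr_config: RWRConfig = RWRConfig(),
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int = 0,
    exclude_seeds: bool = False,
    config_echo: dict | None = None,
    transition: sp.csr_array | None = None,
) -> DrugEffectReport:
    """End-to-end assessment from two ranked top-k DEG lists."""
    echo = {
        "k_drug": drug_degs.k_requested,
        "k_disease": disease_degs.k_requested,
    }
    if config_echo:
        echo.update(config_echo)
    return assess_seed_sets(
        drug_degs.gene_ids,
        disease_degs.gene_ids,
        network,
        rwr_config=rwr_config,
        n_perm=n_perm,
        rng_seed=rng_seed,
        drug_label=drug_degs.contrast_label or "drug",
        disease_label=disease_degs.contrast_label or "disease",
        exclude_seeds=exclude_seeds,
        config_echo=echo,
        transition=transition,
    )
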