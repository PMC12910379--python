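"""Seeded generator of ground-truth multi-omics cohorts.

Emulates exactly the structure the factorization model assumes: non-negative
layered data X(d) = clip(W*(d)H* + noise, 0) scaled row-wise to [0, 1], with

  * sample group structure — each sample belongs to one of ``n_groups``
    groups; a group activates its own latent component (plus components
    shared by all groups), so H* columns cluster by group;
  * sparse non-negative W*(d) — every feature has one dominant latent
    component and mostly-zero side loadings;
  * a planted interaction network — a fraction ``network_fidelity`` of edges
    connect feature pairs (within and across layers) sharing a dominant
    component ("informative" edges); the rest are uniformly random;
  * binary labels derived from group membership and survival times drawn
    from an exponential hazard proportional to exp(λ*ᵀH*·,i) with fixed-
    quantile censoring.

The generator targets the model's assumed structure, not the marginal
distributions of any real cohort; see docs/methods.md for what that implies
about test conclusions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data_model import ClinicalTable, MultiOmicsDataset, OmicsLayer, read_clinical, read_edge_list, read_omics_matrix
from . import network as net

import pandas as pd

__all__ = ["SyntheticSpec", "SyntheticCohort", "generate", "write_fixture", "read_fixture"]


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults define the package's standard test cohort."""

    D: int = 2
    m: tuple[int, ...] = (60, 30)
    N: int = 80
    K_true: int = 4
    n_groups: int = 3
    noise_sd: float = 0.05
    sparsity: float = 0.8  # fraction of zero off-dominant entries in W*
    network_fidelity: float = 1.0  # fraction of edges among co-component pairs
    density: float = 0.05  # planted edge density per block
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.m) != self.D:
            raise ValueError("len(m) must equal D")
        if self.n_groups > self.K_true:
            raise ValueError("n_groups must be <= K_true")
        if not 0 <= self.network_fidelity <= 1:
            raise ValueError("network_fidelity must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticCohort:
    dataset: MultiOmicsDataset
    W_true: list[np.ndarray]
    H_true: np.ndarray
    network: net.BlockInteractionNetwork
    edges: dict[tuple[str, str], list[tuple[str, str]]]
    group_labels: np.ndarray
    lambda_true: np.ndarray
    clinical: ClinicalTable
    spec: SyntheticSpec
    dominant: list[np.ndarray] = field(default_factory=list)


def _sample_edges(
    rng: np.random.Generator,
    dom_p: np.ndarray,
    dom_q: np.ndarray,
    intra: bool,
    density: float,
    fidelity: float,
) -> list[tuple[int, int]]:
    """Pick block edges: ``fidelity`` fraction among co-dominant-component
    pairs, the rest uniform, all without replacement."""
    m_p, m_q = len(dom_p), len(dom_q)
    if intra:
        iu, ju = np.triu_indices(m_p, k=1)
        n_possible = len(iu)
        n_edges = int(round(density * n_possible))
    else:
        iu, ju = np.unravel_index(np.arange(m_p * m_q), (m_p, m_q))
        n_possible = m_p * m_q
        n_edges = int(round(density * n_possible))
    if n_edges > n_possible:
        raise ValueError("requested density exceeds the number of feature pairs")
    informative = np.flatnonzero(dom_p[iu] == dom_q[ju])
    other = np.flatnonzero(dom_p[iu] != dom_q[ju])
    n_info = min(int(round(fidelity * n_edges)), len(informative))
    n_rand = n_edges - n_info
    chosen = []
    if n_info:
        chosen.append(rng.choice(informative, size=n_info, replace=False))
    if n_rand:
        pool = other if len(other) >= n_rand else np.arange(n_possible)
        chosen.append(rng.choice(pool, size=n_rand, replace=False))
    idx = np.unique(np.concatenate(chosen)) if chosen else np.array([], dtype=int)
    return [(int(iu[i]), int(ju[i])) for i in idx]


def generate(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a full cohort (layers, truth, network, labels, survival)."""
    rng = np.random.default_rng(spec.seed)
    K, N = spec.K_true, spec.N

    # --- sample groups and H*: component g is specific to group g, the
    # remaining K - n_groups components are shared across all groups
    groups = rng.permutation(np.arange(N) % spec.n_groups)
    H = np.zeros((K, N))
    for i, g in enumerate(groups):
        H[g, i] = rng.gamma(shape=3.0, scale=1.0)
        for k in range(spec.n_groups, K):
            H[k, i] = rng.gamma(shape=2.0, scale=0.5)

    # --- W*(d): one dominant component per feature, sparse side loadings
    W_list, dominant = [], []
    for d in range(spec.D):
        m_d = spec.m[d]
        dom = rng.integers(0, K, size=m_d)
        # guarantee every component owns at least one feature per layer
        dom[:K] = np.arange(K) if m_d >= K else dom[:K]
        W = np.zeros((m_d, K))
        W[np.arange(m_d), dom] = rng.gamma(shape=3.0, scale=1.0, size=m_d) + 0.5
        side = rng.random((m_d, K)) >= spec.sparsity
        side[np.arange(m_d), dom] = False
        W[side] = rng.gamma(shape=1.5, scale=0.15, size=int(side.sum()))
        W_list.append(W)
        dominant.append(dom)

    # --- noisy layers, scaled row-wise (truth W* rescaled by the same factor
    # so that with noise_sd = 0 the identity X = W*H* is preserved exactly)
    layer_ids = [f"omic{d + 1}" for d in range(spec.D)]
    sample_ids = [f"S{i:04d}" for i in range(N)]
    layers = []
    for d in range(spec.D):
        clean = W_list[d] @ H
        X = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape) if spec.noise_sd > 0 else clean
        X = np.clip(X, 0.0, None)
        row_max = X.max(axis=1, keepdims=True)
        row_max[row_max == 0] = 1.0
        X = X / row_max
        W_list[d] = W_list[d] / row_max
        feature_ids = [f"{layer_ids[d]}_f{j:04d}" for j in range(spec.m[d])]
        layers.append(OmicsLayer(layer_ids[d], feature_ids, sample_ids, X))
    dataset = MultiOmicsDataset(layers)

    # --- planted network, assembled through the network module so the
    # cohort carries the exact Ã/L the solver will see
    edges: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for p in range(spec.D):
        for q in range(p, spec.D):
            pairs = _sample_edges(
                rng, dominant[p], dominant[q], intra=p == q,
                density=spec.density, fidelity=spec.network_fidelity,
            )
            edges[(layer_ids[p], layer_ids[q])] = [
                (layers[p].feature_ids[i], layers[q].feature_ids[j]) for i, j in pairs
            ]
    network = net.assemble(dataset, prior_blocks=edges)

    # --- labels and survival
    labels = (groups < (spec.n_groups + 1) // 2).astype(int)
    lam = np.zeros(K)
    lam[: spec.n_groups] = rng.normal(0.0, 1.0, size=spec.n_groups)
    Hz = (H - H.mean(axis=1, keepdims=True)) / (H.std(axis=1, keepdims=True) + 1e-12)
    rate = 0.1 * np.exp(lam @ Hz)
    times = rng.exponential(1.0 / rate)
    censor = np.quantile(times, 0.7)
    event = (times <= censor).astype(int)
    obs_time = np.minimum(times, censor)
    clinical = ClinicalTable(
        pd.DataFrame(
            {"label": labels, "time": obs_time, "event": event},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    return SyntheticCohort(
        dataset=dataset,
        W_true=W_list,
        H_true=H,
        network=network,
        edges=edges,
        group_labels=groups,
        lambda_true=lam,
        clinical=clinical,
        spec=spec,
        dominant=dominant,
    )


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort in the exact on-disk formats the CLI consumes,
    plus truth files (W*, H*, λ*, groups) for recovery scoring."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for layer in cohort.dataset.layers:
        p = directory / f"{layer.layer_id}.tsv"
        layer.to_frame().to_csv(p, sep="\t")
        paths[f"layer:{layer.layer_id}"] = p

    for (p_id, q_id), pairs in cohort.edges.items():
        p = directory / f"edges_{p_id}_{q_id}.tsv"
        with open(p, "w") as fh:
            for a, b in pairs:
                fh.write(f"{a}\t{b}\n")
        paths[f"edges:{p_id}:{q_id}"] = p

    p = directory / "clinical.tsv"
    cohort.clinical.data.to_csv(p, sep="\t")
    paths["clinical"] = p

    sample_ids = cohort.dataset.sample_ids
    pd.DataFrame(
        cohort.H_true,
        index=[f"k{k}" for k in range(cohort.H_true.shape[0])],
        columns=sample_ids,
    ).to_csv(directory / "H_true.tsv", sep="\t")
    for layer, W in zip(cohort.dataset.layers, cohort.W_true):
        pd.DataFrame(
            W, index=layer.feature_ids,
            columns=[f"k{k}" for k in range(W.shape[1])],
        ).to_csv(directory / f"W_true_{layer.layer_id}.tsv", sep="\t")
    pd.Series(cohort.lambda_true, index=[f"k{k}" for k in range(len(cohort.lambda_true))]).to_csv(
        directory / "lambda_true.tsv", sep="\t", header=["lambda"]
    )
    pd.Series(cohort.group_labels, index=sample_ids).to_csv(
        directory / "groups.tsv", sep="\t", header=["group"]
    )
    with open(directory / "spec.json", "w") as fh:
        json.dump(asdict(cohort.spec), fh, indent=2)
    paths["spec"] = directory / "spec.json"
    return paths


def read_fixture(directory: str | Path) -> tuple[MultiOmicsDataset, dict[tuple[str, str], list[tuple[str, str]]], ClinicalTable]:
    """Round-trip reader for a written fixture (layers, edge lists, clinical)."""
    directory = Path(directory)
    with open(directory / "spec.json") as fh:
        spec = json.load(fh)
    layer_ids = [f"omic{d + 1}" for d in range(spec["D"])]
    layers = [read_omics_matrix(directory / f"{lid}.tsv", lid) for lid in layer_ids]
    dataset = MultiOmicsDataset(layers)
    edges = {}
    for p in range(spec["D"]):
        for q in range(p, spec["D"]):
            key = (layer_ids[p], layer_ids[q])
            path = directory / f"edges_{key[0]}_{key[1]}.tsv"
            if path.exists():
                edges[key] = read_edge_list(path)
    clinical = read_clinical(directory / "clinical.tsv")
    return dataset, edges, clinical
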