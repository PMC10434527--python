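"""Synthetic questionnaire data from a known sparse partial-correlation truth.

The generator builds a ground-truth Gaussian graphical model with two
communities and a controllable set of cross-community (bridge) edges, draws
latent multivariate-normal respondents from it, and discretizes them to the
instruments' Likert ranges through fixed thresholds (a latent Gaussian
copula — the standard generative model under which correlation-based
network estimation of ordinal data is studied).

Construction of the truth: requested partial correlations are written into
a unit-diagonal precision matrix as K_ij = -rho_ij, positive definiteness
is enforced by diagonal inflation (smallest eigenvalue >= 0.05), and the
matrix is rescaled to unit partial variances.  With the moderate weights
used here the inflation step is usually a no-op, so realized bridge weights
sit within +/- 0.02 of their targets; infeasible weight sets raise.

Symptom nodes default to thresholds at the standard-normal quantiles of
cumulative proportions (0.55, 0.80, 0.93), skewing responses toward low
severity as non-clinical student samples show.  Personality nodes default
to quasi-continuous values on [1, 7] (real dimension scores are means of
two items), with a seven-level discretization available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .network import PartialCorrelationNetwork, precision_to_partial
from .scales import NODE_COMMUNITIES, NODE_IDS, NodeScoreTable

#: default cumulative category proportions for 0-3 symptom nodes
SYMPTOM_CUMPROBS: tuple[float, ...] = (0.55, 0.80, 0.93)

#: the six designated bridge edges of the paper-like truth (node-id pairs)
PAPER_LIKE_CROSS_EDGES: tuple[tuple[str, str, float], ...] = (
    ("EXT", "D4", -0.06),
    ("AGR", "D9", -0.06),
    ("CON", "A2", -0.05),
    ("NEU", "A3", 0.14),
    ("NEU", "A6", 0.11),
    ("OPE", "D6", -0.06),
)


@dataclass
class GroundTruthNetwork:
    """Known sparse precision/partial-correlation structure."""

    K_true: np.ndarray
    W_true: np.ndarray
    node_ids: tuple[str, ...]
    community: dict[str, str]
    cross_edges: tuple[tuple[int, int, float], ...]  # (i, j, target weight)

    @property
    def p(self) -> int:
        return self.K_true.shape[0]

    def to_network(self) -> PartialCorrelationNetwork:
        """Wrap the true weights as a network (e.g. for true-BEI readoff)."""
        return PartialCorrelationNetwork(
            W=self.W_true.copy(),
            node_ids=self.node_ids,
            community=dict(self.community),
            provenance={"source": "ground_truth"},
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "K_true": self.K_true.tolist(),
                "node_ids": list(self.node_ids),
                "community": self.community,
                "cross_edges": [list(e) for e in self.cross_edges],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "GroundTruthNetwork":
        d = json.loads(s)
        K = np.asarray(d["K_true"], dtype=float)
        return cls(
            K_true=K,
            W_true=precision_to_partial(K),
            node_ids=tuple(d["node_ids"]),
            community=dict(d["community"]),
            cross_edges=tuple((int(i), int(j), float(w)) for i, j, w in d["cross_edges"]),
        )


@dataclass
class SimulationConfig:
    """Respondent count, per-node discretization thresholds, and seed."""

    n: int
    seed: int
    thresholds: dict[str, tuple[float, ...]] = field(default_factory=dict)
    personality_range: tuple[float, float] = (1.0, 7.0)
    discretize_personality: bool = False

    def __post_init__(self) -> None:
        for nid, th in self.thresholds.items():
            t = np.asarray(th, dtype=float)
            if len(t) and np.any(np.diff(t) <= 0):
                raise ValidationError(f"thresholds for {nid!r} must be strictly increasing")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "seed": self.seed,
                "thresholds": {k: list(v) for k, v in self.thresholds.items()},
                "personality_range": list(self.personality_range),
                "discretize_personality": self.discretize_personality,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "SimulationConfig":
        d = json.loads(s)
        return cls(
            n=int(d["n"]),
            seed=int(d["seed"]),
            thresholds={k: tuple(v) for k, v in d["thresholds"].items()},
            personality_range=tuple(d["personality_range"]),
            discretize_personality=bool(d["discretize_personality"]),
        )


def make_ground_truth(
    p: int,
    communities: list[str] | tuple[str, ...],
    cross_edges: list[tuple[int, int, float]],
    intra_density: float = 0.25,
    seed: int = 0,
    node_ids: tuple[str, ...] | None = None,
    intra_weight_range: tuple[float, float] = (0.1, 0.3),
) -> GroundTruthNetwork:
    """Construct a sparse two-community precision matrix with set bridges.

    Intra-community edges are placed independently with probability
    ``intra_density`` and weights drawn uniformly (random sign) from
    ``intra_weight_range``; the listed ``cross_edges`` are placed exactly.
    Requested weights above 0.4 in magnitude are refused (positive
    definiteness would not be attainable reliably).
    """
    if p < 4:
        raise ValidationError("ground truth needs p >= 4 nodes")
    if len(communities) != p:
        raise ValidationError("communities must label all p nodes")
    for i, j, w in cross_edges:
        if abs(w) > 0.4:
            raise ValidationError(
                f"requested edge weight {w:g} exceeds 0.4; use smaller weights"
            )
        if communities[i] == communities[j]:
            raise ValidationError(f"edge ({i}, {j}) does not cross communities")
    rng = np.random.default_rng(seed)
    ids = node_ids if node_ids is not None else tuple(f"N{k}" for k in range(p))
    W0 = np.zeros((p, p))
    lo, hi = intra_weight_range
    for i in range(p):
        for j in range(i + 1, p):
            if communities[i] == communities[j] and rng.random() < intra_density:
                w = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
                W0[i, j] = W0[j, i] = w
    for i, j, w in cross_edges:
        W0[i, j] = W0[j, i] = w
    K = np.eye(p) - W0
    eig_min = float(np.linalg.eigvalsh(K).min())
    if eig_min < 0.05:
        K = K + (0.05 - eig_min) * np.eye(p)
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d)  # unit partial variances
    W_true = precision_to_partial(K)
    for i, j, w in cross_edges:
        if abs(W_true[i, j] - w) > 0.02:
            raise ValidationError(
                f"edge ({i}, {j}) realized at {W_true[i, j]:.3f}, target {w:g}; "
                "weight set infeasible — use smaller weights or lower density"
            )
    return GroundTruthNetwork(
        K_true=K,
        W_true=W_true,
        node_ids=ids,
        community={nid: c for nid, c in zip(ids, communities)},
        cross_edges=tuple((int(i), int(j), float(w)) for i, j, w in cross_edges),
    )


def default_symptom_thresholds() -> tuple[float, ...]:
    """Standard-normal quantiles of the default cumulative proportions."""
    return tuple(float(stats.norm.ppf(q)) for q in SYMPTOM_CUMPROBS)


def simulate_responses(
    truth: GroundTruthNetwork,
    cfg: SimulationConfig,
    mode: str = "likert",
    return_latent: bool = False,
) -> NodeScoreTable | tuple[NodeScoreTable, np.ndarray]:
    """Draw respondents from the truth and discretize to Likert ranges.

    ``mode="likert"`` discretizes symptom nodes to {0..3} through their
    thresholds and maps personality nodes onto [1, 7] (continuously by
    default, or through seven levels when the config requests it);
    ``mode="continuous"`` returns the standardized latent draws unchanged
    (used for recovery studies without discretization attenuation).
    With ``return_latent`` the latent matrix is also returned.
    """
    if mode not in ("likert", "continuous"):
        raise ValidationError(f"unknown simulation mode {mode!r}")
    rng = np.random.default_rng(cfg.seed)
    Sigma = np.linalg.inv(truth.K_true)
    d = np.sqrt(np.diag(Sigma))
    R = Sigma / np.outer(d, d)  # latent correlation matrix
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((cfg.n, truth.p)) @ L.T
    cols: dict[str, np.ndarray] = {}
    for k, nid in enumerate(truth.node_ids):
        z = Z[:, k]
        if mode == "continuous":
            cols[nid] = z
            continue
        if truth.community[nid] == "personality":
            lo, hi = cfg.personality_range
            if cfg.discretize_personality:
                th = stats.norm.ppf(np.arange(1, 7) / 7.0)
                cols[nid] = lo + np.searchsorted(th, z).astype(float)
            else:
                mid = 0.5 * (lo + hi)
                cols[nid] = np.clip(mid + z, lo, hi)
        else:
            th = np.asarray(
                cfg.thresholds.get(nid, default_symptom_thresholds()), dtype=float
            )
            if len(th) != 3:
                raise ValidationError(
                    f"symptom node {nid!r} needs 3 thresholds for a 0-3 range"
                )
            cols[nid] = np.searchsorted(th, z).astype(float)
    table = NodeScoreTable(
        values=pd.DataFrame(cols, columns=list(truth.node_ids)),
        community=dict(truth.community),
    )
    return (table, Z) if return_latent else table


def paper_like_config(n: int = 507, seed: int = 0) -> tuple[GroundTruthNetwork, SimulationConfig]:
    """Ground truth and simulation settings emulating the study layout.

    21 nodes (5 personality, 16 symptom) in two communities, about a
    quarter of intra-community pairs connected, and six designated bridge
    edges concentrated on the neuroticism analogue (the only node with a
    sizable positive true BEI).
    """
    ids = NODE_IDS
    communities = [NODE_COMMUNITIES[nid] for nid in ids]
    index = {nid: k for k, nid in enumerate(ids)}
    cross = [(index[a], index[b], w) for a, b, w in PAPER_LIKE_CROSS_EDGES]
    truth = make_ground_truth(
        p=len(ids),
        communities=communities,
        cross_edges=cross,
        intra_density=0.25,
        seed=seed,
        node_ids=ids,
    )
    cfg = SimulationConfig(
        n=n,
        seed=seed + 1,
        thresholds={nid: default_symptom_thresholds() for nid in ids[5:]},
    )
    return truth, cfg


def mcar_mask(values: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Blank entries completely at random (for completeness-filter tests)."""
    if not 0.0 <= rate < 1.0:
        raise ValidationError("MCAR rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = values.copy().astype(float)
    mask = rng.random(out.shape) < rate
    out[mask] = np.nan
    return out


def write_scores_csv(scores: NodeScoreTable, path: str) -> None:
    """Write a node-score table in the CSV dialect the pipeline reads."""
    scores.values.to_csv(path, index=False)
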