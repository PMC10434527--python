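"""Bootstrap robustness checks for the estimated network.

Three procedures, all re-running the full EBIC-glasso estimator with the
exact settings of the primary fit (no shortcut estimators):

* **edge accuracy** — nonparametric bootstrap (rows resampled with
  replacement) giving percentile confidence intervals per edge weight;
* **centrality stability** — case-dropping bootstrap: for increasing drop
  proportions q, subsamples of ceil((1-q) n) rows are drawn without
  replacement, bridge expected influence is re-estimated, and its
  correlation with the full-sample BEI is recorded.  The correlation
  stability (CS) coefficient is the largest q at which at least 95% of
  replicates keep that correlation >= 0.7, required to hold contiguously
  from the smallest tested proportion (a CS above 0.5 is conventionally
  read as ideal stability);
* **difference tests** — bootstrap percentile intervals for pairwise
  differences of edge weights or of node BEI values; a difference is
  significant when its interval excludes zero.  No multiplicity
  correction is applied.

Every procedure is a pure function of (data, config, seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bridge import bridge_expected_influence
from .exceptions import EstimationError, ValidationError
from .network import ebic_glasso
from .scales import NodeScoreTable

logger = logging.getLogger(__name__)

#: default case-dropping grid: ten equally spaced proportions in [0.05, 0.75]
DEFAULT_DROP_PROPORTIONS: tuple[float, ...] = tuple(
    np.round(np.linspace(0.05, 0.75, 10), 10)
)


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings plus the estimator settings they must reuse."""

    B: int = 1000
    seed: int = 0
    alpha: float = 0.05
    gamma: float = 0.5
    method: str = "pearson"
    n_lambda: int = 100
    min_ratio: float = 0.01

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValidationError("bootstrap needs B >= 2 replicates")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")

    def estimate(self, scores: NodeScoreTable):
        net, _ = ebic_glasso(
            scores,
            gamma=self.gamma,
            method=self.method,
            n_lambda=self.n_lambda,
            min_ratio=self.min_ratio,
        )
        return net


@dataclass
class BootstrapEdgeResult:
    """Edge-weight bootstrap: sample estimate, replicates, percentile CIs."""

    node_ids: tuple[str, ...]
    sample_W: np.ndarray  # (p, p) full-sample weights
    replicates: np.ndarray  # (B, p, p) replicate weights
    alpha: float

    @property
    def B(self) -> int:
        return self.replicates.shape[0]

    def edge_replicates(self) -> tuple[list[str], np.ndarray]:
        """Upper-triangle replicate matrix (B x n_pairs) with pair labels."""
        p = len(self.node_ids)
        iu = np.triu_indices(p, k=1)
        labels = [f"{self.node_ids[i]}~{self.node_ids[j]}" for i, j in zip(*iu)]
        return labels, self.replicates[:, iu[0], iu[1]]

    def table(self) -> pd.DataFrame:
        """Per-pair estimate, bootstrap mean, and percentile 95% CI."""
        p = len(self.node_ids)
        iu = np.triu_indices(p, k=1)
        rep = self.replicates[:, iu[0], iu[1]]
        lo, hi = np.quantile(rep, [self.alpha / 2, 1 - self.alpha / 2], axis=0)
        return pd.DataFrame(
            {
                "node_i": [self.node_ids[i] for i in iu[0]],
                "node_j": [self.node_ids[j] for j in iu[1]],
                "estimate": self.sample_W[iu],
                "boot_mean": rep.mean(axis=0),
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )


@dataclass
class CaseDropResult:
    """Case-dropping bootstrap correlations per drop proportion."""

    proportions: tuple[float, ...]
    correlations: np.ndarray  # (n_proportions, B); NaN marks undefined
    full_bei: pd.DataFrame


@dataclass(frozen=True)
class StabilityResult:
    cs: float
    r_crit: float
    certainty: float
    pass_fraction: dict[float, float] = field(default_factory=dict)


@dataclass
class DifferenceTestResult:
    """Pairwise bootstrap difference CIs with a boolean significance layer."""

    labels: list[str]
    lower: pd.DataFrame
    upper: pd.DataFrame
    significant: pd.DataFrame

    def long_table(self) -> pd.DataFrame:
        rows = []
        for a in range(len(self.labels)):
            for b in range(a + 1, len(self.labels)):
                la, lb = self.labels[a], self.labels[b]
                rows.append(
                    (la, lb, self.lower.iloc[a, b], self.upper.iloc[a, b],
                     bool(self.significant.iloc[a, b]))
                )
        return pd.DataFrame(
            rows, columns=["a", "b", "ci_lower", "ci_upper", "significant"]
        )


def _resample(
    scores: NodeScoreTable, rng: np.random.Generator, size: int, replace: bool
) -> NodeScoreTable:
    """Draw one bootstrap sample, redrawing on zero-variance columns."""
    X = scores.values
    for attempt in range(10):
        idx = (
            rng.integers(0, len(X), size=size)
            if replace
            else rng.permutation(len(X))[:size]
        )
        sub = X.iloc[idx].reset_index(drop=True)
        if (sub.std(axis=0, ddof=0) > 0).all():
            return NodeScoreTable(values=sub, community=dict(scores.community))
        logger.warning("bootstrap replicate had a zero-variance column; redrawing")
    raise EstimationError(
        "10 consecutive bootstrap replicates had a zero-variance column"
    )


def bootstrap_edges(scores: NodeScoreTable, cfg: BootstrapConfig) -> BootstrapEdgeResult:
    """Nonparametric bootstrap of edge weights with percentile CIs."""
    if scores.n < len(scores.node_ids):
        raise ValidationError("need n >= p respondents for the edge bootstrap")
    rng = np.random.default_rng(cfg.seed)
    sample_net = cfg.estimate(scores)
    p = sample_net.p
    reps = np.empty((cfg.B, p, p))
    for b in range(cfg.B):
        reps[b] = cfg.estimate(_resample(scores, rng, scores.n, replace=True)).W
    return BootstrapEdgeResult(
        node_ids=sample_net.node_ids,
        sample_W=sample_net.W,
        replicates=reps,
        alpha=cfg.alpha,
    )


def case_drop_bootstrap(
    scores: NodeScoreTable,
    cfg: BootstrapConfig,
    proportions: tuple[float, ...] = DEFAULT_DROP_PROPORTIONS,
) -> CaseDropResult:
    """Case-dropping bootstrap of bridge expected influence.

    For each drop proportion q, draws ``cfg.B`` subsamples of
    ceil((1 - q) n) rows without replacement, re-estimates the network and
    its BEI, and records the Pearson correlation with the full-sample BEI.
    Proportions whose retained size falls below p + 1 are skipped with a
    warning; undefined correlations (zero variance) are recorded as NaN.
    """
    props = tuple(sorted(proportions))
    if any(not 0.0 <= q < 1.0 for q in props):
        raise ValidationError("drop proportions must lie in [0, 1)")
    p = len(scores.node_ids)
    rng = np.random.default_rng(cfg.seed)
    full_net = cfg.estimate(scores)
    full_tbl = bridge_expected_influence(full_net)
    full_bei = full_tbl["bei"].to_numpy()
    usable = []
    for q in props:
        if int(np.ceil((1.0 - q) * scores.n)) >= p + 1:
            usable.append(q)
        else:
            warnings.warn(
                f"drop proportion {q:g} retains fewer than p+1 rows; skipped",
                stacklevel=2,
            )
    corr = np.full((len(usable), cfg.B), np.nan)
    for qi, q in enumerate(usable):
        size = int(np.ceil((1.0 - q) * scores.n))
        for b in range(cfg.B):
            try:
                sub = _resample(scores, rng, size, replace=False)
                net = cfg.estimate(sub)
            except EstimationError:
                continue  # recorded as missing
            bei = bridge_expected_influence(net)["bei"].to_numpy()
            if bei.std() == 0 or full_bei.std() == 0:
                continue
            corr[qi, b] = np.corrcoef(full_bei, bei)[0, 1]
    return CaseDropResult(
        proportions=tuple(usable), correlations=corr, full_bei=full_tbl
    )


def cs_coefficient(
    result: CaseDropResult, r_crit: float = 0.7, certainty: float = 0.95
) -> StabilityResult:
    """Correlation stability coefficient of the case-dropping bootstrap.

    CS is the largest tested drop proportion q such that the fraction of
    replicates with correlation >= ``r_crit`` is at least ``certainty`` at q
    *and at every smaller tested proportion* (no interpolation); 0 when even
    the smallest proportion fails.
    """
    valid_counts = np.sum(~np.isnan(result.correlations), axis=1)
    if len(result.proportions) == 0 or valid_counts.max(initial=0) < 10:
        raise ValidationError(
            "case-dropping result has no proportion with >= 10 valid replicates"
        )
    pass_fraction: dict[float, float] = {}
    cs = 0.0
    contiguous = True
    for qi, q in enumerate(result.proportions):
        row = result.correlations[qi]
        row = row[~np.isnan(row)]
        frac = float(np.mean(row >= r_crit)) if len(row) else 0.0
        pass_fraction[q] = frac
        if contiguous and frac >= certainty:
            cs = q
        else:
            contiguous = False
    return StabilityResult(
        cs=cs, r_crit=r_crit, certainty=certainty, pass_fraction=pass_fraction
    )


def bei_replicates(
    result: BootstrapEdgeResult, partition: dict[str, str]
) -> np.ndarray:
    """Per-replicate BEI matrix (B x p) derived from edge replicates."""
    labels = np.asarray([partition[nid] for nid in result.node_ids])
    cross = (labels[:, None] != labels[None, :]).astype(float)
    return np.einsum("bij,ij->bi", result.replicates, cross)


def difference_test(
    replicates: np.ndarray,
    labels: list[str],
    alpha: float = 0.05,
) -> DifferenceTestResult:
    """Bootstrap percentile difference test over all pairs of quantities.

    ``replicates`` is a (B x m) matrix of bootstrapped values for m
    quantities (edges or node BEI).  For each pair the percentile interval
    of the replicate-wise difference at level 1 - alpha is computed;
    the pair differs significantly iff that interval excludes zero.
    """
    R = np.asarray(replicates, dtype=float)
    if R.ndim != 2 or R.shape[1] < 2:
        raise ValidationError("difference test needs at least 2 quantities")
    if R.shape[1] != len(labels):
        raise ValidationError("labels must match replicate columns")
    m = R.shape[1]
    lower = np.full((m, m), np.nan)
    upper = np.full((m, m), np.nan)
    sig = np.zeros((m, m), dtype=bool)
    for i in range(m - 1):
        d = R[:, i : i + 1] - R[:, i + 1 :]
        lo, hi = np.quantile(d, [alpha / 2, 1 - alpha / 2], axis=0)
        lower[i, i + 1 :] = lo
        upper[i, i + 1 :] = hi
        lower[i + 1 :, i] = -hi
        upper[i + 1 :, i] = -lo
        s = (lo > 0) | (hi < 0)
        sig[i, i + 1 :] = s
        sig[i + 1 :, i] = s
    return DifferenceTestResult(
        labels=list(labels),
        lower=pd.DataFrame(lower, index=labels, columns=labels),
        upper=pd.DataFrame(upper, index=labels, columns=labels),
        significant=pd.DataFrame(sig, index=labels, columns=labels),
    )
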