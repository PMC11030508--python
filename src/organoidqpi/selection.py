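"""Feature ranking: mRMR, neighborhood component analysis, chi-square.

Three complementary rankings of a tiles × features table against a class
label, mirroring the MATLAB trio ``fscmrmr`` / ``fscnca`` / ``fscchi2``:

* **mRMR** — greedy mutual-information ranking maximizing label relevance
  minus mean redundancy against already-selected features (MID scheme by
  default; MIQ optional).  Features are discretized into equal-frequency
  bins for the MI estimates.
* **NCA** — per-feature weights maximizing the expected leave-one-out
  accuracy of a stochastic nearest-neighbor classifier with weighted-L1
  distances, L2-regularized, fitted by L-BFGS on standardized features.
* **chi-square** — per-feature χ² statistic of the binned-feature × class
  contingency table.

The consensus set is the union of each method's top-k, annotated with the
per-method ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "Ranking",
    "rank_mrmr",
    "rank_nca",
    "rank_chi2",
    "consensus_top_features",
    "discretize_equal_frequency",
    "mutual_information",
]


@dataclass
class Ranking:
    """Ordered feature names with matching scores (best first)."""

    method: str
    features: list[str]
    scores: np.ndarray
    converged: bool = True

    def top(self, k: int) -> list[str]:
        return self.features[:k]


def _as_matrix(table, feature_names=None):
    if isinstance(table, pd.DataFrame):
        names = list(table.columns) if feature_names is None else list(feature_names)
        x = table[names].to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        names = (
            [f"f{i}" for i in range(x.shape[1])]
            if feature_names is None
            else list(feature_names)
        )
    return x, names


def discretize_equal_frequency(x: np.ndarray, bins: int = 8) -> np.ndarray:
    """Equal-frequency binning of one feature column to integer codes."""
    uniq = np.unique(x)
    if uniq.size <= bins:
        return np.searchsorted(uniq, x)
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), x, side="right")


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two discrete code vectors."""
    from sklearn.metrics import mutual_info_score

    return float(mutual_info_score(a, b))


def rank_mrmr(
    table,
    labels,
    k: int | None = None,
    feature_names=None,
    bins: int = 8,
    scheme: str = "MID",
) -> Ranking:
    """Greedy minimum-redundancy maximum-relevance feature ordering.

    Score of a candidate f given selected set S: relevance I(f; y) minus
    (MID) or divided by (MIQ) the mean redundancy mean_{s∈S} I(f; s).
    Deterministic; ties break lexicographically on feature name.  Constant
    features have zero relevance and sort last.
    """
    x, names = _as_matrix(table, feature_names)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    if scheme not in ("MID", "MIQ"):
        raise ValueError("scheme must be MID or MIQ")
    d = x.shape[1]
    k = d if k is None else min(k, d)
    disc = np.stack([discretize_equal_frequency(x[:, j], bins) for j in range(d)], 1)
    relevance = np.array([mutual_information(disc[:, j], y) for j in range(d)])

    selected: list[int] = []
    scores: list[float] = []
    remaining = set(range(d))
    red_cache = np.zeros((d,))
    while len(selected) < k and remaining:
        best_j, best_score = None, None
        for j in sorted(remaining, key=lambda j: names[j]):
            if selected:
                red = red_cache[j] / len(selected)
                score = (
                    relevance[j] - red
                    if scheme == "MID"
                    else relevance[j] / (red + 1e-12)
                )
            else:
                score = relevance[j]
            if best_score is None or score > best_score + 1e-15:
                best_j, best_score = j, score
        selected.append(best_j)
        scores.append(float(best_score))
        remaining.discard(best_j)
        for j in remaining:
            red_cache[j] += mutual_information(disc[:, j], disc[:, best_j])
    order = selected + sorted(remaining, key=lambda j: names[j])
    full_scores = scores + [float("-inf")] * (len(order) - len(scores))
    return Ranking("mrmr", [names[j] for j in order], np.array(full_scores))


def _nca_objective(w, absdiff, same, lam):
    # absdiff: (n, n, d) |x_i - x_j|; same: (n, n) same-class mask (diag False)
    n = absdiff.shape[0]
    w2 = w**2
    dist = absdiff @ w2
    np.fill_diagonal(dist, np.inf)
    dist = dist - dist.min(axis=1, keepdims=True)  # log-sum-exp shift
    p = np.exp(-dist)
    p /= p.sum(axis=1, keepdims=True)
    p_i = (p * same).sum(axis=1)
    f = p_i.mean() - lam * w2.sum()
    # gradient wrt w
    inner = (p * absdiff.transpose(2, 0, 1)).sum(axis=2)  # (d, n) Σ_j p_ij |Δ|
    inner_same = ((p * same) * absdiff.transpose(2, 0, 1)).sum(axis=2)
    grad = (2 * w / n) * (p_i * inner - inner_same).sum(axis=1) - 2 * lam * w
    return -f, -grad


def rank_nca(
    table,
    labels,
    feature_names=None,
    regularization: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
) -> Ranking:
    """Neighborhood component analysis feature weighting.

    Features are standardized; weights are initialized at 1 and fitted by
    L-BFGS on the expected leave-one-out accuracy under stochastic neighbor
    assignment with distance Σ_r w_r²|Δx_r|, minus λΣw_r² (λ = 1/n by
    default).  Ranking is by the non-negative weight w_r²; a non-convergent
    fit returns the best iterate flagged ``converged=False``.
    """
    x, names = _as_matrix(table, feature_names)
    y = np.asarray(labels)
    n, d = x.shape
    lam = 1.0 / n if regularization is None else regularization
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    absdiff = np.abs(xs[:, None, :] - xs[None, :, :])
    same = (y[:, None] == y[None, :]) & ~np.eye(n, dtype=bool)

    w0 = np.ones(d)
    res = minimize(
        _nca_objective,
        w0,
        args=(absdiff, same.astype(float), lam),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol},
    )
    weights = res.x**2
    order = np.lexsort((np.array(names, dtype=object), -weights))
    return Ranking(
        "nca",
        [names[j] for j in order],
        weights[order],
        converged=bool(res.success),
    )


def rank_chi2(table, labels, feature_names=None, bins: int = 8) -> Ranking:
    """Chi-square ranking from binned-feature × class contingency tables."""
    x, names = _as_matrix(table, feature_names)
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    stats = []
    for j in range(x.shape[1]):
        codes = discretize_equal_frequency(x[:, j], bins)
        obs = np.zeros((codes.max() + 1, classes.size))
        np.add.at(obs, (codes, y_idx), 1.0)
        obs = obs[obs.sum(axis=1) > 0]
        if obs.shape[0] < 2:
            stats.append(0.0)  # constant feature
            continue
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        stats.append(float(((obs - expected) ** 2 / expected).sum()))
    stats = np.array(stats)
    order = np.lexsort((np.array(names, dtype=object), -stats))
    return Ranking("chi2", [names[j] for j in order], stats[order])


def chi2_pvalue(stat: float, df: int) -> float:
    """Upper-tail p-value for a chi-square statistic."""
    return float(chi2_dist.sf(stat, df))


def consensus_top_features(rankings: list[Ranking], n: int = 150) -> pd.DataFrame:
    """Union of each method's top-``n`` features with per-method ranks.

    Rows are ordered by the best (minimum) rank across methods, then name.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    members: set[str] = set()
    for r in rankings:
        members |= set(r.top(n))
    rows = []
    for name in sorted(members):
        row: dict = {"feature": name}
        best = math.inf
        for r in rankings:
            try:
                rank = r.features.index(name) + 1
            except ValueError:
                rank = None
            row[f"rank_{r.method}"] = rank
            if rank is not None:
                best = min(best, rank)
        row["best_rank"] = best
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(["best_rank", "feature"]).reset_index(drop=True)
    return df
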