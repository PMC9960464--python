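"""Feature ranking against SBP/DBP labels: CFS, RReliefF and MRMR.

All three selectors return a full ranking with importance scores:

* **CFS** (correlation-based feature selection) greedily grows a feature set
  maximizing the merit ``k * r_cf / sqrt(k + k*(k-1) * r_ff)`` where ``r_cf``
  is the mean absolute feature-label correlation of the set and ``r_ff`` the
  mean absolute pairwise feature-feature correlation — features should be
  correlated with the label and uncorrelated with each other.
* **RReliefF** weights features by contrasting, over nearest neighbors of
  sampled instances, the probability of a feature differing given that the
  (continuous) label differs against the probability of differing when the
  label agrees.
* **MRMR** (minimum redundancy, maximum relevance) greedily selects the
  feature maximizing relevance to the label minus mean redundancy with the
  already-selected set, both measured by mutual information on
  equal-frequency-binned values (an F-statistic variant is available).

Determinism: ties are broken lexicographically by feature name and all
stochastic steps flow from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionResult",
    "cfs_rank",
    "rrelieff_rank",
    "mrmr_rank",
    "selection_report",
]


@dataclass
class SelectionResult:
    """Ranked feature names with per-feature importance scores."""

    method: str
    label: str
    ranking: list[str]
    scores: dict = field(default_factory=dict)
    k: int = 20

    def top(self, k: int | None = None) -> list[str]:
        return self.ranking[: (k or self.k)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "label": self.label,
                "rank": np.arange(1, len(self.ranking) + 1),
                "feature": self.ranking,
                "score": [self.scores[f] for f in self.ranking],
            }
        )


def _clean_matrix(table: pd.DataFrame, label: str):
    """Split a feature table into the numeric feature matrix and the label.

    Non-feature bookkeeping columns and the two label columns are dropped;
    rows with a missing label are removed and remaining NaNs are imputed
    with the column median (selectors need complete cases).
    """
    drop = {"sbp", "dbp", "record_id", "chunk_id", "pulse_id", "onset"}
    feats = [c for c in table.columns if c not in drop]
    X = table[feats].apply(pd.to_numeric, errors="coerce")
    X = X.replace([np.inf, -np.inf], np.nan)
    y = pd.to_numeric(table[label], errors="coerce")
    keep = y.notna()
    X, y = X.loc[keep], y.loc[keep]
    X = X.fillna(X.median(numeric_only=True))
    X = X.dropna(axis=1, how="all")
    return X, y.to_numpy(dtype=float)


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


def _merit(k: int, r_cf: float, r_ff: float) -> float:
    denom = np.sqrt(k + k * (k - 1) * r_ff)
    return k * r_cf / denom if denom > 0 else 0.0


def cfs_rank(table: pd.DataFrame, label: str = "sbp") -> SelectionResult:
    """Greedy forward CFS ranking.

    Features are added while they improve the subset merit; each selected
    feature's score is the merit of the set at its inclusion.  Features
    never selected are appended ranked by the merit the final set would
    have with them added.  Constant features have zero correlation.
    """
    X, y = _clean_matrix(table, label)
    names = sorted(X.columns)
    xv = {f: X[f].to_numpy(dtype=float) for f in names}
    r_cf = {f: _abs_corr(xv[f], y) for f in names}
    corr_cache: dict[tuple, float] = {}

    def r_ff(f, g):
        key = (f, g) if f < g else (g, f)
        if key not in corr_cache:
            corr_cache[key] = _abs_corr(xv[f], xv[g])
        return corr_cache[key]

    selected: list[str] = []
    scores: dict = {}
    remaining = list(names)
    current_merit = 0.0
    while remaining:
        best_f, best_m = None, -np.inf
        for f in remaining:
            k = len(selected) + 1
            cf = (sum(r_cf[g] for g in selected) + r_cf[f]) / k
            if k == 1:
                ff = 0.0
            else:
                pair_sum = sum(r_ff(a, b) for i, a in enumerate(selected)
                               for b in selected[i + 1 :])
                pair_sum += sum(r_ff(f, g) for g in selected)
                ff = pair_sum / (k * (k - 1) / 2)
            m = _merit(k, cf, ff)
            if m > best_m + 1e-12 or (abs(m - best_m) <= 1e-12 and (best_f is None or f < best_f)):
                best_f, best_m = f, m
        if best_m <= current_merit + 1e-12 and selected:
            break
        selected.append(best_f)
        scores[best_f] = best_m
        current_merit = best_m
        remaining.remove(best_f)

    # leftovers: hypothetical merit when added to the final selected set
    leftover_scores = {}
    for f in remaining:
        k = len(selected) + 1
        cf = (sum(r_cf[g] for g in selected) + r_cf[f]) / k
        pair_sum = sum(r_ff(a, b) for i, a in enumerate(selected) for b in selected[i + 1 :])
        pair_sum += sum(r_ff(f, g) for g in selected)
        ff = pair_sum / (k * (k - 1) / 2) if k > 1 else 0.0
        leftover_scores[f] = _merit(k, cf, ff)
    remaining.sort(key=lambda f: (-leftover_scores[f], f))
    for f in remaining:
        scores[f] = leftover_scores[f]
    return SelectionResult("CFS", label, selected + remaining, scores)


def rrelieff_rank(table: pd.DataFrame, label: str = "sbp", n_neighbors: int = 10,
                  n_iterations: int | None = None, seed: int = 0) -> SelectionResult:
    """RReliefF weights for a continuous label.

    Features and label are range-normalized internally, so the result is
    invariant to affine rescaling.  With ``n_iterations=None`` every
    instance is visited in order (fully deterministic); otherwise
    ``n_iterations`` instances are sampled with the given seed.  Neighbor
    influence decays exponentially with neighbor rank.  Weights lie in
    ``[-1, 1]``; larger means the feature separates differently-labeled
    neighbors.
    """
    X, y = _clean_matrix(table, label)
    names = sorted(X.columns)
    xm = X[names].to_numpy(dtype=float)
    n, nf = xm.shape
    if n <= n_neighbors:
        raise ValueError("need more rows than neighbors")
    rng_range = np.ptp(xm, axis=0)
    rng_range[rng_range == 0] = 1.0
    xs = (xm - xm.min(axis=0)) / rng_range
    y_range = np.ptp(y)
    ys = (y - y.min()) / (y_range if y_range > 0 else 1.0)

    if n_iterations is None:
        idx_iter = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        idx_iter = rng.choice(n, size=min(n_iterations, n), replace=False)

    ranks = np.arange(1, n_neighbors + 1)
    sigma = max(1.0, n_neighbors / 3.0)
    infl = np.exp(-((ranks / sigma) ** 2))
    infl = infl / infl.sum()

    n_dc = 0.0
    n_da = np.zeros(nf)
    n_dcda = np.zeros(nf)
    for i in idx_iter:
        d = np.abs(xs - xs[i]).sum(axis=1)
        d[i] = np.inf
        nn = np.argpartition(d, n_neighbors)[:n_neighbors]
        nn = nn[np.argsort(d[nn], kind="stable")]
        dy = np.abs(ys[nn] - ys[i])
        da = np.abs(xs[nn] - xs[i])
        n_dc += float((infl * dy).sum())
        n_da += (infl[:, None] * da).sum(axis=0)
        n_dcda += ((infl * dy)[:, None] * da).sum(axis=0)
    m_total = float(len(idx_iter))
    w = np.full(nf, -np.inf)
    if n_dc > 0 and m_total > n_dc:
        w = n_dcda / n_dc - (n_da - n_dcda) / (m_total - n_dc)
    scores = {f: float(w[j]) for j, f in enumerate(names)}
    ranking = sorted(names, key=lambda f: (-scores[f], f))
    return SelectionResult("RReliefF", label, ranking, scores)


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two integer-coded discrete variables."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / a.size
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa[:, None] * pb[None, :])[nz])))


def _bin_ef(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning; constant columns collapse to one bin."""
    if np.ptp(v) == 0:
        return np.zeros(v.size, dtype=int)
    qs = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), v, side="right")


def mrmr_rank(table: pd.DataFrame, label: str = "sbp", mode: str = "difference",
              relevance: str = "mi", n_bins: int = 10) -> SelectionResult:
    """Greedy minimum-redundancy maximum-relevance ranking.

    Relevance is the mutual information between the binned feature and the
    binned label (or a correlation F-statistic with ``relevance="f"``);
    redundancy is the mean mutual information with already-selected
    features.  ``mode`` picks the difference (default) or quotient
    objective.  The first feature's score is its relevance; later scores
    are the objective at the selection step.
    """
    X, y = _clean_matrix(table, label)
    names = sorted(X.columns)
    binned = {f: _bin_ef(X[f].to_numpy(dtype=float), n_bins) for f in names}
    yb = _bin_ef(y, n_bins)
    if relevance == "mi":
        rel = {f: _mutual_information(binned[f], yb) for f in names}
    elif relevance == "f":
        n = y.size
        rel = {}
        for f in names:
            r = _abs_corr(X[f].to_numpy(dtype=float), y)
            rel[f] = (n - 2) * r**2 / (1 - r**2) if r < 1 else np.inf
    else:
        raise ValueError("relevance must be 'mi' or 'f'")

    mi_cache: dict[tuple, float] = {}

    def red(f, g):
        key = (f, g) if f < g else (g, f)
        if key not in mi_cache:
            mi_cache[key] = _mutual_information(binned[f], binned[g])
        return mi_cache[key]

    selected: list[str] = []
    scores: dict = {}
    remaining = list(names)
    while remaining:
        best_f, best_v = None, -np.inf
        for f in remaining:
            if not selected:
                v = rel[f]
            else:
                redun = np.mean([red(f, g) for g in selected])
                v = rel[f] - redun if mode == "difference" else rel[f] / max(redun, 1e-12)
            if v > best_v + 1e-12 or (abs(v - best_v) <= 1e-12 and (best_f is None or f < best_f)):
                best_f, best_v = f, v
        selected.append(best_f)
        scores[best_f] = float(best_v)
        remaining.remove(best_f)
    return SelectionResult("MRMR", label, selected, scores)


def selection_report(results, k: int = 20) -> dict:
    """Top-k summary and cross-method agreement.

    Returns a dict with a tidy top-k DataFrame (bar-chart-ready) and, per
    label, the features appearing in at least two methods' top-k.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one SelectionResult")
    frames = []
    for r in results:
        df = r.to_frame().head(min(k, len(r.ranking)))
        frames.append(df)
    topk = pd.concat(frames, ignore_index=True)
    agreement: dict = {}
    for lab in sorted({r.label for r in results}):
        sets = [set(r.top(k)) for r in results if r.label == lab]
        counts: dict = {}
        for s in sets:
            for f in s:
                counts[f] = counts.get(f, 0) + 1
        agreement[lab] = sorted(f for f, c in counts.items() if c >= 2)
    return {"topk": topk, "agreement": agreement}
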