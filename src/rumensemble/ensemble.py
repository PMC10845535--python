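"""Consensus of full-population and extreme-group tests on microbial taxa.

The ensemble tallies up to ten significance votes per genus:

* stepwise-AICc linear-model selection on all cows, one vote per data
  representation (count, relative abundance, CLR);
* cross-validated ridge feature selection on all cows, again one vote per
  representation;
* the four differential-abundance tests on the 50 most vs 50 least
  efficient cows.

A taxon significant in at least ``min_votes`` (default 4) tests is part of
the trait's *core microbiome*; core taxa are then correlated (Pearson, on
CLR values) with the trait over the extreme cows to attach a direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import daa as daa_mod
from .features import clr_transform, relative_abundance
from .mlpredict import cv_feature_select
from .simdata import CountTable

log = logging.getLogger(__name__)

REPRESENTATIONS = ("count", "relabund", "clr")


def aicc(aic: float, k: int, n: int) -> float:
    """Small-sample AIC correction: AIC + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        return float("inf")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _ols_aicc(X: np.ndarray, y: np.ndarray) -> float:
    """Gaussian AICc of an OLS fit with intercept; k counts all parameters."""
    n = len(y)
    Xc = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    rss = float(((y - Xc @ beta) ** 2).sum())
    k = Xc.shape[1] + 1   # coefficients + residual variance
    if rss <= 0:
        return float("-inf")
    aic = n * np.log(rss / n) + 2 * k
    return aicc(aic, k, n)


def _coef_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """t-test p-values of the slopes in an OLS fit with intercept."""
    n = len(y)
    Xc = np.column_stack([np.ones(n), X])
    k = Xc.shape[1]
    XtX_inv = np.linalg.inv(Xc.T @ Xc)
    beta = XtX_inv @ (Xc.T @ y)
    rss = float(((y - Xc @ beta) ** 2).sum())
    df = n - k
    if df <= 0:
        return np.ones(k - 1)
    s2 = rss / df
    se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 1e-300))
    t = beta / se
    return 2.0 * stats.t.sf(np.abs(t[1:]), df)


def stepwise_select(features, y, alpha: float = 0.05,
                    max_steps: int | None = None) -> list:
    """Forward-backward stepwise OLS selection; returns the lowest-AICc model.

    At each step the candidate with the smallest partial-F p-value enters if
    it clears the entry threshold; any included term whose p-value then
    exceeds ``alpha`` is dropped.  Among all visited models the one with
    lowest AICc wins.  The entry threshold is Bonferroni-adjusted for the
    number of remaining candidates (alpha / #remaining), which keeps the
    selection honest when hundreds of taxa are screened: on a pure-noise
    trait the selected set stays (near-)empty.
    """
    from .mlpredict import _as_matrix
    X, ids, _ = _as_matrix(features)
    y = np.asarray(y, float)
    n, p = X.shape
    if max_steps is None:
        max_steps = min(p, max(2, n // 5))
    yc = y - y.mean()
    current: list[int] = []
    visited = {(): _ols_aicc(np.empty((n, 0)), y)}
    seen = {frozenset()}
    for _ in range(max_steps):
        remaining = [j for j in range(p) if j not in current]
        if not remaining:
            break
        k = len(current)
        if n - k - 3 <= 0:
            break   # no residual degrees of freedom for another term
        # orthonormal basis of [1, X_current]
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), X[:, current]]))
        yr = yc - Q @ (Q.T @ yc)
        Xr = X[:, remaining] - Q @ (Q.T @ X[:, remaining])
        xnorm = np.sqrt((Xr ** 2).sum(axis=0))
        ynorm = np.sqrt((yr ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(xnorm > 1e-10, Xr.T @ yr / (xnorm * ynorm), 0.0)
        df = n - k - 2
        fstat = r ** 2 * df / np.maximum(1 - r ** 2, 1e-300)
        pvals = stats.f.sf(fstat, 1, df)
        best = int(np.argmin(pvals))
        if pvals[best] > alpha / len(remaining):
            break
        current.append(remaining[best])
        # backward sweep
        while current:
            pv = _coef_pvalues(X[:, current], y)
            worst = int(np.argmax(pv))
            if pv[worst] > alpha:
                current.pop(worst)
            else:
                break
        key = frozenset(current)
        if key in seen:
            break   # cycle: a term re-enters and leaves
        seen.add(key)
        visited[tuple(current)] = _ols_aicc(X[:, current], y)
    best_model = min(visited, key=visited.get)
    return [ids[j] for j in best_model]


def extreme_groups(trait: pd.Series, n_each: int = 50,
                   higher_is_efficient: bool = False) -> pd.Series:
    """Label the n_each most and least efficient cows; the rest are excluded.

    For RFI-type traits the lowest values are the most efficient
    (``higher_is_efficient=False``); residual MFE/MPE flip the orientation.
    Ties are broken by stable position order.
    """
    n = len(trait)
    if 2 * n_each > n:
        raise ValueError("2 * n_each exceeds the number of cows")
    order = np.argsort(trait.to_numpy(), kind="stable")
    labels = pd.Series("excluded", index=trait.index, name="group")
    low, high = order[:n_each], order[-n_each:]
    if higher_is_efficient:
        low, high = high, low
    labels.iloc[low] = "most_efficient"
    labels.iloc[high] = "least_efficient"
    return labels


@dataclass
class ConsensusTable:
    """Cross-test vote tally with core flags and extreme-group correlations."""

    table: pd.DataFrame   # index taxon; per-test bools, votes, core, r, r_sign
    test_labels: list
    min_votes: int

    @property
    def core_taxa(self) -> list:
        return list(self.table.index[self.table["core"]])


def tally_votes(test_results, universe,
                min_votes: int = 4) -> ConsensusTable:
    """Count per-taxon significance votes over uniquely labelled tests.

    ``test_results`` maps test label -> significant taxa (a dict or a
    sequence of (label, taxa) pairs).
    """
    pairs = (list(test_results.items()) if isinstance(test_results, dict)
             else list(test_results))
    labels = [label for label, _ in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate test label")
    universe = list(universe)
    table = pd.DataFrame(False, index=pd.Index(universe, name="taxon"),
                         columns=labels)
    for label, taxa in pairs:
        hits = [t for t in taxa if t in table.index]
        table.loc[hits, label] = True
    table["votes"] = table[labels].sum(axis=1)
    table["core"] = table["votes"] >= min_votes
    table["r"] = np.nan
    table["r_sign"] = ""
    table = table.sort_values("votes", ascending=False)
    return ConsensusTable(table=table, test_labels=labels, min_votes=min_votes)


def extreme_correlation(counts: CountTable, taxa, trait: pd.Series,
                        groups: pd.Series,
                        pseudocount: float = 0.5) -> pd.Series:
    """Pearson r between CLR taxon values and the trait over extreme cows.

    A negative r with RFI means the taxon is associated with efficiency.
    """
    extreme = groups.index[groups != "excluded"]
    clr = clr_transform(counts, pseudocount)[extreme]
    t = trait.loc[extreme].to_numpy(float)
    out = {}
    for taxon in taxa:
        x = clr.loc[taxon].to_numpy(float)
        if x.std() == 0:
            raise ValueError(f"zero-variance taxon {taxon!r} in extremes")
        out[taxon] = float(np.corrcoef(x, t)[0, 1])
    return pd.Series(out, name="r")


def export_vote_network(consensus: ConsensusTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bipartite (taxon, test) edge list plus node attributes."""
    edges = []
    for taxon, row in consensus.table.iterrows():
        for label in consensus.test_labels:
            if row[label]:
                edges.append({"taxon": taxon, "test": label})
    edge_df = pd.DataFrame(edges, columns=["taxon", "test"])
    nodes = consensus.table[["votes", "core", "r"]].reset_index()
    return edge_df, nodes


def run_ensemble(counts: CountTable, trait: pd.Series,
                 n_extreme: int = 50, min_votes: int = 4,
                 higher_is_efficient: bool = False, seed: int = 0,
                 min_prevalence: float = 0.10, pseudocount: float = 0.5,
                 max_ml_features: int = 30,
                 vote_granularity: str = "method_x_representation"
                 ) -> ConsensusTable:
    """Full two-part consensus for one trait at the genus rank.

    Stepwise and ridge-selection votes use every cow; the four DAA votes use
    the extreme groups only.  With
    ``vote_granularity='method_x_representation'`` (default) each of the ten
    tests counts separately; ``'method'`` collapses the three representation
    votes of stepwise and of the ridge selector into one vote each.
    """
    filtered = daa_mod.prevalence_filter(counts, min_prevalence)
    reps = {
        "count": filtered.counts.astype(float).T,
        "relabund": relative_abundance(filtered).T,
        "clr": clr_transform(filtered, pseudocount).T,
    }
    votes: dict[str, list] = {}
    rng = np.random.default_rng(seed)
    for rep in REPRESENTATIONS:
        X = reps[rep].loc[trait.index]
        votes[f"stepwise_{rep}"] = stepwise_select(X, trait)
        report = cv_feature_select(X, trait, seed=int(rng.integers(2 ** 31)),
                                   max_features=max_ml_features)
        votes[f"ml_{rep}"] = report.selected
    groups = extreme_groups(trait, n_each=n_extreme,
                            higher_is_efficient=higher_is_efficient)
    extreme = groups.index[groups != "excluded"]
    sub = CountTable(filtered.counts[extreme], filtered.lineages)
    daa_results = daa_mod.run_all(sub, groups.loc[extreme],
                                  seed=int(rng.integers(2 ** 31)),
                                  min_prevalence=0.0)
    for method, result in daa_results.items():
        votes[method] = result.significant_taxa
    if vote_granularity == "method":
        collapsed = {
            "stepwise": set().union(*(votes[f"stepwise_{r}"]
                                      for r in REPRESENTATIONS)),
            "ml": set().union(*(votes[f"ml_{r}"] for r in REPRESENTATIONS)),
        }
        collapsed.update({m: votes[m] for m in daa_mod.METHODS})
        votes = collapsed
    elif vote_granularity != "method_x_representation":
        raise ValueError(f"unknown vote granularity {vote_granularity!r}")
    consensus = tally_votes(votes, universe=filtered.taxon_ids,
                            min_votes=min_votes)
    if consensus.core_taxa:
        r = extreme_correlation(filtered, consensus.core_taxa, trait, groups,
                                pseudocount)
        consensus.table.loc[r.index, "r"] = r
        consensus.table.loc[r.index, "r_sign"] = np.where(r > 0, "+", "-")
    return consensus
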