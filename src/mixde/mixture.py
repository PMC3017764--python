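"""Phenotype contrasts, two-component mixture classification and DE calling.

For each gene, the three phenotype contrasts (Polled-Horned, Polled-Scurred,
Horned-Scurred) are standardised by the prediction-error SE of the BLUP
difference, giving a t-like statistic per gene and contrast.  Each contrast's
statistics are then classified by a two-component normal mixture fitted with
EM: the component with mean nearest zero (ties to the smaller variance) is
the null, and the posterior probability of the non-null component drives gene
selection.  The declared set is the largest posterior-ranked set whose
estimated FDR — the mean of (1 - posterior) over the selected genes — stays
below the target (1% by default).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .simulate import CONTRAST_PAIRS, PHENOTYPES

logger = logging.getLogger(__name__)


class MixtureConvergenceError(RuntimeError):
    """All EM starts collapsed to a degenerate component."""


def compute_contrasts(profiles: pd.DataFrame, pev: np.ndarray) -> pd.DataFrame:
    """Standardised per-gene phenotype differences.

    Parameters
    ----------
    profiles : DataFrame, genes x (Polled, Horned, Scurred) HG BLUPs.
    pev : (G, 3, 3) prediction-error covariances aligned with ``profiles``.

    Returns a long table: gene_id, contrast, raw_diff, se, statistic.
    """
    if len(profiles) != pev.shape[0]:
        raise ValueError("profiles and PEV are not aligned")
    cols = {p: i for i, p in enumerate(PHENOTYPES)}
    out = []
    vals = profiles.to_numpy()
    skipped = profiles.index[np.isnan(vals).any(axis=1)]
    if len(skipped):
        logger.info("skipping %d genes with missing profiles", len(skipped))
    for contrast, (a, b) in CONTRAST_PAIRS.items():
        ia, ib = cols[a], cols[b]
        diff = vals[:, ia] - vals[:, ib]
        var = pev[:, ia, ia] + pev[:, ib, ib] - 2.0 * pev[:, ia, ib]
        se = np.sqrt(np.maximum(var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = diff / se
        df = pd.DataFrame({"gene_id": profiles.index, "contrast": contrast,
                           "raw_diff": diff, "se": se, "statistic": stat})
        out.append(df[~df["gene_id"].isin(skipped) & (se > 0)])
    return pd.concat(out, ignore_index=True)


class TwoComponentMixture(BaseEstimator):
    """EM fit of a two-component normal mixture to contrast statistics.

    The first EM start splits the data at the 90th percentile of the absolute
    statistics; the remaining ``n_starts - 1`` starts jitter that split.  A
    start whose component variance collapses is discarded; if every start
    collapses a :class:`MixtureConvergenceError` is raised.

    Attributes (after ``fit``)
    --------------------------
    weights_, means_, variances_ : (2,) arrays, component 0 = null
    null_component_ : index of the null component before relabelling (0 or 1)
    loglik_path_ : per-iteration log-likelihood of the winning start
    n_iter_, converged_
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 2000,
                 n_starts: int = 5, random_state: int | None = None,
                 min_obs: int = 50):
        self.tol = tol
        self.max_iter = max_iter
        self.n_starts = n_starts
        self.random_state = random_state
        self.min_obs = min_obs

    def fit(self, X, y=None):
        x = np.asarray(X, float).ravel()
        x = x[np.isfinite(x)]
        if len(x) < self.min_obs:
            raise ValueError(
                f"mixture needs >= {self.min_obs} statistics, got {len(x)}")
        if np.ptp(x) == 0.0:
            raise ValueError("statistics are constant; no mixture to fit")
        rng = np.random.default_rng(self.random_state)
        var_floor = 1e-8 * max(np.var(x), 1e-12)
        best = None
        for start in range(self.n_starts):
            params = self._init_params(x, rng, jitter=start > 0)
            res = self._em(x, params, var_floor)
            if res is None:
                continue
            if best is None or res["loglik"][-1] > best["loglik"][-1]:
                best = res
        if best is None:
            raise MixtureConvergenceError(
                f"all {self.n_starts} EM starts degenerated")
        w, mu, var = best["w"], best["mu"], best["var"]
        null = int(np.argmin(np.abs(mu)))
        if np.isclose(abs(mu[0]), abs(mu[1])):
            null = int(np.argmin(var))
        order = [null, 1 - null]
        self.weights_ = w[order]
        self.means_ = mu[order]
        self.variances_ = var[order]
        self.null_component_ = null
        self.loglik_path_ = best["loglik"]
        self.n_iter_ = len(best["loglik"])
        self.converged_ = best["converged"]
        return self

    def _init_params(self, x, rng, jitter: bool):
        q = 0.9
        if jitter:
            q = float(np.clip(0.9 + rng.normal(0, 0.05), 0.55, 0.995))
        cut = np.quantile(np.abs(x), q)
        hi = np.abs(x) > cut
        if hi.sum() < 2 or (~hi).sum() < 2:
            hi = np.abs(x) > np.median(np.abs(x))
        w = np.array([(~hi).mean(), hi.mean()])
        mu = np.array([x[~hi].mean(), x[hi].mean()])
        var = np.array([max(x[~hi].var(), 1e-6), max(x[hi].var(), 1e-6)])
        if jitter:
            mu = mu + rng.normal(0, 0.1 * (np.std(x) + 1e-9), 2)
            var = var * np.exp(rng.normal(0, 0.2, 2))
        return w, mu, var

    def _em(self, x, params, var_floor):
        w, mu, var = (p.copy() for p in params)
        n = len(x)
        loglik = []
        converged = False
        for _ in range(self.max_iter):
            dens = np.stack([w[j] * norm.pdf(x, mu[j], np.sqrt(var[j]))
                             for j in range(2)])
            tot = dens.sum(axis=0)
            tot = np.maximum(tot, 1e-300)
            ll = float(np.sum(np.log(tot)))
            loglik.append(ll)
            resp = dens / tot
            nk = resp.sum(axis=1)
            if np.any(nk < 1e-8):
                return None
            w = nk / n
            mu = resp @ x / nk
            var = np.array([resp[j] @ (x - mu[j]) ** 2 / nk[j]
                            for j in range(2)])
            if np.any(var < var_floor):
                return None
            if len(loglik) > 1 and abs(loglik[-1] - loglik[-2]) < self.tol:
                converged = True
                break
        return {"w": w, "mu": mu, "var": var, "loglik": loglik,
                "converged": converged}

    def posterior_nonnull(self, X) -> np.ndarray:
        """Posterior probability of the non-null component for each value."""
        x = np.asarray(X, float).ravel()
        d0 = self.weights_[0] * norm.pdf(x, self.means_[0],
                                         np.sqrt(self.variances_[0]))
        d1 = self.weights_[1] * norm.pdf(x, self.means_[1],
                                         np.sqrt(self.variances_[1]))
        tot = np.maximum(d0 + d1, 1e-300)
        return d1 / tot

    predict_proba = posterior_nonnull


def fit_two_component_mixture(stats, tol: float = 1e-8, max_iter: int = 2000,
                              n_starts: int = 5, random_state=None
                              ) -> TwoComponentMixture:
    """Functional wrapper around :class:`TwoComponentMixture`."""
    return TwoComponentMixture(tol=tol, max_iter=max_iter, n_starts=n_starts,
                               random_state=random_state).fit(stats)


def fold_from_log2(d: float):
    """Signed fold change from a log2 difference.

    Down-regulation (d < 0) is reported as the negated reciprocal:
    d = 3 -> 8.0, d = -3 -> -8.0, d = 0 -> 1.0.
    """
    d = np.asarray(d, float)
    out = np.where(d >= 0, np.exp2(d), -np.exp2(-d))
    return float(out) if out.ndim == 0 else out


def call_de(contrast_stats: pd.DataFrame, fit: TwoComponentMixture,
            fdr_target: float = 0.01) -> pd.DataFrame:
    """Select DE genes for one contrast at the posterior-based FDR target.

    Genes are ranked by non-null posterior; the declared set is the largest
    prefix whose estimated FDR (mean of 1 - posterior over the prefix) is
    below ``fdr_target``.  An empty selection is a valid outcome.
    """
    df = contrast_stats.copy()
    df["posterior"] = fit.posterior_nonnull(df["statistic"].to_numpy())
    order = np.argsort(-df["posterior"].to_numpy(), kind="stable")
    post_sorted = df["posterior"].to_numpy()[order]
    est_fdr = np.cumsum(1.0 - post_sorted) / np.arange(1, len(df) + 1)
    k = int(np.max(np.nonzero(est_fdr < fdr_target)[0]) + 1) \
        if np.any(est_fdr < fdr_target) else 0
    flag = np.zeros(len(df), bool)
    flag[order[:k]] = True
    df["de_flag"] = flag
    df["log2_diff"] = df["raw_diff"]
    df["fold_change"] = fold_from_log2(df["raw_diff"].to_numpy())
    return df


def summarise_de(results: pd.DataFrame,
                 chromosome_map: pd.Series | dict | None = None) -> dict:
    """Per-contrast DE counts, pairwise overlaps and per-chromosome tallies."""
    de = results[results["de_flag"]]
    sets = {c: set(de.loc[de["contrast"] == c, "gene_id"])
            for c in CONTRAST_PAIRS}
    counts = {c: len(s) for c, s in sets.items()}
    overlaps = {}
    names = list(CONTRAST_PAIRS)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlaps[f"{a}&{b}"] = len(sets[a] & sets[b])
    overlaps["&".join(names)] = len(sets[names[0]] & sets[names[1]]
                                    & sets[names[2]])
    summary = {"counts": counts, "overlaps": overlaps,
               "total_genes": len(set().union(*sets.values()))}
    if chromosome_map is not None:
        cmap = pd.Series(chromosome_map)
        chrom_rows = []
        for c, s in sets.items():
            chroms = cmap.reindex(sorted(s)).fillna("unplaced")
            tab = chroms.value_counts().to_dict()
            for chrom, n in sorted(tab.items(), key=lambda kv: str(kv[0])):
                chrom_rows.append({"contrast": c, "chromosome": chrom,
                                   "n_de": int(n)})
        summary["per_chromosome"] = pd.DataFrame(
            chrom_rows, columns=["contrast", "chromosome", "n_de"])
    return summary
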