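"""REML fitting of the gene-expression normalization mixed model.

The model for a background-adjusted log2 intensity is

    y = mu + C + G + AG + DG + HG + SG + eps

with a fixed comparison effect C per (chip, array, dye) channel and mutually
independent i.i.d. normal random effects: gene G, array-position-by-gene AG,
dye-by-gene DG, horn-phenotype-by-gene HG and sex-by-gene SG, plus residual
eps.  The quantities of scientific interest are the HG best linear unbiased
predictions (BLUPs) — the per-gene normalized expression value of each
phenotype — and their prediction-error variances, from which downstream
phenotype contrasts are standardised.

Because every random effect is gene-indexed, the mixed-model equations have
an arrowhead structure: a dense block for the channel effects plus one small
independent block per gene.  Solves, inverse blocks (traces for EM-REML and
prediction-error variances) and log-determinants are computed exactly by
absorbing the per-gene blocks, so no generic sparse solver is needed.
Variance components are estimated by EM-REML accelerated with
average-information (AI) candidate steps; at every iteration the EM and AI
candidates are scored by the REML log-likelihood and the better one is
accepted, so the accepted log-likelihood is monotone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .simulate import PHENOTYPES, SEXES

logger = logging.getLogger(__name__)

#: order of the variance components throughout this module
COMPONENTS = ("var_g", "var_ag", "var_dg", "var_hg", "var_sg")


@dataclass
class ModelData:
    """Factorised incidence structure of the model for one data set."""

    y: np.ndarray                 # (n,) responses
    gene_idx: np.ndarray          # (n,) 0..G-1
    chan_idx: np.ndarray          # (n,) 0..p-1 fixed comparison level
    slot_idx: np.ndarray          # (n, 5) within-gene random-effect slots
    genes: np.ndarray             # gene labels
    channels: pd.DataFrame        # channel level table (chip, array, dye)
    n_arrays: int                 # array positions per chip
    dropped_genes: list = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_slots(self) -> int:
        return 1 + self.n_arrays + 2 + 3 + 2

    def slot_slices(self) -> dict:
        """Slot ranges of each random factor inside a gene block."""
        a = self.n_arrays
        return {"var_g": slice(0, 1),
                "var_ag": slice(1, 1 + a),
                "var_dg": slice(1 + a, 3 + a),
                "var_hg": slice(3 + a, 6 + a),
                "var_sg": slice(6 + a, 8 + a)}


def build_design(qc: pd.DataFrame, design: pd.DataFrame) -> ModelData:
    """Merge QC output with the design table and factorise the model terms.

    Spots that failed QC (or have missing intensity) are excluded.  Genes with
    no passing observation are dropped (and listed); a phenotype with no
    observations at all is an error because the downstream contrasts would be
    undefined.
    """
    keys = ["chip", "array", "dye"]
    df = qc.merge(design[keys + ["phenotype", "sex"]], on=keys, how="left")
    if df["phenotype"].isna().any():
        raise ValueError("spots reference channels absent from the design table")
    all_genes = pd.unique(df["probe_id"])
    df = df[df["passed"] & df["log2_intensity"].notna()]
    if len(df) == 0:
        raise ValueError("no passing spots to model")
    missing_ph = set(PHENOTYPES) - set(df["phenotype"].unique())
    if missing_ph:
        raise ValueError(f"phenotypes without observations: {sorted(missing_ph)}")

    gene_codes, genes = pd.factorize(df["probe_id"], sort=True)
    dropped = sorted(set(all_genes) - set(genes))
    if dropped:
        logger.info("dropped %d genes with no passing spots: %s",
                    len(dropped), dropped[:20])

    chan_key = df[keys].astype(str).agg("|".join, axis=1)
    chan_codes, chan_levels = pd.factorize(chan_key, sort=True)
    channels = (df.assign(_c=chan_codes)[keys + ["_c"]]
                .drop_duplicates("_c").sort_values("_c")
                .reset_index(drop=True).drop(columns="_c"))

    n_arrays = int(design["array"].max())
    arr = df["array"].to_numpy(int) - 1
    dye = np.where(df["dye"].to_numpy() == "green", 1, 0)
    ph = df["phenotype"].map({p: i for i, p in enumerate(PHENOTYPES)}).to_numpy(int)
    sex = df["sex"].map({s: i for i, s in enumerate(SEXES)}).to_numpy(int)
    a = n_arrays
    slot_idx = np.column_stack([
        np.zeros(len(df), int), 1 + arr, 1 + a + dye, 3 + a + ph, 6 + a + sex])
    return ModelData(y=df["log2_intensity"].to_numpy(float),
                     gene_idx=gene_codes.astype(np.int64),
                     chan_idx=chan_codes.astype(np.int64),
                     slot_idx=slot_idx,
                     genes=np.asarray(genes),
                     channels=channels,
                     n_arrays=n_arrays,
                     dropped_genes=dropped)


class _SuffStats:
    """Cross-products needed by the arrowhead mixed-model equations."""

    def __init__(self, md: ModelData):
        n = len(md.y)
        G, p, m = md.n_genes, len(md.channels), md.n_slots
        self.n, self.p, self.m, self.G = n, p, m, G
        self.yty = float(md.y @ md.y)
        self.A_diag = np.bincount(md.chan_idx, minlength=p).astype(float)
        self.Xty = np.bincount(md.chan_idx, weights=md.y, minlength=p)
        self.ZtZ = np.zeros((G, m, m))
        self.Zty = np.zeros((G, m))
        self.B = np.zeros((G, p, m))
        g, c, S = md.gene_idx, md.chan_idx, md.slot_idx
        for i in range(5):
            np.add.at(self.Zty, (g, S[:, i]), md.y)
            np.add.at(self.B, (g, c, S[:, i]), 1.0)
            for j in range(5):
                np.add.at(self.ZtZ, (g, S[:, i], S[:, j]), 1.0)
        self.slot_slices = md.slot_slices()
        self.q = {k: G * (sl.stop - sl.start)
                  for k, sl in self.slot_slices.items()}
        self.q_tot = sum(self.q.values())


class _Solve:
    """One exact MME solve at a given set of variance components."""

    def __init__(self, ss: _SuffStats, sigma: dict):
        self.sigma = dict(sigma)
        se = sigma["var_e"]
        lam = np.empty(ss.m)
        for k, sl in ss.slot_slices.items():
            lam[sl] = se / sigma[k]
        D = ss.ZtZ + np.diag(lam)[None, :, :]
        self.Dinv = np.linalg.inv(D)
        self.T = np.einsum("gpm,gmn->gpn", ss.B, self.Dinv)  # B D^-1
        S = np.diag(ss.A_diag) - np.einsum("gpm,gqm->pq", self.T, ss.B)
        self.S_cho = cho_factor(S)
        rhs = ss.Xty - np.einsum("gpm,gm->p", self.T, ss.Zty)
        self.b = cho_solve(self.S_cho, rhs)
        self.u = np.einsum("gmn,gn->gm", self.Dinv,
                           ss.Zty - np.einsum("gpm,p->gm", ss.B, self.b))
        self.resid_quad = (ss.yty - self.b @ ss.Xty
                           - float(np.sum(self.u * ss.Zty)))
        sign, logdet_D = np.linalg.slogdet(D)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("non-PD gene block")
        logdet_S = 2.0 * float(np.sum(np.log(np.diag(self.S_cho[0]))))
        self.logdet_M = float(np.sum(logdet_D)) + logdet_S
        # inverse gene blocks of the MME coefficient matrix
        Sinv = cho_solve(self.S_cho, np.eye(ss.p))
        self.Cgg = self.Dinv + np.einsum(
            "gpm,pq,gqn->gmn", self.T, Sinv, self.T)
        diag = np.einsum("gmm->gm", self.Cgg)
        self.tr = {k: float(diag[:, sl].sum())
                   for k, sl in ss.slot_slices.items()}
        self.usq = {k: float(np.sum(self.u[:, sl] ** 2))
                    for k, sl in ss.slot_slices.items()}
        n, p = ss.n, ss.p
        self.neg2ll = ((n - p - ss.q_tot) * np.log(se)
                       + sum(ss.q[k] * np.log(sigma[k]) for k in COMPONENTS)
                       + self.logdet_M + self.resid_quad / se)
        self.ss = ss

    def solve_extra(self, Xtf: np.ndarray, Ztf: np.ndarray):
        """Solve the MME for extra right-hand sides (AI working vectors)."""
        rhs = Xtf - np.einsum("gpm,gmf->pf", self.T, Ztf)
        bF = cho_solve(self.S_cho, rhs)
        uF = np.einsum("gmn,gnf->gmf", self.Dinv,
                       Ztf - np.einsum("gpm,pf->gmf", self.ss.B, bF))
        return bF, uF


class DyeSwapMixedModel(BaseEstimator):
    """REML estimator of the six-variance-component normalization model.

    Parameters
    ----------
    tol : float
        Relative change in every variance component below which the fit is
        declared converged.
    loglik_tol : float
        Alternative convergence rule on the REML log-likelihood change
        (in -2 log L units).
    max_iter : int
        Iteration cap; hitting it flags the fit as non-converged.
    min_variance : float
        Lower truncation bound for variance updates.
    use_ai : bool
        Offer average-information candidate steps alongside EM updates.
    variance_components : dict or None
        If given (keys var_g, var_ag, var_dg, var_hg, var_sg, var_e), REML is
        skipped and BLUPs are solved at these fixed values.

    Attributes (after ``fit``)
    --------------------------
    variance_components_ : dict of the six estimates
    mu_, c_effects_ : overall mean and channel deviations (fixed solutions)
    hg_solutions_ : DataFrame gene x (Polled, Horned, Scurred) HG BLUPs
    hg_pev_ : (G, 3, 3) prediction-error covariances of the HG triples
    gene_solutions_ : Series of gene BLUPs
    converged_, n_iter_, loglik_path_, boundary_components_
    """

    def __init__(self, tol: float = 1e-6, loglik_tol: float = 1e-8,
                 max_iter: int = 200, min_variance: float = 1e-10,
                 use_ai: bool = True, variance_components: dict | None = None):
        self.tol = tol
        self.loglik_tol = loglik_tol
        self.max_iter = max_iter
        self.min_variance = min_variance
        self.use_ai = use_ai
        self.variance_components = variance_components

    # -- fitting -----------------------------------------------------------

    def fit(self, qc: pd.DataFrame, design: pd.DataFrame):
        return self.fit_model_data(build_design(qc, design))

    def fit_model_data(self, md: ModelData):
        ss = _SuffStats(md)
        self._md, self._ss = md, ss
        if self.variance_components is not None:
            sigma = {k: float(self.variance_components[k])
                     for k in COMPONENTS + ("var_e",)}
            sol = _Solve(ss, sigma)
            self.converged_, self.n_iter_ = True, 0
            self.loglik_path_ = [-0.5 * sol.neg2ll]
        else:
            sigma, sol = self._reml(ss)
        self._finalize(md, ss, sigma, sol)
        return self

    def _reml(self, ss: _SuffStats):
        var_y = ss.yty / ss.n - (float(np.mean(ss.Xty / np.maximum(ss.A_diag, 1)))) ** 2
        var_y = max(var_y, 1e-6)
        sigma = {k: 0.1 * var_y for k in COMPONENTS}
        sigma["var_e"] = 0.5 * var_y
        sol = _Solve(ss, sigma)
        self.loglik_path_ = [-0.5 * sol.neg2ll]
        self.converged_ = False
        it = 0
        for it in range(1, self.max_iter + 1):
            cand = [self._em_step(ss, sigma, sol)]
            if self.use_ai:
                ai = self._ai_step(ss, sigma, sol)
                if ai is not None:
                    cand.append(ai)
            best_sigma, best_sol = None, None
            for c_sigma in cand:
                try:
                    c_sol = _Solve(ss, c_sigma)
                except np.linalg.LinAlgError:
                    continue
                if best_sol is None or c_sol.neg2ll < best_sol.neg2ll:
                    best_sigma, best_sol = c_sigma, c_sol
            if best_sol is None:
                break
            rel = max(abs(best_sigma[k] - sigma[k]) / max(sigma[k], 1e-12)
                      for k in sigma)
            dll = sol.neg2ll - best_sol.neg2ll
            sigma, sol = best_sigma, best_sol
            self.loglik_path_.append(-0.5 * sol.neg2ll)
            if rel < self.tol or abs(dll) < self.loglik_tol:
                self.converged_ = True
                break
        self.n_iter_ = it
        if not self.converged_:
            logger.warning("REML did not converge in %d iterations", it)
        return sigma, sol

    def _em_step(self, ss, sigma, sol) -> dict:
        se = sigma["var_e"]
        new = {}
        for k in COMPONENTS:
            new[k] = max((sol.usq[k] + se * sol.tr[k]) / ss.q[k],
                         self.min_variance)
        new["var_e"] = max(sol.resid_quad / (ss.n - ss.p), self.min_variance)
        return new

    def _ai_step(self, ss, sigma, sol):
        md = self._md
        se = sigma["var_e"]
        n = ss.n
        # working vectors f_k = Z_k u_k / s2_k and f_e = residual / s2_e
        uvals = sol.u[md.gene_idx[:, None], md.slot_idx]      # (n, 5)
        keys = list(COMPONENTS)
        F = np.empty((n, 6))
        for j, k in enumerate(keys):
            F[:, j] = uvals[:, j] / sigma[k]
        zu = uvals.sum(axis=1)
        e = md.y - sol.b[md.chan_idx] - zu
        F[:, 5] = e / se
        Xtf = np.zeros((ss.p, 6))
        Ztf = np.zeros((ss.G, ss.m, 6))
        for j in range(6):
            Xtf[:, j] = np.bincount(md.chan_idx, weights=F[:, j], minlength=ss.p)
            for i in range(5):
                np.add.at(Ztf[:, :, j], (md.gene_idx, md.slot_idx[:, i]), F[:, j])
        bF, uF = sol.solve_extra(Xtf, Ztf)
        FtF = F.T @ F
        quad = (FtF - Xtf.T @ bF
                - np.einsum("gmk,gml->kl", Ztf, uF)) / se
        AI = 0.5 * (quad + quad.T) / 2.0
        grad = np.empty(6)
        for j, k in enumerate(keys):
            lam_k = se / sigma[k]
            grad[j] = -0.5 * ((ss.q[k] - lam_k * sol.tr[k]) / sigma[k]
                              - sol.usq[k] / sigma[k] ** 2)
        tr_sum = sum((se / sigma[k]) * sol.tr[k] for k in keys)
        grad[5] = -0.5 * ((n - ss.p - ss.q_tot + tr_sum) / se
                          - float(e @ e) / se ** 2)
        try:
            delta = np.linalg.solve(AI, grad)
        except np.linalg.LinAlgError:
            return None
        theta = np.array([sigma[k] for k in keys] + [se]) + delta
        if not np.all(np.isfinite(theta)):
            return None
        new = {k: max(float(theta[j]), self.min_variance)
               for j, k in enumerate(keys)}
        new["var_e"] = max(float(theta[5]), self.min_variance)
        return new

    # -- results -----------------------------------------------------------

    def _finalize(self, md, ss, sigma, sol):
        self.variance_components_ = dict(sigma)
        self.loglik_ = self.loglik_path_[-1]
        self.boundary_components_ = [
            k for k in COMPONENTS if sigma[k] <= 10 * self.min_variance]
        if self.boundary_components_:
            logger.info("variance components at boundary: %s",
                        self.boundary_components_)
        self.mu_ = float(np.mean(sol.b))
        ch = md.channels.copy()
        ch["effect"] = sol.b - self.mu_
        self.c_effects_ = ch
        sl = ss.slot_slices
        self.gene_solutions_ = pd.Series(
            sol.u[:, 0], index=md.genes, name="gene_blup")
        hg = sol.u[:, sl["var_hg"]]
        self.hg_solutions_ = pd.DataFrame(hg, index=md.genes,
                                          columns=list(PHENOTYPES))
        self.hg_pev_ = sigma["var_e"] * sol.Cgg[:, sl["var_hg"], :][:, :, sl["var_hg"]]
        self.random_solutions_ = {
            k: sol.u[:, s] for k, s in sl.items()}
        self.genes_ = md.genes
        self.n_obs_ = ss.n
        self.dropped_genes_ = md.dropped_genes

    def fit_report(self) -> pd.DataFrame:
        """Variance components and diagnostics as a small table."""
        rows = [{"component": k, "estimate": v}
                for k, v in self.variance_components_.items()]
        rep = pd.DataFrame(rows)
        rep.attrs["converged"] = self.converged_
        rep.attrs["n_iter"] = self.n_iter_
        rep.attrs["loglik"] = self.loglik_
        return rep


def fit_reml(md: ModelData, tol: float = 1e-6, max_iter: int = 200,
             **kwargs) -> DyeSwapMixedModel:
    """Fit the model on a prepared :class:`ModelData`."""
    return DyeSwapMixedModel(tol=tol, max_iter=max_iter,
                             **kwargs).fit_model_data(md)


def extract_phenotype_profiles(fit: DyeSwapMixedModel) -> pd.DataFrame:
    """Per-gene normalized expression triple (Polled, Horned, Scurred).

    These are the phenotype-by-gene BLUPs on the log2 scale — the values the
    phenotype contrasts are computed from.
    """
    return fit.hg_solutions_.copy()
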