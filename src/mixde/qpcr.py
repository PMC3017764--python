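"""Relative quantification of qPCR validation data by the ddCt contrast.

Ct readings (threshold cycle numbers) for one target and one reference gene
across two phenotypes are fitted with the linear model

    Ct ~ phenotype + gene + phenotype:gene

and ddCt is the combinational-effect contrast CE1 - CE2 - CE3 + CE4 of the
four phenotype-by-gene cell means (e.g. for Polled vs Horned with DSC1 as
target and GAPDH as reference: polled-DSC1 - horned-DSC1 - polled-GAPDH +
horned-GAPDH).  The standard error and two-sided p-value come from the
t-distribution of that linear contrast.  Fold change is 2^(-ddCt), with
values below 1 reported as the negated reciprocal, so a negative ddCt means
higher expression in the first-named phenotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .simulate import CONTRAST_PAIRS


def ddct_to_fold(ddct: float) -> float:
    """Signed fold change from a ddCt estimate: 2^(-ddCt), negated-reciprocal
    convention for ratios below 1 (ddCt = -3 -> 8.0, ddCt = 3 -> -8.0)."""
    fold = 2.0 ** (-float(ddct))
    if fold >= 1.0:
        return fold
    return -1.0 / fold


class DdctEstimator(BaseEstimator):
    """Least-squares ddCt for one (contrast, target gene) pair.

    Parameters
    ----------
    contrast : 'PvH', 'PvS' or 'HvS' (first minus second phenotype).
    target, reference : gene names in the Ct table.
    average_technical : average technical replicates per (animal, gene)
        before fitting instead of entering each Ct as an observation.

    Attributes (after ``fit``)
    --------------------------
    ddct_, se_, p_value_, fold_, df_resid_, cell_means_
    """

    def __init__(self, contrast: str = "PvH", target: str = "DSC1",
                 reference: str = "GAPDH", average_technical: bool = False):
        self.contrast = contrast
        self.target = target
        self.reference = reference
        self.average_technical = average_technical

    def fit(self, records: pd.DataFrame, y=None):
        if self.contrast not in CONTRAST_PAIRS:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        ph_a, ph_b = CONTRAST_PAIRS[self.contrast]
        df = records[records["phenotype"].isin([ph_a, ph_b])
                     & records["gene"].isin([self.target, self.reference])]
        if (df["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        for ph in (ph_a, ph_b):
            for gene in (self.target, self.reference):
                if not ((df["phenotype"] == ph) & (df["gene"] == gene)).any():
                    raise ValueError(f"empty cell: ({ph}, {gene})")
        if self.average_technical:
            df = (df.groupby(["animal_id", "phenotype", "gene"],
                             as_index=False)["ct"].mean())

        # cell-mean coding: one column per (phenotype, gene) cell, no intercept
        cells = [(ph_a, self.target), (ph_b, self.target),
                 (ph_a, self.reference), (ph_b, self.reference)]
        X = np.column_stack([
            ((df["phenotype"] == ph) & (df["gene"] == g)).to_numpy(float)
            for ph, g in cells])
        fit = sm.OLS(df["ct"].to_numpy(float), X).fit()
        # CE1 - CE2 - CE3 + CE4
        L = np.array([1.0, -1.0, -1.0, 1.0])
        test = fit.t_test(L)
        self.ddct_ = float(np.squeeze(test.effect))
        self.se_ = float(np.squeeze(test.sd))
        self.p_value_ = float(np.squeeze(test.pvalue))
        self.fold_ = ddct_to_fold(self.ddct_)
        self.df_resid_ = int(fit.df_resid)
        self.cell_means_ = {c: float(b) for c, b in zip(cells, fit.params)}
        return self


def estimate_ddct(records: pd.DataFrame, contrast: str, target: str,
                  reference: str = "GAPDH",
                  average_technical: bool = False) -> dict:
    """Fit :class:`DdctEstimator` and return one report row as a dict."""
    est = DdctEstimator(contrast=contrast, target=target, reference=reference,
                        average_technical=average_technical).fit(records)
    return {"contrast": contrast, "gene": target, "ddct": est.ddct_,
            "se": est.se_, "p_value": est.p_value_, "fold": est.fold_}


def ddct_report(records: pd.DataFrame, targets, reference: str = "GAPDH",
                contrasts=("PvH", "PvS", "HvS")) -> pd.DataFrame:
    """ddCt table over all requested (contrast, target) pairs."""
    rows = [estimate_ddct(records, c, t, reference)
            for c in contrasts for t in targets]
    return pd.DataFrame(rows)
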