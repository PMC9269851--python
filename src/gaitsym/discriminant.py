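"""Canonical linear discriminant analysis with Wilks' Lambda.

Used to quantify how much the symmetry index and the normalized walking
speed each contribute to separating the age groups within one speed
condition.  Solves the between/within scatter generalized eigenproblem,
reports per-function eigenvalues and percent of discriminating variance,
Wilks' Lambda with Bartlett's chi-square approximation for functions j..J,
and the structure matrix (pooled within-group correlations between each
input variable and the discriminant scores).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps


class LdaError(ValueError):
    pass


@dataclass
class LdaResult:
    eigenvalues: np.ndarray  # one per discriminant function, descending
    proportions: np.ndarray  # percent of discriminating variance, sums to 100
    wilks_lambda: np.ndarray  # Lambda for functions j..J
    chi2: np.ndarray
    dof: np.ndarray
    p_values: np.ndarray
    structure_matrix: pd.DataFrame  # variables x functions
    coefficients: np.ndarray  # raw canonical coefficients (features x functions)
    feature_names: list
    n: int
    n_groups: int

    def table(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.eigenvalues)):
            row = {"function": i + 1, "eigenvalue": self.eigenvalues[i],
                   "pct_variance": self.proportions[i],
                   "wilks_lambda": self.wilks_lambda[i], "chi2": self.chi2[i],
                   "df": self.dof[i], "p": self.p_values[i]}
            for name in self.feature_names:
                row[f"loading_{name}"] = float(
                    self.structure_matrix.loc[name].iloc[i])
            rows.append(row)
        return pd.DataFrame(rows)


def lda_per_condition(table: pd.DataFrame,
                      features=("si", "normalized_speed"),
                      label_col: str = "group") -> LdaResult:
    """Canonical discriminant analysis of ``features`` against ``label_col``.

    ``table`` is one condition's slice with one row per participant.
    """
    features = list(features)
    X = table[features].to_numpy(float)
    labels = table[label_col].to_numpy()
    ok = np.all(np.isfinite(X), axis=1)
    X, labels = X[ok], labels[ok]
    uniq = pd.unique(labels)
    n, p = X.shape
    j = len(uniq)
    if p < 2 or j < 3:
        raise LdaError("need >= 2 features and >= 3 groups")
    if n <= p + j:
        raise LdaError("too few observations for discriminant analysis")

    grand = X.mean(axis=0)
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    for g in uniq:
        sub = X[labels == g]
        mu = sub.mean(axis=0)
        d = sub - mu
        sw += d.T @ d
        diff = (mu - grand)[:, None]
        sb += sub.shape[0] * (diff @ diff.T)

    for i, name in enumerate(features):
        if sw[i, i] <= 0:
            raise LdaError(f"feature {name!r} has zero within-group variance; "
                           "within-group scatter is singular")
    if np.linalg.cond(sw) > 1e12:
        raise LdaError("within-group scatter matrix is numerically singular")

    n_func = min(p, j - 1)
    evals, evecs = linalg.eigh(sb, sw)  # ascending
    order = np.argsort(evals)[::-1][:n_func]
    lam = np.clip(evals[order], 0.0, None)
    vecs = evecs[:, order]

    total = lam.sum()
    proportions = 100.0 * lam / total if total > 0 else np.full(n_func, np.nan)

    # Wilks' Lambda for functions i..J and Bartlett's chi-square approximation
    wilks = np.array([np.prod(1.0 / (1.0 + lam[i:])) for i in range(n_func)])
    chi2 = -(n - 1 - (p + j) / 2.0) * np.log(wilks)
    dof = np.array([(p - i) * (j - 1 - i) for i in range(n_func)], dtype=float)
    p_values = sps.chi2.sf(chi2, dof)

    # scale coefficients so discriminant scores have unit pooled within variance
    s_pooled = sw / (n - j)
    for i in range(n_func):
        scale = float(vecs[:, i] @ s_pooled @ vecs[:, i])
        if scale > 0:
            vecs[:, i] = vecs[:, i] / np.sqrt(scale)

    # structure matrix: pooled within-group correlation feature <-> score
    scores = X @ vecs
    aug = np.column_stack([X, scores])
    cov_w = np.zeros((aug.shape[1], aug.shape[1]))
    for g in uniq:
        sub = aug[labels == g]
        d = sub - sub.mean(axis=0)
        cov_w += d.T @ d
    cov_w /= (n - j)
    sd = np.sqrt(np.diag(cov_w))
    corr = cov_w / np.outer(sd, sd)
    loadings = corr[:p, p:]

    structure = pd.DataFrame(loadings, index=features,
                             columns=[f"function_{i+1}" for i in range(n_func)])
    return LdaResult(eigenvalues=lam, proportions=proportions, wilks_lambda=wilks,
                     chi2=chi2, dof=dof, p_values=p_values,
                     structure_matrix=structure, coefficients=vecs,
                     feature_names=features, n=n, n_groups=j)
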