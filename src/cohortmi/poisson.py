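"""Modified Poisson regression: risk ratios for a binary outcome.

A log-link Poisson working model applied to a 0/1 outcome gives consistent
estimates of risk ratios (unlike the odds ratio, the risk ratio is
collapsible, which matters once the outcome is common).  The Poisson
variance is wrong for a Bernoulli outcome, so inference uses the robust
HC0 sandwich variance ``A^-1 B A^-1`` with ``A`` the information matrix and
``B`` the sum of outer products of scores.  Estimation is delegated to
statsmodels' IRLS GLM with ``cov_type="HC0"``; this module adds complete-case
handling, rank diagnostics that name offending columns, and a compact result
container on both the log and risk-ratio scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import RankError

Z975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class FitResult:
    """Risk-ratio regression estimates with robust (sandwich) inference."""

    terms: list[str]
    beta: np.ndarray          # log risk ratio per term
    robust_se: np.ndarray
    n_used: int
    converged: bool
    diagnostics: str = ""

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.robust_se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.beta - Z975 * self.robust_se)
        hi = np.exp(self.beta + Z975 * self.robust_se)
        return np.column_stack([lo, hi])

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "beta": self.beta,
                "robust_se": self.robust_se,
                "rr": self.rr,
                "rr_lo": ci[:, 0],
                "rr_hi": ci[:, 1],
                "z": self.z,
                "p": self.p,
            },
            index=self.terms,
        )

    def p_for(self, columns: list[str]) -> float:
        """Smallest two-sided Wald p over the given design columns.

        Categorical variables expand to several indicator columns; the
        variable-level decision uses the minimum level-wise p-value.
        """
        idx = [self.terms.index(c) for c in columns]
        return float(np.min(self.p[idx]))


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return
    # identify offending columns by greedy QR build-up
    offending = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
        else:
            offending.append(names[j])
    raise RankError(
        "design matrix is rank deficient; collinear columns: "
        + ", ".join(offending)
    )


def fit(
    outcome: pd.Series,
    design: pd.DataFrame,
    weights: pd.Series | np.ndarray | None = None,
    check_rank: bool = True,
) -> FitResult:
    """Fit the modified Poisson model by IRLS on complete cases.

    Parameters
    ----------
    outcome:
        0/1 series (may contain NaN; those rows are dropped).
    design:
        Numeric design matrix including the intercept column (see
        :func:`cohortmi.design.build_design`); rows with any NaN are dropped
        and counted out of ``n_used``.
    weights:
        Optional frequency weights aligned with ``outcome``.

    Non-convergence or separation never yields a silent estimate: the result
    carries ``converged=False`` plus diagnostics.  A rank-deficient design
    raises :class:`RankError` naming the collinear columns.
    """
    y = pd.to_numeric(outcome, errors="raise")
    mask = y.notna() & design.notna().all(axis=1)
    if weights is not None:
        w = pd.Series(np.asarray(weights, dtype=float), index=y.index)
        mask &= w.notna()
        w = w[mask].to_numpy()
    else:
        w = None
    yv = y[mask].to_numpy(dtype=float)
    X = design.loc[mask]
    bad = set(np.unique(yv)) - {0.0, 1.0}
    if bad:
        raise ValueError(f"outcome must be coded 0/1; found {sorted(bad)}")
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if check_rank:
        _check_rank(Xv, names)
    model = sm.GLM(yv, Xv, family=sm.families.Poisson(), freq_weights=w)
    try:
        res = model.fit(cov_type="HC0", maxiter=100, tol=1e-8)
        converged = bool(res.converged) and np.all(np.isfinite(res.params))
        diag = "" if converged else "IRLS did not converge (possible separation)"
        beta = np.asarray(res.params, dtype=float)
        se = np.asarray(res.bse, dtype=float)
    except Exception as exc:  # pragma: no cover - defensive
        converged = False
        diag = f"fit failed: {exc}"
        beta = np.full(len(names), np.nan)
        se = np.full(len(names), np.nan)
    return FitResult(
        terms=names,
        beta=beta,
        robust_se=se,
        n_used=int(mask.sum()),
        converged=converged,
        diagnostics=diag,
    )


def wald_p(beta: float, se: float) -> float:
    """Two-sided Wald p-value ``2*Phi(-|beta/se|)``."""
    if se <= 0:
        raise ValueError("se must be positive")
    return float(2.0 * stats.norm.sf(abs(beta / se)))
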