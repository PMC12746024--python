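"""Session x Language mixed-effects analysis of ERP measures.

Each measure is modeled as ``value ~ Session * Language + (1 | subject)``
over the unbalanced longitudinal table.  Fixed effects use sum-to-zero
(effects) coding so that marginal (Type III) F-tests of each term are
obtained by testing its coefficient block.  The random-intercept model is
fit by REML; denominator degrees of freedom come from the Satterthwaite
approximation, which propagates the sampling covariance of the variance
parameters (from the observed REML information) into each contrast's
variance.  Partial eta-squared is computed from each F and its degrees of
freedom.  Maximum Bayes factors over the MMR window are natural-log
transformed before the same factorial analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats

logger = logging.getLogger(__name__)

__all__ = [
    "LmeResult", "RandomInterceptLme", "fit_random_intercept_reml",
    "fit_factorial_lme", "partial_eta_squared", "summarize_descriptives",
    "analyze_log_bf", "build_factorial_design",
]

SESSIONS = ("T1", "T2", "T3")
LANGUAGES = ("native", "nonnative")

TERMS = {
    "Session": (1, 2),
    "Language": (3,),
    "Session:Language": (4, 5),
}


@dataclass
class LmeResult:
    """One fixed-effect test: F, degrees of freedom, p, partial eta-squared."""

    term: str
    F: float
    df1: int
    df2: float
    p: float
    eta_p2: float

    def __post_init__(self) -> None:
        if self.F < 0 or self.df1 < 1 or not self.df2 > 0:
            raise ValueError("invalid F-test")
        expected = self.F * self.df1 / (self.F * self.df1 + self.df2)
        if abs(self.eta_p2 - expected) > 1e-6:
            raise ValueError("eta_p2 inconsistent with F and df")


def partial_eta_squared(F: float, df1: float, df2: float,
                        ndigits: int | None = None) -> float:
    """Effect size from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 < 1 or df2 <= 0:
        raise ValueError("need F >= 0, df1 >= 1, df2 > 0")
    value = F * df1 / (F * df1 + df2)
    return round(value, ndigits) if ndigits is not None else value


def build_factorial_design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum-to-zero coded design for Session (3) x Language (2).

    Returns (y is not included) the design matrix X with columns
    [intercept, S1, S2, L1, S1*L1, S2*L1], the group codes, and the response.
    """
    session = table["session"].to_numpy()
    language = table["language"].to_numpy()
    s1 = np.where(session == SESSIONS[0], 1.0, np.where(session == SESSIONS[2], -1.0, 0.0))
    s2 = np.where(session == SESSIONS[1], 1.0, np.where(session == SESSIONS[2], -1.0, 0.0))
    l1 = np.where(language == LANGUAGES[0], 1.0, -1.0)
    X = np.column_stack([np.ones(len(table)), s1, s2, l1, s1 * l1, s2 * l1])
    groups = pd.factorize(table["subject"])[0]
    return X, groups


class RandomInterceptLme:
    """REML fit of y = X beta + (1|group) + noise, with Satterthwaite tests."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.groups = np.asarray(groups)
        self.n, self.p = self.X.shape
        order = np.argsort(self.groups, kind="stable")
        Xs, ys, gs = self.X[order], self.y[order], self.groups[order]
        _, starts = np.unique(gs, return_index=True)
        bounds = list(starts) + [self.n]
        self._blocks = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            Xj, yj = Xs[a:b], ys[a:b]
            self._blocks.append((
                b - a, Xj.T @ Xj, Xj.sum(axis=0), Xj.T @ yj,
                yj.sum(), float(yj @ yj),
            ))
        self.singular = False
        self._fit()

    # -- REML machinery -------------------------------------------------
    def _assemble(self, sigma2: float, sigma_b2: float):
        p = self.p
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        c = 0.0
        logdet = 0.0
        for nj, xtx, sx, xty, sy, yty in self._blocks:
            dj = sigma_b2 / (sigma2 * (sigma2 + nj * sigma_b2))
            A += xtx / sigma2 - dj * np.outer(sx, sx)
            bvec += xty / sigma2 - dj * sx * sy
            c += yty / sigma2 - dj * sy * sy
            logdet += (nj - 1) * np.log(sigma2) + np.log(sigma2 + nj * sigma_b2)
        return A, bvec, c, logdet

    def _neg_reml(self, theta: np.ndarray) -> float:
        sigma2, sigma_b2 = np.exp(theta[0]), np.exp(theta[1])
        A, bvec, c, logdet = self._assemble(sigma2, sigma_b2)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, bvec)
        rss = c - bvec @ beta
        if rss <= 0:
            return np.inf
        return 0.5 * (logdet + logdet_a + rss)

    def _profiled_neg_reml(self, log_lambda: float) -> tuple[float, float]:
        """REML criterion with the residual variance profiled out; returns
        (criterion, sigma2_hat) for a given variance ratio sigma_b2/sigma2."""
        lam = np.exp(log_lambda)
        A1, b1, c1, logdet1 = self._assemble(1.0, lam)
        sign, logdet_a = np.linalg.slogdet(A1)
        if sign <= 0:
            return np.inf, np.nan
        rss = c1 - b1 @ np.linalg.solve(A1, b1)
        if rss <= 0:
            return np.inf, np.nan
        dof = self.n - self.p
        sigma2 = rss / dof
        return 0.5 * (dof * np.log(sigma2) + logdet1 + logdet_a + dof), sigma2

    def _fit(self) -> None:
        res = optimize.minimize_scalar(
            lambda ll: self._profiled_neg_reml(ll)[0],
            bounds=(-25.0, 10.0), method="bounded",
            options={"xatol": 1e-10})
        log_lambda = float(res.x)
        _, sigma2 = self._profiled_neg_reml(log_lambda)
        self.sigma2 = float(sigma2)
        self.sigma_b2 = float(np.exp(log_lambda) * sigma2)
        if self.sigma_b2 < 1e-8 * self.sigma2:
            self.singular = True
            warnings.warn(
                "random-intercept variance estimated at the zero boundary; "
                "fixed-effect tests reduce to the no-random-intercept model",
                stacklevel=2)
        A, bvec, _, _ = self._assemble(self.sigma2, self.sigma_b2)
        self.beta = np.linalg.solve(A, bvec)
        self.vcov_beta = np.linalg.inv(A)
        self._theta_cov = self._observed_theta_cov()

    def _neg_reml_raw(self, sigma2: float, sigma_b2: float) -> float:
        if sigma2 <= 0 or sigma_b2 < 0:
            return np.inf
        return self._neg_reml(np.log([max(sigma2, 1e-300),
                                      max(sigma_b2, 1e-300)]))

    def _observed_theta_cov(self) -> np.ndarray:
        """Inverse observed information of the REML criterion in
        (sigma2, sigma_b2), by central finite differences."""
        th = np.array([self.sigma2, self.sigma_b2])
        h = np.maximum(1e-4 * np.maximum(np.abs(th), self.sigma2 * 1e-3), 1e-12)
        H = np.zeros((2, 2))
        f0 = self._neg_reml_raw(*th)
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                if i == j:
                    fp = self._neg_reml_raw(*(th + ei))
                    fm = self._neg_reml_raw(*np.maximum(th - ei, [1e-300, 0.0]))
                    H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
                else:
                    fpp = self._neg_reml_raw(*(th + ei + ej))
                    fpm = self._neg_reml_raw(*np.maximum(th + ei - ej, [1e-300, 0.0]))
                    fmp = self._neg_reml_raw(*np.maximum(th - ei + ej, [1e-300, 0.0]))
                    fmm = self._neg_reml_raw(*np.maximum(th - ei - ej, [1e-300, 0.0]))
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        if not np.all(np.isfinite(H)):
            return np.zeros((2, 2))
        return np.linalg.pinv(H)

    def _vcov_at(self, sigma2: float, sigma_b2: float) -> np.ndarray:
        A, _, _, _ = self._assemble(sigma2, max(sigma_b2, 0.0))
        return np.linalg.inv(A)

    def contrast_test(self, L: np.ndarray) -> tuple[float, int, float, float]:
        """Satterthwaite F-test of L beta = 0; returns (F, df1, df2, p)."""
        L = np.atleast_2d(np.asarray(L, float))
        q = L.shape[0]
        M = L @ self.vcov_beta @ L.T
        Lb = L @ self.beta
        F = float(Lb @ np.linalg.solve(M, Lb) / q)
        evals, evecs = np.linalg.eigh(M)
        th = np.array([self.sigma2, self.sigma_b2])
        h = np.maximum(1e-4 * np.maximum(np.abs(th), self.sigma2 * 1e-3), 1e-12)
        nus = []
        for d in range(q):
            ell = L.T @ evecs[:, d]
            grad = np.zeros(2)
            for i in range(2):
                e = np.eye(2)[i] * h[i]
                up = ell @ self._vcov_at(*(th + e)) @ ell
                lo_th = np.maximum(th - e, [1e-300, 0.0])
                lo = ell @ self._vcov_at(*lo_th) @ ell
                grad[i] = (up - lo) / (th[i] + e[i] - lo_th[i])
            denom = float(grad @ self._theta_cov @ grad)
            lam = float(evals[d])
            nu = 2.0 * lam ** 2 / denom if denom > 0 else np.inf
            nus.append(nu)
        if q == 1:
            df2 = nus[0]
        else:
            finite = [nu for nu in nus if nu > 2]
            E = sum(nu / (nu - 2.0) for nu in finite) if finite else 0.0
            df2 = 2.0 * E / (E - q) if E > q else np.inf
        if not np.isfinite(df2) or df2 <= 0:
            df2 = float(self.n - self.p)
        p = float(sstats.f.sf(F, q, df2))
        return F, q, float(df2), p


def fit_random_intercept_reml(y, X, groups) -> RandomInterceptLme:
    return RandomInterceptLme(y, X, groups)


def _validate_table(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    required = {"subject", "session", "language", measure}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"measures table missing columns {sorted(missing)}")
    df = table.dropna(subset=[measure]).copy()
    dup = df.duplicated(subset=["subject", "session", "language"])
    if dup.any():
        raise ValueError("at most one row per subject x session x language")
    bad_sessions = set(df["session"]) - set(SESSIONS)
    if bad_sessions:
        raise ValueError(f"unknown sessions {sorted(bad_sessions)}")
    bad_langs = set(df["language"]) - set(LANGUAGES)
    if bad_langs:
        raise ValueError(f"unknown languages {sorted(bad_langs)}")
    return df


def fit_factorial_lme(table: pd.DataFrame, measure: str) -> list[LmeResult]:
    """Fit value ~ Session * Language + (1 | subject) and return marginal
    Type III Satterthwaite F-tests for Session, Language and the interaction,
    each with partial eta-squared."""
    df = _validate_table(table, measure)
    if df["session"].nunique() < 2 or df["language"].nunique() < 2:
        raise ValueError("need >= 2 sessions and both languages represented")
    if df["subject"].nunique() < 10:
        raise ValueError("need >= 10 subjects")
    X, groups = build_factorial_design(df)
    y = df[measure].to_numpy(float)
    if np.var(y) == 0:
        # degenerate constant response: no evidence for any effect
        df2 = float(max(len(y) - X.shape[1], 1))
        return [LmeResult(term, 0.0, len(cols), df2, 1.0, 0.0)
                for term, cols in TERMS.items()]
    model = RandomInterceptLme(y, X, groups)
    results = []
    for term, cols in TERMS.items():
        L = np.zeros((len(cols), X.shape[1]))
        for r, c in enumerate(cols):
            L[r, c] = 1.0
        F, df1, df2, p = model.contrast_test(L)
        results.append(LmeResult(term, F, df1, df2, p,
                                 partial_eta_squared(F, df1, df2)))
    return results


def summarize_descriptives(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Per session x language cell: mean, sample SD (n-1), and N."""
    df = _validate_table(table, measure)
    if df.empty:
        raise ValueError("measures table is empty")
    rows = []
    for session in SESSIONS:
        for language in LANGUAGES:
            cell = df[(df["session"] == session) & (df["language"] == language)][measure]
            rows.append({
                "session": session, "language": language,
                "mean": cell.mean() if len(cell) else np.nan,
                "sd": cell.std(ddof=1) if len(cell) >= 2 else np.nan,
                "n": int(len(cell)),
            })
    return pd.DataFrame(rows)


def analyze_log_bf(table: pd.DataFrame, bf_column: str = "bf_max",
                   strong: float = 10.0) -> tuple[list[LmeResult], pd.DataFrame]:
    """Factorial LME on natural-log maximum Bayes factors, plus the per-cell
    proportion of subjects with strong evidence (BF > 10, strict)."""
    df = _validate_table(table, bf_column)
    if (df[bf_column] <= 0).any():
        raise ValueError("Bayes factors must be positive")
    df = df.assign(log_bf=np.log(df[bf_column].to_numpy(float)))
    results = fit_factorial_lme(df, "log_bf")
    rows = []
    for session in SESSIONS:
        for language in LANGUAGES:
            cell = df[(df["session"] == session) & (df["language"] == language)]
            prop = float((cell[bf_column] > strong).mean()) if len(cell) else np.nan
            rows.append({"session": session, "language": language,
                         "prop_strong": prop, "n": int(len(cell))})
    return results, pd.DataFrame(rows)
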