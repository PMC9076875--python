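"""Stage-specific path analysis of multidiversity drivers.

The model is an observed-variable recursive path model: exogenous drivers
(time since deglaciation, mean growth-season soil temperature, optionally pH
and nutrients) send directed effects to the Shannon diversities of the five
organismal groups (the mediators), the mediators send directed effects to
multidiversity (the outcome), and the mediator residuals covary freely
pairwise.  Residual covariance that survives conditioning on the shared
abiotic drivers is the model's proxy for biotic interactions among groups;
positive community covariance suggests facilitation.

Estimation is normal-theory maximum likelihood on the sample covariance
matrix: with S the (standardised) sample covariance and Sigma(theta) the
model-implied covariance, the discrepancy

    F(theta) = log|Sigma| + tr(S Sigma^-1) - log|S| - p

is minimised and chi2 = (n - 1) F_min.  Standard errors come from the
inverse Hessian of F (normal-theory ACOV), indirect effects from the product
rule with delta-method (or bootstrap) standard errors, and global fit from
chi2 / CFI / TLI / RMSEA (with a noncentral-chi2 confidence interval) / SRMR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "PathModelSpec",
    "PathModel",
    "PathResults",
    "standardize",
    "stepwise_exogenous_pruning",
]


def standardize(data: pd.DataFrame) -> pd.DataFrame:
    """Center to mean 0 and scale to sd 1 (ddof=1) every column."""
    sd = data.std(ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"constant columns cannot be standardised: {bad}")
    return (data - data.mean()) / sd


@dataclass(frozen=True)
class PathModelSpec:
    """Structure of the path model.

    Parameters
    ----------
    exogenous
        Driver column names (order fixes reporting order).
    mediators
        Group-diversity column names.
    outcome
        Outcome column name (multidiversity).
    outcome_mode
        ``"free"`` estimates mediator->outcome paths; ``"fixed_composite"``
        fixes them to ``composite_weights`` (default equal), treating the
        outcome as a built index rather than a freely mediated response.
    include_direct
        Also estimate direct exogenous->outcome paths (saturates the model
        when all are included).
    zero_paths
        (exogenous, mediator) pairs whose directed path is fixed to zero
        while the variable stays in the model — used for nested
        likelihood-ratio tests of a driver's joint contribution.
    """

    exogenous: tuple[str, ...]
    mediators: tuple[str, ...]
    outcome: str = "mD"
    outcome_mode: str = "free"
    include_direct: bool = False
    composite_weights: tuple[float, ...] | None = None
    zero_paths: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "exogenous", tuple(self.exogenous))
        object.__setattr__(self, "mediators", tuple(self.mediators))
        object.__setattr__(
            self, "zero_paths", tuple(tuple(p) for p in self.zero_paths)
        )
        if self.outcome_mode not in ("free", "fixed_composite"):
            raise ValueError("outcome_mode must be 'free' or 'fixed_composite'")
        if len(self.mediators) < 1 or len(self.exogenous) < 1:
            raise ValueError("need at least one exogenous and one mediator variable")

    @property
    def variables(self) -> list[str]:
        return list(self.exogenous) + list(self.mediators) + [self.outcome]


class PathModel:
    """Maximum-likelihood path model on standardised plot data.

    Parameters
    ----------
    data
        Plots x variables table containing every variable in ``spec``;
        complete cases only (rows with NaN are dropped with a warning).
    spec
        Model structure.
    standardize_data
        Standardise columns before fitting (the conventional treatment; all
        coefficients are then standardised betas).
    """

    def __init__(self, data: pd.DataFrame, spec: PathModelSpec, standardize_data: bool = True):
        missing = [v for v in spec.variables if v not in data.columns]
        if missing:
            raise ValueError(f"data lacks model variables {missing}")
        d = data[spec.variables].astype(float)
        if d.isna().any().any():
            n0 = len(d)
            d = d.dropna()
            warnings.warn(
                f"dropped {n0 - len(d)} incomplete cases", RuntimeWarning, stacklevel=2
            )
        self.spec = spec
        self.data = standardize(d) if standardize_data else d
        self.n = len(d)
        self._build_index()
        if self.n <= self.n_free:
            raise ValueError(
                f"n = {self.n} must exceed the {self.n_free} free parameters"
            )
        self.S = np.cov(self.data.to_numpy(), rowvar=False, ddof=1)
        # guard: the sample covariance itself must be PD
        try:
            linalg.cholesky(self.S, lower=True)
        except linalg.LinAlgError as e:
            raise ValueError("sample covariance is not positive definite") from e
        sign, self._logdet_S = np.linalg.slogdet(self.S)
        self.p = len(spec.variables)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, spec: PathModelSpec, **kw
    ) -> "PathModel":
        return cls(data, spec, **kw)

    # -- parameter bookkeeping --------------------------------------------
    def _build_index(self) -> None:
        s = self.spec
        q, m = len(s.exogenous), len(s.mediators)
        self._q, self._m = q, m
        idx: dict[tuple, int] = {}
        k = 0
        zero = set(s.zero_paths)
        for med in s.mediators:           # a-paths (unless fixed to zero)
            for exo in s.exogenous:
                if (exo, med) in zero:
                    continue
                idx[("a", exo, med)] = k
                k += 1
        if s.outcome_mode == "free":      # b-paths
            for med in s.mediators:
                idx[("b", med)] = k
                k += 1
        if s.include_direct:              # direct exo -> outcome
            for exo in s.exogenous:
                idx[("c", exo)] = k
                k += 1
        for v in list(s.mediators) + [s.outcome]:   # residual variances
            idx[("psi", v)] = k
            k += 1
        for m1, m2 in combinations(s.mediators, 2):  # residual covariances
            idx[("psi", m1, m2)] = k
            k += 1
        for i, e1 in enumerate(s.exogenous):         # exogenous (co)variances
            for e2 in s.exogenous[i:]:
                idx[("phi", e1, e2)] = k
                k += 1
        self._idx = idx
        self.n_free = k

    def _weights(self) -> np.ndarray:
        s = self.spec
        if s.composite_weights is not None:
            w = np.asarray(s.composite_weights, dtype=float)
            if w.size != self._m:
                raise ValueError("composite_weights length must match mediators")
            return w
        return np.full(self._m, 1.0 / self._m)

    def implied_sigma(self, theta: np.ndarray) -> np.ndarray:
        """Model-implied covariance in variable order exo + mediators + outcome."""
        s, idx = self.spec, self._idx
        q, m = self._q, self._m
        r = m + 1  # endogenous block
        Gamma = np.zeros((r, q))
        for i, med in enumerate(s.mediators):
            for j, exo in enumerate(s.exogenous):
                key = ("a", exo, med)
                if key in idx:
                    Gamma[i, j] = theta[idx[key]]
        if s.include_direct:
            for j, exo in enumerate(s.exogenous):
                Gamma[m, j] = theta[idx[("c", exo)]]
        B = np.zeros((r, r))
        b = (
            np.array([theta[idx[("b", med)]] for med in s.mediators])
            if s.outcome_mode == "free"
            else self._weights()
        )
        B[m, :m] = b
        Psi = np.zeros((r, r))
        for i, v in enumerate(list(s.mediators) + [s.outcome]):
            Psi[i, i] = theta[idx[("psi", v)]]
        for m1, m2 in combinations(s.mediators, 2):
            i, j = s.mediators.index(m1), s.mediators.index(m2)
            Psi[i, j] = Psi[j, i] = theta[idx[("psi", m1, m2)]]
        Phi = np.zeros((q, q))
        for i, e1 in enumerate(s.exogenous):
            for jj, e2 in enumerate(s.exogenous[i:], start=i):
                Phi[i, jj] = Phi[jj, i] = theta[idx[("phi", e1, e2)]]
        A = linalg.solve(np.eye(r) - B, np.eye(r))
        cov_y = A @ (Gamma @ Phi @ Gamma.T + Psi) @ A.T
        cov_yx = A @ Gamma @ Phi
        Sigma = np.empty((q + r, q + r))
        Sigma[:q, :q] = Phi
        Sigma[q:, :q] = cov_yx
        Sigma[:q, q:] = cov_yx.T
        Sigma[q:, q:] = cov_y
        return Sigma

    def discrepancy(self, theta: np.ndarray) -> float:
        """Normal-theory ML discrepancy F(theta); large penalty off the PD cone."""
        Sigma = self.implied_sigma(theta)
        try:
            c = linalg.cholesky(Sigma, lower=True)
        except linalg.LinAlgError:
            return 1e10
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        inv = linalg.cho_solve((c, True), np.eye(self.p))
        f = logdet + float(np.sum(self.S * inv)) - self._logdet_S - self.p
        return f if np.isfinite(f) else 1e10

    # -- start values ------------------------------------------------------
    def _start(self) -> np.ndarray:
        """Regression-based start: per-equation OLS and residual moments."""
        s, idx = self.spec, self._idx
        d = self.data
        theta = np.zeros(self.n_free)
        X = d[list(s.exogenous)].to_numpy()
        Xc = np.column_stack([np.ones(self.n), X])
        resid = {}
        for med in s.mediators:
            yv = d[med].to_numpy()
            coef, *_ = np.linalg.lstsq(Xc, yv, rcond=None)
            for j, exo in enumerate(s.exogenous):
                key = ("a", exo, med)
                if key in idx:
                    theta[idx[key]] = coef[1 + j]
            resid[med] = yv - Xc @ coef
        M = d[list(s.mediators)].to_numpy()
        Zc = np.column_stack([np.ones(self.n), M] + ([X] if s.include_direct else []))
        yo = d[s.outcome].to_numpy()
        coef, *_ = np.linalg.lstsq(Zc, yo, rcond=None)
        if s.outcome_mode == "free":
            for i, med in enumerate(s.mediators):
                theta[idx[("b", med)]] = coef[1 + i]
            bvec = coef[1 : 1 + self._m]
        else:
            bvec = self._weights()
        if s.include_direct:
            for j, exo in enumerate(s.exogenous):
                theta[idx[("c", exo)]] = coef[1 + self._m + j]
        r_out = yo - M @ bvec
        if s.include_direct:
            r_out = r_out - X @ coef[1 + self._m :]
        for v in s.mediators:
            theta[idx[("psi", v)]] = max(np.var(resid[v], ddof=1), 1e-4)
        theta[idx[("psi", s.outcome)]] = max(np.var(r_out, ddof=1), 1e-4)
        for m1, m2 in combinations(s.mediators, 2):
            theta[idx[("psi", m1, m2)]] = float(
                np.cov(resid[m1], resid[m2], ddof=1)[0, 1]
            )
        Phi_s = np.cov(X, rowvar=False, ddof=1).reshape(self._q, self._q)
        for i, e1 in enumerate(s.exogenous):
            for jj, e2 in enumerate(s.exogenous[i:], start=i):
                theta[idx[("phi", e1, e2)]] = Phi_s[i, jj]
        return theta

    # -- fitting -----------------------------------------------------------
    def fit(self, tol: float = 1e-10, maxiter: int = 5000) -> "PathResults":
        """Minimise the ML discrepancy from the regression-based start.

        The optimisation is deterministic (fixed start, quasi-Newton), so
        refitting the same data reproduces the estimates exactly.
        """
        theta0 = self._start()
        res = optimize.minimize(
            self.discrepancy,
            theta0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-9},
        )
        # polish with Nelder-Mead if the quasi-Newton step stalled
        if not res.success:  # pragma: no cover - rare
            res = optimize.minimize(
                self.discrepancy, res.x, method="Nelder-Mead",
                options={"maxiter": 20000, "fatol": 1e-12, "xatol": 1e-10},
            )
        theta = res.x
        f_min = float(self.discrepancy(theta))
        Sigma = self.implied_sigma(theta)
        try:
            linalg.cholesky(Sigma, lower=True)
        except linalg.LinAlgError as e:  # pragma: no cover
            raise RuntimeError("implied covariance not PD at the solution") from e
        return PathResults(self, theta, f_min, Sigma, res)

    def _acov(self, theta: np.ndarray) -> np.ndarray:
        """Normal-theory ACOV(theta) = (2/(n-1)) H^-1, H the Hessian of F."""
        k = theta.size
        h = 1e-5 * np.maximum(np.abs(theta), 1.0)
        H = np.empty((k, k))
        f0 = self.discrepancy(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    fpp = self.discrepancy(theta + ei)
                    fmm = self.discrepancy(theta - ei)
                    H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
                else:
                    fpp = self.discrepancy(theta + ei + ej)
                    fpm = self.discrepancy(theta + ei - ej)
                    fmp = self.discrepancy(theta - ei + ej)
                    fmm = self.discrepancy(theta - ei - ej)
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        H = 0.5 * (H + H.T)
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:  # pragma: no cover
            Hinv = np.linalg.pinv(H)
        acov = (2.0 / (self.n - 1)) * Hinv
        return acov


# ---------------------------------------------------------------------------
# results


@dataclass
class PathResults:
    """Fitted path model: estimates, uncertainty, mediation, global fit."""

    model: PathModel
    theta: np.ndarray
    f_min: float
    implied: np.ndarray
    optim: object = field(repr=False)
    _acov: np.ndarray | None = field(default=None, repr=False)

    @property
    def acov(self) -> np.ndarray:
        """Normal-theory parameter covariance (computed on first use)."""
        if self._acov is None:
            self._acov = self.model._acov(self.theta)
        return self._acov

    # -- parameter access --------------------------------------------------
    def estimate(self, key: tuple) -> float:
        return float(self.theta[self.model._idx[key]])

    def se(self, key: tuple) -> float:
        i = self.model._idx[key]
        v = self.acov[i, i]
        return float(np.sqrt(v)) if v > 0 else np.nan

    def _wald(self, key: tuple) -> tuple[float, float, float]:
        est, se = self.estimate(key), self.se(key)
        z = est / se if se and np.isfinite(se) and se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        return est, se, p

    def params(self) -> pd.DataFrame:
        """Tidy table of every free parameter: estimate, SE, z, p."""
        rows = []
        s = self.model.spec
        for key, i in self.model._idx.items():
            est, se, p = self._wald(key)
            kind = key[0]
            if kind == "a":
                label = f"{key[1]} -> {key[2]}"
            elif kind == "b":
                label = f"{key[1]} -> {s.outcome}"
            elif kind == "c":
                label = f"{key[1]} -> {s.outcome} (direct)"
            elif kind == "psi" and len(key) == 2:
                label = f"resid var {key[1]}"
            elif kind == "psi":
                label = f"resid cov {key[1]} ~~ {key[2]}"
            else:
                label = f"cov {key[1]} ~~ {key[2]}" if key[1] != key[2] else f"var {key[1]}"
            rows.append(
                {
                    "kind": kind,
                    "path": label,
                    "estimate": est,
                    "se": se,
                    "z": est / se if se and se > 0 else np.nan,
                    "p": p,
                }
            )
        return pd.DataFrame(rows)

    def path_coefficients(self) -> pd.DataFrame:
        """Directed standardised paths only (a, b and direct c paths)."""
        t = self.params()
        return t[t["kind"].isin(("a", "b", "c"))].reset_index(drop=True)

    def residual_covariances(self) -> pd.DataFrame:
        t = self.params()
        return t[(t["kind"] == "psi") & t["path"].str.contains("~~")].reset_index(
            drop=True
        )

    # -- mediation ---------------------------------------------------------
    def indirect_effects(
        self,
        bootstrap: int = 0,
        seed: int | np.random.Generator | None = None,
    ) -> pd.DataFrame:
        """Indirect effect of each exogenous driver on the outcome.

        indirect(exo) = sum over mediators of a(exo->med) * b(med->outcome),
        with delta-method SE from the joint parameter covariance.  With
        ``bootstrap`` > 0, a nonparametric bootstrap SE (resampling plots,
        refitting, seeded) is appended for comparison.
        """
        s, idx = self.model.spec, self.model._idx
        bvec = (
            np.array([self.estimate(("b", med)) for med in s.mediators])
            if s.outcome_mode == "free"
            else self.model._weights()
        )
        rows = []
        for exo in s.exogenous:
            avec = np.array(
                [
                    self.estimate(("a", exo, med)) if ("a", exo, med) in idx else 0.0
                    for med in s.mediators
                ]
            )
            eff = float(avec @ bvec)
            g = np.zeros(self.theta.size)
            for i, med in enumerate(s.mediators):
                if ("a", exo, med) in idx:
                    g[idx[("a", exo, med)]] = bvec[i]
                if s.outcome_mode == "free":
                    g[idx[("b", med)]] = avec[i]
            var = float(g @ self.acov @ g)
            se = np.sqrt(var) if var > 0 else np.nan
            z = eff / se if se and se > 0 else np.nan
            rows.append(
                {
                    "exogenous": exo,
                    "indirect": eff,
                    "se": se,
                    "z": z,
                    "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                }
            )
        out = pd.DataFrame(rows)
        if bootstrap:
            out["se_boot"] = self._bootstrap_indirect(bootstrap, seed)
        return out

    def _bootstrap_indirect(self, n_boot: int, seed) -> np.ndarray:
        rng = np.random.default_rng(seed)
        s = self.model.spec
        raw = self.model.data
        effs = np.empty((n_boot, len(s.exogenous)))
        for b in range(n_boot):
            take = rng.integers(0, self.model.n, self.model.n)
            sample = raw.iloc[take].reset_index(drop=True)
            try:
                fit = PathModel(sample, s, standardize_data=True).fit()
                bvec = (
                    np.array([fit.estimate(("b", m)) for m in s.mediators])
                    if s.outcome_mode == "free"
                    else fit.model._weights()
                )
                for j, exo in enumerate(s.exogenous):
                    avec = np.array(
                        [
                            fit.estimate(("a", exo, m))
                            if ("a", exo, m) in fit.model._idx
                            else 0.0
                            for m in s.mediators
                        ]
                    )
                    effs[b, j] = float(avec @ bvec)
            except Exception:  # degenerate resample
                effs[b] = np.nan
        return np.nanstd(effs, axis=0, ddof=1)

    # -- global fit ---------------------------------------------------------
    @property
    def df(self) -> int:
        p = self.model.p
        return p * (p + 1) // 2 - self.model.n_free

    @property
    def chi2(self) -> float:
        return (self.model.n - 1) * self.f_min

    def _baseline(self) -> tuple[float, int]:
        """Independence baseline: free variances, free exogenous covariances."""
        S = self.model.S
        q = self.model._q
        p = self.model.p
        Sigma_b = np.diag(np.diag(S)).astype(float)
        Sigma_b[:q, :q] = S[:q, :q]
        sign, logdet_b = np.linalg.slogdet(Sigma_b)
        f_b = (
            logdet_b
            + float(np.trace(S @ np.linalg.inv(Sigma_b)))
            - self.model._logdet_S
            - p
        )
        n_free_b = p + q * (q - 1) // 2
        df_b = p * (p + 1) // 2 - n_free_b
        return (self.model.n - 1) * f_b, df_b

    def fit_indices(self, rmsea_ci: float = 0.90) -> dict:
        """chi2, CFI, TLI, RMSEA (+ CI) and SRMR; degenerate df flagged."""
        n = self.model.n
        chi2, df = self.chi2, self.df
        chi2_b, df_b = self._baseline()
        out = {"chi2": chi2, "df": df, "n": n}
        out["p_chi2"] = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
        if df <= 0:
            out.update(
                cfi=1.0, tli=np.nan, rmsea=0.0, rmsea_ci_lower=0.0,
                rmsea_ci_upper=0.0, srmr=self._srmr(), saturated=True,
            )
            return out
        d_t = max(chi2 - df, 0.0)
        d_b = max(chi2_b - df_b, 0.0)
        out["cfi"] = 1.0 - d_t / max(d_b, d_t, np.finfo(float).tiny)
        denom = chi2_b / df_b - 1.0
        out["tli"] = (
            (chi2_b / df_b - chi2 / df) / denom if denom != 0 else np.nan
        )
        out["rmsea"] = float(np.sqrt(d_t / (df * (n - 1))))
        lo, hi = _rmsea_ci(chi2, df, n, level=rmsea_ci)
        out["rmsea_ci_lower"] = lo
        out["rmsea_ci_upper"] = hi
        out["srmr"] = self._srmr()
        out["saturated"] = False
        return out

    def _srmr(self) -> float:
        S, Sigma = self.model.S, self.implied
        d = np.sqrt(np.diag(S))
        R = (S - Sigma) / np.outer(d, d)
        iu = np.triu_indices_from(R)
        return float(np.sqrt(np.mean(R[iu] ** 2)))

    def summary(self) -> str:
        """Human-readable fit report."""
        fi = self.fit_indices()
        lines = [
            f"Path model: {len(self.model.spec.exogenous)} exogenous -> "
            f"{len(self.model.spec.mediators)} mediators -> {self.model.spec.outcome}"
            f"  (n = {self.model.n})",
            f"chi2({fi['df']}) = {fi['chi2']:.3f}, p = {fi.get('p_chi2', float('nan')):.3f} | "
            f"CFI = {fi.get('cfi', float('nan')):.3f}, TLI = {fi.get('tli', float('nan')):.3f}, "
            f"RMSEA = {fi.get('rmsea', float('nan')):.3f} "
            f"[{fi.get('rmsea_ci_lower', float('nan')):.3f}, {fi.get('rmsea_ci_upper', float('nan')):.3f}], "
            f"SRMR = {fi.get('srmr', float('nan')):.3f}",
            "",
            self.path_coefficients().to_string(index=False, float_format="%.4f"),
            "",
            "Indirect effects:",
            self.indirect_effects().to_string(index=False, float_format="%.4f"),
        ]
        return "\n".join(lines)


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Noncentral-chi2 confidence interval for RMSEA."""
    alpha = 1.0 - level
    scale = df * (n - 1)

    def lam_for(prob: float) -> float:
        # find noncentrality with P(X >= chi2 | df, lam) = prob
        f = lambda lam: stats.ncx2.sf(chi2, df, lam) - prob
        if f(0.0) >= 0:
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) < 0 and hi < 1e7:
            hi *= 2
        return optimize.brentq(f, 0.0, hi, xtol=1e-8)

    lam_lo = lam_for(alpha / 2)
    lam_hi = lam_for(1.0 - alpha / 2)
    lo = float(np.sqrt(max(lam_lo, 0.0) / scale))
    hi = float(np.sqrt(max(lam_hi, 0.0) / scale))
    return min(lo, hi), max(lo, hi)


# ---------------------------------------------------------------------------
# stepwise pruning of extra exogenous drivers


def stepwise_exogenous_pruning(
    data: pd.DataFrame,
    full_spec: PathModelSpec,
    prunable: tuple[str, ...],
    alpha: float = 0.05,
) -> tuple[PathModelSpec, list[dict]]:
    """Drop extra exogenous drivers that show no significant effect.

    Candidates in ``prunable`` are removed one at a time — least significant
    first — whenever they have no significant direct effect on any mediator
    and no significant indirect effect on the outcome (Wald, two-sided,
    ``alpha``).  After every removal the model is refitted and the remaining
    candidates re-examined (an effect may become significant in the absence
    of a collinear driver).  Before a removal is accepted, a nested
    likelihood-ratio test compares the current model against one with the
    candidate's directed paths fixed to zero (same variable set); a
    significant Delta-chi2 keeps the driver, logged.  Returns the reduced
    spec and an audit trail of every decision.
    """
    unknown = [v for v in prunable if v not in full_spec.exogenous]
    if unknown:
        raise ValueError(f"prunable variables {unknown} not in the model")
    spec = full_spec
    trail: list[dict] = []
    retained: set[str] = set()
    while True:
        fit = PathModel(data, spec).fit()
        cands = [v for v in prunable if v in spec.exogenous and v not in retained]
        if not cands:
            break
        removable = []
        for v in cands:
            p_direct = [fit._wald(("a", v, med))[2] for med in spec.mediators]
            p_ind = float(fit.indirect_effects().set_index("exogenous").loc[v, "p"])
            significant = any(p < alpha for p in p_direct) or p_ind < alpha
            if not significant:
                removable.append((min(min(p_direct), p_ind), v))
        if not removable:
            trail.append(
                {"action": "stop", "reason": "remaining candidates significant"}
            )
            break
        # remove the candidate with the weakest evidence first
        _, victim = max(removable)
        # nested LR test: fix the victim's directed paths to zero, keeping
        # the variable in the covariance structure
        constrained = replace(
            spec,
            zero_paths=spec.zero_paths
            + tuple((victim, med) for med in spec.mediators),
        )
        fit_c = PathModel(data, constrained).fit()
        d_chi2 = fit_c.chi2 - fit.chi2
        d_df = fit.model.n_free - fit_c.model.n_free
        p_lr = float(stats.chi2.sf(max(d_chi2, 0.0), d_df)) if d_df > 0 else np.nan
        if d_df > 0 and p_lr < alpha:
            retained.add(victim)
            trail.append(
                {
                    "action": "retain",
                    "variable": victim,
                    "reason": f"removal degrades fit (delta-chi2 p = {p_lr:.4f})",
                }
            )
            continue
        trail.append(
            {
                "action": "remove",
                "variable": victim,
                "delta_chi2": float(d_chi2),
                "delta_df": int(d_df),
                "p_lr": p_lr,
            }
        )
        spec = replace(
            spec, exogenous=tuple(e for e in spec.exogenous if e != victim)
        )
    return spec, trail
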