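"""Multivariate stages: random-forest permutation importance with the
negative-importance threshold rule and a four-run stability protocol,
moderator regression with simple slopes, and beta regression.

The forest identifies predictors of activity from a mixed candidate set
without linear-model assumptions.  A predictor is *informative* when its
out-of-bag permutation importance exceeds the absolute value of the most
negative importance observed (noise variables fluctuate symmetrically
around zero, so the most negative score calibrates that fluctuation).  To
guard against seed luck, the model is refit four times with different tree
counts and seeds; only predictors informative in all four runs are reported
as consistently informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.tree import DecisionTreeRegressor
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "ForestConfig",
    "ImportanceResult",
    "RegressionResult",
    "forest_importance",
    "moderator_regression",
    "beta_regression",
]


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    mtry: int = 3
    min_node_size: int = 5
    seed: int = 0
    #: four (n_trees, seed) stability configurations; default varies the
    #: number of bootstrap samples and the seed across runs
    stability_runs: tuple = ()
    correlation_aware: bool = True
    #: |Spearman r| above which a covariate defines permutation strata
    correlation_cutoff: float = 0.2

    def resolved_stability_runs(self) -> tuple:
        if self.stability_runs:
            if len(self.stability_runs) != 4:
                raise ValueError("stability protocol requires exactly 4 runs")
            return tuple(self.stability_runs)
        return tuple(
            (n, self.seed + i + 1) for i, n in enumerate((250, 500, 750, 1000))
        )


@dataclass
class ImportanceResult:
    variables: list
    importances: dict  # run label -> per-variable importance array
    thresholds: dict  # run label -> threshold
    informative: dict  # run label -> set of informative variables
    consistently_informative: set = field(default_factory=set)

    def summary(self) -> str:
        df = pd.DataFrame(self.importances, index=self.variables)
        lines = ["OOB permutation importance (increase in MSE) by run:"]
        lines.append(df.round(4).to_string())
        lines.append(
            "thresholds: "
            + ", ".join(f"{k}={v:.4f}" for k, v in self.thresholds.items())
        )
        lines.append(
            "consistently informative: "
            + (", ".join(sorted(self.consistently_informative)) or "(none)")
        )
        return "\n".join(lines)


def _encode_predictors(X) -> tuple[np.ndarray, list]:
    """DataFrame -> numeric matrix; ordered categoricals/strings by rank code."""
    if isinstance(X, pd.DataFrame):
        cols = []
        names = list(X.columns)
        for c in X.columns:
            col = X[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                col = col.astype("category").cat.codes
            cols.append(col.to_numpy(dtype=float))
        return np.column_stack(cols), names
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _strata_map(Xm: np.ndarray, cutoff: float) -> dict[int, np.ndarray | None]:
    """For each predictor, quartile-bin labels of its most correlated
    covariate (|Spearman| > cutoff), used to stratify the permutation."""
    p = Xm.shape[1]
    if p < 2:
        return {0: None}
    rho = sps.spearmanr(Xm).statistic
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 0.0)
    out: dict[int, np.ndarray | None] = {}
    for j in range(p):
        partner = int(np.nanargmax(np.abs(rho[j])))
        if np.abs(rho[j, partner]) <= cutoff:
            out[j] = None
            continue
        v = Xm[:, partner]
        qs = np.quantile(v, [0.25, 0.5, 0.75])
        out[j] = np.searchsorted(qs, v)
    return out


def _single_run_importance(
    Xm: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    seed: int,
    mtry: int,
    min_node_size: int,
    strata: dict[int, np.ndarray | None],
) -> np.ndarray:
    n, p = Xm.shape
    rng = np.random.default_rng(seed)
    increase = np.zeros(p)
    n_used = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if oob.size < 2:
            continue
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=min_node_size,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(Xm[boot], y[boot])
        X_oob = Xm[oob]
        # one stacked prediction call: baseline + each feature permuted
        stacked = np.tile(X_oob, (p + 1, 1))
        for j in range(p):
            col = X_oob[:, j].copy()
            st = strata.get(j)
            if st is None:
                perm = rng.permutation(oob.size)
            else:
                perm = np.arange(oob.size)
                labels = st[oob]
                for lab in np.unique(labels):
                    idx = np.where(labels == lab)[0]
                    perm[idx] = idx[rng.permutation(idx.size)]
            stacked[(j + 1) * oob.size : (j + 2) * oob.size, j] = col[perm]
        pred = tree.predict(stacked).reshape(p + 1, oob.size)
        base_mse = np.mean((y[oob] - pred[0]) ** 2)
        perm_mse = np.mean((y[oob] - pred[1:]) ** 2, axis=1)
        increase += perm_mse - base_mse
        n_used += 1
    return increase / np.maximum(n_used, 1)


def forest_importance(X, y, config: ForestConfig | None = None) -> ImportanceResult:
    """Regression-forest OOB permutation importance with the threshold rule.

    Trees are CART-style with ``mtry`` random candidate predictors per split,
    grown on bootstrap samples.  Importance is the mean out-of-bag increase
    in squared error after permuting each predictor (within quartile strata
    of its most correlated covariate when ``correlation_aware``).  The
    informativeness threshold is |most negative importance| (0 when no
    importance is negative); the stability protocol intersects the
    informative sets of four runs.
    """
    config = config or ForestConfig()
    Xm, names = _encode_predictors(X)
    y = np.asarray(y, dtype=float)
    if Xm.shape[0] != len(y):
        raise ValueError("X and y length mismatch")
    if Xm.shape[0] < 10:
        raise ValueError("need at least 10 observations")
    if np.all(y == y[0]):
        raise ValueError("constant outcome: forest undefined")
    if config.mtry > Xm.shape[1]:
        raise ValueError(
            f"mtry ({config.mtry}) exceeds number of predictors ({Xm.shape[1]})"
        )
    strata = (
        _strata_map(Xm, config.correlation_cutoff)
        if config.correlation_aware
        else {j: None for j in range(Xm.shape[1])}
    )
    runs = config.resolved_stability_runs()
    importances: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    informative: dict[str, set] = {}
    for n_trees, seed in runs:
        label = f"trees={n_trees},seed={seed}"
        imp = _single_run_importance(
            Xm, y, n_trees, seed, config.mtry, config.min_node_size, strata
        )
        thr = max(0.0, -float(imp.min()))
        importances[label] = imp
        thresholds[label] = thr
        informative[label] = {
            names[j] for j in range(len(names)) if imp[j] > thr
        }
    consistent = set(names)
    for s in informative.values():
        consistent &= s
    return ImportanceResult(
        variables=names,
        importances=importances,
        thresholds=thresholds,
        informative=informative,
        consistently_informative=consistent,
    )


# ---------------------------------------------------------------------------
# regression


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    interaction_p: float | None = None
    simple_slopes: pd.DataFrame | None = None  # moderator value, slope, se
    phi: float | None = None
    phi_se: float | None = None
    method: str = ""

    def summary(self) -> str:
        df = pd.DataFrame({"coef": self.params, "se": self.bse, "p": self.pvalues})
        lines = [f"{self.method}", df.round(4).to_string(), f"R^2 = {self.r_squared:.4f}"]
        if self.phi is not None:
            lines.append(f"precision phi = {self.phi:.3f} (se {self.phi_se:.3f})")
        if self.simple_slopes is not None:
            lines.append("simple slopes:")
            lines.append(self.simple_slopes.round(4).to_string(index=False))
        return "\n".join(lines)


def moderator_regression(y, x, m) -> RegressionResult:
    """OLS moderator model on centred data with simple slopes.

    Fits ``y ~ xc + mc + xc:mc`` where xc, mc are mean-centred, and
    evaluates the slope of y on x at moderator values mean - 1 SD, mean,
    and mean + 1 SD, with standard errors from the coefficient covariance.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    n = len(y)
    if not (len(x) == len(m) == n):
        raise ValueError("y, x, m must have equal length")
    if n <= 10:
        raise ValueError("moderator regression needs n > 10")
    if np.any(np.isnan(y)) or np.any(np.isnan(x)) or np.any(np.isnan(m)):
        raise ValueError("missing values are not supported")
    if np.var(y) == 0:
        raise ValueError("constant outcome")
    xc = x - x.mean()
    mc = m - m.mean()
    design = np.column_stack([np.ones(n), xc, mc, xc * mc])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("collinear design (is x or m constant, or x == m?)")
    names = ["const", "x", "m", "x:m"]
    fit = sm.OLS(y, design).fit()
    cov = fit.cov_params()
    sd_m = mc.std(ddof=1)
    rows = []
    for label, m0 in (("mean - 1 SD", -sd_m), ("mean", 0.0), ("mean + 1 SD", sd_m)):
        slope = fit.params[1] + fit.params[3] * m0
        var = cov[1, 1] + m0**2 * cov[3, 3] + 2 * m0 * cov[1, 3]
        rows.append({"moderator": label, "slope": slope, "se": np.sqrt(var)})
    return RegressionResult(
        params=pd.Series(fit.params, index=names),
        bse=pd.Series(fit.bse, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        r_squared=float(fit.rsquared),
        interaction_p=float(fit.pvalues[3]),
        simple_slopes=pd.DataFrame(rows),
        method="OLS moderator regression (centred)",
    )


def _compress_unit(y: np.ndarray) -> np.ndarray:
    n = len(y)
    return (y * (n - 1) + 0.5) / n


def beta_regression(y01, X, add_constant: bool = True) -> RegressionResult:
    """Beta regression with logit mean link and constant precision phi.

    ``y01`` lies in [0, 1]; exact 0/1 values are compressed with the
    standard ``(y (n - 1) + 0.5) / n`` transform.  Coefficients and their
    standard errors come from the ML fit; pseudo-R^2 is the squared
    correlation between the linked fitted values and the linked response.
    """
    y = np.asarray(y01, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("y01 must lie in [0, 1]")
    if np.any(y <= 0) or np.any(y >= 1):
        y = _compress_unit(y)
    if isinstance(X, pd.DataFrame):
        exog = X.astype(float)
    else:
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        if arr.shape[0] == 1 and len(y) > 1:
            arr = arr.T
        exog = pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])
    if add_constant:
        exog = sm.add_constant(exog)
    model = BetaModel(y, exog)
    fit = model.fit(disp=False)
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(f"beta regression did not converge: {fit.mle_retvals}")
    k = exog.shape[1]
    names = list(exog.columns)
    all_params = np.asarray(fit.params, dtype=float)
    all_bse = np.asarray(fit.bse, dtype=float)
    all_p = np.asarray(fit.pvalues, dtype=float)
    params = pd.Series(all_params[:k], index=names)
    bse = pd.Series(all_bse[:k], index=names)
    pvalues = pd.Series(all_p[:k], index=names)
    # precision is modelled on the log scale; delta method for the SE of phi
    phi = float(np.exp(all_params[k]))
    phi_se = float(phi * all_bse[k])
    eta_hat = exog.to_numpy() @ params.to_numpy()
    eta_obs = np.log(y / (1 - y))
    pseudo_r2 = float(np.corrcoef(eta_hat, eta_obs)[0, 1] ** 2) if k > 1 else 0.0
    return RegressionResult(
        params=params,
        bse=bse,
        pvalues=pvalues,
        r_squared=pseudo_r2,
        phi=phi,
        phi_se=phi_se,
        method="beta regression (logit link, constant precision)",
    )
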