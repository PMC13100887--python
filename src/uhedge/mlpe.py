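"""Maximum-likelihood population effects (MLPE) regression and model ranking.

Pairwise distance data violate ordinary regression assumptions: every
individual appears in n-1 rows, so rows sharing an individual are correlated.
The MLPE model adds a Gaussian random effect per individual, each pair
receiving the sum of its two members' effects:

    y_ab = X beta + u_a + u_b + e_ab,   u ~ N(0, tau2),  e ~ N(0, sigma2)

Fitting is by full maximum likelihood: the variance ratio lambda =
tau2/sigma2 is profiled out (the covariance is sigma2 (I + lambda Z Z'),
diagonalised once through the eigendecomposition of Z Z'), beta by GLS at
each lambda, and the scalar profile likelihood maximised numerically.  ML
rather than REML is used throughout because competing models differ in their
fixed effects and are ranked by AICc/BIC.

Isolation-by-distance versus isolation-by-resistance comparison: genetic
distance is regressed on the natural-log resistance distance of each named
hypothesis (least-cost-path or commute), with or without a straight-line
distance covariate, and models ranked within blocks by AICc.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .connectivity import (
    PairwiseDistanceMatrix,
    build_transition_graph,
    commute_distance,
    lcp_distance,
    euclidean_distance,
)
from .resistance import build_resistance_surface


class MLPEError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# pairwise table
# ---------------------------------------------------------------------------

def build_pairwise_table(
    gdist: PairwiseDistanceMatrix,
    predictors: dict[str, PairwiseDistanceMatrix],
    log_transform: bool | set[str] = True,
    drop_infinite: bool = True,
) -> pd.DataFrame:
    """One row per unordered individual pair: response plus predictors.

    Predictor matrices are log-transformed (natural log) where flagged —
    ``True`` transforms all, or pass the set of names; the conventional
    Euclidean-distance covariate is left untransformed by passing its name
    out of the set.  Pairs with an infinite predictor (disconnected graph)
    are dropped with a warning.
    """
    ids = gdist.ids
    for name, m in predictors.items():
        if m.ids != ids:
            raise MLPEError(f"predictor {name!r} id set differs from the response")
    if log_transform is True:
        log_set = set(predictors)
    elif log_transform is False:
        log_set = set()
    else:
        log_set = set(log_transform)
    rows = []
    dropped = 0
    for i, j in itertools.combinations(range(len(ids)), 2):
        row = {"id_a": ids[i], "id_b": ids[j], "gd": gdist.values[i, j]}
        ok = True
        for name, m in predictors.items():
            v = m.values[i, j]
            if not np.isfinite(v):
                ok = False
                break
            if name in log_set:
                if v <= 0:
                    raise MLPEError(
                        f"nonpositive {name!r} distance for pair "
                        f"({ids[i]}, {ids[j]}); cannot log-transform"
                    )
                v = np.log(v)
            row[name] = v
        if ok:
            rows.append(row)
        else:
            dropped += 1
    if dropped:
        if not drop_infinite:
            raise MLPEError(f"{dropped} pairs have infinite predictor distances")
        warnings.warn(f"dropped {dropped} pairs with infinite predictor distances")
    return pd.DataFrame(rows)


def _incidence(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    ids = sorted(set(table["id_a"]) | set(table["id_b"]))
    pos = {s: k for k, s in enumerate(ids)}
    z = np.zeros((len(table), len(ids)))
    for r, (a, b) in enumerate(zip(table["id_a"], table["id_b"])):
        z[r, pos[a]] = 1.0
        z[r, pos[b]] = 1.0
    return z, ids


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class MLPEFit:
    predictors: list[str]
    beta: np.ndarray  # intercept first
    tau2: float
    sigma2: float
    loglik: float
    k: int
    n: int
    aicc: float
    bic: float
    r_squared: float

    @property
    def rho(self) -> float:
        """Correlation between pairs sharing one individual."""
        return self.tau2 / (2 * self.tau2 + self.sigma2)

    def to_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "beta": [float(b) for b in self.beta],
            "tau2": self.tau2,
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
            "bic": self.bic,
            "r_squared": self.r_squared,
            "rho": self.rho,
        }


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion; undefined for n <= k + 1."""
    if n <= k + 1:
        raise MLPEError(f"AICc undefined for n={n}, k={k}")
    return -2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def bic(loglik: float, k: int, n: int) -> float:
    return -2 * loglik + k * np.log(n)


def _profile_loglik(lam: float, evals, y_t, x_t):
    """Profile log-likelihood of lambda (variance ratio), beta/sigma2 profiled."""
    n = y_t.size
    d = 1.0 + lam * evals
    xtw = x_t.T / d
    xtx = xtw @ x_t
    beta = np.linalg.solve(xtx, xtw @ y_t)
    resid = y_t - x_t @ beta
    rss = float(resid @ (resid / d))
    sigma2 = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + np.log(d).sum() + n)
    return ll, beta, sigma2


def fit_mlpe(table: pd.DataFrame, predictors: list[str]) -> MLPEFit:
    """Fit the MLPE mixed model by profile maximum likelihood.

    ``k`` counts the intercept, each slope, and the two variance parameters.
    R-squared is the squared Pearson correlation between the fixed-effect
    predictions and the response.
    """
    y = table["gd"].to_numpy(dtype=float)
    n = y.size
    if np.all(y == y[0]):
        raise MLPEError("response is constant")
    x = np.column_stack([np.ones(n)] + [table[p].to_numpy(dtype=float) for p in predictors])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise MLPEError("singular fixed-effect design")
    z, ids = _incidence(table)
    if len(ids) < 3:
        raise MLPEError("need at least three individuals")
    evals, evecs = np.linalg.eigh(z @ z.T)
    evals = np.clip(evals, 0, None)
    y_t = evecs.T @ y
    x_t = evecs.T @ x

    def neg(u):
        return -_profile_loglik(np.exp(u), evals, y_t, x_t)[0]

    res = minimize_scalar(neg, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise MLPEError(f"profile-likelihood optimisation failed: {res}")
    ll_int, lam = -res.fun, float(np.exp(res.x))
    ll0, beta0, s0 = _profile_loglik(0.0, evals, y_t, x_t)
    if ll0 >= ll_int:  # boundary optimum tau2 = 0
        lam, ll, beta, sigma2 = 0.0, ll0, beta0, s0
    else:
        ll, beta, sigma2 = _profile_loglik(lam, evals, y_t, x_t)
    tau2 = lam * sigma2
    k = x.shape[1] + 2
    fitted = x @ beta
    r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2) if np.std(fitted) > 0 else 0.0
    return MLPEFit(
        predictors=list(predictors),
        beta=beta,
        tau2=float(tau2),
        sigma2=float(sigma2),
        loglik=float(ll),
        k=k,
        n=n,
        aicc=aicc(ll, k, n),
        bic=bic(ll, k, n),
        r_squared=r2,
    )


def pseudo_r_squared(fit: MLPEFit, null_loglik: float) -> float:
    """Likelihood-based alternative R2 (1 - exp(2 (ll0 - ll)/n))."""
    return 1.0 - float(np.exp(2 * (null_loglik - fit.loglik) / fit.n))


# ---------------------------------------------------------------------------
# comparison tables
# ---------------------------------------------------------------------------

def compare_models(
    fits: dict[tuple, MLPEFit],
    block_keys: list[str],
    key_names: list[str] | None = None,
) -> pd.DataFrame:
    """Rank fits by AICc within blocks.

    ``fits`` maps key tuples to fits; ``block_keys`` names the tuple slots
    that define a block (models within one block must share the identical
    pair set).  Exactly one best per block; AICc ties fall to lower BIC.
    """
    if not fits:
        raise MLPEError("no fits to compare")
    key_len = len(next(iter(fits)))
    names = key_names or [f"key{i}" for i in range(key_len)]
    rows = []
    for key, fit in fits.items():
        row = dict(zip(names, key))
        row.update(aicc=fit.aicc, bic=fit.bic, r_squared=fit.r_squared, n_pairs=fit.n)
        rows.append(row)
    df = pd.DataFrame(rows)
    block_cols = [c for c in names if c in block_keys]
    ns = df.groupby(block_cols)["n_pairs"].nunique() if block_cols else pd.Series([df["n_pairs"].nunique()])
    if (ns > 1).any():
        raise MLPEError("fits within a block use different pair sets")

    def _rank(g: pd.DataFrame) -> pd.DataFrame:
        g = g.sort_values(["aicc", "bic"], kind="stable").copy()
        g["delta_aicc"] = g["aicc"] - g["aicc"].min()
        g["best"] = False
        g.iloc[0, g.columns.get_loc("best")] = True
        return g

    if block_cols:
        df = (
            df.groupby(block_cols, group_keys=False, sort=False)[df.columns]
            .apply(_rank)
            .reset_index(drop=True)
        )
    else:
        df = _rank(df).reset_index(drop=True)
    return df


def run_model_suite(
    gdist: PairwiseDistanceMatrix,
    landcover,
    hypotheses: dict,
    points: pd.DataFrame,
    algorithms: tuple[str, ...] = ("lcp", "commute"),
    include_distance_term: bool = True,
    epsilon: float = 1e-4,
    neighbours: int = 8,
    area: str = "area",
) -> tuple[pd.DataFrame, dict[tuple, MLPEFit]]:
    """Fit genetic distance against every hypothesis x algorithm and rank.

    For each named resistance hypothesis the landcover is converted to a
    surface, pairwise distances computed (epsilon repair applied to commute
    only), and an MLPE fitted with and, optionally, without a straight-line
    distance covariate.  The NULL (uniform) hypothesis keeps its
    distance-free fit in the +distance column, since its resistance distance
    already measures distance.  Pairs with an infinite LCP under any
    hypothesis are dropped from all fits of that algorithm block so ranked
    models share a response.
    """
    euclid = euclidean_distance(points)
    results: dict[tuple, MLPEFit] = {}
    dist_mats: dict[tuple[str, str], PairwiseDistanceMatrix] = {}
    for name, hyp in hypotheses.items():
        surface = build_resistance_surface(landcover, hyp)
        for algo in algorithms:
            if algo == "lcp":
                g = build_transition_graph(surface, epsilon=0.0, neighbours=neighbours)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    dist_mats[(name, algo)] = lcp_distance(g, points)
            elif algo == "commute":
                g = build_transition_graph(surface, epsilon=epsilon, neighbours=neighbours)
                dist_mats[(name, algo)] = commute_distance(g, points)
            else:
                raise MLPEError(f"unknown algorithm {algo!r}")

    for algo in algorithms:
        finite = None
        for name in hypotheses:
            v = dist_mats[(name, algo)].values
            f = np.isfinite(v)
            finite = f if finite is None else (finite & f)
        for name in hypotheses:
            pred = {"rdist": dist_mats[(name, algo)], "euclid": euclid}
            vals = pred["rdist"].values.copy()
            vals[~finite] = np.inf  # force the shared pair set
            pred["rdist"] = PairwiseDistanceMatrix(
                pred["rdist"].kind, pred["rdist"].ids, vals, pred["rdist"].units
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = build_pairwise_table(gdist, pred, log_transform={"rdist"})
            base = fit_mlpe(table, ["rdist"])
            results[(area, algo, name, False)] = base
            if include_distance_term:
                if name == "NULL":
                    results[(area, algo, name, True)] = base
                else:
                    results[(area, algo, name, True)] = fit_mlpe(table, ["rdist", "euclid"])

    table = compare_models(
        results,
        block_keys=["area", "algorithm", "with_distance"],
        key_names=["area", "algorithm", "hypothesis", "with_distance"],
    )
    return table, results
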