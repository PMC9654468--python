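"""Data-driven dietary patterns by correlation-matrix PCA.

Single-day gram intakes of the major food groups are standardized, the
correlation matrix eigendecomposed, components with eigenvalue > 1 retained,
and the retained loadings varimax-rotated for interpretability.  Sampling
adequacy is screened beforehand with the Kaiser–Meyer–Olkin statistic (overall
and per-variable MSA, from the anti-image/partial correlations) and Bartlett's
test of sphericity; variables with inadequate MSA are pruned iteratively.
Participant pattern scores use the regression (Thomson) estimator
Z·R⁻¹·L, and each food group is attributed to the single factor on which its
absolute rotated loading is largest, provided it exceeds 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class SingularCorrelationError(ValueError):
    """Correlation matrix is singular; partial correlations are undefined.
    Prune collinear variables and retry."""


@dataclass
class Adequacy:
    kmo_overall: float
    msa: dict[str, float]
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


@dataclass
class PatternModel:
    variables: list[str]
    dropped: list[str]
    adequacy: Adequacy
    eigenvalues: np.ndarray          # all p, descending
    retained_k: int
    loadings: pd.DataFrame           # variables × retained factors, rotated
    pct_variance: np.ndarray         # per retained factor, of total p
    cumulative_pct: float
    scores: pd.DataFrame             # participants × factors
    attribution: dict[str, int | None]  # variable → 1-based factor or None
    mean_: np.ndarray = field(repr=False, default=None)
    std_: np.ndarray = field(repr=False, default=None)
    corr_: np.ndarray = field(repr=False, default=None)


# -- adequacy ------------------------------------------------------------------

def adequacy(R: np.ndarray, n: int, variables: list[str] | None = None) -> Adequacy:
    """KMO / per-variable MSA and Bartlett's sphericity test for a correlation
    matrix estimated from ``n`` observations."""
    R = np.asarray(R, float)
    p = R.shape[0]
    if variables is None:
        variables = [f"v{i}" for i in range(p)]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise SingularCorrelationError(
            "correlation matrix is singular or indefinite; prune variables"
        )
    try:
        S = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        raise SingularCorrelationError("correlation matrix not invertible") from None
    d = 1.0 / np.sqrt(np.diag(S))
    Q = -S * np.outer(d, d)          # partial correlations off the diagonal
    np.fill_diagonal(Q, 0.0)
    R_off = R - np.eye(p)

    r2 = R_off**2
    q2 = Q**2

    def _ratio(num: float, den: float) -> float:
        # all-zero correlations (identity matrix): no sampling adequacy signal
        return float(num / den) if den > 0 else 0.0

    kmo = _ratio(r2.sum(), r2.sum() + q2.sum())
    msa = {
        v: _ratio(r2[i].sum(), r2[i].sum() + q2[i].sum())
        for i, v in enumerate(variables)
    }
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return Adequacy(kmo, msa, float(chi2), int(df), p_value)


# -- rotation ------------------------------------------------------------------

def varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Orthogonal varimax rotation (unnormalized) of a loadings matrix."""
    L = np.asarray(loadings, float)
    p, k = L.shape
    if k < 2:
        return L.copy()
    R = np.eye(k)
    obj = 0.0
    for _ in range(max_iter):
        B = L @ R
        grad = L.T @ (B**3 - B * (B**2).sum(axis=0) / p)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        new_obj = s.sum()
        if new_obj <= obj * (1.0 + tol):
            break
        obj = new_obj
    return L @ R


def _fix_signs(L: np.ndarray) -> np.ndarray:
    """Resolve sign indeterminacy: each factor's largest-|loading| variable
    loads positively."""
    L = L.copy()
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


def congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence coefficient (cosine similarity of loading vectors)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


# -- extraction ----------------------------------------------------------------

def extract(
    data: pd.DataFrame,
    eigenvalue_cut: float = 1.0,
    msa_cut: float = 0.5,
    loading_cut: float = 0.2,
) -> PatternModel:
    """Fit the full pattern model on a participants × food-group gram table.

    Zero-variance columns are dropped; variables are then pruned one at a
    time (worst first) until every MSA reaches ``msa_cut``.  Components with
    eigenvalue > ``eigenvalue_cut`` are retained and varimax-rotated.
    """
    X = data.to_numpy(dtype=float)
    variables = list(data.columns)
    n = X.shape[0]
    if n < 3:
        raise ValueError("pattern extraction needs at least 3 participants")

    dropped: list[str] = []
    keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]
    dropped += [variables[i] for i in range(X.shape[1]) if i not in keep]
    X = X[:, keep]
    variables = [variables[i] for i in keep]

    # iterative MSA pruning
    while True:
        if X.shape[1] < 2:
            raise ValueError("fewer than 2 variables remain after pruning")
        R = np.corrcoef(X, rowvar=False)
        adq = adequacy(R, n, variables)
        worst = min(adq.msa, key=adq.msa.get)
        if adq.msa[worst] >= msa_cut:
            break
        idx = variables.index(worst)
        dropped.append(worst)
        variables.pop(idx)
        X = np.delete(X, idx, axis=1)

    p = X.shape[1]
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    k = max(1, int((eigval > eigenvalue_cut).sum()))
    raw = eigvec[:, :k] * np.sqrt(eigval[:k])
    rotated = _fix_signs(varimax(raw))
    # order factors by explained variance after rotation
    ss = (rotated**2).sum(axis=0)
    forder = np.argsort(ss)[::-1]
    rotated, ss = rotated[:, forder], ss[forder]
    pct = ss / p * 100.0

    mean, std = X.mean(axis=0), X.std(axis=0, ddof=1)
    Z = (X - mean) / std
    factor_cols = [f"factor_{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(rotated, index=variables, columns=factor_cols)
    scores = pd.DataFrame(
        _regression_scores(Z, R, rotated), index=data.index, columns=factor_cols
    )
    model = PatternModel(
        variables=variables,
        dropped=dropped,
        adequacy=adq,
        eigenvalues=eigval,
        retained_k=k,
        loadings=loadings,
        pct_variance=pct,
        cumulative_pct=float(pct.sum()),
        scores=scores,
        attribution=attribute(loadings, loading_cut),
        mean_=mean,
        std_=std,
        corr_=R,
    )
    return model


def _regression_scores(Z: np.ndarray, R: np.ndarray, L: np.ndarray) -> np.ndarray:
    return Z @ np.linalg.solve(R, L)


def factor_scores(model: PatternModel, data: pd.DataFrame) -> pd.DataFrame:
    """Regression-method factor scores for new data on the model's variables."""
    missing = [v for v in model.variables if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    X = data[model.variables].to_numpy(dtype=float)
    Z = (X - model.mean_) / model.std_
    return pd.DataFrame(
        _regression_scores(Z, model.corr_, model.loadings.to_numpy()),
        index=data.index,
        columns=list(model.loadings.columns),
    )


def attribute(
    loadings: pd.DataFrame, loading_cut: float = 0.2
) -> dict[str, int | None]:
    """Assign each food group to the factor of its maximum |loading| when that
    exceeds ``loading_cut`` (strict); ties break to the lowest factor index."""
    out: dict[str, int | None] = {}
    L = loadings.to_numpy()
    for i, var in enumerate(loadings.index):
        j = int(np.argmax(np.abs(L[i])))  # argmax takes first (lowest) on ties
        out[var] = (j + 1) if abs(L[i, j]) > loading_cut else None
    return out


def loadings_table(model: PatternModel, loading_cut: float = 0.2) -> pd.DataFrame:
    """Long-format summary mirroring a published pattern table: one row per
    attributed food group with its signed loading, factor eigenvalue and
    % of variance."""
    p = len(model.variables)
    rows = []
    for j, col in enumerate(model.loadings.columns):
        # rotated sum of squared loadings; pct_variance is this over p
        ss_j = float(model.pct_variance[j]) * p / 100.0
        for var, fac in model.attribution.items():
            if fac == j + 1:
                rows.append(
                    {
                        "factor": j + 1,
                        "food_group": var,
                        "loading": float(model.loadings.loc[var, col]),
                        "eigenvalue": ss_j,
                        "pct_variance": float(model.pct_variance[j]),
                    }
                )
    return pd.DataFrame(rows, columns=["factor", "food_group", "loading", "eigenvalue", "pct_variance"])
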