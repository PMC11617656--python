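"""Statistical layer: linear models with type-II ANOVA and Tukey-HSD,
Bray-Curtis dissimilarity, multi-factor PERMANOVA, and principal-coordinate
projection.

Ordinary model fitting is delegated to statsmodels (OLS, ``anova_lm`` with
type-II sums of squares, studentized-range Tukey-HSD); Bray-Curtis distances
come from scipy and ordination from scikit-bio.  The multi-factor PERMANOVA
is implemented here: distance-matrix variance is partitioned over sequential
model terms via hat-matrix traces of the Gower-centered matrix, and
significance is assessed by permutation of raw sample labels (scikit-bio's
one-way test is used as an independent cross-check in the test suite, not as
the implementation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

__all__ = [
    "LinearModelResult",
    "PermanovaResult",
    "SingularDesignError",
    "DegenerateDesignError",
    "fit_lm",
    "tukey_hsd",
    "bray_curtis",
    "permanova",
    "pcoa_projection",
]


class SingularDesignError(ValueError):
    """The requested design matrix is rank deficient (aliased terms)."""


class DegenerateDesignError(ValueError):
    """No factor in the design has more than one level."""


@dataclass
class LinearModelResult:
    """An OLS fit with its type-II ANOVA table and residual diagnostics."""

    formula: str
    coefficients: pd.Series
    std_errors: pd.Series
    r_squared: float
    adj_r_squared: float
    anova_type2: pd.DataFrame
    shapiro_p: float
    residual_sd: float
    n: int
    data: pd.DataFrame = field(repr=False)
    sm_result: object = field(repr=False, default=None)

    def summary_dict(self) -> dict:
        return {
            "formula": self.formula,
            "n": self.n,
            "coefficients": self.coefficients.to_dict(),
            "std_errors": self.std_errors.to_dict(),
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "residual_sd": self.residual_sd,
            "shapiro_p": self.shapiro_p,
            "anova_type2": {
                term: {k: (None if pd.isna(v) else float(v))
                       for k, v in row.items()}
                for term, row in self.anova_type2.to_dict("index").items()
            },
        }


def fit_lm(data: pd.DataFrame, formula: str) -> LinearModelResult:
    """Least-squares fit of a model formula with type-II ANOVA.

    Raises :class:`SingularDesignError` when the design matrix is rank
    deficient (e.g. an interaction requested over empty cells), naming the
    aliased columns.
    """
    model = smf.ols(formula, data=data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        aliased = _aliased_columns(exog, model.exog_names)
        raise SingularDesignError(
            f"design matrix is rank deficient ({rank} < {exog.shape[1]}); "
            f"aliased terms: {aliased}"
        )
    res = model.fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova = anova_lm(res, typ=2)
    resid = res.resid
    shapiro_p = float(scipy.stats.shapiro(resid).pvalue) if len(resid) >= 3 else float("nan")
    return LinearModelResult(
        formula=formula,
        coefficients=res.params,
        std_errors=res.bse,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        anova_type2=anova,
        shapiro_p=shapiro_p,
        residual_sd=float(np.sqrt(res.mse_resid)),
        n=int(res.nobs),
        data=data,
        sm_result=res,
    )


def _aliased_columns(exog: np.ndarray, names: list[str]) -> list[str]:
    """Columns that add no rank when appended left-to-right."""
    aliased, cols = [], []
    for j, name in enumerate(names):
        trial = exog[:, [*cols, j]]
        if np.linalg.matrix_rank(trial) == len(cols):
            aliased.append(name)
        else:
            cols.append(j)
    return aliased


def tukey_hsd(model: LinearModelResult, factor: str, alpha: float = 0.05
              ) -> pd.DataFrame:
    """All pairwise mean differences for a factor with family-wise adjusted
    p-values from the studentized-range distribution.
    """
    if factor not in model.data.columns:
        raise KeyError(f"factor {factor!r} not in the model data")
    if factor not in model.formula:
        raise KeyError(f"factor {factor!r} is not a term of {model.formula!r}")
    groups = model.data[factor].astype(str)
    if groups.nunique() < 2:
        raise DegenerateDesignError(f"factor {factor!r} has < 2 levels")
    response = model.formula.split("~")[0].strip()
    res = pairwise_tukeyhsd(
        endog=model.data[response].to_numpy(dtype=float),
        groups=groups.to_numpy(),
        alpha=alpha,
    )
    tbl = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    tbl["p-adj"] = res.pvalues
    return tbl


def bray_curtis(
    abundance: pd.DataFrame | np.ndarray,
    relative: bool = True,
    ids: list[str] | None = None,
) -> DistanceMatrix:
    """Bray-Curtis dissimilarities among rows of an abundance matrix.

    d(i, j) = sum |x_i - x_j| / sum (x_i + x_j).  With ``relative=True``
    rows are normalised to sum to 1 first (the compositional view); a row
    summing to zero is then undefined and raises.
    """
    if isinstance(abundance, pd.DataFrame):
        ids = ids or [str(i) for i in abundance.index]
        X = abundance.to_numpy(dtype=float)
    else:
        X = np.asarray(abundance, dtype=float)
        ids = ids or [str(i) for i in range(X.shape[0])]
    if np.any(X < 0):
        raise ValueError("abundances must be nonnegative")
    if relative:
        totals = X.sum(axis=1)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            raise ValueError(
                f"relative composition undefined for zero-total sample(s): "
                f"{[ids[i] for i in zero]}"
            )
        X = X / totals[:, None]
    D = squareform(pdist(X, metric="braycurtis"))
    D = np.nan_to_num(D, nan=0.0)  # two all-zero rows (relative=False) coincide
    return DistanceMatrix(D, ids=ids)


@dataclass(frozen=True)
class PermanovaResult:
    """Distance-based multivariate ANOVA table with permutation p-values."""

    table: pd.DataFrame  # per term: sum_sq, df, pseudo_F, p_value
    n_permutations: int
    seed: int

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p_value"])

    def pseudo_f(self, term: str) -> float:
        return float(self.table.loc[term, "pseudo_F"])


def _design_matrices(design: pd.DataFrame, terms: list[str]) -> list[np.ndarray]:
    """Nested design matrices for 1, 1+t1, 1+t1+t2, ... (patsy-coded)."""
    from patsy import dmatrix

    mats = [np.ones((len(design), 1))]
    for k in range(1, len(terms) + 1):
        rhs = " + ".join(terms[:k])
        X = np.asarray(dmatrix(f"1 + {rhs}", design, return_type="matrix"))
        mats.append(X)
    return mats


def _hat(X: np.ndarray) -> np.ndarray:
    """Projection onto the column space of X (rank-deficiency tolerant)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > s.max() * 1e-10
    U = U[:, keep]
    return U @ U.T


def permanova(
    dist: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA over a factorial design.

    Distance sums of squares are partitioned sequentially over ``terms``
    (default: ``drought + inoculated + drought:inoculated`` if those columns
    exist, else all design columns).  The pseudo-F for each term is
    (SS_term/df_term)/(SS_residual/df_residual); its p-value is
    (1 + #{permuted F >= observed F}) / (n_perm + 1) under permutation of
    raw sample labels, reproducible for a given ``seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    design = design.loc[list(dist.ids)]
    if terms is None:
        if {"drought", "inoculated"} <= set(design.columns):
            terms = ["drought", "inoculated", "drought:inoculated"]
        else:
            terms = list(design.columns)
    base_cols = sorted({c for t in terms for c in t.split(":")})
    if all(design[c].nunique() <= 1 for c in base_cols):
        raise DegenerateDesignError("every factor has a single level")

    n = len(design)
    D = dist.data
    G = _gower_center(D)
    mats = _design_matrices(design, terms)
    hats = [_hat(X) for X in mats]
    ranks = [int(np.linalg.matrix_rank(X)) for X in mats]
    df_terms = np.diff(ranks)
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise DegenerateDesignError("no residual degrees of freedom")

    tol = 1e-10 * max(abs(float(np.trace(G))), 1.0)

    def term_stats(Gm: np.ndarray):
        tr = np.array([float(np.sum(H * Gm)) for H in hats])  # tr(H G)
        ss_terms = np.diff(tr)
        ss_res = float(np.trace(Gm)) - tr[-1]
        if ss_res < tol:  # perfect separation: no within-group scatter
            ss_res = 0.0
            F = np.where(ss_terms > tol, np.inf, np.nan)
        else:
            F = (ss_terms / df_terms) / (ss_res / df_res)
        return ss_terms, ss_res, F

    ss_terms, ss_res, F_obs = term_stats(G)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        _, _, F_p = term_stats(G[np.ix_(p, p)])
        exceed += F_p >= F_obs
    p_values = (1.0 + exceed) / (n_perm + 1.0)

    table = pd.DataFrame(
        {
            "sum_sq": list(ss_terms) + [ss_res],
            "df": list(df_terms) + [df_res],
            "pseudo_F": list(F_obs) + [np.nan],
            "p_value": list(p_values) + [np.nan],
        },
        index=terms + ["Residual"],
    )
    return PermanovaResult(table=table, n_permutations=n_perm, seed=seed)


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D ** 2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def pcoa_projection(dist: DistanceMatrix, k: int = 2):
    """Classical (metric) multidimensional scaling of a distance matrix.

    Returns ``(coordinates, eigenvalues)`` where coordinates is an (n, k)
    array.  If fewer than ``k`` positive eigenvalues exist the projection is
    truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ord_res = _skbio_pcoa(dist, number_of_dimensions=min(k, len(dist.ids) - 1))
    eig = ord_res.eigvals.to_numpy()
    n_pos = int(np.sum(eig > 1e-12))
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating projection "
            f"from {k} to {n_pos} dimensions"
        )
        k = max(n_pos, 1)
    coords = ord_res.samples.to_numpy()[:, :k]
    return coords, eig
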