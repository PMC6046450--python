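"""Permutation and ordination statistics, implemented from first principles.

Mantel tests, marginal-term PERMANOVA (the McArdle-Anderson
partitioning of a Gower-centred inner-product matrix), principal
coordinates analysis retaining negative eigenvalues, multivariate
dispersion (distance to group centroid with Anderson's real/imaginary
correction), Welch's t with Benjamini-Hochberg correction, and
standardized major axis (type-2) regression.

All permutation p-values carry the +1 correction,
p = (#{perm stat >= observed} + 1) / (n_perm + 1),
and are reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

DEFAULT_PERMUTATIONS = 1000


@dataclass
class PermTestResult:
    statistic: float
    n_permutations: int
    p_value: float
    seed: int | None
    scheme: str

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "seed": self.seed,
            "scheme": self.scheme,
        }


@dataclass
class Ordination:
    """PCoA embedding with negative-eigenvalue axes kept as imaginary coords.

    Squared distances are reconstructed as
    ||x_i - x_j||^2 (real axes) - ||y_i - y_j||^2 (imaginary axes).
    """

    ids: list[str]
    real: np.ndarray  # n x k_pos, axes ordered by decreasing eigenvalue
    imaginary: np.ndarray  # n x k_neg, ordered by decreasing |eigenvalue|
    eigenvalues: np.ndarray  # all retained eigenvalues, decreasing

    def reconstructed_distances(self) -> np.ndarray:
        def sq(coords: np.ndarray) -> np.ndarray:
            g = coords @ coords.T
            d2 = np.diag(g)[:, None] + np.diag(g)[None, :] - 2 * g
            return d2

        d2 = sq(self.real) - sq(self.imaginary)
        return np.sqrt(np.clip(d2, 0.0, None))


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> PermTestResult:
    """One-tailed Mantel test of positive matrix association.

    The statistic is the Pearson correlation between the strictly-lower
    triangles; the null permutes the rows and columns of ``d2``
    simultaneously.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("Mantel requires identical labels in identical order")
    n = d1.shape[0]
    if n < 4:
        raise ValueError("Mantel needs at least 4 samples")
    a = _lower_triangle(d1.data)
    b2 = d2.data
    b = _lower_triangle(b2)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance distance triangle")
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    observed = float(np.mean(az * bz))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        bp = _lower_triangle(b2[np.ix_(p, p)])
        r = float(np.mean(az * (bp - bp.mean()) / bp.std()))
        if r >= observed - 1e-10:  # tolerance so analytic ties count as ties
            count += 1
    p_value = (count + 1) / (n_perm + 1)
    return PermTestResult(observed, n_perm, p_value, seed, "free row/column permutation of d2")


# -- PERMANOVA -----------------------------------------------------------------


def _gower_centre(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # pseudo-inverse hat matrix; tolerant of rank deficiency
    return x @ np.linalg.pinv(x)


def _design_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    col = design[term]
    if col.dtype.kind in "fiu" and col.nunique() > 8:
        return col.to_numpy(float)[:, None]  # continuous covariate
    dummies = pd.get_dummies(col.astype(str), drop_first=True)
    return dummies.to_numpy(float)


def permanova(
    d: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str] | None = None,
    n_perm: int = DEFAULT_PERMUTATIONS,
    mode: str = "margin",
    seed: int = 0,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA with marginal term tests.

    ``design`` rows must align with ``d.ids``.  In margin mode each
    term's sum of squares is the drop from the full model to the model
    without that term, so every term is adjusted for all others.
    P-values come from free permutation of sample labels.

    Returns a table with one row per term plus Residual and Total.
    """
    if mode != "margin":
        raise ValueError("only marginal term tests are implemented")
    if terms is None:
        terms = list(design.columns)
    if set(d.ids) <= set(design.index):
        design = design.loc[list(d.ids), terms]
    elif len(design) == d.shape[0]:
        design = design[terms].set_axis(list(d.ids))
    else:
        raise ValueError("design rows do not align with distance-matrix labels")
    n = d.shape[0]
    for term in terms:
        col = design[term]
        if not (col.dtype.kind in "fiu" and col.nunique() > 8):
            sizes = col.astype(str).value_counts()
            if (sizes < 2).any():
                bad = sizes.index[sizes < 2].tolist()
                raise ValueError(f"factor {term!r} has singleton level(s): {bad}")

    g = _gower_centre(d.data)
    ss_total = float(np.trace(g))
    intercept = np.ones((n, 1))
    blocks = {t: _design_columns(design, t) for t in terms}
    x_full = np.hstack([intercept] + [blocks[t] for t in terms])
    rank_full = np.linalg.matrix_rank(x_full)
    h_full = _hat(x_full)
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    def model_ss(h: np.ndarray, gram: np.ndarray) -> float:
        return float(np.sum(h * gram.T))  # tr(H G)

    def pseudo_f(ss_term: float, df_term: int, ss_resid: float, df_resid: int) -> float:
        # clip the epsilon-negative SS a perfect fit produces
        ss_term = max(ss_term, 0.0)
        ss_resid = max(ss_resid, 0.0)
        if ss_resid == 0.0:
            return np.inf if ss_term > 0 else 0.0
        return (ss_term / df_term) / (ss_resid / df_resid)

    eps = 1e-10 * max(abs(ss_total), 1.0)
    ss_model_full = model_ss(h_full, g)
    ss_res = ss_total - ss_model_full
    if abs(ss_res) < eps:
        ss_res = 0.0

    rows = []
    rng = np.random.default_rng(seed)
    for term in terms:
        # marginal SS: drop from the full model to the model without this term;
        # with a single term the reduced model is the intercept and the marginal
        # SS equals the full model SS (tr(H_1 G) = 0 for centred G).
        x_red = np.hstack([intercept] + [blocks[t] for t in terms if t != term])
        rank_red = np.linalg.matrix_rank(x_red)
        df_term = rank_full - rank_red
        if df_term == 0:
            raise ValueError(f"term {term!r} is aliased with the remaining terms")
        h_red = _hat(x_red)
        ss_term = ss_model_full - model_ss(h_red, g)
        f_obs = pseudo_f(ss_term, df_term, ss_res, df_res)

        count = 0
        for _ in range(n_perm):
            p = rng.permutation(n)
            gp = g[np.ix_(p, p)]
            ss_model_p = model_ss(h_full, gp)
            ss_res_p = ss_total - ss_model_p
            if abs(ss_res_p) < eps:
                ss_res_p = 0.0
            ss_term_p = ss_model_p - model_ss(h_red, gp)
            f_p = pseudo_f(ss_term_p, df_term, ss_res_p, df_res)
            if f_p >= f_obs * (1 - 1e-10) - 1e-12:  # count analytic ties
                count += 1
        rows.append(
            {
                "term": term,
                "df": df_term,
                "sum_sq": ss_term,
                "pseudo_F": f_obs,
                "R2": ss_term / ss_total,
                "p_value": (count + 1) / (n_perm + 1),
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "sum_sq": ss_res,
            "pseudo_F": np.nan,
            "R2": ss_res / ss_total,
            "p_value": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "sum_sq": ss_total,
            "pseudo_F": np.nan,
            "R2": 1.0,
            "p_value": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")


def pcoa(d: DistanceMatrix, eig_tol: float = 1e-9) -> Ordination:
    """Principal coordinates of a distance matrix.

    Eigendecomposition of the Gower-centred matrix; positive-eigenvalue
    axes carry the real coordinates, negative-eigenvalue axes (common
    for non-Euclidean dissimilarities like Jaccard) are kept as
    imaginary coordinates rather than discarded or shifted.
    """
    data = np.asarray(d.data if isinstance(d, DistanceMatrix) else d, float)
    if not np.allclose(data, data.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    ids = list(d.ids) if isinstance(d, DistanceMatrix) else [str(i) for i in range(len(data))]
    n = data.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    g = _gower_centre(data)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0)
    keep = np.abs(eigvals) > eig_tol * scale
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    pos = eigvals > 0
    real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    neg_idx = np.argsort(eigvals[~pos])  # most negative first
    neg_vals = eigvals[~pos][neg_idx]
    imaginary = eigvecs[:, ~pos][:, neg_idx] * np.sqrt(-neg_vals)
    return Ordination(ids, real, imaginary, eigvals)


def dispersion_to_centroid(
    d: DistanceMatrix,
    groups: pd.Series | list,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> tuple[pd.Series, PermTestResult]:
    """Distance of each sample to its group centroid, plus a homogeneity test.

    Samples are embedded by PCoA; the squared distance to the centroid is
    the real-axis squared distance minus the imaginary-axis squared
    distance (Anderson's correction for negative eigenvalues), floored at
    zero before the square root.  Homogeneity of dispersion is tested
    with a one-way F statistic on the centroid distances, permuting the
    group-centred residuals.  Singleton groups get distance 0 and do not
    enter the F test.
    """
    groups = pd.Series(list(groups), index=list(d.ids))
    ord_ = pcoa(d)
    z = pd.Series(0.0, index=list(d.ids))
    for level in groups.unique():
        members = np.asarray([i for i, sid in enumerate(ord_.ids) if groups[sid] == level])
        xr = ord_.real[members]
        xi = ord_.imaginary[members]
        d2 = ((xr - xr.mean(axis=0)) ** 2).sum(axis=1) - ((xi - xi.mean(axis=0)) ** 2).sum(axis=1)
        z.iloc[members] = np.sqrt(np.clip(d2, 0.0, None))

    sizes = groups.value_counts()
    testable = groups[groups.map(sizes) >= 2]
    k = testable.nunique()
    if k < 2:
        return z, PermTestResult(np.nan, 0, np.nan, seed, "not testable (<2 groups)")
    zt = z.loc[testable.index].to_numpy()
    labels = testable.to_numpy()

    def f_stat(values: np.ndarray) -> float:
        grand = values.mean()
        ss_b = ss_w = 0.0
        for level in np.unique(labels):
            grp = values[labels == level]
            ss_b += len(grp) * (grp.mean() - grand) ** 2
            ss_w += ((grp - grp.mean()) ** 2).sum()
        df_b, df_w = k - 1, len(values) - k
        if ss_w == 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / df_b) / (ss_w / df_w)

    observed = f_stat(zt)
    # Freedman-Lane: permute the residuals of the null (grand-mean) model;
    # F is invariant to the common mean, so permuting z itself is identical.
    residuals = zt - zt.mean()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(residuals)
        if f_stat(perm) >= observed * (1 - 1e-10) - 1e-12:
            count += 1
    result = PermTestResult(
        observed, n_perm, (count + 1) / (n_perm + 1), seed, "permutation of residual distances"
    )
    return z, result


def welch_bh(features: pd.DataFrame, group: pd.Series | np.ndarray) -> pd.DataFrame:
    """Welch's unequal-variance t per feature with Benjamini-Hochberg q-values.

    ``features`` is feature x sample; ``group`` is a binary labelling of
    the samples.  Features with zero variance and equal means in both
    groups get t = 0, p = 1.
    """
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError("welch_bh requires exactly two groups")
    a = features.loc[:, group == levels[0]].to_numpy(float)
    b = features.loc[:, group == levels[1]].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = np.isnan(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"t": t, "p_value": p, "q_value": q}, index=features.index)


def sma_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Standardized major axis (type-2) regression of y on x.

    slope = sign(r) * sd(y)/sd(x); intercept = mean(y) - slope * mean(x).
    Symmetric in the errors of both variables, hence suited to allometric
    log-log fits where neither axis is error-free.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("SMA needs at least 3 points")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return float(slope), intercept, r
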