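"""Pointwise and global permutation statistics on deformation markers.

The model at each template point k is an ordinary linear model

    J_k(s) = beta_k0 + beta_k1 * gamma(s) + sum_cov a_cov X_cov(s) + eps_k(s)

with gamma = 1 for patients (FES) and 0 for controls, covarying for age,
gender and total intracranial volume (age and TIV only within a single
gender).  Group inference uses Fisher's randomization logic with the
Freedman-Lane scheme (reduced-model residuals are permuted, so nuisance
covariates are respected), Monte-Carlo with a configurable number of
permutations (10,000 in a full study) or exhaustive enumeration when the
label assignments can be counted.  Family-wise error over the template
points is controlled by the single-step Westfall-Young max-|t| statistic,
whose largest exceedance also yields the single omnibus shape p-value.
The reported effect is -beta_k1, so positive values mean inward deformation
in the patient group; effect sizes are Cohen's d on the raw markers.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STRUCTURES = ("CC", "gCC", "bCC", "sCC")


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class Design:
    X: np.ndarray
    columns: list
    group_col: int
    subject_ids: list

    @property
    def n(self) -> int:
        return self.X.shape[0]


def build_design(cov: pd.DataFrame, scope: str = "all",
                 interaction: bool = False) -> Design:
    """Build the covariate-adjusted design matrix for a comparison scope.

    scope 'all' covaries age, gender and TIV; 'female'/'male' restrict the
    cohort and covary age and TIV only.  With ``interaction=True`` the model
    adds gender, group and their product (main factors + interaction),
    covarying age and TIV; the product column is the tested term.
    """
    cov = cov.sort_values("subject_id").reset_index(drop=True)
    if scope == "female":
        cov = cov[cov.gender == "F"].reset_index(drop=True)
    elif scope == "male":
        cov = cov[cov.gender == "M"].reset_index(drop=True)
    elif scope != "all":
        raise ValueError(f"unknown scope {scope!r}")
    if len(cov) == 0:
        raise ValueError(f"no subjects in scope {scope!r}")
    if not set(cov.group) <= {"FES", "HC"}:
        raise ValueError("group must be FES or HC")

    gamma = (cov.group == "FES").to_numpy(float)
    gender_m = (cov.gender == "M").to_numpy(float)
    cols = [np.ones(len(cov)), gamma]
    names = ["intercept", "group"]
    if interaction:
        if scope != "all":
            raise ValueError("interaction model requires the full cohort")
        cells = cov.groupby(["group", "gender"]).size()
        if len(cells) < 4:
            raise ValueError("interaction test requires all four group x gender cells nonempty")
        cols += [gender_m, gamma * gender_m]
        names += ["gender", "gender_x_group"]
        group_name = "gender_x_group"
    else:
        if scope == "all":
            cols.append(gender_m)
            names.append("gender")
        group_name = "group"
    cols += [cov.age.to_numpy(float), cov.tiv.to_numpy(float)]
    names += ["age", "tiv"]
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariates in design")
    _check_rank(X, names)
    return Design(X=X, columns=names, group_col=names.index(group_name),
                  subject_ids=list(cov.subject_id))


def _check_rank(X: np.ndarray, names: list):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = [nm for j, nm in enumerate(names)
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# OLS core
# ---------------------------------------------------------------------------

def fit_pointwise_glm(Y: np.ndarray, design: Design):
    """Per-point ordinary least squares.

    Y is (n_subjects, K).  Returns a dict with beta (p, K), the tested
    coefficient beta1, its t statistic, residuals and residual variance.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = design.X
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("markers and design have mismatched subject counts")
    if n <= p + 2:
        raise ValueError(f"need n > rank + 2 (n={n}, p={p})")
    g_til, gg, Qz, Qx = _fl_basis(X, design.group_col)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.sum(resid ** 2, axis=0)
    sigma2 = rss / (n - p)
    beta1 = beta[design.group_col]
    se = np.sqrt(sigma2 / gg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta1 / se, 0.0)
    return {"beta": beta, "beta1": beta1, "t": t, "residuals": resid,
            "sigma2": sigma2, "se": se}


def _fl_basis(X: np.ndarray, group_col: int):
    """Orthonormal bases for the Freedman-Lane shortcut.

    Returns (residualized group column, its squared norm, Q of the reduced
    model, Q of the full model).
    """
    Z = np.delete(X, group_col, axis=1)
    Qz, _ = np.linalg.qr(Z)
    g = X[:, group_col]
    g_til = g - Qz @ (Qz.T @ g)
    gg = float(g_til @ g_til)
    if gg < 1e-10 * max(float(g @ g), 1.0):
        raise ValueError("tested column is collinear with the nuisance model "
                         "(constant group label?)")
    Qx, _ = np.linalg.qr(X)
    return g_til, gg, Qz, Qx


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

@dataclass
class PointwiseStats:
    """Result of pointwise covariate-adjusted group inference."""

    beta1: np.ndarray
    t: np.ndarray
    p_raw: np.ndarray
    p_fwer: np.ndarray
    cohens_d: np.ndarray
    omnibus_p: float
    sigma2: np.ndarray
    n_permutations: int
    seed: int | None
    method: str
    regions: np.ndarray | None = None
    interaction_p: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def effect(self) -> np.ndarray:
        """-beta1: positive = inward deformation in the patient group."""
        return -self.beta1


def _pvalues_from_null(t_obs: np.ndarray, t_null: np.ndarray, add_one: bool):
    """p_raw / p_fwer / omnibus from a (m, K) null |t| sample."""
    tol = 1e-12
    abs_obs = np.abs(t_obs)
    abs_null = np.abs(t_null)
    m = abs_null.shape[0]
    add = 1 if add_one else 0
    exceed = np.sum(abs_null >= abs_obs[None, :] - tol, axis=0)
    p_raw = (add + exceed) / (add + m)
    max_null = abs_null.max(axis=1)
    exceed_max = np.sum(max_null[:, None] >= abs_obs[None, :] - tol, axis=0)
    p_fwer = (add + exceed_max) / (add + m)
    omnibus = (add + int(np.sum(max_null >= abs_obs.max() - tol))) / (add + m)
    return p_raw, np.maximum(p_fwer, p_raw), float(omnibus)


def _null_t_montecarlo(Y, X, group_col, n_perm, rng, block=200):
    n, p = X.shape
    g_til, gg, Qz, Qx = _fl_basis(X, group_col)
    fitted_red = Qz @ (Qz.T @ Y)
    R = Y - fitted_red
    r_norm2 = np.sum(R ** 2, axis=0)
    out = np.empty((n_perm, Y.shape[1]))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        Rp = R[perms]                                   # (b, n, K)
        u = np.einsum("j,bjk->bk", g_til, Rp)
        qr_ = np.einsum("jp,bjk->bpk", Qx, Rp)
        rss = r_norm2[None, :] - np.sum(qr_ ** 2, axis=1)
        rss = np.maximum(rss, 1e-300)
        se = np.sqrt(rss / (n - p) / gg)
        out[done:done + b] = (u / gg) / se
        done += b
    return out


def _null_t_exhaustive(Y, X, group_col):
    """All distinct group-label assignments (nuisance-free designs only)."""
    n = X.shape[0]
    g = X[:, group_col]
    n1 = int(round(g.sum()))
    y_norm2 = np.sum(Y ** 2, axis=0)
    ybar = Y.mean(axis=0)
    gg = n1 * (n - n1) / n
    rows = []
    for combo in itertools.combinations(range(n), n1):
        gstar = np.zeros(n)
        gstar[list(combo)] = 1.0
        gt = gstar - n1 / n
        u = gt @ Y
        rss = np.maximum(y_norm2 - n * ybar ** 2 - u ** 2 / gg, 1e-300)
        se = np.sqrt(rss / (n - 2) / gg)
        rows.append((u / gg) / se)
    return np.asarray(rows)


def permutation_inference(Y: np.ndarray, design: Design, n_perm: int = 10000,
                          seed: int = 0, groups: np.ndarray | None = None,
                          add_cohens_d: bool = True,
                          method: str = "auto") -> PointwiseStats:
    """Freedman-Lane permutation inference on the tested design column.

    Computes pointwise raw p-values, single-step max-|t| FWER-corrected
    p-values and the omnibus shape p-value.  Rows are processed in canonical
    subject order (the design carries sorted subject ids), so results do not
    depend on the input ordering.  Switches to exhaustive enumeration with a
    log note when the design is nuisance-free and the distinct assignments
    are fewer than ``n_perm``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != design.n:
        raise ValueError("marker rows must match design rows")
    fit = fit_pointwise_glm(Y, design)
    X = design.X

    if method not in ("auto", "montecarlo", "exhaustive"):
        raise ValueError(f"unknown method {method!r}")
    nuisance_free = set(design.columns) <= {"intercept", "group"}
    g = X[:, design.group_col]
    n1 = int(round(g.sum()))
    n_assign = math.comb(design.n, n1) if nuisance_free else None
    if method == "exhaustive" and not nuisance_free:
        raise ValueError("exhaustive enumeration requires a nuisance-free design")
    use_exhaustive = nuisance_free and (
        method == "exhaustive" or (method == "auto" and n_assign <= n_perm))
    if use_exhaustive:
        log.info("switching to exhaustive enumeration over %d assignments", n_assign)
        t_null = _null_t_exhaustive(Y, X, design.group_col)
        p_raw, p_fwer, omnibus = _pvalues_from_null(fit["t"], t_null, add_one=False)
        method, n_used = "exhaustive", n_assign
    else:
        rng = np.random.default_rng(seed)
        t_null = _null_t_montecarlo(Y, X, design.group_col, n_perm, rng)
        p_raw, p_fwer, omnibus = _pvalues_from_null(fit["t"], t_null, add_one=True)
        method, n_used = "montecarlo", n_perm

    d = np.full(Y.shape[1], np.nan)
    if add_cohens_d:
        gamma = groups if groups is not None else g
        mask = gamma > 0.5
        if mask.sum() >= 2 and (~mask).sum() >= 2:
            d = np.array([_cohens_d_safe(Y[mask, k], Y[~mask, k]) for k in range(Y.shape[1])])
    return PointwiseStats(
        beta1=fit["beta1"], t=fit["t"], p_raw=p_raw, p_fwer=p_fwer,
        cohens_d=d, omnibus_p=omnibus, sigma2=fit["sigma2"],
        n_permutations=n_used, seed=seed, method=method,
    )


def cohens_d(group_a, group_b) -> float:
    """|mean difference| / pooled SD with (n-1) weights."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = math.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                       / (len(a) + len(b) - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return abs(a.mean() - b.mean()) / pooled


def _cohens_d_safe(a, b) -> float:
    try:
        return cohens_d(a, b)
    except ValueError:
        return float("nan")


def interaction_test(Y: np.ndarray, cov: pd.DataFrame, n_perm: int = 10000,
                     seed: int = 0) -> PointwiseStats:
    """Permutation test of the gender x group interaction coefficient.

    Main factors gender and group plus their product, covarying age and TIV;
    Freedman-Lane with the reduced model = main effects + covariates.  For a
    single column Y this is the area-level interaction test; for a marker
    matrix it is pointwise, with the same max-|t| FWER machinery.
    """
    design = build_design(cov, scope="all", interaction=True)
    stats = permutation_inference(Y, design, n_perm=n_perm, seed=seed,
                                  add_cohens_d=False)
    stats.meta["model"] = "gender + group + gender_x_group + age + tiv"
    return stats


def area_group_analysis(areas: pd.DataFrame, cov: pd.DataFrame,
                        scope: str = "all", n_perm: int = 10000,
                        seed: int = 0) -> pd.DataFrame:
    """Adjusted group comparison of CC/gCC/bCC/sCC areas within a scope.

    One linear model + permutation test per structure; reports the raw group
    means, the permutation p-value, Cohen's d on the raw areas, and the
    covariate-adjusted group difference beta1 (FES - HC).  No correction
    across the four structures (each is reported on its own).
    """
    design = build_design(cov, scope=scope, interaction=False)
    areas = areas.set_index("subject_id") if "subject_id" in areas.columns else areas
    A = areas.loc[design.subject_ids]
    cov_sorted = cov.set_index("subject_id").loc[design.subject_ids]
    fes = (cov_sorted.group == "FES").to_numpy()
    rows = []
    for j, structure in enumerate(STRUCTURES):
        y = A[structure].to_numpy(float)[:, None]
        st = permutation_inference(y, design, n_perm=n_perm, seed=seed + j,
                                   add_cohens_d=False)
        rows.append({
            "structure": structure,
            "scope": scope,
            "hc_mean": float(y[~fes].mean()),
            "hc_sd": float(y[~fes].std(ddof=1)),
            "fes_mean": float(y[fes].mean()),
            "fes_sd": float(y[fes].std(ddof=1)),
            "p_value": float(st.p_raw[0]),
            "cohens_d": _cohens_d_safe(y[fes, 0], y[~fes, 0]),
            "group_difference": float(st.beta1[0]),
        })
    return pd.DataFrame(rows)


def summarize_significant(stats: PointwiseStats, alpha: float = 0.05,
                          regions: np.ndarray | None = None) -> dict:
    """Summary of FWER-significant template points.

    Returns the significant indices, counts per sub-region, the mean +/- SD
    of Cohen's d over significant points (absent when the set is empty) and
    the contiguous cyclic arc clusters of significant indices.
    """
    from .curves import REGION_NAMES

    sig = np.nonzero(stats.p_fwer <= alpha)[0]
    out = {"alpha": alpha, "indices": sig.tolist(), "n_significant": int(len(sig))}
    regions = regions if regions is not None else stats.regions
    if regions is not None:
        names = [REGION_NAMES[int(r)] for r in np.asarray(regions)[sig]]
        out["counts_by_region"] = {nm: names.count(nm) for nm in ("gCC", "bCC", "sCC")}
    if len(sig) > 0 and np.all(np.isfinite(stats.cohens_d[sig])):
        d = stats.cohens_d[sig]
        out["mean_cohens_d"] = float(d.mean())
        out["sd_cohens_d"] = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    else:
        out["mean_cohens_d"] = None
        out["sd_cohens_d"] = None
    if regions is not None:
        k = len(np.asarray(regions))
    else:
        k = len(stats.p_fwer)
    mask = np.zeros(k, dtype=bool)
    mask[sig] = True
    out["clusters"] = _cyclic_runs(mask)
    return out


def _cyclic_runs(mask: np.ndarray) -> list:
    """Contiguous cyclic index runs [start, end] of True entries."""
    n = len(mask)
    if mask.all():
        return [[0, n - 1]]
    if not mask.any():
        return []
    runs = []
    # rotate so position 0 is False, then scan linearly
    shift = int(np.argmin(mask))
    rolled = np.roll(mask, -shift)
    start = None
    for i, v in enumerate(rolled):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append([(start + shift) % n, (i - 1 + shift) % n])
            start = None
    if start is not None:
        runs.append([(start + shift) % n, (len(rolled) - 1 + shift) % n])
    return runs
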