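"""Vertex-wise Hotelling's T^2 group inference with permutation correction.

At every template vertex each subject contributes a 4-vector (three mTBM
components plus radial distance).  The group difference is measured with the
Mahalanobis distance

    M = [N_S N_T / (N_S + N_T)] (S_bar - T_bar)^T Sigma^{-1} (S_bar - T_bar)

where Sigma is the pooled (combined, Bessel-corrected) covariance of the two
groups — identically Hotelling's two-sample T^2.  Vertex p-values come from a
permutation test sharing one label-shuffle schedule across vertices; the
map-level (multiple-comparison corrected) p-value is the permutation
probability of an equal-or-larger total surface area of vertices passing the
pointwise p <= 0.05 threshold, with each permutation's vertex p-values
computed against the same permutation null (nested scheme, evaluated by
ranking).  CDFs of the uncorrected p-values against the uniform null line
summarize effect sizes across contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PMap",
    "CdfCurve",
    "mahalanobis_group_distance",
    "mahalanobis_map",
    "vertex_permutation_test",
    "overall_map_significance",
    "pvalue_cdf",
    "run_group_contrast",
    "hotelling_f_pvalue",
]


@dataclass
class PMap:
    m_value: np.ndarray
    p_uncorrected: np.ndarray
    suprathreshold_area: float
    overall_p: float
    n_permutations: int
    seed: int
    p_threshold: float = 0.05
    note: str = ""


@dataclass
class CdfCurve:
    """Empirical CDF of vertex p-values with null and FDR reference lines."""

    p_sorted: np.ndarray
    cum_fraction: np.ndarray
    fdr_q: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p": self.p_sorted,
                "cdf": self.cum_fraction,
                "null_line": self.p_sorted,
                "fdr_line": self.p_sorted / self.fdr_q,
            }
        )

    def value_at(self, abscissa: float) -> float:
        """CDF evaluated at a p-value abscissa (fraction of p <= abscissa)."""
        return float(np.searchsorted(self.p_sorted, abscissa, side="right")) / len(
            self.p_sorted
        )


def _pooled_covariance(S: np.ndarray, T: np.ndarray) -> np.ndarray:
    cs = np.cov(S, rowvar=False, ddof=1)
    ct = np.cov(T, rowvar=False, ddof=1)
    p, q = len(S), len(T)
    return ((p - 1) * cs + (q - 1) * ct) / (p + q - 2)


def mahalanobis_group_distance(group_s: np.ndarray, group_t: np.ndarray) -> float:
    """Mahalanobis group-mean distance M for two samples of d-vectors.

    Symmetric in group order and zero iff the sample means coincide.  A
    near-singular pooled covariance is ridge-regularized with
    eps = 1e-8 tr(Sigma)/d before inversion.
    """
    S = np.atleast_2d(np.asarray(group_s, float))
    T = np.atleast_2d(np.asarray(group_t, float))
    if S.ndim == 2 and S.shape[1] == 1:
        pass
    p, q = len(S), len(T)
    if p < 2 or q < 2:
        raise ValueError("each group needs at least 2 subjects")
    d = S.shape[1]
    diff = S.mean(axis=0) - T.mean(axis=0)
    sigma = np.atleast_2d(_pooled_covariance(S, T))
    try:
        sol = np.linalg.solve(sigma, diff)
    except np.linalg.LinAlgError:
        eps = 1e-8 * np.trace(sigma) / d
        sol = np.linalg.solve(sigma + eps * np.eye(d), diff)
    return float(p * q / (p + q) * diff @ sol)


def hotelling_f_pvalue(m_value: float, n_s: int, n_t: int, dim: int = 4) -> float:
    """Analytic p of Hotelling's T^2 (= M) via its F transformation."""
    n = n_s + n_t
    df2 = n - dim - 1
    if df2 <= 0:
        raise ValueError("too few subjects for the F approximation")
    f_stat = m_value * df2 / (dim * (n - 2))
    return float(sps.f.sf(f_stat, dim, df2))


# ---------------------------------------------------------------------------
# vectorized machinery over vertices and permutations


def _label_matrix(n_s: int, n_t: int, n_perm: int, seed: int) -> np.ndarray:
    """(n_perm + 1, N) boolean membership of group S; row 0 is observed."""
    rng = np.random.default_rng(seed)
    n = n_s + n_t
    rows = np.zeros((n_perm + 1, n), dtype=bool)
    rows[0, :n_s] = True
    for r in range(1, n_perm + 1):
        rows[r, rng.permutation(n)[:n_s]] = True
    return rows

def _m_matrix(X: np.ndarray, labels: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """M at every vertex for every labelling. X: (N, V, d) finite data.

    Uses the identity  sum_g (x - m_g)(x - m_g)^T = sum x x^T - p m_S m_S^T
    - q m_T m_T^T  so only group means vary across permutations; the total
    second moment is computed once.
    """
    N, V, d = X.shape
    R = labels.shape[0]
    total2 = np.einsum("nvi,nvj->vij", X, X)  # (V, d, d)
    total1 = X.sum(axis=0)  # (V, d)
    p = labels[0].sum()
    q = N - p
    factor = p * q / N
    M = np.empty((R, V))
    eye = np.eye(d)
    chunk = max(1, int(2e7 // (V * d * d)))
    for r0 in range(0, R, chunk):
        lab = labels[r0 : r0 + chunk]  # (r, N)
        sum_s = np.einsum("rn,nvi->rvi", lab.astype(float), X)
        m_s = sum_s / p
        m_t = (total1[None] - sum_s) / q
        scatter = (
            total2[None]
            - p * np.einsum("rvi,rvj->rvij", m_s, m_s)
            - q * np.einsum("rvi,rvj->rvij", m_t, m_t)
        )
        sigma = scatter / (N - 2)
        tr = np.trace(sigma, axis1=2, axis2=3)
        sigma = sigma + (ridge * tr / d)[..., None, None] * eye
        diff = m_s - m_t
        sol = np.linalg.solve(sigma, diff[..., None])[..., 0]
        M[r0 : r0 + chunk] = factor * np.einsum("rvi,rvi->rv", diff, sol)
    return M


def _rank_pvalues(M: np.ndarray) -> np.ndarray:
    """p_i = #{j: M_j >= M_i} / R per column (self included).

    For the observed row (i = 0) this equals the add-one estimator
    (1 + #{permuted >= observed}) / (1 + n_perm); permutation rows get their
    p on the same scale against the same shared null, which is what the
    nested map-level correction needs.
    """
    R = M.shape[0]
    sortedM = np.sort(M, axis=0)
    smaller = np.empty(M.shape, dtype=np.int64)
    for v in range(M.shape[1]):
        smaller[:, v] = np.searchsorted(sortedM[:, v], M[:, v], side="left")
    return (R - smaller) / R


def vertex_permutation_test(
    group_s: np.ndarray,
    group_t: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex permutation p-values for the Mahalanobis statistic.

    ``group_s``/``group_t`` are (N_g, V, d) arrays.  One shuffle schedule is
    shared by all vertices.  Returns ``(p_uncorrected, observed_M)``; p uses
    the add-one convention p = (1 + #{M_perm >= M_obs}) / (1 + n_perm), so
    its smallest attainable value is 1/(n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    X = np.concatenate([group_s, group_t], axis=0)
    labels = _label_matrix(len(group_s), len(group_t), n_perm, seed)
    M = _m_matrix(X, labels)
    obs = M[0]
    count_ge = (M[1:] >= obs[None]).sum(axis=0)
    p = (1.0 + count_ge) / (1.0 + n_perm)
    return p, obs


def overall_map_significance(
    group_s: np.ndarray,
    group_t: np.ndarray,
    vertex_areas: np.ndarray,
    p_threshold: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
) -> PMap:
    """Suprathreshold-area correction of the vertex p-map.

    The observed statistic is the total surface area (mm^2) of vertices with
    p <= ``p_threshold``.  The null distribution recomputes that area for
    every label permutation, with each permutation's vertex p-values ranked
    against the same shared permutation null (nested scheme);
    overall_p = (1 + #{null area >= observed}) / (1 + n_perm).
    """
    X = np.concatenate([group_s, group_t], axis=0)
    labels = _label_matrix(len(group_s), len(group_t), n_perm, seed)
    M = _m_matrix(X, labels)
    R = M.shape[0]

    p_all = _rank_pvalues(M)
    p_obs = p_all[0]
    areas = np.where(p_all <= p_threshold, vertex_areas[None, :], 0.0).sum(axis=1)
    area_obs = float(np.where(p_obs <= p_threshold, vertex_areas, 0.0).sum())
    null_areas = areas[1:]
    overall_p = (1.0 + (null_areas >= area_obs - 1e-12).sum()) / (1.0 + n_perm)
    note = ""
    if area_obs == 0.0:
        overall_p = 1.0
        note = "zero suprathreshold area"
    return PMap(
        m_value=M[0],
        p_uncorrected=p_obs,
        suprathreshold_area=area_obs,
        overall_p=float(overall_p),
        n_permutations=n_perm,
        seed=seed,
        p_threshold=p_threshold,
        note=note,
    )


def pvalue_cdf(p_values: np.ndarray, fdr_q: float = 0.05) -> CdfCurve:
    """Empirical CDF of a p-map (sorted p vs cumulative vertex fraction)."""
    p = np.asarray(p_values, float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("empty p-map")
    ps = np.sort(p)
    frac = np.arange(1, len(ps) + 1) / len(ps)
    return CdfCurve(p_sorted=ps, cum_fraction=frac, fdr_q=fdr_q)


def plot_cdfs(curves: dict, path, max_abscissa: float = 1.0) -> None:
    """Plot p-value CDFs against the y = x null line and the q=0.05 FDR line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        ax.plot(
            np.concatenate([[0.0], curve.p_sorted]),
            np.concatenate([[0.0], curve.cum_fraction]),
            drawstyle="steps-post",
            label=name,
        )
    x = np.linspace(0, max_abscissa, 64)
    ax.plot(x, x, "k--", lw=1, label="null (y = x)")
    ax.plot(x, np.clip(x / 0.05, 0, 1), "k:", lw=1, label="FDR q = 0.05")
    ax.set_xlim(0, max_abscissa)
    ax.set_ylim(0, 1)
    ax.set_xlabel("p-value")
    ax.set_ylabel("cumulative vertex fraction")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_group_contrast(
    cohort: pd.DataFrame,
    stats_by_subject: dict,
    selector_s,
    selector_t,
    vertex_areas: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    p_threshold: float = 0.05,
    mask: np.ndarray | None = None,
) -> tuple[PMap, CdfCurve, dict]:
    """Run one two-group contrast over a cohort table.

    ``selector_s`` / ``selector_t`` are either sets of dose levels (pooling,
    e.g. {1, 2} = carriers) or callables on the cohort frame returning a
    boolean mask.  ``stats_by_subject`` maps subject_id -> (V, 4) array.
    Vertices invalid in any selected subject (or excluded by ``mask``) are
    dropped from inference; the report records group sizes and the mask.
    """

    def _select(sel):
        if callable(sel):
            rows = cohort[sel(cohort)]
        else:
            rows = cohort[cohort["dose"].isin(set(sel))]
        ids = [s for s in rows["subject_id"] if s in stats_by_subject]
        return ids

    ids_s = _select(selector_s)
    ids_t = _select(selector_t)
    if not ids_s or not ids_t:
        available = sorted(cohort["dose"].unique().tolist())
        raise ValueError(
            f"empty group selection (S={len(ids_s)}, T={len(ids_t)}); "
            f"available dose levels: {available}"
        )
    S = np.stack([stats_by_subject[i] for i in ids_s])
    T = np.stack([stats_by_subject[i] for i in ids_t])
    finite = np.all(np.isfinite(S), axis=(0, 2)) & np.all(np.isfinite(T), axis=(0, 2))
    if mask is not None:
        finite &= np.asarray(mask, bool)
    if not finite.any():
        raise ValueError("no vertices usable in every selected subject")
    Sm = S[:, finite]
    Tm = T[:, finite]
    pm = overall_map_significance(
        Sm, Tm, vertex_areas[finite], p_threshold=p_threshold, n_perm=n_perm, seed=seed
    )

    V = S.shape[1]
    p_full = np.full(V, np.nan)
    m_full = np.full(V, np.nan)
    p_full[finite] = pm.p_uncorrected
    m_full[finite] = pm.m_value
    pm.p_uncorrected = p_full
    pm.m_value = m_full
    cdf = pvalue_cdf(p_full[finite])
    report = {
        "n_s": len(ids_s),
        "n_t": len(ids_t),
        "subjects_s": ids_s,
        "subjects_t": ids_t,
        "n_perm": n_perm,
        "n_vertices_tested": int(finite.sum()),
        "n_vertices_masked": int(V - finite.sum()),
        "suprathreshold_area": pm.suprathreshold_area,
        "overall_p": pm.overall_p,
        "seed": seed,
    }
    return pm, cdf, report
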