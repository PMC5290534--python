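"""Group statistics: age residualization, Hotelling T² permutation tests,
structure-wise correction, volume tests, ratio and correlation maps.

All permutation p-values use the add-one estimator
``p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm)`` so they are never
zero, and one label schedule drawn from the seed is shared by every vertex
(and across structures analyzed with the same seed), which makes the
combined-structure omnibus test well defined.

The structure-wise multiple-comparisons correction uses a suprathreshold
vertex-count omnibus statistic: the observed statistic joins its n_perm
permuted replicates in one exchangeable pool per vertex; an element is
"significant" at a vertex when its pooled p-value is <= alpha_vertex, and
the corrected p compares the observed count of significant vertices with
the count achieved by each permutation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, ValidationError

_PERM_CHUNK = 512  # permutations per vectorized block

COHORT_COLUMNS = ("id", "group", "age", "sex", "santa_ana")


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check the covariates table invariants and return it."""
    for col in ("id", "group", "age"):
        if col not in table.columns:
            raise ValidationError(f"cohort table missing column {col!r}")
    if table["id"].duplicated().any():
        raise ValidationError("cohort table has duplicate subject ids")
    if not set(table["group"]) <= {"high", "low"}:
        raise ValidationError("group labels must be 'high' or 'low'")
    if (table["group"] == "high").sum() < 2 or (table["group"] == "low").sum() < 2:
        raise ValidationError("each exposure group needs at least 2 subjects")
    if (table["age"] <= 0).any():
        raise ValidationError("ages must be positive")
    return table


@dataclass
class StatMap:
    """Vertex-wise statistic map plus its structure-wise correction.

    ``stat`` and ``p`` are flat per-vertex arrays; ``corrected_p`` is the
    single structure-wise p; ``perm_counts`` holds the omnibus
    (suprathreshold-vertex) count for each permutation so that maps from
    different structures sharing a schedule can be combined.
    """

    stat: np.ndarray
    p: np.ndarray
    corrected_p: float
    omnibus_count: int
    perm_counts: np.ndarray
    n_perm: int
    seed: int
    alpha_vertex: float
    statistic: str = "hotelling_t2"
    notes: list = field(default_factory=list)


def _as_bool_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    uniq = sorted(set(labels.tolist()))
    if uniq == ["high", "low"]:
        return labels == "high"
    if len(uniq) != 2:
        raise ValidationError(f"labels must be two-level, got {uniq}")
    return labels == uniq[0]


def permutation_schedule(n: int, n_perm: int, seed: int):
    """Shared label-shuffle schedule: (n_perm, n) index matrix.

    If the requested count exceeds the number of distinct label arrangements
    for the given group split, all distinct arrangements are enumerated
    instead (with a notice).
    """
    rng = np.random.default_rng(seed)
    return np.argsort(rng.random((n_perm, n)), axis=1)


def _distinct_assignments(labels: np.ndarray, n_perm: int):
    """Enumerate all distinct boolean label assignments if fewer than n_perm."""
    n = labels.size
    nA = int(labels.sum())
    total = math.comb(n, nA)
    if total > n_perm:
        return None
    from itertools import combinations

    out = np.zeros((total, n), dtype=bool)
    for k, pos in enumerate(combinations(range(n), nA)):
        out[k, list(pos)] = True
    return out


def residualize(features: np.ndarray, ages) -> np.ndarray:
    """Remove a pooled linear age trend from every vertex-channel.

    ``features`` is (n_subjects, ...); each trailing component is regressed
    on (intercept, age) by OLS across subjects, and the residuals returned.
    Residuals are mean-zero and exactly orthogonal to age.
    """
    X = np.asarray(features, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n = X.shape[0]
    if ages.shape != (n,):
        raise ValidationError("ages must have one entry per subject")
    if n < 3:
        raise ValidationError("residualization needs at least 3 subjects")
    if np.ptp(ages) == 0:
        raise DomainError("constant age vector: degenerate regression design")
    A = np.column_stack([np.ones(n), ages])
    flat = X.reshape(n, -1)
    coef, *_ = np.linalg.lstsq(A, flat, rcond=None)
    resid = flat - A @ coef
    return resid.reshape(X.shape)


def hotelling_t2(group_a: np.ndarray, group_b: np.ndarray, ridge: float = 1e-8) -> float:
    """Two-sample Hotelling T² with pooled covariance.

    T² = (nA nB / n) (x̄A - x̄B)ᵀ Σ̂⁻¹ (x̄A - x̄B).  A ridge of
    ``ridge * trace(Σ̂)/c`` is added only when Σ̂ is ill-conditioned
    (condition number > 1e10).
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    nA, nB = len(A), len(B)
    if nA < 2 or nB < 2:
        raise ValidationError("each group needs at least 2 observations")
    c = A.shape[1]
    d = A.mean(axis=0) - B.mean(axis=0)
    S = ((A - A.mean(axis=0)).T @ (A - A.mean(axis=0)) +
         (B - B.mean(axis=0)).T @ (B - B.mean(axis=0))) / (nA + nB - 2)
    if np.linalg.cond(S) > 1e10:
        S = S + ridge * np.trace(S) / c * np.eye(c)
    t2 = nA * nB / (nA + nB) * float(d @ np.linalg.solve(S, d))
    return t2


def hotelling_t2_f_pvalue(t2: float, n_a: int, n_b: int, n_channels: int) -> float:
    """Analytic p via the T²->F transform (used as an oracle, not primary)."""
    n = n_a + n_b
    df2 = n - 1 - n_channels
    f = t2 * df2 / (n_channels * (n - 2))
    return float(sps.f.sf(f, n_channels, df2))


def _t2_for_assignments(X: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Hotelling T² for many label assignments at once.

    X: (n, V, C) features; G: (P, n) boolean, True = group A.
    Returns (P, V).  Uses the scatter identity
    S_pooled = Σ x xᵀ - nA m_A m_Aᵀ - nB m_B m_Bᵀ.
    """
    n, V, C = X.shape
    nA = int(G[0].sum())
    nB = n - nA
    total = X.sum(axis=0)  # (V, C)
    TXX = np.einsum("nvc,nvd->vcd", X, X)  # (V, C, C)
    out = np.empty((len(G), V))
    for s in range(0, len(G), _PERM_CHUNK):
        Gc = G[s : s + _PERM_CHUNK].astype(float)
        sumA = np.einsum("pn,nvc->pvc", Gc, X)
        mA = sumA / nA
        mB = (total[None] - sumA) / nB
        d = mA - mB
        S = (
            TXX[None]
            - nA * np.einsum("pvc,pvd->pvcd", mA, mA)
            - nB * np.einsum("pvc,pvd->pvcd", mB, mB)
        ) / (n - 2)
        try:
            sol = np.linalg.solve(S, d[..., None])[..., 0]
        except np.linalg.LinAlgError:
            S = S + 1e-8 * np.einsum("pvii->pv", S)[..., None, None] / C * np.eye(C)
            sol = np.linalg.solve(S, d[..., None])[..., 0]
        out[s : s + len(Gc)] = nA * nB / n * np.einsum("pvc,pvc->pv", d, sol)
    return out


def _pooled_significance(obs: np.ndarray, perm: np.ndarray, alpha: float):
    """Suprathreshold counts from the exchangeable obs+perm pool.

    Element x is significant at a vertex iff #{pool >= x} <= K with
    K = floor(alpha * (P + 1)); equivalently x strictly exceeds the
    (K+1)-th largest pooled value.
    """
    P = perm.shape[0]
    pool = np.vstack([obs[None], perm])  # (P+1, V)
    K = int(np.floor(alpha * (P + 1)))
    if K < 1:
        # alpha below the permutation resolution: nothing can be significant
        return 0, np.zeros(P, dtype=int)
    cut = np.partition(pool, P + 1 - (K + 1), axis=0)[P + 1 - (K + 1)]  # (K+1)-th largest
    count_obs = int((obs > cut).sum())
    perm_counts = (perm > cut[None]).sum(axis=1)
    return count_obs, perm_counts


def vertexwise_permutation_test(
    features: np.ndarray,
    labels,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha_vertex: float = 0.05,
    return_archive: bool = False,
):
    """Vertex-wise Hotelling T² group test with a shared permutation null.

    ``features`` is (n_subjects, n_vertices, n_channels), typically the
    age-residualized 4-feature; ``labels`` marks the two exposure groups.
    Returns a :class:`StatMap`; with ``return_archive=True`` also the full
    (n_perm, n_vertices) permuted-T² array for diagnostic use.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 2:
        X = X[..., None]
    n, V, C = X.shape
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if not (0 < alpha_vertex < 1):
        raise ValidationError("alpha_vertex must lie in (0, 1)")
    lab = _as_bool_labels(labels)
    if lab.shape != (n,):
        raise ValidationError("labels must have one entry per subject")
    notes = []
    enum = _distinct_assignments(lab, n_perm)
    if enum is not None:
        notes.append(
            f"only {len(enum)} distinct label assignments; exhaustive enumeration used"
        )
        G = enum
        n_eff = len(enum)
        obs = _t2_for_assignments(X, lab[None])[0]
        perm = _t2_for_assignments(X, G)
    else:
        sched = permutation_schedule(n, n_perm, seed)
        G = lab[sched]
        n_eff = n_perm
        obs = _t2_for_assignments(X, lab[None])[0]
        perm = _t2_for_assignments(X, G)
    p = (1 + (perm >= obs[None]).sum(axis=0)) / (1 + n_eff)
    count_obs, perm_counts = _pooled_significance(obs, perm, alpha_vertex)
    corrected = (1 + int((perm_counts >= count_obs).sum())) / (1 + n_eff)
    sm = StatMap(
        stat=obs,
        p=p,
        corrected_p=corrected,
        omnibus_count=count_obs,
        perm_counts=perm_counts,
        n_perm=n_eff,
        seed=seed,
        alpha_vertex=alpha_vertex,
        notes=notes,
    )
    if return_archive:
        return sm, perm
    return sm


def structurewise_correction(
    statmap: StatMap, perm_archive: np.ndarray, alpha_vertex: float = 0.05
) -> float:
    """Recompute the structure-wise corrected p from a permutation archive.

    The archive must come from the same schedule that produced the map
    (``vertexwise_permutation_test(..., return_archive=True)``).
    """
    if not (0 < alpha_vertex < 1):
        raise ValidationError("alpha_vertex must lie in (0, 1)")
    if perm_archive.shape != (statmap.n_perm, statmap.stat.size):
        raise ValidationError("permutation archive does not match the stat map")
    count_obs, perm_counts = _pooled_significance(
        statmap.stat, perm_archive, alpha_vertex
    )
    return (1 + int((perm_counts >= count_obs).sum())) / (1 + statmap.n_perm)


def combine_structures(statmaps) -> float:
    """Corrected p over the union of vertex sets of several stat maps.

    All maps must share the permutation schedule (same seed and n_perm);
    omnibus counts add across structures/sides.
    """
    statmaps = list(statmaps)
    if not statmaps:
        raise ValidationError("need at least one stat map")
    first = statmaps[0]
    for sm in statmaps[1:]:
        if (sm.seed, sm.n_perm, sm.alpha_vertex) != (
            first.seed,
            first.n_perm,
            first.alpha_vertex,
        ):
            raise ValidationError(
                "stat maps use different permutation schedules; refuse to combine"
            )
    count_obs = sum(sm.omnibus_count for sm in statmaps)
    perm_counts = np.sum([sm.perm_counts for sm in statmaps], axis=0)
    return (1 + int((perm_counts >= count_obs).sum())) / (1 + first.n_perm)


def pooled_t_statistic(values: np.ndarray, mask_a: np.ndarray) -> float:
    """Two-sample pooled-variance t statistic."""
    a = values[mask_a]
    b = values[~mask_a]
    nA, nB = len(a), len(b)
    sp2 = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    sp2 /= nA + nB - 2
    if sp2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / nA + 1 / nB)))


def volume_permutation_ttest(
    volumes, labels, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Two-sided permutation p of the pooled t statistic on structure volumes."""
    vols = np.asarray(volumes, dtype=float)
    lab = _as_bool_labels(labels)
    if lab.sum() < 2 or (~lab).sum() < 2:
        raise ValidationError("each group needs at least 2 volumes")
    a, b = vols[lab], vols[~lab]
    sp2 = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if sp2 == 0:
        warnings.warn("all volumes equal within groups: p = 1", stacklevel=2)
        return 1.0
    obs = abs(pooled_t_statistic(vols, lab))
    n = len(vols)
    nA = int(lab.sum())
    nB = n - nA
    sched = permutation_schedule(n, n_perm, seed)
    G = lab[sched].astype(float)
    # pooled t for all shuffles at once via the fixed-total-scatter identity
    tot = vols.sum()
    mean = tot / n
    ss_tot = ((vols - mean) ** 2).sum()
    mA = (G @ vols) / nA
    mB = (tot - G @ vols) / nB
    ss_between = nA * (mA - mean) ** 2 + nB * (mB - mean) ** 2
    sp2_perm = np.maximum(ss_tot - ss_between, 0.0) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        perm = np.abs(mA - mB) / np.sqrt(sp2_perm * (1 / nA + 1 / nB))
    perm = np.nan_to_num(perm, nan=np.inf, posinf=np.inf)
    return (1 + int((perm >= obs).sum())) / (1 + n_perm)


def detj_ratio_map(high_detj: np.ndarray, low_detj: np.ndarray) -> np.ndarray:
    """Vertex-wise mean det J ratio, high over low exposure group.

    Values above 1 mark local enlargement in the high group.  Vertices with
    a zero or undefined denominator come back NaN.
    """
    high = np.atleast_2d(np.asarray(high_detj, dtype=float))
    low = np.atleast_2d(np.asarray(low_detj, dtype=float))
    if high.shape[1:] != low.shape[1:]:
        raise ValidationError("group det J fields have mismatched vertex counts")
    mh = np.nanmean(high, axis=0)
    ml = np.nanmean(low, axis=0)
    out = np.full(mh.shape, np.nan)
    ok = np.isfinite(ml) & (ml != 0) & np.isfinite(mh)
    out[ok] = mh[ok] / ml[ok]
    return out


@dataclass
class CorrelationMap:
    """Vertex-wise Pearson r of det J against a behavioral score."""

    r: np.ndarray
    p: np.ndarray
    corrected_p: float
    omnibus_count: int
    perm_counts: np.ndarray
    n_perm: int
    seed: int
    alpha_vertex: float


def score_correlation_map(
    detj: np.ndarray,
    scores,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha_vertex: float = 0.05,
) -> CorrelationMap:
    """Pearson correlation of vertex det J with motor scores, permutation p.

    Two-sided p from permuting the score vector (shared schedule); the
    structure-wise correction pools |r| exactly as the group test pools T².
    Negative r at a vertex means local enlargement goes with worse
    performance (scores are higher-is-better).
    """
    X = np.asarray(detj, dtype=float)
    s = np.asarray(scores, dtype=float)
    n, V = X.shape
    if s.shape != (n,):
        raise ValidationError("scores must have one entry per subject")
    if n < 4:
        raise ValidationError("correlation map needs at least 4 subjects")
    if np.ptp(s) == 0:
        raise ValidationError("constant scores: correlation undefined")
    Xc = X - X.mean(axis=0)
    xnorm = np.linalg.norm(Xc, axis=0)
    xnorm = np.where(xnorm == 0, np.inf, xnorm)
    sc = s - s.mean()
    snorm = np.linalg.norm(sc)
    r = (sc @ Xc) / (snorm * xnorm)
    sched = permutation_schedule(n, n_perm, seed)
    perm_r = (sc[sched] @ Xc) / (snorm * xnorm[None])
    obs_abs = np.abs(r)
    perm_abs = np.abs(perm_r)
    p = (1 + (perm_abs >= obs_abs[None]).sum(axis=0)) / (1 + n_perm)
    count_obs, perm_counts = _pooled_significance(obs_abs, perm_abs, alpha_vertex)
    corrected = (1 + int((perm_counts >= count_obs).sum())) / (1 + n_perm)
    return CorrelationMap(
        r=r,
        p=p,
        corrected_p=corrected,
        omnibus_count=count_obs,
        perm_counts=perm_counts,
        n_perm=n_perm,
        seed=seed,
        alpha_vertex=alpha_vertex,
    )
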