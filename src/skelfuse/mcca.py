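"""Multi-set regularized (linear-kernel) canonical correlation analysis.

Given K z-scored views X_k (subjects x features, shared subject order), the
model seeks per-view projections W_k maximizing the sum of pairwise
correlations between the projected variates A_k = X_k W_k (the SUMCOR
objective), subject to per-view regularized unit variance
W_k^T (C_kk + c I) W_k = I.  This is the generalized eigenproblem

    [ 0    C_12 ... ]            [ C_11 + cI           ]
    [ C_21  0   ... ]  w  =  λ   [           C_22 + cI ]  w
    [ ...           ]            [                ...  ]

whose top-D eigenvectors, partitioned by view, give the D canonical
components.  With two views this reduces to classical regularized CCA.

The solve is carried out in each view's row space (an SVD reduction), which is
exact for the linear kernel and keeps the eigenproblem at most
``n_views * n_subjects`` dimensional regardless of voxel count — the same
reason the motivating design uses a linear kernel on high-dimensional
skeleton data.

Downstream, canonical components are screened for group discrimination:
per (component, view) the variate scores undergo IQR outlier removal and a
two-sided Mann-Whitney U test between groups, Benjamini-Hochberg corrected
across the whole component x view family; components significant in >= 2
views are labelled *joint*, in exactly one view *unique*.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .data_model import CohortDataset

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ViewSet:
    """Named z-scored views sharing subject order."""

    views: dict[str, np.ndarray]

    @property
    def view_names(self) -> list[str]:
        return list(self.views)

    @property
    def n_subjects(self) -> int:
        return next(iter(self.views.values())).shape[0]

    def subset(self, idx: np.ndarray) -> "ViewSet":
        return ViewSet({k: v[idx] for k, v in self.views.items()})


def prepare_views(
    dataset: CohortDataset, view_names: Sequence[str] | None = None
) -> ViewSet:
    """Per-feature z-scoring over subjects; constant features are dropped."""
    names = list(view_names) if view_names is not None else dataset.metric_names
    views: dict[str, np.ndarray] = {}
    for name in names:
        x = dataset.metrics[name]
        sd = x.std(axis=0, ddof=0)
        keep = sd > 0
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning(
                "view %s: dropped %d constant features", name, n_drop
            )
        if not keep.any():
            raise ValueError(f"view {name} reduced to zero features")
        xk = x[:, keep]
        views[name] = (xk - xk.mean(axis=0)) / sd[keep]
    return ViewSet(views)


@dataclasses.dataclass
class CCAModel:
    """Fitted multi-set CCA: weights, variates, and per-component pairwise
    canonical-correlation matrices (``ccc[d][i, j]``)."""

    view_names: list[str]
    weights: dict[str, np.ndarray]  # V_k x D
    variates: dict[str, np.ndarray]  # N x D
    D: int
    reg: float
    ccc: np.ndarray  # D x K x K

    def transform(self, views: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        return {k: np.asarray(views[k]) @ self.weights[k] for k in self.view_names}


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_mcca(views: ViewSet, reg: float = 0.01, D: int = 1) -> CCAModel:
    """Fit the SUMCOR generalized eigenproblem; deterministic up to the sign
    convention (each variate positively correlated with view 1's, component
    by component)."""
    if reg < 0:
        raise ValueError("regularization must be non-negative")
    names = views.view_names
    mats = [np.asarray(views.views[k], dtype=float) for k in names]
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("views must share the subject dimension")

    # reduce each view to its row space: X_k = U_k S_k V_k^T, w_k = V_k b_k
    bases: list[np.ndarray] = []
    reduced: list[np.ndarray] = []  # Z_k = U_k S_k  (n x r_k)
    for k, x in enumerate(mats):
        if reg == 0 and x.shape[1] > n:
            raise ValueError(
                f"view {names[k]}: singular autocovariance at c=0 with more "
                "features than subjects; use reg > 0"
            )
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        keep = s > max(s.max(), 1.0) * 1e-10 if s.size else np.zeros(0, bool)
        if not keep.any():
            raise ValueError(f"view {names[k]} has zero variance")
        bases.append(vt[keep].T)
        reduced.append(u[:, keep] * s[keep])
    ranks = [z.shape[1] for z in reduced]
    if D > min(ranks):
        raise ValueError(f"D={D} exceeds the smallest view rank {min(ranks)}")
    offsets = np.concatenate([[0], np.cumsum(ranks)])
    dim = offsets[-1]

    denom = max(n - 1, 1)
    lhs = np.zeros((dim, dim))
    rhs = np.zeros((dim, dim))
    for i, zi in enumerate(reduced):
        si = slice(offsets[i], offsets[i + 1])
        rhs[si, si] = (zi.T @ zi) / denom + reg * np.eye(ranks[i])
        for j in range(i + 1, len(reduced)):
            sj = slice(offsets[j], offsets[j + 1])
            cij = (zi.T @ reduced[j]) / denom
            lhs[si, sj] = cij
            lhs[sj, si] = cij.T
    if reg == 0:
        # guard against numerically singular autocovariances
        try:
            linalg.cholesky(rhs)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "singular regularized autocovariance at c=0; use reg > 0"
            ) from exc
    vals, vecs = linalg.eigh(lhs, rhs)
    order = np.argsort(vals)[::-1][:D]
    top = vecs[:, order]  # dim x D

    weights: dict[str, np.ndarray] = {}
    variates: dict[str, np.ndarray] = {}
    for i, name in enumerate(names):
        b = top[offsets[i]: offsets[i + 1]]
        # per-view regularized unit variance
        zi = reduced[i]
        for d in range(D):
            var = (zi @ b[:, d]).var(ddof=1) + reg * (b[:, d] @ b[:, d])
            if var > 0:
                b[:, d] = b[:, d] / np.sqrt(var)
        weights[name] = bases[i] @ b
        variates[name] = mats[i] @ weights[name]

    # sign convention: anchor view 1's variate to a positive leading weight,
    # then make every other view's variate positively correlated with it
    anchor = names[0]
    for d in range(D):
        wa = weights[anchor][:, d]
        lead = wa[np.argmax(np.abs(wa))] if wa.size else 0.0
        if lead < 0:
            for name in (anchor,):
                weights[name][:, d] *= -1
                variates[name][:, d] *= -1
        for name in names[1:]:
            if _safe_corr(variates[name][:, d], variates[anchor][:, d]) < 0:
                weights[name][:, d] *= -1
                variates[name][:, d] *= -1

    k = len(names)
    ccc = np.zeros((D, k, k))
    for d in range(D):
        for i in range(k):
            ccc[d, i, i] = 1.0
            for j in range(i + 1, k):
                r = _safe_corr(variates[names[i]][:, d], variates[names[j]][:, d])
                ccc[d, i, j] = ccc[d, j, i] = r
    return CCAModel(
        view_names=names, weights=weights, variates=variates,
        D=D, reg=float(reg), ccc=ccc,
    )


def default_reg_grid() -> np.ndarray:
    """10 log-spaced regularization values in [1e-4, 1e2]."""
    return np.logspace(-4, 2, 10)


def cv_select_hyperparams(
    views: ViewSet,
    reg_grid: Sequence[float] | None = None,
    D_grid: Sequence[int] = (1, 2, 3, 4, 5),
    k_folds: int = 5,
    seed: int | None = 0,
) -> tuple[float, int]:
    """Subject-level k-fold CV over (c, D); score = mean held-out between-view
    correlation over folds, components and view pairs.  Ties prefer smaller D
    then larger c."""
    regs = np.asarray(
        reg_grid if reg_grid is not None else default_reg_grid(), dtype=float
    )
    if regs.size == 0 or len(D_grid) == 0:
        raise ValueError("grids must be non-empty")
    n = views.n_subjects
    if n < 2 * k_folds:
        raise ValueError("folds too small to estimate covariances")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    names = views.view_names
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]

    best: tuple[float, int] | None = None
    best_score = -np.inf
    for D in sorted(D_grid):
        for c in sorted(regs)[::-1]:  # larger c first -> wins ties
            scores = []
            for test_idx in folds:
                train_idx = np.setdiff1d(order, test_idx)
                model = fit_mcca(views.subset(train_idx), reg=float(c), D=D)
                a_test = model.transform(views.subset(test_idx).views)
                for d in range(D):
                    for i, j in pairs:
                        scores.append(
                            _safe_corr(
                                a_test[names[i]][:, d], a_test[names[j]][:, d]
                            )
                        )
            score = float(np.mean(scores))
            if score > best_score:
                best_score = score
                best = (float(c), int(D))
    assert best is not None
    logger.info("cv_select: c*=%.4g D*=%d (score %.3f)", *best, best_score)
    return best


@dataclasses.dataclass
class ComponentViewTest:
    component: int
    view: str
    U: float
    p_raw: float
    p_adj: float
    n_after_outlier_removal: int
    significant: bool


@dataclasses.dataclass
class DiscriminativeReport:
    tests: list[ComponentViewTest]
    labels: dict[int, str]  # component -> joint | unique | none
    alpha: float

    def component_views(self, component: int, significant_only: bool = True):
        return [
            t.view
            for t in self.tests
            if t.component == component and (t.significant or not significant_only)
        ]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mannwhitney_u(
    a: np.ndarray, b: np.ndarray, exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first sample).

    Exact null distribution when the smaller group has <= ``exact_max_n``
    observations and there are no ties; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _iqr_inliers(x: np.ndarray, factor: float = 1.5) -> np.ndarray:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    return (x >= lo) & (x <= hi)


def component_group_test(
    model: CCAModel,
    labels: np.ndarray,
    alpha: float = 0.05,
    iqr_factor: float = 1.5,
) -> DiscriminativeReport:
    """Joint/unique group-discriminative component detection.

    Per (component, view): pooled IQR outlier removal on the variate scores,
    two-sided Mann-Whitney U between the remaining group-A and group-B
    subjects, then BH correction across the full component x view family.
    """
    labels = np.asarray(labels, dtype=object)
    is_a = labels == "A"
    tests: list[ComponentViewTest] = []
    raw_ps: list[float] = []
    for d in range(model.D):
        for view in model.view_names:
            scores = model.variates[view][:, d]
            if scores.shape[0] != labels.shape[0]:
                raise ValueError("variates and labels are not aligned")
            inliers = _iqr_inliers(scores, iqr_factor)
            a = scores[inliers & is_a]
            b = scores[inliers & ~is_a]
            if a.size == 0 or b.size == 0:
                logger.warning(
                    "component %d view %s: a group was emptied by outlier "
                    "removal; test marked NA", d, view,
                )
                continue
            u, p = mannwhitney_u(a, b)
            tests.append(
                ComponentViewTest(
                    component=d, view=view, U=u, p_raw=p, p_adj=np.nan,
                    n_after_outlier_removal=int(a.size + b.size),
                    significant=False,
                )
            )
            raw_ps.append(p)
    adj = bh_adjust(raw_ps)
    for t, pa in zip(tests, adj):
        t.p_adj = float(pa)
        t.significant = bool(pa < alpha)
    comp_labels: dict[int, str] = {}
    for d in range(model.D):
        n_sig = sum(1 for t in tests if t.component == d and t.significant)
        comp_labels[d] = "joint" if n_sig >= 2 else ("unique" if n_sig == 1 else "none")
    return DiscriminativeReport(tests=tests, labels=comp_labels, alpha=alpha)


def spatial_maps(
    model: CCAModel, views: ViewSet, component: int
) -> dict[str, np.ndarray]:
    """Per-view z-scored structure-coefficient maps for one component.

    The structure coefficient of a feature is its correlation over subjects
    with that view's component variate; coefficients are z-scored across
    features within the view.
    """
    if not 0 <= component < model.D:
        raise ValueError(f"component {component} not in fitted model (D={model.D})")
    maps: dict[str, np.ndarray] = {}
    for name in model.view_names:
        x = np.asarray(views.views[name], dtype=float)
        v = model.variates[name][:, component]
        if v.std() == 0:
            raise ValueError(f"zero-variance variate for view {name}")
        vc = (v - v.mean()) / v.std()
        xc = x - x.mean(axis=0)
        sd = x.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        r = (xc / sd).T @ vc / x.shape[0]
        z = (r - r.mean()) / (r.std() if r.std() > 0 else 1.0)
        maps[name] = z
    return maps


class MultiViewCCA(BaseEstimator, TransformerMixin):
    """sklearn-style front end: fit selects (c, D) by CV when not given,
    exposes ``model_``, ``ccc_``, ``variates_`` and transforms new views."""

    def __init__(
        self,
        reg: float | None = None,
        D: int | None = None,
        reg_grid: Sequence[float] | None = None,
        D_grid: Sequence[int] = (1, 2, 3, 4, 5),
        k_folds: int = 5,
        random_state: int | None = 0,
    ) -> None:
        self.reg = reg
        self.D = D
        self.reg_grid = reg_grid
        self.D_grid = D_grid
        self.k_folds = k_folds
        self.random_state = random_state

    def fit(self, views: ViewSet, y=None) -> "MultiViewCCA":
        reg, D = self.reg, self.D
        if reg is None or D is None:
            c_star, d_star = cv_select_hyperparams(
                views,
                reg_grid=self.reg_grid,
                D_grid=self.D_grid,
                k_folds=self.k_folds,
                seed=self.random_state,
            )
            reg = c_star if reg is None else reg
            D = d_star if D is None else D
        self.model_ = fit_mcca(views, reg=reg, D=D)
        self.reg_ = self.model_.reg
        self.D_ = self.model_.D
        self.ccc_ = self.model_.ccc
        self.variates_ = self.model_.variates
        return self

    def transform(self, views: ViewSet) -> dict[str, np.ndarray]:
        return self.model_.transform(
            views.views if isinstance(views, ViewSet) else views
        )
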