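"""Phenotype preparation, design matrices, AI-REML and the mixed-model solver.

Single-trait animal model y = Xb + Zu + e with u ~ N(0, H sigma2_u) over all
pedigree animals and e ~ N(0, I sigma2_e). Variance components come from
average-information REML with an expectation-maximization fallback whenever
an AI update would leave the parameter space.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .kinship import Hinverse
from .pedigree import Pedigree

log = logging.getLogger(__name__)


@dataclass
class PhenotypeTable:
    """One record per row: animal id, trait value, factors and covariates."""

    animal: np.ndarray                      # string ids
    y: np.ndarray                           # trait values
    factors: dict[str, np.ndarray] = field(default_factory=dict)
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=object)
        self.y = np.asarray(self.y, dtype=float)
        if self.animal.shape != self.y.shape:
            raise ValueError("animal and y must have equal length")
        for name, col in {**self.factors, **self.covariates}.items():
            if len(col) != len(self.y):
                raise ValueError(f"column {name!r} length mismatch")

    @property
    def n(self) -> int:
        return self.y.size

    def subset(self, keep: np.ndarray) -> "PhenotypeTable":
        keep = np.atleast_1d(keep)
        return PhenotypeTable(
            animal=self.animal[keep],
            y=self.y[keep],
            factors={k: np.asarray(v)[keep] for k, v in self.factors.items()},
            covariates={k: np.asarray(v)[keep] for k, v in self.covariates.items()},
            trait=self.trait,
        )


@dataclass(frozen=True)
class ModelSpec:
    trait: str
    factors: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    intercept: bool = True

    def __post_init__(self) -> None:
        if not self.intercept and not self.factors:
            raise ValueError("model needs an intercept or at least one factor")


@dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float
    se_h2: float = float("nan")
    converged: bool = False
    n_iter: int = 0
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if self.sigma2_u < 0 or self.sigma2_e <= 0:
            raise ValueError("variances must satisfy sigma2_u >= 0, sigma2_e > 0")

    @property
    def h2(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)


@dataclass
class MixedModelSolution:
    b_hat: np.ndarray
    a_hat: np.ndarray               # GEBV for every pedigree animal
    residual_rel: float = 0.0       # relative MME residual norm
    column_names: tuple[str, ...] = ()


def prepare_phenotypes(
    raw: PhenotypeTable,
    spec: ModelSpec,
    outlier_sd: float = 3.0,
    trait_rules: Mapping[str, float] | None = None,
) -> PhenotypeTable:
    """Trait-specific floor rules, then a mean +/- k*SD outlier cut.

    ``trait_rules`` maps column names (the trait itself or a covariate) to
    minimum admissible values; rows below the floor are dropped before the
    outlier pass.
    """
    keep = np.ones(raw.n, dtype=bool)
    for name, floor in (trait_rules or {}).items():
        if name == spec.trait or name == raw.trait:
            col = raw.y
        elif name in raw.covariates:
            col = np.asarray(raw.covariates[name], dtype=float)
        else:
            continue
        below = keep & (col < floor)
        if below.any():
            log.info("phenotype floor %s < %s: removed %d records",
                     name, floor, int(below.sum()))
        keep &= ~below
    y = raw.y[keep]
    if y.size >= 2:
        mu, sd = y.mean(), y.std(ddof=1)
        lo, hi = mu - outlier_sd * sd, mu + outlier_sd * sd
        inlier = (raw.y >= lo) & (raw.y <= hi)
        n_out = int((keep & ~inlier).sum())
        if n_out:
            log.info("outlier cut +/-%.1f SD: removed %d records", outlier_sd, n_out)
        keep &= inlier
    if keep.sum() < 2:
        raise ValueError("fewer than 2 phenotype records remain after preparation")
    return raw.subset(np.flatnonzero(keep))


def sturges_classes(values: Sequence[float]) -> tuple[np.ndarray, int]:
    """Equal-width classes with k = ceil(1 + 3.322 log10(n)) bins.

    Returns (per-record class index in 0..k-1, k). A constant vector maps
    to a single class.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 1:
        raise ValueError("need at least one value")
    k = max(1, math.ceil(1.0 + 3.322 * math.log10(n))) if n > 1 else 1
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros(n, dtype=int), 1
    idx = np.clip(np.floor((v - lo) / (hi - lo) * k).astype(int), 0, k - 1)
    return idx, k


class DesignMatrices(NamedTuple):
    y: np.ndarray
    X: np.ndarray
    record_animals: np.ndarray      # pedigree code per record
    column_names: tuple[str, ...]


def build_design(
    ph: PhenotypeTable, spec: ModelSpec, ped: Pedigree
) -> DesignMatrices:
    """Treatment-coded fixed-effect design plus the record->animal map.

    Rank-deficient columns are dropped (pivoted QR) and logged; the
    intercept is always retained.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.intercept:
        cols.append(np.ones(ph.n))
        names.append("intercept")
    for f in spec.factors:
        levels = sorted(set(map(str, ph.factors[f])))
        lab = np.asarray([str(v) for v in ph.factors[f]], dtype=object)
        for lv in levels[1:]:  # first level is the reference
            cols.append((lab == lv).astype(float))
            names.append(f"{f}[{lv}]")
    for c in spec.covariates:
        cols.append(np.asarray(ph.covariates[c], dtype=float))
        names.append(c)
    if not cols:
        raise ValueError("empty design: no intercept, factors or covariates")
    X = np.column_stack(cols)

    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank == 0:
        raise ValueError("design matrix has rank 0")
    keep = np.zeros(X.shape[1], dtype=bool)
    keep[piv[:rank]] = True
    if spec.intercept and not keep[0]:
        # prefer the intercept over whichever aliased column the pivot chose
        keep[0] = True
        keep[piv[rank - 1]] = False
    if rank < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if not keep[j]]
        log.info("design rank %d < %d; dropped columns: %s",
                 rank, X.shape[1], ", ".join(dropped))
    kept_idx = np.flatnonzero(keep)
    record_animals = np.array([ped.code(str(a)) for a in ph.animal], dtype=np.int64)
    return DesignMatrices(
        y=ph.y.copy(),
        X=X[:, kept_idx],
        record_animals=record_animals,
        column_names=tuple(names[j] for j in kept_idx),
    )


def _dense_hinv(hinv) -> np.ndarray:
    if isinstance(hinv, Hinverse):
        return hinv.to_dense()
    if sp.issparse(hinv):
        return hinv.toarray()
    return np.asarray(hinv, dtype=float)


def _h_from_hinv(hinv) -> np.ndarray:
    M = _dense_hinv(hinv)
    c, low = scipy.linalg.cho_factor(M, check_finite=False)
    H = scipy.linalg.cho_solve((c, low), np.eye(M.shape[0]), check_finite=False)
    return 0.5 * (H + H.T)


class _RotatedModel:
    """REML workspace in the eigenbasis of K = Z H Z'.

    With K = Q diag(lam) Q', V = s2u*K + s2e*I is diagonal after rotation,
    so the likelihood, gradients and AI terms are O(n p^2) per iterate.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, K: np.ndarray) -> None:
        lam, Q = scipy.linalg.eigh(K, check_finite=False)
        self.lam = np.clip(lam, 0.0, None)
        self.yt = Q.T @ y
        self.Xt = Q.T @ X
        self.n, self.p = X.shape

    def core(self, s2u: float, s2e: float):
        w = 1.0 / (s2u * self.lam + s2e)
        XtW = self.Xt * w[:, None]
        XtWX = self.Xt.T @ XtW
        cf = scipy.linalg.cho_factor(XtWX, check_finite=False)
        beta = scipy.linalg.cho_solve(cf, XtW.T @ self.yt, check_finite=False)
        r = self.yt - self.Xt @ beta
        py = w * r                                     # rotated P y
        ypy = float(r @ py)
        logdet_v = float(np.sum(np.log(s2u * self.lam + s2e)))
        logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * (logdet_v + logdet_xvx + ypy)
        return w, cf, py, ll

    def p_apply(self, w, cf, v: np.ndarray) -> np.ndarray:
        wv = w * v
        return wv - w * (self.Xt @ scipy.linalg.cho_solve(cf, self.Xt.T @ wv,
                                                          check_finite=False))

    def loglik(self, s2u: float, s2e: float) -> float:
        return self.core(s2u, s2e)[3]


def reml_aireml(
    y: np.ndarray,
    X: np.ndarray,
    record_animals: np.ndarray,
    hinv=None,
    start: VarianceComponents | tuple[float, float] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    *,
    H: np.ndarray | None = None,
    n_random: int | None = None,
) -> VarianceComponents:
    """Average-information REML for (sigma2_u, sigma2_e).

    ``hinv`` may be an :class:`Hinverse`, a sparse or a dense matrix; pass
    ``H=`` directly (the covariance of u, e.g. a tabular A) to skip the
    inversion. Standard errors come from the inverse AI matrix at the
    optimum; ``loglik`` is the REML log-likelihood up to a constant.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rec = np.asarray(record_animals, dtype=np.int64)
    if H is None:
        if hinv is None:
            raise ValueError("provide hinv or H")
        H = _h_from_hinv(hinv)
    N = n_random if n_random is not None else H.shape[0]
    K = H[np.ix_(rec, rec)]
    rot = _RotatedModel(y, X, K)
    n = y.size

    vary = float(y.var(ddof=1))
    if vary <= 0:
        raise ValueError("phenotype variance is zero")
    floor = 1e-8 * vary
    if start is None:
        s2u, s2e = vary / 2.0, vary / 2.0
    elif isinstance(start, VarianceComponents):
        s2u, s2e = max(start.sigma2_u, floor), max(start.sigma2_e, floor)
    else:
        s2u, s2e = (max(float(start[0]), floor), max(float(start[1]), floor))

    def profile_sigma_e(s2u_fix: float, lo: float, hi: float) -> float:
        """Golden-section maximization of the loglik over s2e at fixed s2u."""
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = np.log(lo), np.log(hi)
        c, d = b - gr * (b - a), a + gr * (b - a)
        fc, fd = rot.loglik(s2u_fix, np.exp(c)), rot.loglik(s2u_fix, np.exp(d))
        for _ in range(60):
            if fc >= fd:
                b, d, fd = d, c, fc
                c = b - gr * (b - a)
                fc = rot.loglik(s2u_fix, np.exp(c))
            else:
                a, c, fc = c, d, fd
                d = a + gr * (b - a)
                fd = rot.loglik(s2u_fix, np.exp(d))
            if b - a < 1e-10:
                break
        return float(np.exp(0.5 * (a + b)))

    AI = np.eye(2)
    converged = False
    it = 0
    w, cf, py, ll = rot.core(s2u, s2e)
    n_em_burnin = 2
    for it in range(1, max_iter + 1):
        lam = rot.lam
        # gradient pieces
        tr_vk = float(np.sum(w * lam))
        XtA = rot.Xt * (w**2 * lam)[:, None]
        tr_pk = tr_vk - float(np.trace(
            scipy.linalg.cho_solve(cf, rot.Xt.T @ XtA, check_finite=False)))
        XtB = rot.Xt * (w**2)[:, None]
        tr_p = float(np.sum(w)) - float(np.trace(
            scipy.linalg.cho_solve(cf, rot.Xt.T @ XtB, check_finite=False)))
        ykpy = float(py @ (lam * py))
        yppy = float(py @ py)
        grad = -0.5 * np.array([tr_pk - ykpy, tr_p - yppy])

        v1 = lam * py
        pv1 = rot.p_apply(w, cf, v1)
        pv2 = rot.p_apply(w, cf, py)
        AI = 0.5 * np.array([
            [float(v1 @ pv1), float(v1 @ pv2)],
            [float(py @ pv1), float(py @ pv2)],
        ])

        theta = np.array([s2u, s2e])
        new = None
        hit_boundary = False
        try:
            delta = np.linalg.solve(AI, grad)
            cand = theta + delta
            if np.all(np.isfinite(cand)):
                hit_boundary = cand[0] < floor or cand[1] < floor
            if (it > n_em_burnin and np.all(np.isfinite(cand))
                    and cand[0] >= floor and cand[1] >= floor):
                # halve the step if the likelihood would drop
                for _ in range(8):
                    if rot.loglik(cand[0], cand[1]) >= ll - 1e-10:
                        new = cand
                        break
                    delta = delta / 2.0
                    cand = theta + delta
        except np.linalg.LinAlgError:
            pass
        if new is None:
            # EM fallback step (monotone, stays in the parameter space)
            em = np.maximum(np.array([
                s2u + s2u**2 * (ykpy - tr_pk) / N,
                s2e + s2e**2 * (yppy - tr_p) / n,
            ]), floor)
            new = em
            if hit_boundary and it > n_em_burnin:
                # candidate: jump to the boundary and profile the other variance
                bd = np.array([floor, profile_sigma_e(floor, floor, 10 * vary)])
                if rot.loglik(*bd) > rot.loglik(*em):
                    new = bd

        change = float(np.max(np.abs(new - theta) / np.maximum(theta, floor)))
        s2u, s2e = float(new[0]), float(new[1])
        ll_prev = ll
        w, cf, py, ll = rot.core(s2u, s2e)
        if change < tol or (it > n_em_burnin + 2 and
                            abs(ll - ll_prev) < 1e-10 * (1.0 + abs(ll))):
            if s2u <= 2 * floor:
                # EM cannot leave sigma2_u ~ 0; probe the interior before
                # accepting a boundary solution
                probe = 0.05 * vary
                if rot.loglik(probe, s2e) > ll + 1e-8:
                    s2u = probe
                    w, cf, py, ll = rot.core(s2u, s2e)
                    continue
            converged = True
            break

    try:
        cov = np.linalg.inv(AI)
        g = np.array([s2e, -s2u]) / (s2u + s2e) ** 2
        se_h2 = float(np.sqrt(max(g @ cov @ g, 0.0)))
    except np.linalg.LinAlgError:
        se_h2 = float("nan")
    if not converged:
        log.warning("AI-REML did not converge in %d iterations", max_iter)
    return VarianceComponents(
        sigma2_u=s2u, sigma2_e=s2e, se_h2=se_h2,
        converged=converged, n_iter=it, loglik=ll,
    )


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    record_animals: np.ndarray,
    hinv,
    vc: VarianceComponents,
) -> MixedModelSolution:
    """Solve Henderson's mixed-model equations for b and all-animal GEBVs.

    [X'X  X'W; W'X  W'W + Hinv*(s2e/s2u)] [b; a] = [X'y; W'y] where W maps
    records to animals. Animals without records receive GEBVs through the
    relationship structure. sigma2_u ~= 0 degenerates to OLS with a = 0.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rec = np.asarray(record_animals, dtype=np.int64)
    Hinv_d = _dense_hinv(hinv)
    N = Hinv_d.shape[0]
    n, p = X.shape

    if vc.sigma2_u <= 1e-12 * (vc.sigma2_u + vc.sigma2_e):
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        return MixedModelSolution(b_hat=b, a_hat=np.zeros(N), residual_rel=0.0)

    ratio = vc.sigma2_e / vc.sigma2_u
    XtX = X.T @ X
    XtW = np.zeros((N, p))
    np.add.at(XtW, rec, X)
    XtW = XtW.T
    WtW_diag = np.bincount(rec, minlength=N).astype(float)
    Wty = np.bincount(rec, weights=y, minlength=N)

    C = np.empty((p + N, p + N))
    C[:p, :p] = XtX
    C[:p, p:] = XtW
    C[p:, :p] = XtW.T
    C[p:, p:] = ratio * Hinv_d
    C[p + np.arange(N), p + np.arange(N)] += WtW_diag
    rhs = np.concatenate([X.T @ y, Wty])

    try:
        cfac = scipy.linalg.cho_factor(C, check_finite=False)
        sol = scipy.linalg.cho_solve(cfac, rhs, check_finite=False)
        # one round of iterative refinement
        sol += scipy.linalg.cho_solve(cfac, rhs - C @ sol, check_finite=False)
    except scipy.linalg.LinAlgError:
        sol = np.linalg.solve(C, rhs)
    resid = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    return MixedModelSolution(
        b_hat=sol[:p], a_hat=sol[p:], residual_rel=resid,
    )
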