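"""MAP inference of single-trial normalization signals (D1, D2).

Given an observed response pair R and fitted stimulus-level parameters, the
posterior over the latent denominators follows from Bayes' rule with the
change of variables N = (R - mu_eta) * D:

    -log p(D | R - mu_eta) = 1/2 (N - mu_N)' Sigma_N^-1 (N - mu_N)
                           + 1/2 (D - mu_D)' Sigma_D^-1 (D - mu_D)
                           - log D1 - log D2 + const.

Setting each partial derivative to zero and multiplying by 2 D_i yields a
bivariate quadratic system

    2 A_i D_i^2 + B_i D_i + C D1 D2 - 2 = 0,    i = 1, 2

whose elimination gives a quartic in D1 (four possibly-complex solution
pairs).  The solver evaluates all candidate pairs on the negative log
posterior and returns the minimizer, falling back to direct numerical
minimization when no usable candidate exists.  Quartic roots are computed via
companion-matrix eigenvalues for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy import optimize

from .core import PairParams
from .dataset import Dataset
from .tuning import ContrastTuning, build_pair_params

__all__ = [
    "QuarticCoefficients",
    "MapEstimate",
    "neg_log_posterior",
    "quartic_coefficients",
    "solve_map",
    "solve_map_numeric",
    "map_independent",
    "estimate_dataset",
]

#: A root counts as real when |Im| <= REAL_TOL * (1 + |Re|).
REAL_TOL = 1e-8


def _inverses(params: PairParams):
    SN = params.cov_N
    SD = params.cov_D
    for name, S in (("Sigma_N", SN), ("Sigma_D", SD)):
        det = S[0, 0] * S[1, 1] - S[0, 1] ** 2
        if det <= 0 or S[0, 0] <= 0 or S[1, 1] <= 0:
            raise ValueError(f"{name} is singular; MAP inference requires positive variances "
                             "and |rho| < 1")
    return np.linalg.inv(SN), np.linalg.inv(SD)


def neg_log_posterior(D, R, params: PairParams) -> float:
    """Negative log posterior of the normalization pair (up to a constant).

    ``R`` is the raw response pair; the residual mean is subtracted internally
    (the posterior considered is p(D | R - mu_eta)).  Requires D > 0.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("D must be strictly positive")
    r = np.asarray(R, dtype=float) - params.mu_eta
    iSN, iSD = _inverses(params)
    n = r * D - params.mu_N
    d = D - params.mu_D
    return float(0.5 * n @ iSN @ n + 0.5 * d @ iSD @ d - np.log(D[0]) - np.log(D[1]))


def _nlp_grad(D, r, mu_N, mu_D, iSN, iSD):
    n = r * D - mu_N
    d = D - mu_D
    f = 0.5 * n @ iSN @ n + 0.5 * d @ iSD @ d - np.log(D[0]) - np.log(D[1])
    g = r * (iSN @ n) + iSD @ d - 1.0 / D
    return f, g


@dataclass
class QuarticCoefficients:
    """Coefficients of the stationarity system 2 A_i D_i^2 + B_i D_i + C D1 D2 - 2 = 0."""

    A1: float
    A2: float
    B1: float
    B2: float
    C: float


def quartic_coefficients(R, params: PairParams) -> QuarticCoefficients:
    """Coefficients of the MAP stationarity system for one trial.

    With P = Sigma_N^-1 and Q = Sigma_D^-1 and r = R - mu_eta:

        A_i = r_i^2 P_ii + Q_ii
        B_i = -2 [ r_i (P @ mu_N)_i + (Q @ mu_D)_i ]
        C   = 2 (r_1 r_2 P_12 + Q_12)

    C is shared by both equations and vanishes when both covariances are
    diagonal, decoupling the system into two per-neuron quadratics.
    """
    r = np.asarray(R, dtype=float) - params.mu_eta
    iSN, iSD = _inverses(params)
    Pm = iSN @ params.mu_N
    Qm = iSD @ params.mu_D
    A = r**2 * np.diag(iSN) + np.diag(iSD)
    B = -2.0 * (r * Pm + Qm)
    C = 2.0 * (r[0] * r[1] * iSN[0, 1] + iSD[0, 1])
    return QuarticCoefficients(A1=float(A[0]), A2=float(A[1]),
                               B1=float(B[0]), B2=float(B[1]), C=float(C))


@dataclass
class MapEstimate:
    """Per-trial MAP estimate of the normalization pair."""

    d1: float
    d2: float
    neg_log_posterior: float
    solver: str               # "algebraic", "algebraic-realpart", or "numeric-fallback"
    n_real_roots: int
    converged: bool = True


def _positive_quadratic_root(a: float, b_half: float) -> float:
    """Positive root of a x^2 + b_half x - 1 = 0 (exactly one sign change)."""
    return (-b_half + np.sqrt(b_half**2 + 4.0 * a)) / (2.0 * a)


def _quartic_coeffs_poly(q: QuarticCoefficients) -> np.ndarray:
    """Ascending coefficients of the quartic in D1 after eliminating D2.

    From equation 1, D2 = P(D1) / (C D1) with P(x) = 2 - B1 x - 2 A1 x^2;
    substituting into equation 2 and clearing denominators gives

        2 A2 P^2 + B2 C x P + C^2 x^2 P - 2 C^2 x^2 = 0.
    """
    P = np.array([2.0, -q.B1, -2.0 * q.A1])
    out = 2.0 * q.A2 * npoly.polymul(P, P)
    out = npoly.polyadd(out, q.B2 * q.C * npoly.polymulx(P))
    out = npoly.polyadd(out, q.C**2 * npoly.polymulx(npoly.polymulx(P)))
    out = npoly.polyadd(out, np.array([0.0, 0.0, -2.0 * q.C**2]))
    full = np.zeros(5)
    full[: len(out)] = out
    return full


def solve_map_numeric(R, params: PairParams, starts=None) -> MapEstimate:
    """Direct numerical minimization of the negative log posterior.

    Multi-start L-BFGS-B with analytic gradient over D > 0; default starts are
    the prior mean mu_D and the per-neuron independent estimates.
    """
    r = np.asarray(R, dtype=float) - params.mu_eta
    iSN, iSD = _inverses(params)
    if starts is None:
        ind = np.array([
            map_independent(r[i], params.mu_N[i], params.sigma_N[i],
                            params.mu_D[i], params.sigma_D[i])
            for i in range(2)
        ])
        starts = [params.mu_D.copy(), ind, 0.5 * (params.mu_D + ind)]
    best = None
    lo = 1e-10
    for x0 in starts:
        res = optimize.minimize(
            _nlp_grad, np.maximum(x0, lo), args=(r, params.mu_N, params.mu_D, iSN, iSD),
            method="L-BFGS-B", jac=True,
            bounds=[(lo, None), (lo, None)],
            options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    return MapEstimate(d1=float(best.x[0]), d2=float(best.x[1]),
                       neg_log_posterior=float(best.fun),
                       solver="numeric-fallback", n_real_roots=0,
                       converged=bool(best.success))


def _newton_polish(D, r, mu_N, mu_D, iSN, iSD, max_iter: int = 20):
    """Newton refinement of a stationary point of the negative log posterior.

    The Hessian diag(r) Sigma_N^-1 diag(r) + Sigma_D^-1 + diag(1/D^2) is cheap
    and the polish repairs root-finding error from ill-scaled coefficients.
    """
    D = np.asarray(D, dtype=float).copy()
    for _ in range(max_iter):
        n = r * D - mu_N
        g = r * (iSN @ n) + iSD @ (D - mu_D) - 1.0 / D
        H = (iSN * np.outer(r, r)) + iSD + np.diag(1.0 / D**2)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        nxt = D - step
        if np.any(nxt <= 0):
            # back off toward the boundary without crossing it
            scale = 0.5 * np.min(np.where(step > 0, D / np.maximum(step, 1e-300), np.inf))
            nxt = D - min(1.0, scale) * step
            if np.any(nxt <= 0):
                break
        D = nxt
        if np.max(np.abs(step)) <= 1e-12 * (1.0 + np.max(np.abs(D))):
            break
    return D


def solve_map(R, params: PairParams, allow_fallback: bool = True) -> MapEstimate:
    """MAP estimate of (D1, D2) for one trial via the algebraic quartic system.

    Eliminates D2, solves the quartic in D1 (companion-matrix eigenvalues),
    takes real parts of all four solution pairs, and returns the candidate
    that minimizes the negative log posterior among those with D > 0.  When no
    candidate is usable, falls back to numerical minimization started at the
    prior mean.
    """
    q = quartic_coefficients(R, params)
    r = np.asarray(R, dtype=float) - params.mu_eta
    iSN, iSD = _inverses(params)

    if abs(q.C) <= 1e-14 * (abs(q.A1) + abs(q.A2) + 1.0):
        d1 = _positive_quadratic_root(q.A1, q.B1 / 2.0)
        d2 = _positive_quadratic_root(q.A2, q.B2 / 2.0)
        f, _ = _nlp_grad(np.array([d1, d2]), r, params.mu_N, params.mu_D, iSN, iSD)
        return MapEstimate(d1=float(d1), d2=float(d2), neg_log_posterior=float(f),
                           solver="algebraic", n_real_roots=2)

    coeffs = _quartic_coeffs_poly(q)
    roots1 = npoly.polyroots(coeffs)
    P = np.array([2.0, -q.B1, -2.0 * q.A1])
    roots2 = npoly.polyval(roots1, P) / (q.C * roots1)
    n_real = int(np.count_nonzero(
        (np.abs(roots1.imag) <= REAL_TOL * (1.0 + np.abs(roots1.real)))
        & (np.abs(roots2.imag) <= REAL_TOL * (1.0 + np.abs(roots2.real)))
    ))
    # Candidate D2 values per D1 root: the elimination formula plus the two
    # roots of equation 2's quadratic in D2 (numerically stable when the
    # elimination numerator suffers cancellation under ill-scaled coefficients).
    d1c = np.repeat(roots1.real, 3)
    bq = q.B2 + q.C * roots1.real
    disc = np.sqrt(np.maximum(bq**2 + 16.0 * q.A2, 0.0))
    d2c = np.concatenate([roots2.real, (-bq + disc) / (4.0 * q.A2),
                          (-bq - disc) / (4.0 * q.A2)])
    d1c = np.concatenate([roots1.real] * 3)
    usable = (d1c > 0) & (d2c > 0)
    if not np.any(usable):
        if not allow_fallback:
            return MapEstimate(d1=float("nan"), d2=float("nan"),
                               neg_log_posterior=float("nan"),
                               solver="algebraic-realpart", n_real_roots=n_real,
                               converged=False)
        est = solve_map_numeric(R, params)
        est.n_real_roots = n_real
        return est
    best_f, best = np.inf, None
    for d1, d2 in zip(d1c[usable], d2c[usable]):
        f, _ = _nlp_grad(np.array([d1, d2]), r, params.mu_N, params.mu_D, iSN, iSD)
        if f < best_f:
            best_f, best = f, (d1, d2)
    D = _newton_polish(np.array(best), r, params.mu_N, params.mu_D, iSN, iSD)
    best_f, _ = _nlp_grad(D, r, params.mu_N, params.mu_D, iSN, iSD)
    solver = "algebraic" if n_real > 0 else "algebraic-realpart"
    return MapEstimate(d1=float(D[0]), d2=float(D[1]),
                       neg_log_posterior=float(best_f), solver=solver,
                       n_real_roots=n_real)


def map_independent(r: float, mu_N: float, sigma_N: float, mu_D: float,
                    sigma_D: float) -> float:
    """Single-neuron MAP normalization estimate from the independent model.

    The unique positive root of
    (r^2/sigma_N^2 + 1/sigma_D^2) D^2 - (r mu_N/sigma_N^2 + mu_D/sigma_D^2) D - 1 = 0
    (one sign change, hence exactly one positive root); ``r`` is the response
    with the residual mean already removed.
    """
    if sigma_N <= 0 or sigma_D <= 0:
        raise ValueError("sigma_N and sigma_D must be strictly positive")
    a = r**2 / sigma_N**2 + 1.0 / sigma_D**2
    b_half = -(r * mu_N / sigma_N**2 + mu_D / sigma_D**2)
    return float(_positive_quadratic_root(a, b_half))


# ---------------------------------------------------------------------------
# Vectorized solver over many trials
# ---------------------------------------------------------------------------

def _solve_map_batch(R: np.ndarray, params: PairParams):
    """Vectorized :func:`solve_map` over trials.

    Returns (d (T, 2), nlp (T,), solver codes (T,)) with codes 0=algebraic,
    1=algebraic-realpart, 2=numeric-fallback.
    """
    R = np.asarray(R, dtype=float)
    T = len(R)
    r = R - params.mu_eta
    iSN, iSD = _inverses(params)
    A1 = r[:, 0] ** 2 * iSN[0, 0] + iSD[0, 0]
    A2 = r[:, 1] ** 2 * iSN[1, 1] + iSD[1, 1]
    Pm = iSN @ params.mu_N
    Qm = iSD @ params.mu_D
    B1 = -2.0 * (r[:, 0] * Pm[0] + Qm[0])
    B2 = -2.0 * (r[:, 1] * Pm[1] + Qm[1])
    C = 2.0 * (r[:, 0] * r[:, 1] * iSN[0, 1] + iSD[0, 1])

    # Quartic coefficients (ascending), vectorized expansion of
    # 2 A2 P^2 + B2 C x P + C^2 x^2 P - 2 C^2 x^2 with P = 2 - B1 x - 2 A1 x^2.
    c0 = 8.0 * A2
    c1 = -8.0 * A2 * B1 + 2.0 * B2 * C
    c2 = 2.0 * A2 * (B1**2 - 8.0 * A1) - B2 * C * B1
    c3 = 8.0 * A2 * A1 * B1 - 2.0 * A1 * B2 * C - C**2 * B1
    c4 = 8.0 * A2 * A1**2 - 2.0 * A1 * C**2

    decoupled = np.abs(C) <= 1e-14 * (np.abs(A1) + np.abs(A2) + 1.0)
    d = np.empty((T, 2))
    nlp = np.empty(T)
    solver = np.zeros(T, dtype=int)

    # Decoupled trials: per-neuron quadratics.
    if np.any(decoupled):
        idx = np.nonzero(decoupled)[0]
        bh1 = B1[idx] / 2.0
        bh2 = B2[idx] / 2.0
        d[idx, 0] = (-bh1 + np.sqrt(bh1**2 + 4.0 * A1[idx])) / (2.0 * A1[idx])
        d[idx, 1] = (-bh2 + np.sqrt(bh2**2 + 4.0 * A2[idx])) / (2.0 * A2[idx])

    idx = np.nonzero(~decoupled)[0]
    if len(idx):
        # Monic companion matrices, batched eigenvalues.
        mon = np.stack([c0[idx], c1[idx], c2[idx], c3[idx]], axis=1) / c4[idx, None]
        comp = np.zeros((len(idx), 4, 4))
        comp[:, 1, 0] = comp[:, 2, 1] = comp[:, 3, 2] = 1.0
        comp[:, :, 3] = -mon
        roots1 = np.linalg.eigvals(comp)                       # (n, 4)
        Pval = 2.0 - B1[idx, None] * roots1 - 2.0 * A1[idx, None] * roots1**2
        roots2 = Pval / (C[idx, None] * roots1)
        # D2 candidates: elimination formula plus both roots of equation 2's
        # quadratic (stable under coefficient cancellation), 12 per trial.
        bq = B2[idx, None] + C[idx, None] * roots1.real
        disc = np.sqrt(np.maximum(bq**2 + 16.0 * A2[idx, None], 0.0))
        a2 = 4.0 * A2[idx, None]
        d1c = np.concatenate([roots1.real] * 3, axis=1)
        d2c = np.concatenate([roots2.real, (-bq + disc) / a2, (-bq - disc) / a2],
                             axis=1)
        usable = (d1c > 0) & (d2c > 0)
        # Candidate negative log posteriors (vectorized over trials x roots).
        rr = r[idx]
        n1 = rr[:, 0:1] * d1c - params.mu_N[0]
        n2 = rr[:, 1:2] * d2c - params.mu_N[1]
        e1 = d1c - params.mu_D[0]
        e2 = d2c - params.mu_D[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (0.5 * (iSN[0, 0] * n1**2 + 2 * iSN[0, 1] * n1 * n2 + iSN[1, 1] * n2**2)
                 + 0.5 * (iSD[0, 0] * e1**2 + 2 * iSD[0, 1] * e1 * e2 + iSD[1, 1] * e2**2)
                 - np.log(np.where(usable, d1c, 1.0)) - np.log(np.where(usable, d2c, 1.0)))
        f = np.where(usable, f, np.inf)
        pick = np.argmin(f, axis=1)
        rows = np.arange(len(idx))
        d[idx, 0] = d1c[rows, pick]
        d[idx, 1] = d2c[rows, pick]
        has_real = np.any(
            (np.abs(roots1.imag) <= REAL_TOL * (1.0 + np.abs(roots1.real)))
            & (np.abs(roots2.imag) <= REAL_TOL * (1.0 + np.abs(roots2.real))), axis=1)
        solver[idx] = np.where(has_real, 0, 1)
        # Fallback for trials with no positive candidate.
        none_usable = ~np.any(usable, axis=1)
        for j in np.nonzero(none_usable)[0]:
            est = solve_map_numeric(R[idx[j]], params)
            d[idx[j]] = (est.d1, est.d2)
            solver[idx[j]] = 2
        ok = idx[~none_usable]
        if len(ok):
            d[ok] = _newton_polish_batch(d[ok], r[ok], params.mu_N, params.mu_D,
                                         iSN, iSD)

    n = r * d
    m1 = n - params.mu_N
    m2 = d - params.mu_D
    nlp = (0.5 * (iSN[0, 0] * m1[:, 0]**2 + 2 * iSN[0, 1] * m1[:, 0] * m1[:, 1]
                  + iSN[1, 1] * m1[:, 1]**2)
           + 0.5 * (iSD[0, 0] * m2[:, 0]**2 + 2 * iSD[0, 1] * m2[:, 0] * m2[:, 1]
                    + iSD[1, 1] * m2[:, 1]**2)
           - np.log(d[:, 0]) - np.log(d[:, 1]))
    return d, nlp, solver


def _newton_polish_batch(D, r, mu_N, mu_D, iSN, iSD, max_iter: int = 15):
    """Vectorized Newton refinement (trials in rows) with positivity damping."""
    D = D.copy()
    for _ in range(max_iter):
        n = r * D - mu_N
        e = D - mu_D
        g1 = r[:, 0] * (iSN[0, 0] * n[:, 0] + iSN[0, 1] * n[:, 1]) \
            + iSD[0, 0] * e[:, 0] + iSD[0, 1] * e[:, 1] - 1.0 / D[:, 0]
        g2 = r[:, 1] * (iSN[0, 1] * n[:, 0] + iSN[1, 1] * n[:, 1]) \
            + iSD[0, 1] * e[:, 0] + iSD[1, 1] * e[:, 1] - 1.0 / D[:, 1]
        h11 = r[:, 0] ** 2 * iSN[0, 0] + iSD[0, 0] + 1.0 / D[:, 0] ** 2
        h22 = r[:, 1] ** 2 * iSN[1, 1] + iSD[1, 1] + 1.0 / D[:, 1] ** 2
        h12 = r[:, 0] * r[:, 1] * iSN[0, 1] + iSD[0, 1]
        det = h11 * h22 - h12**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        s1 = (h22 * g1 - h12 * g2) / det
        s2 = (h11 * g2 - h12 * g1) / det
        step = np.stack([s1, s2], axis=1)
        nxt = D - step
        for _damp in range(30):
            bad = np.any(nxt <= 0, axis=1)
            if not np.any(bad):
                break
            step[bad] *= 0.5
            nxt = D - step
        bad = np.any(nxt <= 0, axis=1)
        nxt[bad] = D[bad]
        if np.max(np.abs(nxt - D)) <= 1e-13 * (1.0 + np.max(np.abs(D))):
            D = nxt
            break
        D = nxt
    return D


_SOLVER_NAMES = {0: "algebraic", 1: "algebraic-realpart", 2: "numeric-fallback"}


def estimate_dataset(data, tunings) -> pd.DataFrame:
    """Per-trial MAP normalization estimates for every pair in a dataset.

    ``tunings`` maps pair_id to a :class:`ContrastTuning` (e.g. fitted via
    :func:`pairrog.fit.fit_pair` or ground truth).  Also reports the
    independent-model estimates for comparison.  Returns a tidy table with one
    row per trial.
    """
    if isinstance(data, Dataset):
        pairs = list(data.iter_pairs())
    else:
        pairs = [data]

    def _tuning_for(pair_id):
        t = tunings if isinstance(tunings, ContrastTuning) or hasattr(tunings, "tuning") \
            else tunings[pair_id]
        return t.tuning if hasattr(t, "tuning") else t  # accept FitResult directly

    rows = []
    for obs in pairs:
        tun = _tuning_for(obs.pair_id)
        for c, resp in zip(obs.contrasts, obs.responses):
            params = build_pair_params(tun, c)
            d, nlp, solver = _solve_map_batch(resp, params)
            r = resp - params.mu_eta
            d_ind = np.column_stack([
                _map_independent_vec(r[:, i], params.mu_N[i], params.sigma_N[i],
                                     params.mu_D[i], params.sigma_D[i])
                for i in range(2)
            ])
            for t in range(len(resp)):
                rows.append({
                    "pair_id": obs.pair_id, "stimulus": c, "trial": t,
                    "d1": d[t, 0], "d2": d[t, 1],
                    "d1_independent": d_ind[t, 0], "d2_independent": d_ind[t, 1],
                    "neg_log_posterior": nlp[t],
                    "solver": _SOLVER_NAMES[int(solver[t])],
                })
    return pd.DataFrame(rows, columns=["pair_id", "stimulus", "trial", "d1", "d2",
                                       "d1_independent", "d2_independent",
                                       "neg_log_posterior", "solver"])


def _map_independent_vec(r, mu_N, sigma_N, mu_D, sigma_D):
    a = r**2 / sigma_N**2 + 1.0 / sigma_D**2
    b_half = -(r * mu_N / sigma_N**2 + mu_D / sigma_D**2)
    return (-b_half + np.sqrt(b_half**2 + 4.0 * a)) / (2.0 * a)
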