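"""Sparse l2-lq polynomial regression for the choroidal-scleral interface.

The CSI is fitted as a high-order polynomial with a sparse coefficient
vector by solving

    min_beta  phi(beta) = ||X beta - y||_2^2 + lambda * ||beta||_q^q,   0 < q < 1,

where X is the (scaled) polynomial design matrix of the recorrected
points.  The nonconvex problem is attacked with a hybrid scheme:

1. orthogonal matching pursuit (OMP) produces a sparse initial point
   ``beta0`` and its support,
2. smoothing-gradient (SG) descent on a continuously differentiable
   surrogate of |t|^q further reduces the objective on that support,
3. the solution is purified: entries no larger than the theoretical lower
   bound L on nonzero entries of any local minimizer are set to exactly
   zero, followed by a least-squares debias refit on the surviving support.

The lower bound L = (lambda*q / (2*||X||_2 * sqrt(phi(beta0))))^(1/(1-q))
also caps the support size by phi(beta0) / (lambda * L^q).

Defaults lambda=1, q=0.1, xi=0.1.  Raw monomials of degree 10 at x up to
600 are numerically useless, so x is rescaled to [-1, 1] internally and
the sparsity pattern lives in the scaled basis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .trace import BoundaryTrace

DEFAULT_LAMBDA = 1.0
DEFAULT_Q = 0.1
DEFAULT_XI = 0.1


# ---------------------------------------------------------------------------
# degree rule and design matrix

def select_degree(xs, one_based: bool = False) -> int:
    """Fitting degree from the horizontal extent of the recorrected points.

    A wide point set (reaching both image borders) supports degree 10, a
    narrow one falls back to a cubic, anything between gets degree 6.  The
    thresholds are stated on 1-based columns 1..600; package-convention
    0-based columns are shifted internally.
    """
    xs = np.asarray(xs, dtype=float)
    if xs.size == 0:
        raise ValueError("cannot select a degree from an empty point set")
    if np.any(np.diff(xs) < 0):
        raise ValueError("xs must be sorted ascending")
    x1 = xs[0] + (0 if one_based else 1)
    xm = xs[-1] + (0 if one_based else 1)
    if x1 <= 50 and xm >= 570:
        return 10
    if x1 >= 100 or xm <= 500:
        return 3
    return 6


@dataclass
class DesignMatrix:
    """Polynomial design matrix in the scaled coordinate.

    Row i is (t_i^n, ..., t_i, 1) with t = (x - center)/halfwidth in
    [-1, 1]; the affine map is stored for prediction.
    """

    X: np.ndarray
    y: np.ndarray
    degree: int
    center: float
    halfwidth: float

    @property
    def m(self) -> int:
        return self.X.shape[0]

    def scale(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.center) / self.halfwidth


def build_design_matrix(x, y, degree: int) -> DesignMatrix:
    """Vandermonde matrix (descending powers, last column ones) on scaled x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} points for degree {degree}; "
            "reduce the degree or supply more points"
        )
    c = float((x.min() + x.max()) / 2.0)
    h = float((x.max() - x.min()) / 2.0) or 1.0
    t = (x - c) / h
    X = np.vander(t, N=degree + 1, increasing=False)
    return DesignMatrix(X=X, y=y, degree=degree, center=c, halfwidth=h)


# ---------------------------------------------------------------------------
# objective pieces

def lq_norm(beta: np.ndarray, q: float) -> float:
    return float(np.sum(np.abs(beta) ** q))


def phi(dm: DesignMatrix, beta: np.ndarray, lam: float, q: float) -> float:
    """The l2-lq objective ||X beta - y||^2 + lambda ||beta||_q^q."""
    r = dm.X @ beta - dm.y
    return float(r @ r + lam * lq_norm(beta, q))


def smoothing_value(t, xi: float):
    """Huber-like smoothing of |t|: |t| outside [-xi, xi], quadratic inside.

    s_xi(t) = |t| if |t| > xi else t^2/(2 xi) + xi/2; continuously
    differentiable, s_xi(t) >= |t| with equality iff |t| >= xi.
    """
    if xi <= 0:
        raise ValueError("smoothing parameter xi must be positive")
    t = np.asarray(t, dtype=float)
    a = np.abs(t)
    out = np.where(a > xi, a, t * t / (2.0 * xi) + xi / 2.0)
    return float(out) if out.ndim == 0 else out


def smoothing_grad(t, xi: float):
    """Derivative of ``smoothing_value`` in t (sign outside, linear inside)."""
    t = np.asarray(t, dtype=float)
    out = np.where(np.abs(t) > xi, np.sign(t), t / xi)
    return float(out) if out.ndim == 0 else out


def phi_smooth(dm: DesignMatrix, beta: np.ndarray, lam: float, q: float, xi: float) -> float:
    r = dm.X @ beta - dm.y
    return float(r @ r + lam * np.sum(smoothing_value(beta, xi) ** q))


# ---------------------------------------------------------------------------
# stage 1: OMP initialization

#: an atom must reduce the squared residual by this multiple of its own
#: lambda*|beta_j|^q penalty to enter the support...
ADD_MARGIN = 12.0
#: ...and is pruned again unless it keeps buying this multiple of it.  The
#: hysteresis (ADD_MARGIN > PRUNE_MARGIN) prevents add/remove cycles.
PRUNE_MARGIN = 6.0
#: an atom also enters if it cuts the whole objective by this fraction —
#: a structural gain no noise atom achieves (their phi share is < 2%)
ADD_REL_GAIN = 0.1


def omp_init(
    dm: DesignMatrix,
    cap: int | None = None,
    tol: float = 1e-3,
    improvement_tol: float = 1e-2,
    lam: float | None = None,
    q: float | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Orthogonal matching pursuit initial point.

    Greedily adds the column most correlated with the residual and refits
    least squares on the active set.  Stops when the relative residual
    drops below ``tol``, the support reaches ``cap`` (degree+1 by
    default), or the candidate atom stagnates.  Stagnation is judged
    against the regularizer when ``lam`` and ``q`` are given — the atom's
    squared-residual gain must exceed ``ADD_MARGIN`` times the
    lambda*|coef|^q penalty it would pay, which stops OMP at the noise
    floor — and otherwise by ``improvement_tol`` relative residual
    improvement.
    """
    X, y = dm.X, dm.y
    n_cols = X.shape[1]
    cap = n_cols if cap is None else min(cap, n_cols)
    beta = np.zeros(n_cols)
    support: list[int] = []
    ynorm = float(np.linalg.norm(y))
    if ynorm == 0 or cap == 0:
        return beta, support
    col_norms = np.linalg.norm(X, axis=0)
    col_norms[col_norms == 0] = 1.0

    def refit(sup):
        coef, *_ = np.linalg.lstsq(X[:, sup], y, rcond=None)
        r = y - X[:, sup] @ coef
        return coef, r, float(np.linalg.norm(r))

    r = y.copy()
    rnorm = ynorm
    coef = np.zeros(0)
    for _ in range(4 * n_cols):
        if len(support) >= cap or rnorm / ynorm <= tol:
            break
        corr = np.abs(X.T @ r) / col_norms
        corr[support] = -np.inf
        j = int(np.argmax(corr))
        trial = support + [j]
        coef_new, r_new, rnorm_new = refit(trial)
        if lam is not None and q is not None:
            gain = rnorm**2 - rnorm_new**2
            cost = lam * abs(float(coef_new[-1])) ** q
            phi_cur = rnorm**2 + lam * float(np.sum(np.abs(coef) ** q))
            phi_new = rnorm_new**2 + lam * float(np.sum(np.abs(coef_new) ** q))
            if gain <= ADD_MARGIN * cost and phi_new > (1.0 - ADD_REL_GAIN) * phi_cur:
                break  # the atom does not buy its penalty: noise floor
        elif rnorm_new > (1.0 - improvement_tol) * rnorm:
            break  # stagnation: the new atom only fits noise
        support, coef, r, rnorm = trial, coef_new, r_new, rnorm_new
        if lam is not None and q is not None:
            # backward step: a greedy path can carry a proxy atom (an even
            # power standing in for a lower even power, say) that later
            # additions make redundant; drop any atom whose removal costs
            # less than PRUNE_MARGIN times its own penalty.
            while len(support) > 1:
                worst, worst_ratio = None, np.inf
                for k_pos, k in enumerate(support):
                    sub = support[:k_pos] + support[k_pos + 1 :]
                    _, _, rn = refit(sub)
                    cost = rn**2 - rnorm**2
                    pen = lam * abs(float(coef[k_pos])) ** q
                    ratio = cost / (PRUNE_MARGIN * pen) if pen > 0 else np.inf
                    if ratio < worst_ratio:
                        worst, worst_ratio = k, ratio
                if worst is None or worst_ratio >= 1.0 or worst == j:
                    break
                support = [k for k in support if k != worst]
                coef, r, rnorm = refit(support)
    beta = np.zeros(n_cols)
    if support:
        beta[support] = coef
    return beta, support


# ---------------------------------------------------------------------------
# stage 2: smoothing-gradient descent

def sg_refine(
    dm: DesignMatrix,
    beta0: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    q: float = DEFAULT_Q,
    xi: float = DEFAULT_XI,
    max_iter: int = 5000,
    tol: float = 1e-6,
    support: list[int] | np.ndarray | None = None,
) -> np.ndarray:
    """Armijo-backtracking gradient descent on the smoothed objective.

    Only the coordinates in ``support`` move (all of them when None); the
    smoothed objective never increases along the iterates and the result
    satisfies phi_smooth(beta) <= phi_smooth(beta0).
    """
    if lam <= 0 or not 0 < q < 1 or xi <= 0:
        raise ValueError("require lambda > 0, 0 < q < 1, xi > 0")
    X, y = dm.X, dm.y
    beta = np.asarray(beta0, dtype=float).copy()
    mask = np.zeros(beta.size, dtype=bool)
    if support is None:
        mask[:] = True
    else:
        mask[np.asarray(support, dtype=int)] = True
    if not mask.any():
        return beta
    XtX = X.T @ X
    Xty = X.T @ y

    def f(b):
        val = phi_smooth(dm, b, lam, q, xi)
        if not np.isfinite(val):
            raise FloatingPointError("non-finite smoothed objective")
        return val

    fval = f(beta)
    step = 1.0
    c_armijo = 1e-4
    for _ in range(max_iter):
        s = smoothing_value(beta, xi)
        grad = 2.0 * (XtX @ beta - Xty) + lam * q * s ** (q - 1.0) * smoothing_grad(beta, xi)
        grad[~mask] = 0.0
        gnorm2 = float(grad @ grad)
        if np.sqrt(gnorm2) <= tol:
            break
        step = min(step * 2.0, 1e6)
        for _bt in range(60):
            cand = beta - step * grad
            fc = f(cand)
            if fc <= fval - c_armijo * step * gnorm2:
                break
            step *= 0.5
        else:
            break  # no descent step found at machine precision
        beta, fval = cand, fc
    return beta


# ---------------------------------------------------------------------------
# stage 3: lower bound and purification

def lower_bound(
    X: np.ndarray | DesignMatrix,
    lam: float,
    q: float,
    phi0: float,
    phi_exponent: float = 0.5,
) -> tuple[float, float]:
    """Theoretical lower bound L on nonzero entries of a local minimizer.

    L = (lambda*q / (2 ||X||_2 phi0^phi_exponent))^(1/(1-q)); any entry of
    a local minimizer with |beta_i| <= L must be exactly zero, and the
    support size is bounded by min(m, phi0/(lambda L^q)).  Returns
    ``(L, support_bound)``.  An exact fit (phi0 == 0) yields L = inf with
    support bound 0.
    """
    if isinstance(X, DesignMatrix):
        m = X.m
        X = X.X
    else:
        X = np.asarray(X, dtype=float)
        m = X.shape[0]
    if phi0 < 0:
        raise ValueError("phi0 must be nonnegative")
    if phi0 == 0:
        return float("inf"), 0.0
    spec = float(np.linalg.norm(X, 2))
    L = (lam * q / (2.0 * spec * phi0**phi_exponent)) ** (1.0 / (1.0 - q))
    bound = min(float(m), phi0 / (lam * L**q))
    return float(L), bound


def purify(beta: np.ndarray, L: float) -> np.ndarray:
    """Zero every entry with |beta_i| <= L; larger entries unchanged."""
    if L < 0:
        raise ValueError("L must be nonnegative")
    beta = np.asarray(beta, dtype=float).copy()
    beta[np.abs(beta) <= L] = 0.0
    return beta


def _purify_refit(dm: DesignMatrix, beta: np.ndarray, L: float) -> np.ndarray:
    """Purify, then LS-debias on the support, repeating until the support is
    stable (a refit entry can fall back under L, in which case it is pruned
    and the refit repeated; terminates because the support shrinks)."""
    beta = purify(beta, L)
    while True:
        sup = np.flatnonzero(beta)
        if sup.size == 0:
            return beta
        coef, *_ = np.linalg.lstsq(dm.X[:, sup], dm.y, rcond=None)
        refit = np.zeros_like(beta)
        refit[sup] = coef
        if np.all(np.abs(coef) > L):
            return refit
        beta = purify(refit, L)


def _foba_refine(dm: DesignMatrix, beta: np.ndarray, lam: float, q: float, L: float,
                 phi_cap: float) -> np.ndarray:
    """Forward-backward support refinement around the purified solution.

    OMP's greedy path can admit a correlated proxy atom (an even power
    standing in for a lower even power, say) or skip an atom it would have
    wanted later.  Each atom is re-judged against the same penalty-margin
    rule OMP uses: it is pruned unless removing it would cost more than
    ``PRUNE_MARGIN`` times its own lambda*|beta_j|^q penalty, and a new
    atom is admitted when it buys ``ADD_MARGIN`` times its penalty.  The
    hysteresis between the two margins keeps the search cycle-free and
    biased toward sparsity at the noise floor.  A phi-increasing deletion
    is accepted only while phi stays at or below ``phi_cap`` (the OMP
    starting value), preserving phi(final) <= phi(beta0).
    """
    n_cols = dm.X.shape[1]

    def residual_sq(b):
        r = dm.X @ b - dm.y
        return float(r @ r)

    best = beta
    best_phi = phi(dm, beta, lam, q)
    for _ in range(4 * n_cols):  # each accepted action changes the support
        action = None
        # backward: prune the weakest atom not earning its penalty margin
        for j in np.flatnonzero(best):
            trial = best.copy()
            trial[j] = 0.0
            trial = _purify_refit(dm, trial, L)
            cost = residual_sq(trial) - residual_sq(best)
            penalty = lam * abs(best[j]) ** q
            p = phi(dm, trial, lam, q)
            ok = p < best_phi - 1e-12 or (cost <= PRUNE_MARGIN * penalty and p <= phi_cap)
            if ok and (action is None or p < action[1]):
                action = (trial, p)
        if action is None:
            # forward: admit an atom whose l2 gain clears the entry margin
            sup = set(np.flatnonzero(best).tolist())
            for j in range(n_cols):
                if j in sup:
                    continue
                trial = best.copy()
                trial[j] = 1.0  # marker; the refit recomputes the value
                trial = _purify_refit(dm, trial, L)
                if not trial[j]:
                    continue
                gain = residual_sq(best) - residual_sq(trial)
                penalty = lam * abs(trial[j]) ** q
                p = phi(dm, trial, lam, q)
                admit = gain > ADD_MARGIN * penalty or p < (1.0 - ADD_REL_GAIN) * best_phi
                if admit and p < best_phi and (action is None or p < action[1]):
                    action = (trial, p)
        if action is None:
            break
        new_beta, new_phi = action
        if set(np.flatnonzero(new_beta).tolist()) == set(np.flatnonzero(best).tolist()):
            break
        best, best_phi = new_beta, new_phi
    return best


# ---------------------------------------------------------------------------
# full fit

@dataclass
class FitResult:
    """Sparse polynomial fit of the CSI in the scaled basis.

    ``beta`` holds descending-power coefficients (beta_n, ..., beta_1,
    beta_0) of the polynomial in t = (x - center)/halfwidth.
    """

    beta: np.ndarray
    support: np.ndarray
    objective: float
    L: float
    support_bound: float
    degree: int
    lam: float
    q: float
    xi: float
    center: float
    halfwidth: float
    phi0: float = field(default=np.nan)

    def __call__(self, x):
        t = (np.asarray(x, dtype=float) - self.center) / self.halfwidth
        return np.polyval(self.beta, t)

    def trace(self, width: int) -> BoundaryTrace:
        poly = np.polynomial.Polynomial(
            self.beta[::-1],
            domain=[self.center - self.halfwidth, self.center + self.halfwidth],
            window=[-1.0, 1.0],
        )
        return BoundaryTrace.from_polynomial(poly, width)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "degree": self.degree,
                    "beta_scaled_desc": self.beta.tolist(),
                    "support": self.support.tolist(),
                    "objective": self.objective,
                    "lower_bound": self.L,
                    "support_bound": self.support_bound,
                    "lambda": self.lam,
                    "q": self.q,
                    "xi": self.xi,
                    "scale": {"center": self.center, "halfwidth": self.halfwidth},
                },
                indent=2,
            )
        )


def fit_l2lq(
    x,
    y,
    lam: float = DEFAULT_LAMBDA,
    q: float = DEFAULT_Q,
    xi: float = DEFAULT_XI,
    degree: int | None = None,
    sg_max_iter: int = 5000,
    sg_tol: float = 1e-6,
) -> FitResult:
    """Hybrid OMP + smoothing-gradient fit of the l2-lq regression model.

    ``degree=None`` applies the extent-based degree rule.  The SG stage
    descends on the OMP support; the purified-and-debiased solution and the
    purified solution without debias are both evaluated and the lower
    objective wins, which keeps phi(final) <= phi(beta0) while every
    surviving entry exceeds the lower bound L.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = select_degree(np.sort(x)) if degree is None else degree
    dm = build_design_matrix(x, y, n)

    beta0, sup0 = omp_init(dm, cap=n + 1, lam=lam, q=q)
    phi0 = phi(dm, beta0, lam, q)
    L, bound = lower_bound(dm, lam, q, phi0)
    if not np.isfinite(L):  # exact fit by beta0: nothing to purify
        final = beta0
    else:
        beta_sg = sg_refine(
            dm, beta0, lam, q, xi, max_iter=sg_max_iter, tol=sg_tol, support=sup0
        )
        candidates = [_purify_refit(dm, beta_sg, L), purify(beta_sg, L)]
        final = min(candidates, key=lambda b: phi(dm, b, lam, q))
        final = _foba_refine(dm, final, lam, q, L, phi_cap=max(phi0, phi(dm, final, lam, q)))
    return FitResult(
        beta=final,
        support=np.flatnonzero(final),
        objective=phi(dm, final, lam, q),
        L=L,
        support_bound=bound,
        degree=n,
        lam=lam,
        q=q,
        xi=xi,
        center=dm.center,
        halfwidth=dm.halfwidth,
        phi0=phi0,
    )
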