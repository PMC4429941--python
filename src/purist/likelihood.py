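"""Log-domain model likelihood and analytic block gradients.

The generative model for a cohort of N bulk tumour samples over G
transcripts, given a panel B of R healthy reference distributions, is

    theta_n        ~ Dirichlet(nu)                  (mixing weights + alpha_n)
    m              ~ Dirichlet(kappa' * B @ omega)  (shared cancer profile)
    c_n            ~ Dirichlet(kappa_n * m)         (per-patient cancer profile)
    xhat_n         = sum_r theta_{n,r} b_r + alpha_n c_n
    x_n            ~ Multinomial(depth_n, xhat_n)

MAP estimation maximizes the joint log-density of all of the above.  In
the shared-profile (CPE) stage every c_n is tied to m and the c_n prior
terms are inactive; the per-patient (PPE) stage frees the c_n.

Everything here is computed as sums of logarithms — products of many
per-transcript probabilities are never formed.  Each optimizable block
exposes an objective in *unconstrained* coordinates:

* simplex blocks (theta rows, m, c_n, omega) go through a softmax with the
  last logit pinned to zero, which enforces positivity and the sum-to-one
  constraint implicitly;
* strictly positive scalars/vectors (nu, kappa', kappa_n) go through
  ``minimum + exp(y)``.

Objectives return the *negative* log-likelihood terms containing the
block, plus the analytic gradient in the unconstrained coordinates, ready
for an unconstrained minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

from .data import CountMatrix, CpeState, DataError, PpeState, ReferencePanel

__all__ = [
    "MixtureProbability",
    "BlockGradient",
    "Bounds",
    "mixture_probability",
    "multinomial_loglik",
    "dirichlet_loglik",
    "complete_loglik",
    "block_loglik_grad",
    "softmax_pinned",
    "pinned_logits",
    "positive_from_free",
    "free_from_positive",
    "profile_concentration",
    "CPE_BLOCKS",
    "PPE_BLOCKS",
    "make_cpe_block",
    "make_ppe_block",
]

SIMPLEX_ATOL = 1e-12


@dataclass
class MixtureProbability:
    """Per-patient transcript distribution of the mixed bulk sample."""

    xhat: np.ndarray

    def __post_init__(self) -> None:
        x = np.array(self.xhat, dtype=float)
        if x.ndim != 1 or np.any(x <= 0):
            raise DataError("mixture probability must be strictly positive")
        if abs(x.sum() - 1.0) > SIMPLEX_ATOL:
            raise DataError(f"mixture probability sums to {x.sum():.17g}, not 1")
        x.setflags(write=False)
        self.xhat = x


@dataclass
class BlockGradient:
    """Value and gradient of one block's objective in free coordinates."""

    value: float
    gradient: np.ndarray


@dataclass
class Bounds:
    """Box constraints on the positive hyper-parameters.

    The mixing-weight concentration nu is kept above one (plus a small
    margin) so its prior log-density stays bounded above on the open
    simplex — concentrations below one put infinite density spikes at the
    boundary.  The caps keep runaway concentration growth (possible when a
    profile sits exactly at its prior mean) inside floating-point range.
    """

    nu_min: float = 1.0 + 1e-6
    nu_max: float = 1e6
    kappa_prime_min: float = 2.0
    kappa_n_min: float = 2.0
    kappa_max: float = 1e9


def profile_concentration(strength, mean_profile: np.ndarray) -> np.ndarray:
    """Dirichlet concentration of a profile prior: strength times mean,
    floored elementwise at one.

    The floor makes the prior proper everywhere: transcripts the mean
    profile deems (near-)absent get a flat prior instead of an infinite
    density spike at zero, and the global strength never has to be
    inflated just to keep the smallest concentration entry above one.
    """
    return np.maximum(np.multiply.outer(mean_profile, strength), 1.0)


# ---------------------------------------------------------------------------
# reparametrizations


def softmax_pinned(z: np.ndarray) -> np.ndarray:
    """Map K-1 free logits to a K-simplex point (last logit pinned to 0)."""
    full = np.append(np.asarray(z, dtype=float), 0.0)
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def pinned_logits(p: np.ndarray) -> np.ndarray:
    """Inverse of :func:`softmax_pinned` for strictly positive p."""
    p = np.asarray(p, dtype=float)
    return np.log(p[:-1]) - np.log(p[-1])


def _softmax_chain(p: np.ndarray, grad_p: np.ndarray) -> np.ndarray:
    """Pull a gradient w.r.t. a simplex point back to pinned logits."""
    return (p * (grad_p - p @ grad_p))[:-1]


def _rows_softmax(Z: np.ndarray) -> np.ndarray:
    """Row-wise pinned softmax: N x (K-1) logits -> N x K simplex rows."""
    full = np.concatenate([Z, np.zeros((Z.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    E = np.exp(full)
    return E / E.sum(axis=1, keepdims=True)


def _rows_chain(P: np.ndarray, Gp: np.ndarray) -> np.ndarray:
    inner = np.einsum("ij,ij->i", P, Gp)
    return (P * (Gp - inner[:, None]))[:, :-1]


def positive_from_free(y: np.ndarray, minimum: float) -> np.ndarray:
    """Map free coordinates to values strictly above ``minimum``."""
    return minimum + np.exp(np.asarray(y, dtype=float))


def free_from_positive(v: np.ndarray, minimum: float) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(v < minimum):
        raise DataError(f"value must be at least the configured minimum {minimum}")
    # a value sitting exactly on the floor maps to a very negative (finite)
    # free coordinate rather than -inf
    return np.log(np.maximum(v - minimum, 1e-300))


# ---------------------------------------------------------------------------
# likelihood factors


def mixture_probability(
    theta_row: np.ndarray, B, cancer_profile: np.ndarray
) -> MixtureProbability:
    """Convex combination of the healthy panel and a cancer profile.

    ``theta_row`` carries the R reference weights followed by alpha; the
    result is sum_r theta_r b_r + alpha * c.
    """
    Bm = B.profiles if isinstance(B, ReferencePanel) else np.asarray(B, float)
    theta_row = np.asarray(theta_row, dtype=float)
    c = np.asarray(cancer_profile, dtype=float)
    if theta_row.shape[0] != Bm.shape[1] + 1:
        raise DataError(
            f"theta row length {theta_row.shape[0]} != R+1 = {Bm.shape[1] + 1}"
        )
    if c.shape[0] != Bm.shape[0]:
        raise DataError("cancer profile length does not match panel genes")
    xhat = Bm @ theta_row[:-1] + theta_row[-1] * c
    return MixtureProbability(xhat)


def multinomial_loglik(
    x: np.ndarray, xhat, include_constant: bool = False
) -> float:
    """Multinomial log-pmf of counts ``x`` under probabilities ``xhat``.

    By default the combinatorial coefficient — constant in all model
    parameters — is omitted, leaving sum_g x_g log xhat_g.  Pass
    ``include_constant=True`` for the proper normalized log-pmf.
    """
    x = np.asarray(x)
    p = xhat.xhat if isinstance(xhat, MixtureProbability) else np.asarray(xhat, float)
    if x.shape != p.shape:
        raise DataError("count and probability vectors differ in length")
    if np.any((p <= 0) & (x > 0)):
        raise DataError("zero mixture probability at a transcript with counts")
    with np.errstate(divide="ignore"):
        ll = float(np.where(x > 0, x * np.log(p), 0.0).sum())
    if include_constant:
        n = x.sum()
        ll += float(gammaln(n + 1) - gammaln(x + 1).sum())
    return ll


def dirichlet_loglik(p: np.ndarray, concentration: np.ndarray) -> float:
    """Log-density of a Dirichlet distribution at a simplex point."""
    p = np.asarray(p, dtype=float)
    a = np.asarray(concentration, dtype=float)
    if p.shape != a.shape:
        raise DataError("point and concentration differ in length")
    if np.any(a <= 0):
        raise DataError("Dirichlet concentration must be strictly positive")
    return float(
        gammaln(a.sum()) - gammaln(a).sum() + ((a - 1.0) * np.log(p)).sum()
    )


def _mult_term(X: np.ndarray, xhat: np.ndarray) -> float:
    """sum_{g,n} x_{gn} log xhat_{gn}, with 0 * log 0 treated as 0."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        return float(np.where(X > 0, X * np.log(xhat), 0.0).sum())


def _count_ratio(X: np.ndarray, xhat: np.ndarray) -> np.ndarray:
    """x / xhat where counts are positive, 0 elsewhere (gradient weight)."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        return np.where(X > 0, X / xhat, 0.0)


def _theta_prior(theta: np.ndarray, nu: np.ndarray) -> float:
    """sum_n log Dirichlet(theta_n | nu) over the rows of theta."""
    N = theta.shape[0]
    with np.errstate(divide="ignore"):
        cross = ((nu - 1.0) * np.log(theta).sum(axis=0)).sum()
    return float(N * (gammaln(nu.sum()) - gammaln(nu).sum()) + cross)


def complete_loglik(x, B, state, mode: str) -> float:
    """Full model log-likelihood (all prior and observation terms).

    ``mode='cpe'`` ties every patient profile to the shared profile m and
    omits the (then inactive) per-patient profile priors; ``mode='ppe'``
    uses the individual c_n with their Dirichlet(kappa_n * m) priors.  The
    multinomial combinatorial constant is omitted throughout.
    """
    X = x.values if isinstance(x, CountMatrix) else np.asarray(x)
    Bm = B.profiles if isinstance(B, ReferencePanel) else np.asarray(B, float)
    theta = state.theta.weights
    R = Bm.shape[1]
    if mode == "cpe":
        m = state.m
        xhat = Bm @ theta[:, :R].T + np.outer(m, theta[:, R])
        ll = dirichlet_loglik(
            m, profile_concentration(state.kappa_prime, Bm @ state.omega)
        )
        ll += _theta_prior(theta, state.nu)
        ll += _mult_term(X, xhat)
        return ll
    if mode == "ppe":
        C = state.cancer_profiles
        alpha = theta[:, R]
        xhat = Bm @ theta[:, :R].T + C * alpha[None, :]
        ll = dirichlet_loglik(
            state.m, profile_concentration(state.kappa_prime, Bm @ state.omega)
        )
        A = profile_concentration(state.kappa_n, state.m)  # G x N columns
        ll += float(
            gammaln(A.sum(axis=0)).sum()
            - gammaln(A).sum()
            + ((A - 1.0) * np.log(C)).sum()
        )
        ll += _theta_prior(theta, state.nu)
        ll += _mult_term(X, xhat)
        return ll
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# block objectives (negative log-likelihood terms + analytic gradients)

CPE_BLOCKS = ("theta", "m", "nu", "omega", "kappa_prime")
PPE_BLOCKS = ("c", "theta", "kappa_n", "nu")


def make_cpe_block(block, X, Bm, state: CpeState, bounds):
    """Objective factory for one CPE block.

    Returns ``(fun, z0)`` where ``fun(z) -> (value, gradient)`` is the
    negative of the log-likelihood terms containing the block, in the
    block's unconstrained coordinates, and ``z0`` is the current state's
    coordinate vector.
    """
    G, N = X.shape
    R = Bm.shape[1]
    theta = state.theta.weights
    m = state.m

    if block == "theta":
        A = np.concatenate([Bm, m[:, None]], axis=1)  # G x (R+1)
        nu = state.nu
        norm = N * (gammaln(nu.sum()) - gammaln(nu).sum())

        def fun(zflat):
            Z = zflat.reshape(N, R)
            Th = _rows_softmax(Z)
            xhat = A @ Th.T
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                value = norm + ((nu - 1.0) * np.log(Th)).sum()
                value += _mult_term(X, xhat)
                Gth = (nu - 1.0) / Th + _count_ratio(X, xhat).T @ A
            dZ = _rows_chain(Th, Gth)
            return -value, -dZ.ravel()

        return fun, pinned_logits_rows(theta)

    if block == "m":
        a = profile_concentration(state.kappa_prime, Bm @ state.omega)
        H = Bm @ theta[:, :R].T  # G x N, fixed
        alpha = theta[:, R]
        norm = float(gammaln(a.sum()) - gammaln(a).sum())

        def fun(z):
            mm = softmax_pinned(z)
            xhat = H + np.outer(mm, alpha)
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                value = norm + ((a - 1.0) * np.log(mm)).sum()
                value += _mult_term(X, xhat)
                gm = (a - 1.0) / mm + _count_ratio(X, xhat) @ alpha
            return -value, -_softmax_chain(mm, gm)

        return fun, pinned_logits(m)

    if block == "nu":
        with np.errstate(divide="ignore"):
            S = np.log(theta).sum(axis=0)

        def fun(y):
            nu = positive_from_free(y, bounds.nu_min)
            if np.any(nu > bounds.nu_max):
                return np.inf, np.zeros_like(y)
            value = N * (gammaln(nu.sum()) - gammaln(nu).sum())
            value += ((nu - 1.0) * S).sum()
            gnu = N * (digamma(nu.sum()) - digamma(nu)) + S
            return -value, -(nu - bounds.nu_min) * gnu

        return fun, free_from_positive(state.nu, bounds.nu_min)

    if block == "omega":
        kp = state.kappa_prime
        with np.errstate(divide="ignore"):
            lm = np.log(m)

        def fun(z):
            om = softmax_pinned(z)
            raw = kp * (Bm @ om)
            a = np.maximum(raw, 1.0)
            S = a.sum()
            value = float(gammaln(S) - gammaln(a).sum() + ((a - 1.0) * lm).sum())
            # floored entries do not respond to omega
            active = np.where(raw > 1.0, digamma(S) - digamma(a) + lm, 0.0)
            gom = kp * (Bm.T @ active)
            return -value, -_softmax_chain(om, gom)

        return fun, pinned_logits(state.omega)

    if block == "kappa_prime":
        w = Bm @ state.omega
        with np.errstate(divide="ignore"):
            lm = np.log(m)

        def fun(y):
            kp = positive_from_free(np.asarray(y), bounds.kappa_prime_min)
            if np.any(kp > bounds.kappa_max):
                return np.inf, np.zeros_like(np.atleast_1d(y))
            kp = float(kp[0]) if np.ndim(kp) else float(kp)
            raw = kp * w
            a = np.maximum(raw, 1.0)
            S = a.sum()
            value = float(gammaln(S) - gammaln(a).sum() + ((a - 1.0) * lm).sum())
            active = np.where(raw > 1.0, digamma(S) - digamma(a) + lm, 0.0)
            dkp = float(w @ active)
            grad = -(kp - bounds.kappa_prime_min) * dkp
            return -value, np.atleast_1d(grad)

        return fun, np.atleast_1d(
            free_from_positive(state.kappa_prime, bounds.kappa_prime_min)
        )

    raise ValueError(f"unknown CPE block {block!r}")


def make_ppe_block(block, X, Bm, state: PpeState, bounds, patient: int | None = None):
    """Objective factory for one PPE block (``block='c'`` needs ``patient``)."""
    G, N = X.shape
    R = Bm.shape[1]
    theta = state.theta.weights
    alpha = theta[:, R]
    C = state.cancer_profiles
    m = state.m

    if block == "c":
        n = patient
        if n is None:
            raise ValueError("patient index required for the c block")
        h = Bm @ theta[n, :R]
        a = profile_concentration(float(state.kappa_n[n]), m)
        al = float(alpha[n])
        xn = X[:, n]
        norm = float(gammaln(a.sum()) - gammaln(a).sum())

        def fun(z):
            c = softmax_pinned(z)
            xhat = h + al * c
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                value = norm + ((a - 1.0) * np.log(c)).sum()
                value += float(np.where(xn > 0, xn * np.log(xhat), 0.0).sum())
                gc = (a - 1.0) / c + al * _count_ratio(xn, xhat)
            return -value, -_softmax_chain(c, gc)

        return fun, pinned_logits(C[:, n])

    if block == "theta":
        if R < 2:
            raise ValueError("PPE theta block needs at least two references")
        nu = state.nu
        scale = 1.0 - alpha
        normalized = theta[:, :R] / scale[:, None]
        norm = N * (gammaln(nu.sum()) - gammaln(nu).sum())
        with np.errstate(divide="ignore"):
            alpha_terms = float(((nu[R] - 1.0) * np.log(alpha)).sum())

        def fun(zflat):
            Z = zflat.reshape(N, R - 1)
            S = _rows_softmax(Z)  # N x R
            ThR = scale[:, None] * S
            xhat = Bm @ ThR.T + C * alpha[None, :]
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                value = norm + alpha_terms + ((nu[:R] - 1.0) * np.log(ThR)).sum()
                value += _mult_term(X, xhat)
                Gth = (nu[:R] - 1.0) / ThR + _count_ratio(X, xhat).T @ Bm
            dZ = _rows_chain(S, scale[:, None] * Gth)
            return -value, -dZ.ravel()

        return fun, pinned_logits_rows(normalized)

    if block == "kappa_n":
        with np.errstate(divide="ignore"):
            LC = np.log(C)

        def fun(y):
            kn = positive_from_free(y, bounds.kappa_n_min)
            if np.any(kn > bounds.kappa_max):
                return np.inf, np.zeros_like(y)
            raw = np.outer(m, kn)
            A = np.maximum(raw, 1.0)
            S = A.sum(axis=0)
            value = float(
                gammaln(S).sum() - gammaln(A).sum() + ((A - 1.0) * LC).sum()
            )
            active = np.where(raw > 1.0, digamma(S)[None, :] - digamma(A) + LC, 0.0)
            dkn = m @ active
            return -value, -(kn - bounds.kappa_n_min) * dkn

        return fun, free_from_positive(state.kappa_n, bounds.kappa_n_min)

    if block == "nu":
        with np.errstate(divide="ignore"):
            S = np.log(theta).sum(axis=0)

        def fun(y):
            nu = positive_from_free(y, bounds.nu_min)
            if np.any(nu > bounds.nu_max):
                return np.inf, np.zeros_like(y)
            value = N * (gammaln(nu.sum()) - gammaln(nu).sum())
            value += ((nu - 1.0) * S).sum()
            gnu = N * (digamma(nu.sum()) - digamma(nu)) + S
            return -value, -(nu - bounds.nu_min) * gnu

        return fun, free_from_positive(state.nu, bounds.nu_min)

    raise ValueError(f"unknown PPE block {block!r}")


def pinned_logits_rows(P: np.ndarray) -> np.ndarray:
    """Row-wise :func:`pinned_logits`, flattened for the optimizer."""
    with np.errstate(divide="ignore"):
        L = np.log(P)
    return (L[:, :-1] - L[:, -1:]).ravel()


def block_loglik_grad(block, state, x, B, bounds, mode: str = "cpe",
                      patient: int | None = None) -> BlockGradient:
    """Evaluate one block's objective at the current state.

    The value is the negative of the sum of all log-likelihood terms
    containing the block; the gradient lives in the block's unconstrained
    coordinates.
    """
    X = x.values if isinstance(x, CountMatrix) else np.asarray(x)
    Bm = B.profiles if isinstance(B, ReferencePanel) else np.asarray(B, float)
    if mode == "cpe":
        fun, z0 = make_cpe_block(block, X, Bm, state, bounds)
    elif mode == "ppe":
        fun, z0 = make_ppe_block(block, X, Bm, state, bounds, patient=patient)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    value, grad = fun(z0)
    if not np.isfinite(value):
        raise FloatingPointError(
            f"block {block!r} objective is non-finite at a feasible point"
        )
    return BlockGradient(float(value), np.asarray(grad))
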