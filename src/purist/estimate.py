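"""Two-stage MAP estimation by block coordinate descent.

Stage 1 (**CPE**, cancer profile estimation) fits a shared cancer profile
``m``, per-sample mixing weights ``theta`` (whose last entry is the cancer
fraction alpha), and the hyper-parameters ``nu``, ``omega`` and
``kappa'``.  Stage 2 (**PPE**, patient profile estimation) freezes each
alpha at its CPE value and fits a personalized cancer profile ``c_n`` per
patient, a per-patient prior strength ``kappa_n``, the remaining healthy
weights, and a re-estimated shared ``nu``.

Each sweep minimizes the negative log-likelihood over one block at a time
with the conjugate-gradient engine; because every block objective
contains exactly the likelihood terms that depend on the block, the
complete log-likelihood is non-decreasing across block updates — the
drivers verify this invariant and abort on violation, which would signal
a gradient or reparametrization defect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .data import (
    CountMatrix,
    CpeState,
    DataError,
    ExpressionMatrix,
    PpeState,
    ReferencePanel,
    ThetaMatrix,
)
from .likelihood import (
    Bounds,
    complete_loglik,
    free_from_positive,
    make_cpe_block,
    make_ppe_block,
    pinned_logits,
    pinned_logits_rows,
    positive_from_free,
    softmax_pinned,
    _rows_softmax,
)
from .minimize import LineSearchOptions, MinimizeResult, minimize

log = logging.getLogger("purist.estimate")

__all__ = [
    "FitOptions",
    "CpeResult",
    "PpeResult",
    "initialize_cpe",
    "run_cpe",
    "run_ppe",
    "rescale_to_intensity",
]


@dataclass
class FitOptions:
    """Knobs of the coordinate-descent drivers.

    ``block_budget`` is the per-block function-evaluation budget handed to
    the line-search engine (negative values count evaluations).  A sweep
    visits every block once; sweeps stop when the relative change of the
    complete log-likelihood drops below ``tol`` or after ``max_sweeps``.
    ``hyper_restarts`` adds seeded random restarts for the hyper-parameter
    blocks (nu, omega, kappa'), keeping the best outcome; it is off by
    default so runs are reproducible from a single seed.
    """

    seed: int = 0
    max_sweeps: int = 35
    tol: float = 1e-7
    block_budget: int = -100
    monotone_tol: float = 1e-6
    hyper_restarts: int = 0
    bounds: Bounds = field(default_factory=Bounds)
    line_search: LineSearchOptions = field(default_factory=LineSearchOptions)


@dataclass
class CpeResult:
    alphapurities: np.ndarray
    theta: ThetaMatrix
    m: np.ndarray
    nu: np.ndarray
    omega: np.ndarray
    kappa_prime: float
    loglik_trace: np.ndarray  # one value per completed sweep
    block_trace: np.ndarray  # one value per block update (non-decreasing)
    total_loglik: float
    sample_ids: tuple = ()
    gene_ids: tuple = ()


@dataclass
class PpeResult:
    cancerprofiles_probability: np.ndarray
    cancerprofiles_intensity: np.ndarray
    theta: ThetaMatrix
    nu: np.ndarray
    kappa_n: np.ndarray
    loglik_trace: np.ndarray
    block_trace: np.ndarray
    total_loglik: float
    sample_ids: tuple = ()
    gene_ids: tuple = ()


def initialize_cpe(x: CountMatrix, B: ReferencePanel, seed: int,
                   options: FitOptions | None = None) -> CpeState:
    """Seeded starting point for the CPE stage.

    Mixing weights start at a flat Dirichlet draw per sample; the shared
    profile starts at the (lightly perturbed) mean of the healthy panel;
    hyper-parameters start weak: nu just above its floor, omega uniform,
    kappa' at ten times its floor.
    """
    options = options or FitOptions()
    rng = np.random.default_rng(seed)
    G, N = x.values.shape
    R = B.profiles.shape[1]
    theta = rng.dirichlet(np.ones(R + 1), size=N)
    theta = np.maximum(theta, 1e-12)
    theta /= theta.sum(axis=1, keepdims=True)
    base = B.profiles.mean(axis=1)
    noise = rng.dirichlet(np.ones(G))
    m = 0.95 * base + 0.05 * np.maximum(noise, 1e-300)
    m = np.maximum(m, 1e-300)
    m /= m.sum()
    nu = np.full(R + 1, options.bounds.nu_min + 1e-3)
    omega = np.full(R, 1.0 / R)
    kappa_prime = 10.0 * options.bounds.kappa_prime_min
    return CpeState(
        theta=ThetaMatrix(theta), m=m, nu=nu, omega=omega, kappa_prime=kappa_prime
    )


def _check_monotone(L_new: float, L_old: float, tol: float, where: str) -> None:
    if not np.isfinite(L_new):
        raise FloatingPointError(f"non-finite log-likelihood after {where}")
    if L_new < L_old - tol * max(1.0, abs(L_old)):
        raise RuntimeError(
            f"log-likelihood decreased after {where}: {L_old:.10g} -> {L_new:.10g}"
        )


def _minimize_block(fun, z0, options: FitOptions, restart_rng=None,
                    restartable: bool = False) -> np.ndarray:
    res = minimize(fun, z0, options.block_budget, options.line_search)
    best_z, best_f = res.x_opt, float(res.f_history[-1])
    if restartable and options.hyper_restarts > 0 and restart_rng is not None:
        for _ in range(options.hyper_restarts):
            z_alt = z0 + restart_rng.normal(scale=0.5, size=np.shape(z0))
            f_alt0, _ = fun(z_alt)
            if not np.isfinite(f_alt0):
                continue
            alt = minimize(fun, z_alt, options.block_budget, options.line_search)
            if float(alt.f_history[-1]) < best_f:
                best_z, best_f = alt.x_opt, float(alt.f_history[-1])
    return best_z


def run_cpe(x: CountMatrix, B: ReferencePanel, options: FitOptions | None = None,
            init: CpeState | None = None) -> CpeResult:
    """Fit the shared-profile stage and return cancer fractions.

    Sweeps over the blocks theta -> m -> nu -> omega -> kappa', each
    minimized in its unconstrained coordinates, until the complete
    log-likelihood stabilizes.
    """
    options = options or FitOptions()
    if x.values.shape[0] != B.profiles.shape[0]:
        raise DataError("count matrix and reference panel disagree on genes")
    X = x.values
    Bm = B.profiles
    G, N = X.shape
    R = Bm.shape[1]
    state = init or initialize_cpe(x, B, options.seed, options)
    # the shared profile is pinned by the pooled counts of all patients, so
    # its prior only needs a weak absolute concentration floor
    bounds = replace(
        options.bounds,
        kappa_prime_min=min(options.bounds.kappa_prime_min, state.kappa_prime / 2.0),
    )
    restart_rng = np.random.default_rng(np.random.SeedSequence([options.seed, 104729]))

    L = complete_loglik(x, B, state, "cpe")
    block_trace = [L]
    sweep_trace = []
    for _sweep in range(options.max_sweeps):
        L_start = L
        for block in ("theta", "m", "nu", "omega", "kappa_prime"):
            fun, z0 = make_cpe_block(block, X, Bm, state, bounds)
            z = _minimize_block(
                fun, z0, options, restart_rng,
                restartable=block in ("nu", "omega", "kappa_prime"),
            )
            state = _apply_cpe_update(state, block, z, bounds)
            L_new = complete_loglik(x, B, state, "cpe")
            _check_monotone(L_new, L, options.monotone_tol, f"CPE block {block!r}")
            log.debug(
                "cpe sweep=%d block=%s loglik=%.10g delta=%.4g",
                _sweep, block, L_new, L_new - L,
            )
            L = L_new
            block_trace.append(L)
        sweep_trace.append(L)
        log.info(
            "cpe sweep=%d loglik=%.10g delta=%.4g", _sweep, L, L - L_start
        )
        if L - L_start <= options.tol * abs(L_start):
            break
    theta = state.theta
    return CpeResult(
        alphapurities=theta.alpha.copy(),
        theta=theta,
        m=state.m,
        nu=state.nu,
        omega=state.omega,
        kappa_prime=state.kappa_prime,
        loglik_trace=np.asarray(sweep_trace),
        block_trace=np.asarray(block_trace),
        total_loglik=L,
        sample_ids=x.sample_ids,
        gene_ids=x.gene_ids,
    )


def _apply_cpe_update(state: CpeState, block: str, z: np.ndarray,
                      bounds: Bounds) -> CpeState:
    if block == "theta":
        N = state.theta.n_samples
        R = state.theta.n_components - 1
        theta = _rows_softmax(z.reshape(N, R))
        return replace(state, theta=ThetaMatrix(theta))
    if block == "m":
        return replace(state, m=softmax_pinned(z))
    if block == "nu":
        return replace(state, nu=positive_from_free(z, bounds.nu_min))
    if block == "omega":
        return replace(state, omega=softmax_pinned(z))
    if block == "kappa_prime":
        kp = positive_from_free(z, bounds.kappa_prime_min)
        return replace(state, kappa_prime=float(np.atleast_1d(kp)[0]))
    raise ValueError(block)


def run_ppe(x: CountMatrix, B: ReferencePanel, cpe: CpeResult,
            options: FitOptions | None = None,
            tumour: ExpressionMatrix | None = None) -> PpeResult:
    """Fit per-patient cancer profiles with cancer fractions frozen.

    Each patient's profile c_n gets a Dirichlet prior centred on the CPE
    shared profile with strength kappa_n; the healthy weights are
    re-optimized on the simplex of mass 1 - alpha_n.  The profiles are
    returned both on the probability scale and rescaled to the intensity
    scale of the input tumour data.
    """
    options = options or FitOptions()
    X = x.values
    Bm = B.profiles
    G, N = X.shape
    R = Bm.shape[1]
    if cpe.m.shape[0] != G or cpe.theta.n_samples != N:
        raise DataError("CPE result does not match the tumour/panel dimensions")
    if cpe.theta.n_components != R + 1:
        raise DataError("CPE result does not match the reference panel size")
    bounds = options.bounds
    # carry the CPE prior strength over as the starting point for kappa_n
    kn0 = min(
        max(cpe.kappa_prime, 10.0 * bounds.kappa_n_min), bounds.kappa_max / 10.0
    )
    state = PpeState(
        cancer_profiles=np.tile(cpe.m[:, None], (1, N)),
        kappa_n=np.full(N, kn0),
        theta=cpe.theta,
        nu=cpe.nu,
        m=cpe.m,
        omega=cpe.omega,
        kappa_prime=cpe.kappa_prime,
    )
    alpha_frozen = cpe.theta.alpha.copy()

    L = complete_loglik(x, B, state, "ppe")
    block_trace = [L]
    sweep_trace = []
    for _sweep in range(options.max_sweeps):
        L_start = L
        for n in range(N):
            fun, z0 = make_ppe_block("c", X, Bm, state, bounds, patient=n)
            res = minimize(fun, z0, options.block_budget, options.line_search)
            C = state.cancer_profiles.copy()
            C[:, n] = softmax_pinned(res.x_opt)
            state = replace(state, cancer_profiles=C)
            L_new = complete_loglik(x, B, state, "ppe")
            _check_monotone(
                L_new, L, options.monotone_tol, f"PPE profile of patient {n}"
            )
            L = L_new
            block_trace.append(L)
        remaining = ["kappa_n", "nu"] if R < 2 else ["theta", "kappa_n", "nu"]
        for block in remaining:
            fun, z0 = make_ppe_block(block, X, Bm, state, bounds)
            res = minimize(fun, z0, options.block_budget, options.line_search)
            state = _apply_ppe_update(state, block, res.x_opt, bounds, alpha_frozen)
            L_new = complete_loglik(x, B, state, "ppe")
            _check_monotone(L_new, L, options.monotone_tol, f"PPE block {block!r}")
            log.debug(
                "ppe sweep=%d block=%s loglik=%.10g delta=%.4g",
                _sweep, block, L_new, L_new - L,
            )
            L = L_new
            block_trace.append(L)
        sweep_trace.append(L)
        log.info(
            "ppe sweep=%d loglik=%.10g delta=%.4g", _sweep, L, L - L_start
        )
        if L - L_start <= options.tol * abs(L_start):
            break

    totals = (
        tumour.values.sum(axis=0) if tumour is not None else X.sum(axis=0)
    ).astype(float)
    intensity = state.cancer_profiles * totals[None, :]
    return PpeResult(
        cancerprofiles_probability=state.cancer_profiles,
        cancerprofiles_intensity=intensity,
        theta=state.theta,
        nu=state.nu,
        kappa_n=state.kappa_n,
        loglik_trace=np.asarray(sweep_trace),
        block_trace=np.asarray(block_trace),
        total_loglik=L,
        sample_ids=x.sample_ids,
        gene_ids=x.gene_ids,
    )


def _apply_ppe_update(state: PpeState, block: str, z: np.ndarray, bounds: Bounds,
                      alpha_frozen: np.ndarray) -> PpeState:
    if block == "theta":
        N = state.theta.n_samples
        R = state.theta.n_components - 1
        S = _rows_softmax(z.reshape(N, R - 1))
        thetaR = (1.0 - alpha_frozen)[:, None] * S
        theta = np.concatenate([thetaR, alpha_frozen[:, None]], axis=1)
        return replace(state, theta=ThetaMatrix(theta))
    if block == "kappa_n":
        return replace(state, kappa_n=positive_from_free(z, bounds.kappa_n_min))
    if block == "nu":
        return replace(state, nu=positive_from_free(z, bounds.nu_min))
    raise ValueError(block)


def rescale_to_intensity(cancer_profiles: np.ndarray,
                         tumour: ExpressionMatrix | CountMatrix) -> np.ndarray:
    """Scale probability-scale profiles back to the tumour intensity scale.

    Column n is multiplied by the total signal of tumour sample n, so the
    per-patient total is conserved and within-patient gene ordering is
    unchanged.
    """
    C = np.asarray(cancer_profiles, dtype=float)
    totals = tumour.values.sum(axis=0).astype(float)
    if C.shape[1] != totals.shape[0]:
        raise DataError("profile columns do not match tumour samples")
    return C * totals[None, :]
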