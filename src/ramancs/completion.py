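"""Nuclear-norm matrix completion solved with FISTA.

Missing spectral entries are recovered by approximately minimizing the
unconstrained Lagrangian

    F(X) = 1/2 * ||P_Omega(X - M)||_F^2 + lambda * ||X||_*

where ``P_Omega`` zeroes unobserved entries and ``||.||_*`` is the
nuclear norm (sum of singular values), the convex surrogate for rank.
The proximal operator of the nuclear norm is singular value
thresholding (SVT); the outer loop is proximal gradient descent with
FISTA momentum and an optional monotone restart. Because ``P_Omega`` is
a projection its gradient has Lipschitz constant 1, so any step size
<= 1 is safe; a restart falls back to the plain proximal step from the
previous iterate, which is guaranteed non-increasing, so with restarts
on the reported objective trace never increases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import HyperspectralCube, ObservationMask

__all__ = [
    "CompletionConfig",
    "CompletionResult",
    "svt",
    "fista_complete",
    "choose_lambda",
    "complete_cube",
]

LAMBDA_RULES = ("fixed_fraction_of_sigma_max", "cross_validate_holdout")


@dataclass
class CompletionConfig:
    """Solver settings.

    ``lam`` is the nuclear-norm weight; ``"auto"`` defers to
    :func:`choose_lambda` with ``lambda_rule``. ``step`` must be in
    (0, 1] (unit Lipschitz constant of the sampling operator).
    """

    lam: float | str = "auto"
    max_iter: int = 500
    tol: float = 1e-6
    step: float = 1.0
    restart: bool = True
    clamp_observed: bool = True
    lambda_rule: str = "fixed_fraction_of_sigma_max"
    lambda_c: float = 0.01
    lambda_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.lam, str):
            if self.lam != "auto":
                raise ValueError("lam must be a positive number or 'auto'")
        elif self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not (0.0 < self.step <= 1.0):
            raise ValueError("step must be in (0, 1]")
        if self.lambda_rule not in LAMBDA_RULES:
            raise ValueError(f"lambda_rule must be one of {LAMBDA_RULES}")


@dataclass
class CompletionResult:
    X_hat: np.ndarray
    objective_trace: np.ndarray
    iterations: int
    converged: bool
    lam_used: float


def _svt_with_values(M: np.ndarray, tau: float):
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    shrunk = np.maximum(s - tau, 0.0)
    return (U * shrunk) @ Vt, shrunk


def svt(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding: soft-threshold the singular values
    of ``M`` at ``tau`` (the proximal operator of ``tau * ||.||_*``)."""
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("svt requires finite entries")
    if tau < 0:
        raise ValueError("threshold must be >= 0")
    X, _ = _svt_with_values(M, tau)
    return X


def _validate_mask(observed: np.ndarray) -> np.ndarray:
    observed = np.asarray(observed, dtype=bool)
    if not observed.any():
        raise ValueError("empty observation mask: nothing to fit")
    if not observed.any(axis=1).all():
        bad = int(np.flatnonzero(~observed.any(axis=1))[0])
        raise ValueError(
            f"row {bad} has zero observed entries and cannot constrain completion"
        )
    return observed


def fista_complete(
    M: np.ndarray,
    observed: np.ndarray,
    config: CompletionConfig | None = None,
    X0: np.ndarray | None = None,
) -> CompletionResult:
    """Recover missing entries of ``M`` (values at unobserved positions
    are ignored) by FISTA on the nuclear-norm completion objective.

    Stops when the relative objective change drops below ``config.tol``
    or at ``config.max_iter`` (returned with ``converged=False``, not an
    exception). ``X0`` warm-starts the iteration (defaults to the
    zero-filled observed matrix).
    """
    config = config or CompletionConfig()
    observed = _validate_mask(observed)
    M = np.asarray(M, dtype=float)
    if M.shape != observed.shape:
        raise ValueError("matrix and mask shapes differ")
    if not np.all(np.isfinite(M[observed])):
        raise ValueError("observed entries must be finite")
    Mobs = np.where(observed, M, 0.0)

    lam = config.lam
    if isinstance(lam, str):
        lam = choose_lambda(
            M, observed, rule=config.lambda_rule, c=config.lambda_c,
            seed=config.lambda_seed,
        )
    step = config.step

    def objective(X: np.ndarray, nuclear: float) -> float:
        resid = np.where(observed, X - Mobs, 0.0)
        return 0.5 * float(np.sum(resid * resid)) + lam * nuclear

    X = Mobs.copy() if X0 is None else np.asarray(X0, dtype=float).copy()
    _, s0 = _svt_with_values(X, 0.0)
    F_prev = objective(X, float(s0.sum()))
    trace = [F_prev]
    Y = X
    t = 1.0
    converged = False
    iterations = 0

    for _ in range(config.max_iter):
        iterations += 1
        grad = np.where(observed, Y - Mobs, 0.0)
        X_new, shrunk = _svt_with_values(Y - step * grad, step * lam)
        F_new = objective(X_new, float(shrunk.sum()))
        if config.restart and F_new > F_prev:
            # momentum overshot: plain proximal step from X is monotone
            t = 1.0
            grad = np.where(observed, X - Mobs, 0.0)
            X_new, shrunk = _svt_with_values(X - step * grad, step * lam)
            F_new = objective(X_new, float(shrunk.sum()))
        trace.append(F_new)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        Y = X_new + ((t - 1.0) / t_next) * (X_new - X)
        X = X_new
        if abs(F_new - F_prev) / max(1.0, abs(F_prev)) < config.tol:
            converged = True
            F_prev = F_new
            break
        F_prev = F_new
        t = t_next

    return CompletionResult(
        X_hat=X,
        objective_trace=np.asarray(trace),
        iterations=iterations,
        converged=converged,
        lam_used=float(lam),
    )


def choose_lambda(
    M: np.ndarray,
    observed: np.ndarray,
    rule: str = "fixed_fraction_of_sigma_max",
    c: float = 0.01,
    seed: int = 0,
    holdout_fraction: float = 0.1,
    grid: np.ndarray | None = None,
) -> float:
    """Pick the nuclear-norm weight.

    ``fixed_fraction_of_sigma_max`` (default): ``lambda = c * sigma_max``
    of the zero-filled observed matrix — scale-equivariant and cheap.
    ``cross_validate_holdout``: hide a further ``holdout_fraction`` of
    the observed entries, scan a log-grid of fractions of sigma_max, and
    return the lambda minimizing held-out reconstruction error.
    """
    if rule not in LAMBDA_RULES:
        raise ValueError(f"rule must be one of {LAMBDA_RULES}")
    observed = _validate_mask(observed)
    M = np.asarray(M, dtype=float)
    Mobs = np.where(observed, M, 0.0)
    if not np.any(Mobs[observed] != 0.0):
        raise ValueError("all observed entries are zero; lambda is undefined")
    sigma_max = float(np.linalg.norm(Mobs, 2))

    if rule == "fixed_fraction_of_sigma_max":
        if c <= 0:
            raise ValueError("fraction c must be > 0")
        return c * sigma_max

    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(observed)
    n_hide = max(1, int(round(holdout_fraction * len(obs_idx))))
    hide = obs_idx[rng.choice(len(obs_idx), size=n_hide, replace=False)]
    train = observed.copy()
    train[hide[:, 0], hide[:, 1]] = False
    # never empty a row: restore one held-out entry for rows left blank
    for r in np.flatnonzero(~train.any(axis=1)):
        row_hidden = hide[hide[:, 0] == r]
        train[r, row_hidden[0, 1]] = True
    holdout = observed & ~train

    if grid is None:
        grid = np.logspace(-5, -1, 9)
    # scan lambda descending with warm starts (continuation): each solve
    # starts from the previous solution, which keeps the small-lambda end
    # of the grid converged at modest iteration counts
    inner = CompletionConfig(lam=1.0, max_iter=500, tol=1e-10)
    best_lam, best_err = None, np.inf
    sigma_train = float(np.linalg.norm(np.where(train, M, 0.0), 2))
    X_warm = None
    for frac in np.sort(np.asarray(grid, dtype=float))[::-1]:
        lam = frac * sigma_train
        result = fista_complete(M, train, replace(inner, lam=lam), X0=X_warm)
        X_warm = result.X_hat
        err = float(np.sqrt(np.mean((result.X_hat[holdout] - M[holdout]) ** 2)))
        if err < best_err:
            best_lam, best_err = lam, err
    return float(best_lam)


def complete_cube(
    cube: HyperspectralCube,
    mask: ObservationMask | None = None,
    config: CompletionConfig | None = None,
):
    """Complete a sparsified cube (pixels flattened row-major).

    With ``config.clamp_observed`` (default) the observed measurements
    are restored exactly in the output; only missing entries take the
    recovered values. Returns ``(recovered_cube, CompletionResult)``.
    """
    config = config or CompletionConfig()
    if mask is not None:
        if mask.shape != cube.intensities.shape:
            raise ValueError("mask shape does not match cube")
        observed = mask.observed.copy()
        if cube.observed is not None:
            observed &= cube.observed
    elif cube.observed is not None:
        observed = cube.observed
    else:
        observed = np.ones_like(cube.intensities, dtype=bool)
    result = fista_complete(cube.intensities, observed, config)
    X = result.X_hat.copy()
    if config.clamp_observed:
        X[observed] = cube.intensities[observed]
    recovered = cube.with_intensities(
        X, None,
        completion_lam=result.lam_used,
        completion_iterations=result.iterations,
        completion_converged=bool(result.converged),
    )
    return recovered, result
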