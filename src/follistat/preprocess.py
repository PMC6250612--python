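"""Channel-wise total-variation denoising under a Poisson noise model.

Fluorescence photon counts f are Poisson; the denoised image u minimizes

    J(u) = sum_ij [ u_ij - f_ij * log(u_ij) ]  +  lambda * TV_eps(u),

the Poisson negative log-likelihood plus an epsilon-smoothed isotropic
total variation TV_eps(u) = sum_ij sqrt(|D u|_ij^2 + eps^2), with D the
forward-difference gradient (Neumann boundary). The objective is convex on
u > 0; we solve it by projected gradient descent with backtracking so the
objective is non-increasing over accepted iterations, clipping u to
>= eps to stay in the domain. Channels are denoised independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ChannelImage

__all__ = ["DenoiseParams", "tv_poisson_denoise"]


@dataclass(frozen=True)
class DenoiseParams:
    """Solver knobs for TV-Poisson denoising.

    lambda_reg
        TV regularization weight; 0 returns the input unchanged.
    max_iter
        Iteration cap; hitting it without meeting ``tol`` raises a warning.
    tol
        Relative objective-change stopping threshold.
    epsilon
        TV smoothing constant and lower clip for u (keeps log(u) finite).
    """

    lambda_reg: float = 0.5
    max_iter: int = 200
    tol: float = 1e-4
    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")
        if self.tol <= 0 or self.epsilon <= 0:
            raise ValueError("tol and epsilon must be positive")


def _grad(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences with Neumann boundary (zero at the far edge)."""
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:, :-1] = u[:, 1:] - u[:, :-1]
    gy[:-1, :] = u[1:, :] - u[:-1, :]
    return gx, gy


def _div(px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Negative adjoint of _grad (discrete divergence)."""
    d = np.zeros_like(px)
    d[:, 0] += px[:, 0]
    d[:, 1:-1] += px[:, 1:-1] - px[:, :-2]
    d[:, -1] += -px[:, -2]
    d[0, :] += py[0, :]
    d[1:-1, :] += py[1:-1, :] - py[:-2, :]
    d[-1, :] += -py[-2, :]
    return d


def _objective(u: np.ndarray, f: np.ndarray, lam: float, eps: float) -> float:
    gx, gy = _grad(u)
    tv = np.sqrt(gx**2 + gy**2 + eps**2).sum()
    return float((u - f * np.log(u)).sum() + lam * tv)


def _objective_grad(u: np.ndarray, f: np.ndarray, lam: float, eps: float) -> np.ndarray:
    gx, gy = _grad(u)
    norm = np.sqrt(gx**2 + gy**2 + eps**2)
    return (1.0 - f / u) - lam * _div(gx / norm, gy / norm)


def tv_poisson_denoise(
    img: ChannelImage,
    params: DenoiseParams = DenoiseParams(),
    return_info: bool = False,
):
    """Denoise one channel by minimizing the smoothed TV-Poisson objective.

    Returns the denoised :class:`ChannelImage`; with ``return_info=True``
    also a dict holding the objective trace, iteration count and a
    ``converged`` flag. Non-negative input is required; non-convergence at
    ``max_iter`` returns the current iterate with a warning.
    """
    f = np.asarray(img.data, dtype=float)
    if np.any(f < 0):
        raise ValueError("input pixels must be non-negative for the Poisson model")
    lam, eps = params.lambda_reg, params.epsilon

    if lam == 0.0:
        out = ChannelImage(f.copy(), img.channel, img.pixel_size)
        info = {"objective": [], "n_iter": 0, "converged": True}
        return (out, info) if return_info else out

    u = np.maximum(f, eps)
    J = _objective(u, f, lam, eps)
    trace = [J]
    step = 1.0
    converged = False
    for _ in range(params.max_iter):
        g = _objective_grad(u, f, lam, eps)
        # backtracking: shrink the step until the objective does not increase
        accepted = False
        for _bt in range(30):
            u_new = np.maximum(u - step * g, eps)
            J_new = _objective(u_new, f, lam, eps)
            if J_new <= J:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # no descent direction at machine precision
            break
        rel = (J - J_new) / max(abs(J), 1.0)
        u, J = u_new, J_new
        trace.append(J)
        step *= 1.2  # cautious growth; next backtrack will trim it
        if rel < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            "TV-Poisson denoising did not converge within max_iter; "
            "returning the current iterate",
            stacklevel=2,
        )
    out = ChannelImage(u, img.channel, img.pixel_size)
    info = {"objective": trace, "n_iter": len(trace) - 1, "converged": converged}
    return (out, info) if return_info else out
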