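"""Scaled conjugate gradient minimization (Moller, 1993).

A batch second-order-flavoured optimizer for differentiable objectives:
conjugate search directions, curvature along the direction estimated by a
finite-difference Hessian-vector product (step ``sigma``), and a
Levenberg-Marquardt scale ``lambda`` adapted from the comparison ratio
between predicted and actual decrease.  No line searches, which is what
makes it attractive for training small neural networks on full batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SCGResult", "scg_minimize"]


@dataclass
class SCGResult:
    x: np.ndarray
    fun: float
    trace: list[float] = field(default_factory=list)  # objective after each accepted step
    n_iter: int = 0
    converged: bool = False
    message: str = ""


def scg_minimize(
    fun_grad,
    x0: np.ndarray,
    max_iter: int = 300,
    grad_tol: float = 1e-6,
    sigma: float = 1e-4,
    lambda0: float = 1e-6,
    ftol: float = 0.0,
    ftol_window: int = 10,
) -> SCGResult:
    """Minimize a scalar objective with gradient via scaled conjugate gradient.

    Parameters
    ----------
    fun_grad : callable
        ``fun_grad(x) -> (f, g)`` returning objective and gradient.
    x0 : initial parameter vector.
    max_iter : iteration cap.
    grad_tol : stop when the gradient norm falls below this.
    sigma : relative step for the finite-difference curvature estimate.
    lambda0 : initial Levenberg-Marquardt scale.
    ftol, ftol_window : optional plateau stop — terminate when the objective
        improvement over the last ``ftol_window`` accepted steps falls below
        ``ftol`` (absolute).  Disabled when ftol == 0.

    Returns the best parameters seen and the trace of accepted objective
    values (non-increasing by construction: only steps that decrease the
    objective are accepted).
    """
    x = np.asarray(x0, dtype=float).copy()
    n = x.size
    f, g = fun_grad(x)
    if not np.isfinite(f) or not np.all(np.isfinite(g)):
        raise ValueError("objective or gradient non-finite at x0")

    r = -g
    p = r.copy()
    success = True
    lam, lam_bar = float(lambda0), 0.0
    trace = [float(f)]
    delta = 0.0
    converged = False
    message = "max_iter reached"

    for k in range(1, max_iter + 1):
        rnorm = np.linalg.norm(r)
        if rnorm < grad_tol:
            converged, message = True, "gradient norm below tolerance"
            break
        p2 = float(p @ p)
        pnorm = np.sqrt(p2)
        if pnorm == 0.0:
            converged, message = True, "zero search direction"
            break

        if success:  # curvature along p via finite difference
            sk = sigma / pnorm
            _, g2 = fun_grad(x + sk * p)
            s = (g2 - (-r)) / sk
            delta = float(p @ s)

        # Levenberg-Marquardt scaling; force positive definiteness
        delta += (lam - lam_bar) * p2
        if delta <= 0:
            lam_bar = 2.0 * (lam - delta / p2)
            delta = -delta + lam * p2
            lam = lam_bar

        mu = float(p @ r)
        alpha = mu / delta
        x_new = x + alpha * p
        f_new, g_new = fun_grad(x_new)
        Delta = 2.0 * delta * (f - f_new) / (mu * mu)  # comparison ratio

        if np.isfinite(f_new) and Delta >= 0:
            # accepted step
            x, f = x_new, float(f_new)
            r_new = -g_new
            lam_bar = 0.0
            success = True
            if k % n == 0:  # restart conjugacy every n iterations
                p = r_new.copy()
            else:
                beta = float((r_new @ r_new - r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if Delta >= 0.75:
                lam = max(lam * 0.25, 1e-300)
            trace.append(f)
            if (
                ftol > 0
                and len(trace) > ftol_window
                and trace[-1 - ftol_window] - trace[-1] < ftol
            ):
                converged, message = True, "objective plateau"
                break
        else:
            lam_bar = lam
            success = False

        if Delta < 0.25:
            lam = lam + delta * (1.0 - Delta) / p2
            if not np.isfinite(lam) or lam > 1e200:
                message = "lambda overflow"
                break

    return SCGResult(
        x=x, fun=float(f), trace=trace, n_iter=len(trace) - 1,
        converged=converged, message=message,
    )
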