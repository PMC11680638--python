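"""Compiled kernels for the Q-learning likelihood and individual-level fits.

Everything in the inner loops of the simulation sweeps lives here: the
trial-by-trial negative log-likelihood with its analytic gradient on the
transformed scale (logit learning rate, log inverse temperature), a BFGS
minimizer with backtracking line search, a central-difference Hessian for
Laplace standard errors, and the task simulator.  Individual-level fits are
run by the tens of thousands in the reliability sweeps, so all of this is
numba-compiled and allocation-light.

Transformed coordinates: x = (alpha_logit, beta_log) for one session, or
x = (alpha_logit_1, beta_log_1, alpha_logit_2, beta_log_2) for a joint
two-session fit.  Gaussian priors enter as a mean vector and a precision
matrix, so ML (zero precision), diagonal MAP priors and the joint
empirical-Bayes prior with cross-session covariance all share one code path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Box bound on transformed parameters; |logit alpha|, |log beta| beyond this
#: are numerically indistinguishable from the boundary.
XBOUND = 30.0


@njit(cache=True)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def nll_grad_session(alpha_logit, beta_log, choices, outcomes):
    """Negative log-likelihood of one session and its gradient.

    Returns (nll, d/d alpha_logit, d/d beta_log).  Q values start at
    (0.5, 0.5); the chosen option moves toward the outcome by the learning
    rate, the unchosen option is unchanged; choice follows a softmax on the
    value difference.
    """
    a = _sigmoid(alpha_logit)
    b = np.exp(beta_log)
    q0 = 0.5
    q1 = 0.5
    dq0 = 0.0  # dQ/d alpha (natural scale)
    dq1 = 0.0
    f = 0.0
    ga = 0.0  # d nll / d alpha
    gb = 0.0  # d nll / d beta
    for t in range(choices.shape[0]):
        d = q0 - q1
        s = 1.0 if choices[t] == 0 else -1.0
        x = b * s * d
        # -log sigmoid(x), computed stably, and its derivative -(1 - p)
        if x >= 0.0:
            e = np.exp(-x)
            f += np.log1p(e)
            dldx = -e / (1.0 + e)
        else:
            e = np.exp(x)
            f += -x + np.log1p(e)
            dldx = -1.0 / (1.0 + e)
        gb += dldx * s * d
        ga += dldx * b * s * (dq0 - dq1)
        r = outcomes[t]
        if choices[t] == 0:
            dq0 = (1.0 - a) * dq0 + (r - q0)
            q0 += a * (r - q0)
        else:
            dq1 = (1.0 - a) * dq1 + (r - q1)
            q1 += a * (r - q1)
    return f, ga * a * (1.0 - a), gb * b


@njit(cache=True)
def nll_session(alpha_logit, beta_log, choices, outcomes):
    f, _, _ = nll_grad_session(alpha_logit, beta_log, choices, outcomes)
    return f


@njit(cache=True)
def obj_grad(x, ch1, out1, ch2, out2, two_sessions, pmu, pprec):
    """Penalized objective: session NLL(s) plus Gaussian prior quadratic form."""
    n = x.shape[0]
    g = np.zeros(n)
    f, ga, gb = nll_grad_session(x[0], x[1], ch1, out1)
    g[0] = ga
    g[1] = gb
    if two_sessions:
        f2, ga2, gb2 = nll_grad_session(x[2], x[3], ch2, out2)
        f += f2
        g[2] = ga2
        g[3] = gb2
    d = x - pmu
    pd = pprec @ d
    f += 0.5 * (d @ pd)
    g += pd
    return f, g


@njit(cache=True)
def bfgs_fit(x0s, ch1, out1, ch2, out2, two_sessions, pmu, pprec, tol, maxiter):
    """Multi-restart BFGS with backtracking; returns the best restart.

    x0s is (n_restarts, dim).  Ties broken by lowest objective then lowest
    restart index (the loop keeps the first strict improvement).  Returns
    (x_best, f_best, converged_best) where convergence means the gradient
    infinity-norm fell below tol within maxiter iterations for that restart.
    """
    n_restarts, dim = x0s.shape
    best_x = np.empty(dim)
    best_f = np.inf
    best_conv = False
    for r in range(n_restarts):
        x = np.minimum(np.maximum(x0s[r].copy(), -XBOUND), XBOUND)
        f, g = obj_grad(x, ch1, out1, ch2, out2, two_sessions, pmu, pprec)
        h = np.eye(dim)  # inverse-Hessian approximation
        conv = False
        for _ in range(maxiter):
            gnorm = 0.0
            for k in range(dim):
                if abs(g[k]) > gnorm:
                    gnorm = abs(g[k])
            if gnorm < tol:
                conv = True
                break
            p = -(h @ g)
            # backtracking Armijo line search
            slope = g @ p
            if slope >= 0.0:  # reset a corrupted approximation
                h = np.eye(dim)
                p = -g
                slope = g @ p
            step = 1.0
            f_new = f
            x_new = x
            ok = False
            for _ls in range(40):
                x_new = np.minimum(np.maximum(x + step * p, -XBOUND), XBOUND)
                f_new, g_new = obj_grad(
                    x_new, ch1, out1, ch2, out2, two_sessions, pmu, pprec
                )
                if f_new <= f + 1e-4 * step * slope:
                    ok = True
                    break
                step *= 0.5
            if not ok:
                break
            s = x_new - x
            y = g_new - g
            sy = s @ y
            x = x_new
            f = f_new
            g = g_new
            if sy > 1e-12:
                rho = 1.0 / sy
                hy = h @ y
                yhy = y @ hy
                # BFGS inverse update
                for i in range(dim):
                    for j in range(dim):
                        h[i, j] += (
                            (1.0 + rho * yhy) * rho * s[i] * s[j]
                            - rho * (s[i] * hy[j] + hy[i] * s[j])
                        )
        if f < best_f:
            best_f = f
            best_x = x.copy()
            best_conv = conv
    return best_x, best_f, best_conv


@njit(cache=True)
def hessian_at(x, ch1, out1, ch2, out2, two_sessions, pmu, pprec, step):
    """Hessian of the penalized objective by central differences of the gradient."""
    dim = x.shape[0]
    hess = np.zeros((dim, dim))
    for j in range(dim):
        xp = x.copy()
        xm = x.copy()
        xp[j] += step
        xm[j] -= step
        _, gp = obj_grad(xp, ch1, out1, ch2, out2, two_sessions, pmu, pprec)
        _, gm = obj_grad(xm, ch1, out1, ch2, out2, two_sessions, pmu, pprec)
        for i in range(dim):
            hess[i, j] = (gp[i] - gm[i]) / (2.0 * step)
    # symmetrize
    for i in range(dim):
        for j in range(i + 1, dim):
            v = 0.5 * (hess[i, j] + hess[j, i])
            hess[i, j] = v
            hess[j, i] = v
    return hess


@njit(cache=True)
def simulate_core(alpha, beta, good_is_a, p_good, p_bad, u_choice, u_out):
    """Simulate one session; uniforms are drawn by the caller for seeding."""
    n = good_is_a.shape[0]
    choices = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=np.int64)
    q0 = 0.5
    q1 = 0.5
    for t in range(n):
        p_a = _sigmoid(beta * (q0 - q1))
        c = 0 if u_choice[t] < p_a else 1
        good = (c == 0) == (good_is_a[t] == 1)
        p_r = p_good if good else p_bad
        r = 1 if u_out[t] < p_r else 0
        if c == 0:
            q0 += alpha * (r - q0)
        else:
            q1 += alpha * (r - q1)
        choices[t] = c
        outcomes[t] = r
    return choices, outcomes
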