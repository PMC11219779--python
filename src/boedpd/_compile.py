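"""Symbolic-to-numeric compilation of reaction-network right-hand sides.

Rate laws are parsed once with sympy, common subexpressions are lifted, and
the resulting scalar code is emitted as plain Python source which is then
JIT-compiled with numba.  Three functions are generated per model:

* ``rhs``   — f(y; u, kappa), the species balance equations
* ``jac``   — df/dy, used as the analytic Jacobian for LSODA
* ``dfdp``  — df/d(theta), the partials w.r.t. the uncertain parameters

The forward-sensitivity system  S' = (df/dy) S + df/dtheta,  S(0) = 0  is
assembled from these and integrated alongside the states.  Its (exact upper
block / block-diagonal) Jacobian is also supplied analytically: without it
LSODA numerically differences an (n + n·m)-square Jacobian, which is an
order of magnitude slower.
"""

from __future__ import annotations

import math
import warnings

import numba
import numpy as np
import sympy as sp
from scipy.integrate import ODEintWarning, odeint


class IntegrationError(RuntimeError):
    """ODE solve failed (stiff blow-up or tolerance not met).

    Carries the offending parameter vector and control so callers can log
    or reject the region instead of silently propagating NaNs.
    """

    def __init__(self, message, theta=None, u=None):
        super().__init__(message)
        self.theta = theta
        self.u = u


def _emit(mat: sp.Matrix, name: str, n_species: int, n_params: int) -> str:
    """Emit numba-compilable source filling ``out`` with the matrix entries."""
    rows, cols = mat.shape
    lines = [f"def {name}(y, u, p, out):"]
    for i in range(n_species):
        lines.append(f"    y{i} = y[{i}]")
    for i in range(n_params):
        lines.append(f"    p{i} = p[{i}]")
    subs, exprs = sp.cse(list(mat), order="none")
    for s, e in subs:
        lines.append(f"    {s} = {sp.pycode(e)}")
    k = 0
    for i in range(rows):
        for j in range(cols):
            e = exprs[k]
            k += 1
            if e != 0:
                lines.append(f"    out[{i}, {j}] = {sp.pycode(e)}")
    lines.append("    return out")
    return "\n".join(lines)


class CompiledModel:
    """Numerical backend for one reaction network.

    Parameters
    ----------
    f_exprs : list of sympy expressions, one per species (dy_i/dt).
    species_symbols, param_symbols : the y_i / p_j symbols appearing in them.
    u_symbol : the IC50 control symbol.
    uncertain_idx : positions (into the full parameter vector) of theta.
    """

    def __init__(self, f_exprs, species_symbols, param_symbols, u_symbol,
                 uncertain_idx, rtol=1e-6, atol=1e-9):
        self.n = len(species_symbols)
        self.n_params = len(param_symbols)
        self.uncertain_idx = np.asarray(uncertain_idx, dtype=np.int64)
        self.m = len(uncertain_idx)
        self.rtol = float(rtol)
        self.atol = float(atol)

        # canonicalise symbol names to y0..yN / p0..pM so codegen is uniform
        ymap = {s: sp.Symbol(f"y{i}") for i, s in enumerate(species_symbols)}
        pmap = {s: sp.Symbol(f"p{i}") for i, s in enumerate(param_symbols)}
        umap = {u_symbol: sp.Symbol("u")}
        fvec = sp.Matrix([e.xreplace({**ymap, **pmap, **umap}) for e in f_exprs])
        yv = sp.Matrix([ymap[s] for s in species_symbols])
        th = sp.Matrix([pmap[param_symbols[i]] for i in uncertain_idx])
        jac = fvec.jacobian(yv)
        dfdp = fvec.jacobian(th) if self.m else sp.zeros(self.n, 0)

        src = "\n\n".join([
            _emit(fvec, "_rhs", self.n, self.n_params),
            _emit(jac, "_jac", self.n, self.n_params),
            _emit(dfdp, "_dfdp", self.n, self.n_params),
        ])
        ns: dict = {"math": math, "np": np}
        exec(compile(src, "<boedpd-codegen>", "exec"), ns)
        rhs_ = numba.njit(ns["_rhs"])
        jac_ = numba.njit(ns["_jac"])
        dfdp_ = numba.njit(ns["_dfdp"])
        n, m = self.n, self.m
        naug = n + n * m

        @numba.njit
        def f_core(yv, u, p):
            out = np.zeros((n, 1))
            rhs_(yv, u, p, out)
            return out[:, 0]

        @numba.njit
        def j_core(yv, u, p):
            out = np.zeros((n, n))
            jac_(yv, u, p, out)
            return out

        @numba.njit
        def aug_core(z, u, p):
            yv = z[:n]
            out = np.zeros(naug)
            F = np.zeros((n, 1))
            J = np.zeros((n, n))
            P = np.zeros((n, m))
            rhs_(yv, u, p, F)
            jac_(yv, u, p, J)
            dfdp_(yv, u, p, P)
            out[:n] = F[:, 0]
            S = np.ascontiguousarray(z[n:]).reshape(n, m)
            dS = J @ S + P
            out[n:] = dS.ravel()
            return out

        @numba.njit
        def aug_jac_core(z, u, p):
            # exact in the state block and the dS'/dS blocks; the dS'/dy
            # coupling (second derivatives of f) is dropped — LSODA only
            # uses the Jacobian for Newton convergence, not for accuracy
            J = np.zeros((n, n))
            jac_(z[:n], u, p, J)
            A = np.zeros((naug, naug))
            A[:n, :n] = J
            for i in range(n):
                for k in range(n):
                    Jik = J[i, k]
                    if Jik != 0.0:
                        for j in range(m):
                            A[n + i * m + j, n + k * m + j] = Jik
            return A

        self._f = lambda y, t, u, p: f_core(y, u, p)
        self._j = lambda y, t, u, p: j_core(y, u, p)
        self._fa = lambda z, t, u, p: aug_core(z, u, p)
        self._ja = lambda z, t, u, p: aug_jac_core(z, u, p)
        self._cache: dict = {}

    # -- solvers ---------------------------------------------------------

    def _check(self, info, theta, u):
        if info["message"] != "Integration successful.":
            raise IntegrationError(
                f"ODE integration failed: {info['message']} "
                f"(theta={theta}, u={u})", theta=theta, u=u)

    def solve(self, y0, p_full, u, t_grid):
        """States on ``t_grid`` (which must start at t0)."""
        with warnings.catch_warnings():
            # failures are detected and raised below; don't also warn
            warnings.simplefilter("ignore", ODEintWarning)
            y, info = odeint(self._f, y0, t_grid, args=(float(u), p_full),
                             Dfun=self._j, rtol=self.rtol, atol=self.atol,
                             mxstep=5000, full_output=True, printmessg=False)
        self._check(info, p_full[self.uncertain_idx], u)
        if not np.all(np.isfinite(y)):
            raise IntegrationError("non-finite states in solution",
                                   theta=p_full[self.uncertain_idx], u=u)
        return y

    def solve_final(self, y0, p_full, u, t0, tau):
        """State vector at t = tau only (cheap two-point solve)."""
        y = self.solve(y0, p_full, u, np.array([t0, tau]))
        return y[-1]

    def solve_final_sens(self, y0, p_full, u, t0, tau):
        """(y(tau), S(tau)) with S the n x m sensitivity matrix d y / d theta."""
        z0 = np.concatenate([y0, np.zeros(self.n * self.m)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ODEintWarning)
            z, info = odeint(self._fa, z0, np.array([t0, tau]),
                             args=(float(u), p_full), Dfun=self._ja,
                             rtol=self.rtol, atol=self.atol,
                             mxstep=5000, full_output=True, printmessg=False)
        self._check(info, p_full[self.uncertain_idx], u)
        zf = z[-1]
        if not np.all(np.isfinite(zf)):
            raise IntegrationError("non-finite sensitivities",
                                   theta=p_full[self.uncertain_idx], u=u)
        return zf[:self.n], zf[self.n:].reshape(self.n, self.m)
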