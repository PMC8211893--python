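"""LDDMM curve registration with a currents data term and Jacobian markers.

Each target curve is first rigidly aligned to the template (rotation +
translation only -- size differences must survive into the deformation so
that the Jacobian determinant keeps its area meaning).  The diffeomorphic
match then minimizes

    E(alpha) = sum_t dt sum_ij alpha_i(t) . alpha_j(t) K_V(x_i(t), x_j(t))
               + lambda * || [phi_1(template)] - [target] ||^2_{W'}

over time-discretized momenta ``alpha`` supported on the K template points.
K_V is a Gaussian kernel of width sigma_V; the velocity field is
v_t(x) = sum_i K_V(x, x_i(t)) alpha_i(t) and points follow it by explicit
Euler over n_timesteps.  The data term is the squared currents norm with a
Gaussian kernel of width sigma_W: a curve is represented by its segment
midpoints and tangent vectors, which compares curves without point
correspondence.  Optimization is plain gradient descent with Armijo
backtracking (reproducible, no line-search randomness); the gradient is
computed by a hand-rolled reverse sweep through the Euler steps.

The deformation marker at template point k is J_k = det D_k, where D_k is
the ambient 2x2 Jacobian of the transformation, integrated along the flow
with the same Euler scheme (dD/dt = grad v_t (phi_t(x)) D).  J > 1 means
local outward deformation (expansion) of the target relative to the
template, J < 1 inward deformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import geometry
from .template import TemplateCurve

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration / results
# ---------------------------------------------------------------------------

@dataclass
class RegistrationConfig:
    """Free parameters of the registration.

    ``sigma_V`` (velocity kernel width, mm) defaults to 1/4 of the template
    point-set diameter, about twice the CC thickness: wide enough that
    the two boundary walls are coupled and the marker responds to local
    *areal* change (calibrated against the uniform-scaling oracle, where the
    mean marker must approach the area ratio), yet well below the CC length
    so localized effects stay localized.  ``sigma_W`` (currents kernel
    width) defaults to sigma_V/2; ``lambda_match`` to the value that
    normalizes the initial data term to ``lambda_scale``, a dimensionless
    level chosen so the data term dominates the expected kinetic energy of
    mm-scale deformations.
    """

    sigma_V: float | None = None
    sigma_W: float | None = None
    lambda_match: float | None = None
    lambda_scale: float = 2000.0
    n_timesteps: int = 10
    max_iters: int = 500
    rel_tol: float = 1e-7
    rigid_max_iters: int = 100
    use_rigid: bool = True

    def __post_init__(self):
        if self.n_timesteps < 5:
            raise ValueError("n_timesteps must be >= 5")
        for name in ("sigma_V", "sigma_W", "lambda_match"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")

    def resolved(self, template_points: np.ndarray, mismatch0: float) -> "RegistrationConfig":
        """Fill the auto defaults for a concrete template/target pair."""
        sv = self.sigma_V
        if sv is None:
            # rotation-invariant size scale: the point-set diameter
            d2 = ((template_points[:, None, :] - template_points[None, :, :]) ** 2).sum(-1)
            sv = float(np.sqrt(d2.max())) / 4.0
        sw = self.sigma_W if self.sigma_W is not None else sv / 2.0
        lam = self.lambda_match
        if lam is None:
            lam = self.lambda_scale / mismatch0 if mismatch0 > 1e-12 else 1.0
        return RegistrationConfig(
            sigma_V=sv, sigma_W=sw, lambda_match=lam, lambda_scale=self.lambda_scale,
            n_timesteps=self.n_timesteps, max_iters=self.max_iters,
            rel_tol=self.rel_tol, rigid_max_iters=self.rigid_max_iters,
            use_rigid=self.use_rigid,
        )


@dataclass
class RigidTransform:
    theta: float
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return geometry.apply_rigid(points, self.theta, self.translation)


@dataclass
class RegistrationResult:
    rigid: RigidTransform
    momenta: np.ndarray            # (T, K, 2)
    deformed_template: np.ndarray  # (K, 2)
    jacobians: np.ndarray          # (K, 2, 2)
    markers: np.ndarray            # (K,) det of jacobians
    final_energy: float
    matching_residual: float
    iterations: int
    converged: bool
    config: RegistrationConfig | None = None
    energy_trace: np.ndarray | None = None
    subject_id: str = ""


# ---------------------------------------------------------------------------
# rigid alignment (ICP, rotation + translation only)
# ---------------------------------------------------------------------------

def _symmetric_cost(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared nearest-point distance, symmetrized."""
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab = tb.query(a)[0]
    d_ba = ta.query(b)[0]
    return float((np.sum(d_ab ** 2) + np.sum(d_ba ** 2)) / (len(a) + len(b)))


def _kabsch_rigid(src: np.ndarray, dst: np.ndarray):
    """Least-squares rotation + translation mapping src -> dst (no reflection)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = cd - R @ cs
    return float(np.arctan2(R[1, 0], R[0, 0])), t


def _principal_angle(points: np.ndarray) -> float:
    c = points - points.mean(axis=0)
    cov = c.T @ c / len(c)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    return float(np.arctan2(v[1], v[0]))


def rigid_align(target: np.ndarray, template: np.ndarray,
                max_iters: int = 100) -> tuple:
    """Rigidly align ``target`` onto ``template`` by ICP.

    Rotation + translation only: no scaling, no reflection.  Initialized
    from centroid alignment and principal-axis orientation (both axis
    polarities tried); refined by symmetric nearest-point ICP with a Kabsch
    update.  Returns (RigidTransform, aligned_target).
    """
    target = np.asarray(target, dtype=float)
    template = np.asarray(template, dtype=float)
    if len(target) < 8 or len(template) < 8:
        raise ValueError("rigid alignment needs curves with >= 8 points")

    base = _principal_angle(template) - _principal_angle(target)
    best = None
    for theta0 in (base, base + np.pi):
        R = geometry.rotation_matrix(theta0)
        t0 = template.mean(axis=0) - R @ target.mean(axis=0)
        cost = _symmetric_cost(target @ R.T + t0, template)
        if best is None or cost < best[0]:
            best = (cost, theta0, t0)
    cost, theta, trans = best

    tree_template = cKDTree(template)
    n_increase = 0
    for it in range(max_iters):
        aligned = geometry.apply_rigid(target, theta, trans)
        # symmetric correspondences: aligned->template and template->aligned
        idx_fwd = tree_template.query(aligned)[1]
        idx_bwd = cKDTree(aligned).query(template)[1]
        src = np.vstack([target, target[idx_bwd]])
        dst = np.vstack([template[idx_fwd], template])
        theta_new, trans_new = _kabsch_rigid(src, dst)
        new_cost = _symmetric_cost(geometry.apply_rigid(target, theta_new, trans_new), template)
        if new_cost > cost + 1e-15:
            n_increase += 1
            if n_increase >= 5:
                raise RuntimeError(
                    f"ICP diverged: cost increased 5 consecutive iterations "
                    f"(iteration {it}, cost {new_cost:.6g} > {cost:.6g})"
                )
        else:
            n_increase = 0
        converged = abs(cost - new_cost) <= 1e-14 * max(cost, 1.0)
        theta, trans, cost = theta_new, trans_new, new_cost
        if converged:
            break
    rigid = RigidTransform(theta=theta, translation=np.asarray(trans))
    return rigid, rigid.apply(target)


# ---------------------------------------------------------------------------
# currents data term
# ---------------------------------------------------------------------------

def _segments(points: np.ndarray):
    nxt = np.roll(points, -1, axis=0)
    return (points + nxt) / 2.0, nxt - points  # midpoints, tangents


def currents_norm_sq(points: np.ndarray, sigma_w: float) -> float:
    c, tau = _segments(np.asarray(points, dtype=float))
    d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)
    return float(np.sum((tau @ tau.T) * np.exp(-d2 / sigma_w ** 2)))


def currents_inner(points_a: np.ndarray, points_b: np.ndarray, sigma_w: float) -> float:
    ca, ta = _segments(np.asarray(points_a, dtype=float))
    cb, tb = _segments(np.asarray(points_b, dtype=float))
    d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(-1)
    return float(np.sum((ta @ tb.T) * np.exp(-d2 / sigma_w ** 2)))


def currents_mismatch(points_a: np.ndarray, points_b: np.ndarray, sigma_w: float) -> float:
    """Squared currents distance ||[a] - [b]||^2 between two closed curves."""
    if len(points_a) < 3 or len(points_b) < 3:
        raise ValueError("currents mismatch needs curves with >= 3 points")
    m = (currents_norm_sq(points_a, sigma_w)
         - 2.0 * currents_inner(points_a, points_b, sigma_w)
         + currents_norm_sq(points_b, sigma_w))
    return max(m, 0.0)


def _currents_mismatch_and_grad(points: np.ndarray, target: np.ndarray, sigma_w: float):
    """Mismatch and its gradient with respect to the first curve's points."""
    p = np.asarray(points, dtype=float)
    c, tau = _segments(p)
    cb, tb = _segments(np.asarray(target, dtype=float))
    s2 = sigma_w ** 2

    daa = c[:, None, :] - c[None, :, :]
    kaa = np.exp(-(daa ** 2).sum(-1) / s2)
    dab = c[:, None, :] - cb[None, :, :]
    kab = np.exp(-(dab ** 2).sum(-1) / s2)

    taa = tau @ tau.T
    tab = tau @ tb.T
    norm_b = currents_norm_sq(target, sigma_w)
    mismatch = float(np.sum(taa * kaa) - 2.0 * np.sum(tab * kab) + norm_b)

    tau_bar = 2.0 * (kaa @ tau) - 2.0 * (kab @ tb)
    c_bar = (-4.0 / s2) * (np.einsum("ij,ijd->id", taa * kaa, daa)
                           - np.einsum("ij,ijd->id", tab * kab, dab))
    p_bar = (c_bar + np.roll(c_bar, 1, axis=0)) / 2.0 + (np.roll(tau_bar, 1, axis=0) - tau_bar)
    return mismatch, p_bar


# ---------------------------------------------------------------------------
# flow, energy, adjoint gradient
# ---------------------------------------------------------------------------

def _gram(x: np.ndarray, s2: float) -> np.ndarray:
    sq = np.sum(x * x, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / s2)


def _flow_forward(x0: np.ndarray, alpha: np.ndarray, sigma_v: float):
    """Integrate points under v_t = sum_j K_V(., x_j(t)) alpha_j(t).

    Returns (trajectory x_t for t = 0..T, Gram matrices, kinetic energy).
    """
    T = alpha.shape[0]
    dt = 1.0 / T
    s2 = sigma_v ** 2
    xs = [x0]
    gs = []
    e_reg = 0.0
    x = x0
    for t in range(T):
        G = _gram(x, s2)
        v = G @ alpha[t]
        e_reg += dt * float(np.sum(alpha[t] * v))
        x = x + dt * v
        xs.append(x)
        gs.append(G)
    return xs, gs, e_reg


def _energy_only(x0, alpha, target, sigma_v, sigma_w, lam):
    xs, _, e_reg = _flow_forward(x0, alpha, sigma_v)
    mismatch = currents_mismatch(xs[-1], target, sigma_w)
    return e_reg + lam * mismatch, mismatch


def _energy_and_grad(x0: np.ndarray, alpha: np.ndarray, target: np.ndarray,
                     sigma_v: float, sigma_w: float, lam: float):
    """Energy, exact discrete gradient, and the kernel-preconditioned direction.

    The gradient comes from a reverse sweep through the Euler steps (discrete
    adjoint).  Both of its terms carry an explicit left Gram factor,
    grad_t = dt (2 G alpha_t + G xbar_{t+1}), so the descent direction in the
    RKHS metric on velocities, G^{-1} grad, is available without a solve:
    precond_t = dt (2 alpha_t + xbar_{t+1}).  Descending along it removes the
    severe ill-conditioning of the Gaussian Gram spectrum.
    """
    T = alpha.shape[0]
    dt = 1.0 / T
    s2 = sigma_v ** 2
    xs, gs, e_reg = _flow_forward(x0, alpha, sigma_v)
    mismatch, p_bar = _currents_mismatch_and_grad(xs[-1], target, sigma_w)
    energy = e_reg + lam * mismatch

    grad = np.empty_like(alpha)
    precond = np.empty_like(alpha)
    xbar = lam * p_bar
    for t in range(T - 1, -1, -1):
        x = xs[t]
        a = alpha[t]
        G = gs[t]
        precond[t] = dt * (2.0 * a + xbar)
        grad[t] = dt * (G @ (2.0 * a + xbar))
        inner = xbar @ a.T + a @ xbar.T + 2.0 * (a @ a.T)
        M = G * inner
        xbar = xbar - (2.0 * dt / s2) * (M.sum(axis=1)[:, None] * x - M @ x)
    return energy, grad, precond, mismatch


# ---------------------------------------------------------------------------
# jitted inner loops (numba): the energy/gradient evaluation dominates the
# cohort-registration cost, and at K ~ 50-200 the arrays are small enough
# that explicit loops beat vectorized numpy by a wide margin.
# ---------------------------------------------------------------------------

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if len(args) == 1 and callable(args[0]):
            return args[0]
        return wrap


@_njit(cache=True, fastmath=True)
def _nb_forward(x0, alpha, s2):
    T = alpha.shape[0]
    K = x0.shape[0]
    dt = 1.0 / T
    xs = np.empty((T + 1, K, 2))
    xs[0] = x0
    e_reg = 0.0
    for t in range(T):
        x = xs[t]
        for i in range(K):
            vx = 0.0
            vy = 0.0
            for j in range(K):
                dx = x[i, 0] - x[j, 0]
                dy = x[i, 1] - x[j, 1]
                g = np.exp(-(dx * dx + dy * dy) / s2)
                vx += g * alpha[t, j, 0]
                vy += g * alpha[t, j, 1]
            e_reg += dt * (alpha[t, i, 0] * vx + alpha[t, i, 1] * vy)
            xs[t + 1, i, 0] = x[i, 0] + dt * vx
            xs[t + 1, i, 1] = x[i, 1] + dt * vy
    return xs, e_reg


@_njit(cache=True, fastmath=True)
def _nb_segments(p):
    K = p.shape[0]
    c = np.empty((K, 2))
    tau = np.empty((K, 2))
    for i in range(K):
        j = (i + 1) % K
        c[i, 0] = 0.5 * (p[i, 0] + p[j, 0])
        c[i, 1] = 0.5 * (p[i, 1] + p[j, 1])
        tau[i, 0] = p[j, 0] - p[i, 0]
        tau[i, 1] = p[j, 1] - p[i, 1]
    return c, tau


@_njit(cache=True, fastmath=True)
def _nb_mismatch(p, cb, tb, sw2, norm_b):
    c, tau = _nb_segments(p)
    K = c.shape[0]
    L = cb.shape[0]
    s_aa = 0.0
    for i in range(K):
        for j in range(K):
            dx = c[i, 0] - c[j, 0]
            dy = c[i, 1] - c[j, 1]
            s_aa += (tau[i, 0] * tau[j, 0] + tau[i, 1] * tau[j, 1]) * np.exp(-(dx * dx + dy * dy) / sw2)
    s_ab = 0.0
    for i in range(K):
        for j in range(L):
            dx = c[i, 0] - cb[j, 0]
            dy = c[i, 1] - cb[j, 1]
            s_ab += (tau[i, 0] * tb[j, 0] + tau[i, 1] * tb[j, 1]) * np.exp(-(dx * dx + dy * dy) / sw2)
    m = s_aa - 2.0 * s_ab + norm_b
    return m if m > 0.0 else 0.0


@_njit(cache=True, fastmath=True)
def _nb_energy_only(x0, alpha, cb, tb, s2, sw2, lam, norm_b):
    xs, e_reg = _nb_forward(x0, alpha, s2)
    m = _nb_mismatch(xs[-1], cb, tb, sw2, norm_b)
    return e_reg + lam * m, m


@_njit(cache=True, fastmath=True)
def _nb_mismatch_grad(p, cb, tb, sw2, norm_b):
    c, tau = _nb_segments(p)
    K = c.shape[0]
    L = cb.shape[0]
    tau_bar = np.zeros((K, 2))
    c_bar = np.zeros((K, 2))
    s_aa = 0.0
    for i in range(K):
        for j in range(K):
            dx = c[i, 0] - c[j, 0]
            dy = c[i, 1] - c[j, 1]
            kk = np.exp(-(dx * dx + dy * dy) / sw2)
            tt = tau[i, 0] * tau[j, 0] + tau[i, 1] * tau[j, 1]
            s_aa += tt * kk
            tau_bar[i, 0] += 2.0 * kk * tau[j, 0]
            tau_bar[i, 1] += 2.0 * kk * tau[j, 1]
            c_bar[i, 0] += (-4.0 / sw2) * tt * kk * dx
            c_bar[i, 1] += (-4.0 / sw2) * tt * kk * dy
    s_ab = 0.0
    for i in range(K):
        for j in range(L):
            dx = c[i, 0] - cb[j, 0]
            dy = c[i, 1] - cb[j, 1]
            kk = np.exp(-(dx * dx + dy * dy) / sw2)
            tt = tau[i, 0] * tb[j, 0] + tau[i, 1] * tb[j, 1]
            s_ab += tt * kk
            tau_bar[i, 0] -= 2.0 * kk * tb[j, 0]
            tau_bar[i, 1] -= 2.0 * kk * tb[j, 1]
            c_bar[i, 0] -= (-4.0 / sw2) * tt * kk * dx
            c_bar[i, 1] -= (-4.0 / sw2) * tt * kk * dy
    p_bar = np.empty((K, 2))
    for i in range(K):
        im = (i - 1) % K
        p_bar[i, 0] = 0.5 * (c_bar[i, 0] + c_bar[im, 0]) + (tau_bar[im, 0] - tau_bar[i, 0])
        p_bar[i, 1] = 0.5 * (c_bar[i, 1] + c_bar[im, 1]) + (tau_bar[im, 1] - tau_bar[i, 1])
    return s_aa - 2.0 * s_ab + norm_b, p_bar


@_njit(cache=True, fastmath=True)
def _nb_energy_grad(x0, alpha, cb, tb, s2, sw2, lam, norm_b):
    T = alpha.shape[0]
    K = x0.shape[0]
    dt = 1.0 / T
    xs, e_reg = _nb_forward(x0, alpha, s2)
    mism, p_bar = _nb_mismatch_grad(xs[-1], cb, tb, sw2, norm_b)
    energy = e_reg + lam * mism
    grad = np.empty((T, K, 2))
    precond = np.empty((T, K, 2))
    xbar = lam * p_bar
    for t in range(T - 1, -1, -1):
        x = xs[t]
        newbar = np.empty((K, 2))
        for k in range(K):
            gx = 0.0
            gy = 0.0
            accx = 0.0
            accy = 0.0
            for j in range(K):
                dx = x[k, 0] - x[j, 0]
                dy = x[k, 1] - x[j, 1]
                g = np.exp(-(dx * dx + dy * dy) / s2)
                b0 = 2.0 * alpha[t, j, 0] + xbar[j, 0]
                b1 = 2.0 * alpha[t, j, 1] + xbar[j, 1]
                gx += g * b0
                gy += g * b1
                inner = (xbar[k, 0] * alpha[t, j, 0] + xbar[k, 1] * alpha[t, j, 1]
                         + alpha[t, k, 0] * xbar[j, 0] + alpha[t, k, 1] * xbar[j, 1]
                         + 2.0 * (alpha[t, k, 0] * alpha[t, j, 0] + alpha[t, k, 1] * alpha[t, j, 1]))
                m = g * inner
                accx += m * dx
                accy += m * dy
            grad[t, k, 0] = dt * gx
            grad[t, k, 1] = dt * gy
            precond[t, k, 0] = dt * (2.0 * alpha[t, k, 0] + xbar[k, 0])
            precond[t, k, 1] = dt * (2.0 * alpha[t, k, 1] + xbar[k, 1])
            newbar[k, 0] = xbar[k, 0] - (2.0 * dt / s2) * accx
            newbar[k, 1] = xbar[k, 1] - (2.0 * dt / s2) * accy
        xbar = newbar
    return energy, grad, precond, mism


def _make_objective(x0, target, sigma_v, sigma_w, lam):
    """Closures (energy_only, energy_and_grad) over a fixed problem."""
    s2, sw2 = sigma_v ** 2, sigma_w ** 2
    if _HAVE_NUMBA:
        cb, tb = _segments(np.ascontiguousarray(target))
        norm_b = currents_norm_sq(target, sigma_w)
        x0c = np.ascontiguousarray(x0)

        def e_only(alpha):
            return _nb_energy_only(x0c, alpha, cb, tb, s2, sw2, lam, norm_b)

        def e_grad(alpha):
            return _nb_energy_grad(x0c, alpha, cb, tb, s2, sw2, lam, norm_b)
    else:
        def e_only(alpha):
            return _energy_only(x0, alpha, target, sigma_v, sigma_w, lam)

        def e_grad(alpha):
            return _energy_and_grad(x0, alpha, target, sigma_v, sigma_w, lam)
    return e_only, e_grad


def integrate_flow_and_jacobian(v_fn, grad_fn, points: np.ndarray, n_steps: int):
    """Flow points and their ambient Jacobians under a velocity field.

    ``v_fn(t, x) -> (N, 2)`` and ``grad_fn(t, x) -> (N, 2, 2)`` give the
    field and its spatial gradient at time t in [0, 1); explicit Euler with
    ``n_steps`` steps updates D by D <- (I + dt grad v) D from D(0) = I.
    Generic so tests can inject closed-form fields.
    """
    x = np.asarray(points, dtype=float).copy()
    n = len(x)
    D = np.tile(np.eye(2), (n, 1, 1))
    dt = 1.0 / n_steps
    for step in range(n_steps):
        t = step * dt
        dv = grad_fn(t, x)
        v = v_fn(t, x)
        D = (np.tile(np.eye(2), (n, 1, 1)) + dt * dv) @ D
        x = x + dt * v
    return x, D


def _kernel_velocity_and_grad(control: np.ndarray, alpha_t: np.ndarray,
                              query: np.ndarray, sigma_v: float):
    s2 = sigma_v ** 2
    diff = query[:, None, :] - control[None, :, :]
    G = np.exp(-(diff ** 2).sum(-1) / s2)
    v = G @ alpha_t
    dv = (-2.0 / s2) * np.einsum("ij,ja,ijb->iab", G, alpha_t, diff)
    return v, dv


def propagate_jacobian(trajectory, alpha: np.ndarray, points: np.ndarray,
                       sigma_v: float) -> tuple:
    """Integrate the ambient Jacobian along a completed flow.

    ``trajectory`` holds the control points x(t) for t = 0..T produced by the
    same Euler scheme; the velocity gradient is analytic from the Gaussian
    kernel.  Returns (jacobians (K, 2, 2), markers det D).
    """
    T = alpha.shape[0]
    x = np.asarray(points, dtype=float).copy()
    n = len(x)
    D = np.tile(np.eye(2), (n, 1, 1))
    dt = 1.0 / T
    for t in range(T):
        v, dv = _kernel_velocity_and_grad(trajectory[t], alpha[t], x, sigma_v)
        D = (np.tile(np.eye(2), (n, 1, 1)) + dt * dv) @ D
        x = x + dt * v
    markers = np.linalg.det(D)
    if np.any(markers <= 0):
        raise RuntimeError(
            "non-positive deformation marker: increase n_timesteps or use a "
            "larger sigma_V relative to the deformation scale"
        )
    return D, markers


def lddmm_match(template, target_points: np.ndarray,
                cfg: RegistrationConfig | None = None,
                rigid: RigidTransform | None = None,
                subject_id: str = "") -> RegistrationResult:
    """Match the template curve onto an (aligned) target curve.

    ``template`` is a TemplateCurve or an (K, 2) array; ``target_points``
    should already be rigidly aligned.  Returns the full registration record
    including per-point Jacobians and markers.
    """
    import dataclasses

    x0 = template.points if isinstance(template, TemplateCurve) else np.asarray(template, dtype=float)
    target = np.asarray(target_points, dtype=float)
    cfg = cfg or RegistrationConfig()
    lam_given = cfg.lambda_match
    cfg = cfg.resolved(x0, 1.0)  # fills the kernel widths
    if lam_given is None:
        m0 = currents_mismatch(x0, target, cfg.sigma_W)
        lam = cfg.lambda_scale / m0 if m0 > 1e-12 else 1.0
        cfg = dataclasses.replace(cfg, lambda_match=lam)

    T = cfg.n_timesteps
    alpha = np.zeros((T, len(x0), 2))
    e_only, e_grad = _make_objective(x0, target, cfg.sigma_V, cfg.sigma_W,
                                     cfg.lambda_match)
    energy, grad, precond, mismatch = e_grad(alpha)
    if not np.isfinite(energy):
        raise FloatingPointError("non-finite registration energy at initialization")

    step = 1.0 / (float(np.sqrt(np.sum(precond ** 2))) + 1e-12)
    trace = [energy]
    n_small = 0
    it = 0
    converged = False
    for it in range(1, cfg.max_iters + 1):
        slope = float(np.sum(grad * precond))  # = |grad|^2 in the RKHS metric
        if slope <= 1e-12 * max(1.0, abs(energy)):
            converged = True
            break
        accepted = False
        for _ in range(40):
            cand = alpha - step * precond
            e_new, mm_new = e_only(cand)
            if np.isfinite(e_new) and e_new <= energy - 1e-4 * step * slope:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # no admissible descent step: numerical floor
            break
        rel_drop = (energy - e_new) / max(abs(energy), 1.0)
        alpha, energy, mismatch = cand, e_new, mm_new
        _, grad, precond, _ = e_grad(alpha)
        trace.append(energy)
        step *= 1.5
        if rel_drop < cfg.rel_tol:
            n_small += 1
            if n_small >= 5:
                converged = True
                break
        else:
            n_small = 0
    if not converged and it >= cfg.max_iters:
        log.warning("registration for %s hit max_iters=%d without convergence",
                    subject_id or "<target>", cfg.max_iters)

    xs, _, _ = _flow_forward(x0, alpha, cfg.sigma_V)
    jac, markers = propagate_jacobian(xs, alpha, x0, cfg.sigma_V)
    return RegistrationResult(
        rigid=rigid if rigid is not None else RigidTransform(0.0, np.zeros(2)),
        momenta=alpha,
        deformed_template=xs[-1],
        jacobians=jac,
        markers=markers,
        final_energy=float(energy),
        matching_residual=float(mismatch),
        iterations=it,
        converged=converged,
        config=cfg,
        energy_trace=np.asarray(trace),
        subject_id=subject_id,
    )


def register_curve(curve, template: TemplateCurve,
                   cfg: RegistrationConfig | None = None) -> RegistrationResult:
    """Full single-subject registration: resample, rigid align, LDDMM match."""
    from .template import resample_closed_curve

    cfg = cfg or RegistrationConfig()
    pts, _ = resample_closed_curve(curve, template.k)
    if cfg.use_rigid:
        rigid, aligned = rigid_align(pts, template.points, cfg.rigid_max_iters)
    else:
        rigid, aligned = RigidTransform(0.0, np.zeros(2)), pts
    res = lddmm_match(template, aligned, cfg, rigid=rigid, subject_id=curve.subject_id)
    return res


@dataclass
class MarkerTable:
    """Subjects x template-points deformation markers plus per-subject areas."""

    subject_ids: list
    markers: np.ndarray            # (S, K)
    regions: np.ndarray            # (K,) template point labels
    areas_mm2: np.ndarray          # (S,) target curve areas (pixel dialect)
    template_area_mm2: float
    meta: dict = field(default_factory=dict)

    def to_long_frame(self):
        import pandas as pd
        from .curves import REGION_NAMES

        s, k = self.markers.shape
        return pd.DataFrame({
            "subject_id": np.repeat(self.subject_ids, k),
            "point_index": np.tile(np.arange(k), s),
            "region": np.tile([REGION_NAMES[int(r)] for r in self.regions], s),
            "marker": self.markers.ravel(),
        })


def register_cohort(curves, template: TemplateCurve,
                    cfg: RegistrationConfig | None = None,
                    n_jobs: int = 1) -> tuple:
    """Register every cohort curve to the template.

    Returns (MarkerTable, list of RegistrationResult).  Parallelizes over
    subjects (each registration is deterministic, so results do not depend
    on the worker count).
    """
    from joblib import Parallel, delayed

    curves = list(curves)
    if n_jobs == 1:
        results = [register_curve(c, template, cfg) for c in curves]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(register_curve)(c, template, cfg) for c in curves)
    table = MarkerTable(
        subject_ids=[c.subject_id for c in curves],
        markers=np.stack([r.markers for r in results]),
        regions=template.labels.copy(),
        areas_mm2=np.array([c.area_mm2 for c in curves]),
        template_area_mm2=template.area_mm2,
        meta={"n_converged": int(sum(r.converged for r in results))},
    )
    return table, results
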