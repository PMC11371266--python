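"""Nested forward-backward solvers for re-weighted L1-analysis reconstruction.

The reconstruction schemes minimize, per outer iteration ``k``,

    x_{k+1} = argmin_{x in X}  1/2 ||H x - y||^2 + lam * ||L_k x||_1,

where ``L_k = [diag(mask_c(x_k)) W_c]_c`` is the mask-weighted analysis
operator.  Three nested loops are involved:

* outer loop (``mmr_reconstruct`` / ``safi_reconstruct``): refreshes the mask
  from the current reconstruction; starts from the unweighted operator;
* FBS loop (``fbs_solve``): accelerated proximal gradient with step
  ``alpha = 1/||H||_2^2`` and the inertial rule ``t_{k+1} = (k+5)/3``; one
  step suffices (and is exact) for denoising, where ``H`` is the identity;
* dual prox loop (``prox_weighted_l1``): the proximal map of
  ``gamma ||L . ||_1`` over X evaluated by accelerated projected gradient on
  its dual — the iterates live in the analysis domain and are kept in the box
  ``||u||_inf <= gamma`` by clipping.

Early stopping uses the iteration-dependent tolerance schedules of
``ToleranceSchedule``; a negative tolerance (the training sentinel) disables
early stopping so a fixed number of steps is unrolled.  All functions accept
taped variables, so the training module can differentiate through the whole
computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import _ad
from ._ad import val
from .operators import AnalysisOperator, ForwardModel
from .potentials import eval_psi

__all__ = [
    "ToleranceSchedule",
    "SolverConfig",
    "SolveTrace",
    "eval_tolerance",
    "prox_weighted_l1",
    "fbs_solve",
    "objective_mmr",
    "objective_weighted_l1",
    "majorization_value",
    "mmr_reconstruct",
    "safi_reconstruct",
]


# ---------------------------------------------------------------------------
# tolerance schedules
# ---------------------------------------------------------------------------

def _outer_tol(k_out: int) -> float:
    return 1e-3 * 0.01 ** (k_out / 5.0) if k_out <= 5 else 1e-5


@dataclass
class ToleranceSchedule:
    """Iteration-dependent inner tolerances.

    ``denoising``: the prox tolerance tightens from 1e-3 * 0.01^{k_out/5}
    down to 1e-5 (the FBS loop runs a single step, so it has no tolerance).
    ``general``: the FBS tolerance follows the same law in ``k_out`` and the
    prox tolerance is ``3 eps_FBS (1/9)^{k_FBS/50}``, saturating at
    ``eps_FBS/3``.  ``off`` returns the sentinel -1, which never triggers an
    early stop, so every loop runs its full iteration budget (training mode).
    """

    mode: str = "denoising"

    def __post_init__(self):
        if self.mode not in ("denoising", "general", "off"):
            raise ValueError(f"unknown tolerance mode {self.mode!r}")

    def fbs_tol(self, k_out: int) -> float:
        if self.mode == "general":
            return _outer_tol(k_out)
        return -1.0

    def prox_tol(self, k_out: int, k_fbs: int = 1) -> float:
        if self.mode == "off":
            return -1.0
        if self.mode == "denoising":
            return _outer_tol(k_out)
        eps_fbs = _outer_tol(k_out)
        if k_fbs <= 50:
            return 3.0 * eps_fbs * (1.0 / 9.0) ** (k_fbs / 50.0)
        return eps_fbs / 3.0


def eval_tolerance(s: ToleranceSchedule, k_out: int, k_fbs: int = 1) -> float:
    """Prox tolerance for the given outer/FBS iteration counters."""
    if k_out < 1:
        raise ValueError("outer iteration counter starts at 1")
    return s.prox_tol(k_out, k_fbs)


# ---------------------------------------------------------------------------
# configuration and traces
# ---------------------------------------------------------------------------

@dataclass
class SolverConfig:
    """Knobs of the nested solver.

    ``K_FBS = None`` resolves to 1 for an identity forward model (one FBS
    step is exact there) and 1000 otherwise; ``schedule = None`` resolves to
    the matching tolerance mode.  ``X`` is the constraint set: ``("all_space",)``
    or ``("box", lo, hi)``.
    """

    lam: float = 1e-4
    K_out: int = 10
    K_FBS: Optional[int] = None
    K_prox: int = 500
    eps_out: float = 1e-6
    schedule: Optional[ToleranceSchedule] = None
    X: tuple = ("all_space",)
    l_sq_norm: Optional[float] = None  # override for ||L||_2^2 (training)
    record_masks: bool = False

    def resolved(self, H: ForwardModel) -> "SolverConfig":
        cfg = SolverConfig(**self.__dict__)
        if cfg.K_FBS is None:
            cfg.K_FBS = 1 if H.is_identity else 1000
        if cfg.schedule is None:
            cfg.schedule = ToleranceSchedule("denoising" if H.is_identity else "general")
        return cfg


@dataclass
class SolveTrace:
    """Per-outer-iteration record of the reconstruction path."""

    e: list = dc_field(default_factory=list)            # relative errors e_k
    f: list = dc_field(default_factory=list)            # objective values
    x_norm: list = dc_field(default_factory=list)       # ||x_{k+1}||_2
    inner_iterations: list = dc_field(default_factory=list)
    masks: list = dc_field(default_factory=list)

    def as_dict(self) -> dict:
        return {"e": [float(v) for v in self.e],
                "f": [float(v) for v in self.f],
                "x_norm": [float(v) for v in self.x_norm],
                "inner_iterations": [int(v) for v in self.inner_iterations]}


def _make_proj(X):
    if X[0] == "all_space":
        return lambda x: x
    if X[0] == "box":
        lo, hi = X[1], X[2]
        return lambda x: _ad.clip(x, lo, hi)
    raise ValueError(f"unknown constraint set {X!r}")


def _rel_change(x_new, x_old) -> float:
    dn = float(np.linalg.norm(np.ravel(val(x_new) - val(x_old))))
    n = float(np.linalg.norm(np.ravel(val(x_old))))
    return dn / n if n > 0 else dn


# ---------------------------------------------------------------------------
# dual evaluation of the weighted-L1 prox
# ---------------------------------------------------------------------------

def prox_weighted_l1(L, z, gamma, X=("all_space",), eps: float = -1.0,
                     K_prox: int = 500, l_sq_norm: Optional[float] = None,
                     u_init=None):
    """``argmin_{w in X} 1/2 ||w - z||^2 + gamma ||L w||_1`` via the dual.

    Accelerated projected gradient on the dual variable ``u`` (analysis
    domain), initialized at ``L z`` (or at ``u_init``, used to carry the
    dual variable across consecutive FBS steps), with the primal recovered
    as ``Proj_X(z - L^T u)``.  Returns ``(x, u, iterations_used)``.
    """
    if float(val(gamma)) < 0:
        raise ValueError("gamma must be nonnegative")
    proj = _make_proj(X)
    if float(val(gamma)) == 0.0:
        return proj(z), None, 0
    if l_sq_norm is None:
        l_sq_norm = L.sq_norm(val(z).shape[-2:]) if hasattr(L, "sq_norm") else None
    if l_sq_norm is None or l_sq_norm <= 0:
        raise ValueError("need a positive squared spectral norm for the dual step")
    alpha = 1.0 / float(l_sq_norm)

    u = L.apply(z) if u_init is None else u_init
    v = u
    x_prev = proj(z - L.adjoint(u))
    t = 1.0
    used = 0
    for k in range(1, K_prox + 1):
        used = k
        g = L.apply(proj(L.adjoint(v) - z))
        u_new = _ad.clip(v - alpha * g, -gamma, gamma)
        t_new = (k + 5) / 3.0
        v = u_new + ((t - 1.0) / t_new) * (u_new - u)
        x = proj(z - L.adjoint(u_new))
        u, t = u_new, t_new
        if not np.all(np.isfinite(val(x))):
            raise FloatingPointError("non-finite iterate in the dual prox")
        dn = float(np.linalg.norm(np.ravel(val(x) - val(x_prev))))
        if dn < eps * float(np.linalg.norm(np.ravel(val(x_prev)))):
            x_prev = x
            break
        x_prev = x
    return x_prev, u, used


# ---------------------------------------------------------------------------
# forward-backward splitting on the reconstruction variable
# ---------------------------------------------------------------------------

def fbs_solve(H: ForwardModel, y, L, lam, x_init, config: SolverConfig,
              k_out: int = 1):
    """Accelerated FBS for ``min_x 1/2||Hx-y||^2 + lam ||L x||_1`` over X.

    Step size ``1/||H||_2^2``; each step evaluates the weighted-L1 prox at the
    gradient point.  Returns ``(x, info)`` with the iteration counts used.
    """
    cfg = config.resolved(H)
    if float(val(lam)) < 0:
        raise ValueError("lam must be nonnegative")
    alpha = 1.0 / H.sq_spectral_norm
    l_sq = cfg.l_sq_norm
    if l_sq is None and float(val(lam)) > 0:
        l_sq = L.sq_norm(H.shape)
    eps_fbs = cfg.schedule.fbs_tol(k_out)

    x = x_init
    xt = x_init
    t = 1.0
    prox_iters = 0
    used = 0
    u_carry = None  # dual variable carried across FBS steps (H != Id only)
    for k in range(1, cfg.K_FBS + 1):
        used = k
        grad = H.adjoint(H.apply(xt) - y)
        z = xt - alpha * grad
        x_new, u_carry, it = prox_weighted_l1(L, z, alpha * lam, cfg.X,
                                              eps=cfg.schedule.prox_tol(k_out, k),
                                              K_prox=cfg.K_prox, l_sq_norm=l_sq,
                                              u_init=u_carry)
        prox_iters += it
        t_new = (k + 5) / 3.0
        xt = x_new + ((t - 1.0) / t_new) * (x_new - x)
        e = _rel_change(x_new, x)
        x, t = x_new, t_new
        if not np.all(np.isfinite(val(x))):
            raise FloatingPointError("non-finite FBS iterate")
        if e < eps_fbs:
            break
    return x, {"fbs_iterations": used, "prox_iterations": prox_iters}


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def _is_batched(x, H: ForwardModel) -> bool:
    return np.asarray(val(x)).ndim == 3


def _per_sample(arr: np.ndarray) -> np.ndarray:
    """Sum all but the leading (batch) axis."""
    return arr.reshape(arr.shape[0], -1).sum(axis=1)


def _fidelity(x, H: ForwardModel, y, batched: bool = False):
    r = np.asarray(H.apply(val(x))) - np.asarray(val(y))
    sq = np.real(r * np.conj(r))
    if batched:
        return 0.5 * _per_sample(sq)
    return 0.5 * float(sq.sum())


def _regularizer_mmr(xv: np.ndarray, g, batched: bool):
    wx = np.abs(np.asarray(val(g.W.apply(xv))))
    ba = np.asarray(val(g.B.apply(wx)))
    per_channel = [eval_psi(prof, ba[..., c, :, :]) for c, prof in enumerate(g.profiles)]
    stacked = np.stack(per_channel, axis=-3)
    if batched:
        return _per_sample(stacked)
    return float(stacked.sum())


def objective_mmr(x, H: ForwardModel, y, lam, g):
    """``f(x) = 1/2||Hx-y||^2 + lam * sum_c <1, psi_c(B_c |W_c x|)>``.

    For a batch ``x`` of shape ``(B, H, W)`` (with matching ``y``) the
    per-sample objective values are returned as a length-B array.
    """
    xv = np.asarray(val(x))
    batched = _is_batched(xv, H)
    return (_fidelity(xv, H, y, batched)
            + float(val(lam)) * _regularizer_mmr(xv, g, batched))


def objective_weighted_l1(x, H: ForwardModel, y, lam, L):
    """``1/2||Hx-y||^2 + lam ||L x||_1`` for a fixed analysis operator."""
    xv = np.asarray(val(x))
    batched = _is_batched(xv, H)
    absLx = np.abs(np.asarray(val(L.apply(xv))))
    reg = _per_sample(absLx) if batched else float(absLx.sum())
    return _fidelity(xv, H, y, batched) + float(val(lam)) * reg


def majorization_value(x, x_k, H: ForwardModel, y, lam, g):
    """Surrogate ``g(x, x_k)``: the objective with the concave part linearized
    at ``x_k``.  Upper-bounds ``objective_mmr(x)`` and is tight at ``x = x_k``.
    Batched like :func:`objective_mmr`.
    """
    lamv = float(val(lam))
    xv, xkv = np.asarray(val(x)), np.asarray(val(x_k))
    batched = _is_batched(xv, H)
    wx = np.abs(np.asarray(val(g.W.apply(xv))))
    wxk = np.abs(np.asarray(val(g.W.apply(xkv))))
    mask = g.mask(xkv).detach()
    const = _regularizer_mmr(xkv, g, batched)
    lin = mask * (wx - wxk)
    lin = _per_sample(lin) if batched else float(lin.sum())
    return _fidelity(xv, H, y, batched) + lamv * const + lamv * lin


# ---------------------------------------------------------------------------
# outer refinement loops
# ---------------------------------------------------------------------------

def _zeros_like_domain(H: ForwardModel, y):
    yv = np.asarray(val(y))
    if H.is_identity:
        return np.zeros(yv.shape)
    return np.zeros(yv.shape[:-2] + H.shape) if yv.ndim > 2 else np.zeros(H.shape)


def _reconstruct(H: ForwardModel, y, gen, config: SolverConfig, x_init=None,
                 compute_objective: bool = True):
    cfg = config.resolved(H)
    if float(val(cfg.lam)) < 0:
        raise ValueError("lam must be nonnegative")
    trace = SolveTrace()
    if x_init is None:
        x = _zeros_like_domain(H, y)
        mask = None  # all-ones: the first subproblem is the plain convex one
    else:
        # explicit initializations seed the first mask (robustness variants)
        x = x_init
        mask = gen.mask(x_init).values
    for k in range(1, cfg.K_out + 1):
        L = AnalysisOperator(gen.W, mask)
        x_new, info = fbs_solve(H, y, L, cfg.lam, x, cfg, k_out=k)
        e_k = _rel_change(x_new, x)
        if compute_objective:
            if gen.scheme == "mmr":
                trace.f.append(objective_mmr(x_new, H, y, cfg.lam, gen))
            else:
                trace.f.append(objective_weighted_l1(x_new, H, y, cfg.lam, L.detached()))
        trace.e.append(e_k)
        trace.x_norm.append(float(np.linalg.norm(np.ravel(val(x_new)))))
        trace.inner_iterations.append(info["prox_iterations"])
        mask = gen.mask(x_new).values
        if cfg.record_masks:
            trace.masks.append(np.array(val(mask)))
        x = x_new
        if e_k < cfg.eps_out:
            break
    return x, trace


def mmr_reconstruct(H: ForwardModel, y, g, config: SolverConfig, x_init=None,
                    compute_objective: bool = True):
    """Majorization-minimization reconstruction (descending objective).

    Starts from zero (or ``x_init``) with the unweighted analysis operator
    and alternates convex re-weighted solves with mask refreshes.  The true
    objective recorded in the trace is non-increasing up to the inner-solver
    tolerance.
    """
    if g.scheme != "mmr":
        raise ValueError("expected an MMR mask generator")
    return _reconstruct(H, y, g, config, x_init, compute_objective)


def safi_reconstruct(H: ForwardModel, y, g, config: SolverConfig, x_init=None,
                     compute_objective: bool = True):
    """Solution-adaptive fixed-point reconstruction.

    Same loop with the network mask generator; for invertible ``H`` every
    iterate after the first lies in the ball of radius ``2||y||/sigma_min``.
    """
    if g.scheme != "safi":
        raise ValueError("expected a SAFI mask generator")
    return _reconstruct(H, y, g, config, x_init, compute_objective)


def l1_reconstruct(H: ForwardModel, y, W, lam, config: Optional[SolverConfig] = None,
                   x_init=None):
    """Plain (unweighted) L1-analysis reconstruction with the filters ``W``.

    This is the non-adaptive convex baseline: a single solve of the problem
    with an all-ones mask, run at the tightest tolerance of the schedule.
    """
    cfg = (config or SolverConfig()).resolved(H)
    cfg.lam = lam
    L = AnalysisOperator(W, None)
    x0 = _zeros_like_domain(H, y) if x_init is None else x_init
    x, info = fbs_solve(H, y, L, lam, x0, cfg, k_out=max(6, cfg.K_out))
    trace = SolveTrace(e=[_rel_change(x, x0)],
                       f=[objective_weighted_l1(x, H, y, lam, L)],
                       inner_iterations=[info["prox_iterations"]])
    return x, trace


def reconstruct(H: ForwardModel, y, gen, config: SolverConfig, scheme: Optional[str] = None,
                x_init=None, compute_objective: bool = True):
    """Dispatch on scheme: ``mmr``/``safi`` refinement loops or the ``l1`` baseline."""
    scheme = scheme or gen.scheme
    if scheme == "l1":
        return l1_reconstruct(H, y, gen.W, config.lam, config, x_init)
    if scheme == "mmr":
        return mmr_reconstruct(H, y, gen, config, x_init, compute_objective)
    if scheme == "safi":
        return safi_reconstruct(H, y, gen, config, x_init, compute_objective)
    raise ValueError(f"unknown scheme {scheme!r}")
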