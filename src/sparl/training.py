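"""Unrolled training of the mask-generator denoisers and lambda fine-tuning.

The denoiser ``D^{n1,1,n3}(y)`` is the reconstruction scheme run for ``n1``
outer refinements with a single FBS step each and ``n3`` dual-prox steps,
all early stopping disabled.  Training minimizes the empirical risk

    sum_m 1/2 || D^{n1,1,n3}(x_m + noise) - x_m ||^2

with the (n1, n3) pair drawn uniformly at random per batch — randomizing the
unrolling depth regularizes the model toward fixed-point behaviour.
Gradients flow through every unrolled step via the tape in ``sparl._ad``;
the dual step sizes ``1/||L||^2`` are treated as constants of the graph.
Constraints (zero-mean W kernels, simplex B kernels, non-increasing profile
knots starting at 1, positive scales via magnitude) are re-established by
projection after every optimizer step.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _ad
from ._ad import Var, val
from .masks import MMRMaskGenerator, SAFIMaskGenerator
from .metrics import psnr
from .operators import IdentityModel, ForwardModel
from .solvers import SolverConfig, ToleranceSchedule, reconstruct, _reconstruct
from .synthetic import PatchSet

__all__ = [
    "TrainingConfig",
    "ModelCheckpoint",
    "unrolled_denoise",
    "training_loss",
    "train_denoiser",
    "tune_lambda",
    "make_generator",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the unrolled training run.

    The defaults are the full-scale denoising settings (64 channels, two
    7x7 layers, 40x40 patches, 40 epochs with learning-rate drops at epochs
    5 and 10); :meth:`reduced` gives the desk-scale configuration used by the
    test suite (8 channels, one 5x5 layer, 16x16 patches).
    """

    scheme: str = "mmr"
    sigma: float = 25.0 / 255.0
    patch_size: int = 40
    n_patches: int = 238400
    batch_size: int = 128
    lr: float = 1e-3
    epochs: int = 40
    lr_drop_epochs: tuple = (5, 10)
    lr_drop_factor: float = 0.1
    n1_range: tuple = (4, 5, 6)
    n3_range: tuple = tuple(range(1, 11))
    n_channels: int = 64
    kernel_size: int = 7
    n_layers: int = 2
    lam_init: float = 1e-4
    n_val: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for name in ("patch_size", "batch_size", "epochs", "n_channels", "kernel_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def reduced(cls, **overrides) -> "TrainingConfig":
        base = dict(patch_size=16, n_patches=2000, batch_size=128, epochs=2,
                    n_channels=8, kernel_size=5, n_layers=1, n_val=32)
        base.update(overrides)
        return cls(**base)


@dataclass
class ModelCheckpoint:
    """Trained generator parameters plus training metadata."""

    gen: object                    # MMRMaskGenerator or SAFIMaskGenerator
    scheme: str
    config: TrainingConfig
    history: dict = field(default_factory=dict)

    @property
    def lam(self) -> float:
        return float(val(self.gen.lam))

    def save(self, path) -> None:
        from .io import save_checkpoint

        meta = {"sigma": self.config.sigma, "epochs": self.config.epochs,
                "best_epoch": self.history.get("best_epoch"),
                "val_psnr": self.history.get("best_val_psnr")}
        save_checkpoint(path, self.gen, meta)


def make_generator(config: TrainingConfig, seed: Optional[int] = None):
    """Fresh generator at the canonical initialization for the given scheme."""
    seed = config.seed if seed is None else seed
    kw = dict(n_channels=config.n_channels, kernel_size=config.kernel_size,
              n_layers=config.n_layers, lam=config.lam_init, seed=seed)
    if config.scheme == "mmr":
        return MMRMaskGenerator.random(**kw)
    if config.scheme == "safi":
        return SAFIMaskGenerator.random(**kw)
    raise ValueError(f"unknown scheme {config.scheme!r}")


# ---------------------------------------------------------------------------
# taped parameters
# ---------------------------------------------------------------------------

def _wrap_parameters(gen):
    """Replace every learnable array of ``gen`` with a taped Var, in place.

    Returns the ordered dict name -> Var used by the optimizer.
    """
    params: dict = {}
    conv_names = ("W", "B") if gen.scheme == "mmr" else ("W", "Wt", "Bt", "Bh")
    for name in conv_names:
        op = getattr(gen, name)
        for i in range(len(op.kernels)):
            v = Var(np.array(val(op.kernels[i])))
            op.kernels[i] = v
            params[f"{name}_k{i}"] = v
    if gen.scheme == "mmr":
        for name in ("sigma_knots", "r"):
            v = Var(np.array(val(getattr(gen, name))))
            setattr(gen, name, v)
            params[name] = v
    else:
        for name in ("phi1", "phi2", "phi3"):
            v = Var(np.array(val(getattr(gen, name))))
            setattr(gen, name, v)
            params[name] = v
    v = Var(np.asarray(float(val(gen.lam))))
    gen.lam = v
    params["lam"] = v
    return params


def _detached_copy(gen):
    g = copy.copy(gen)
    conv_names = ("W", "B") if gen.scheme == "mmr" else ("W", "Wt", "Bt", "Bh")
    for name in conv_names:
        setattr(g, name, getattr(gen, name).detached())
    if gen.scheme == "mmr":
        g.sigma_knots = np.array(val(gen.sigma_knots))
        g.r = np.array(val(gen.r))
    else:
        g.phi1 = np.array(val(gen.phi1))
        g.phi2 = np.array(val(gen.phi2))
        g.phi3 = np.array(val(gen.phi3))
    g.lam = float(val(gen.lam))
    return g


# ---------------------------------------------------------------------------
# unrolled forward pass and loss
# ---------------------------------------------------------------------------

def unrolled_denoise(gen, y, n1: int, n3: int, l_sq_norm: Optional[float] = None):
    """``D^{n1,1,n3}(y)``: n1 outer refinements, one FBS step, n3 dual steps.

    Deterministic given the parameters; differentiable with respect to every
    generator parameter when they are taped.  ``y`` is an image ``(H, W)`` or
    a batch ``(B, H, W)``.  ``l_sq_norm`` fixes the dual step size
    ``1/||L||^2``; by default it is bounded by ``||W||^2`` (masks never
    exceed 1), estimated once per call and treated as a constant.
    """
    if n1 < 1 or n3 < 1:
        raise ValueError("n1 and n3 must be >= 1")
    H = IdentityModel(val(y).shape[-2:])
    if l_sq_norm is None:
        l_sq_norm = gen.W.detached().sq_norm(H.shape)
    cfg = SolverConfig(lam=gen.lam, K_out=n1, K_FBS=1, K_prox=n3,
                       eps_out=-1.0, schedule=ToleranceSchedule("off"),
                       l_sq_norm=l_sq_norm)
    x, _ = _reconstruct(H, y, gen, cfg, compute_objective=False)
    return x


def training_loss(gen, clean, noisy, n1: int, n3: int,
                  l_sq_norm: Optional[float] = None):
    """Empirical risk ``1/2 sum_m ||D(noisy_m) - clean_m||^2`` of one batch."""
    if val(clean).size == 0:
        raise ValueError("empty batch")
    d = unrolled_denoise(gen, noisy, n1, n3, l_sq_norm=l_sq_norm)
    diff = d - np.asarray(clean, dtype=np.float64)
    return 0.5 * _ad.asum(diff * diff)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment stochastic gradient descent with standard defaults."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.value[...] = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _project_all(gen) -> None:
    gen.project()
    lam = val(gen.lam)
    if lam < 1e-12:  # keep the learned regularization strength positive
        if isinstance(gen.lam, Var):
            gen.lam.value[...] = 1e-12
        else:
            gen.lam = 1e-12


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train_denoiser(patch_source, config: TrainingConfig,
                   max_steps: Optional[int] = None) -> ModelCheckpoint:
    """Train a mask-generator denoiser on noisy/clean patch pairs.

    ``patch_source`` is a :class:`PatchSet` (noisy versions are generated
    here if absent).  Per batch a fresh ``(n1, n3)`` pair is drawn; after
    every optimizer step the kernel and profile constraints are re-projected.
    Validation PSNR (at the deepest unrolling) picks the returned epoch.
    ``max_steps`` caps the total number of optimizer steps (short runs).
    """
    rng = np.random.default_rng(config.seed)
    if isinstance(patch_source, PatchSet):
        clean = patch_source.clean
        noisy = patch_source.noisy
    else:
        clean, noisy = patch_source
    clean = np.asarray(clean, dtype=np.float64)
    if noisy is None:
        noisy = clean + config.sigma * rng.standard_normal(clean.shape)
    noisy = np.asarray(noisy, dtype=np.float64)

    n_val = min(config.n_val, len(clean) // 5)
    val_clean, val_noisy = clean[:n_val], noisy[:n_val]
    tr_clean, tr_noisy = clean[n_val:], noisy[n_val:]

    gen = make_generator(config, seed=int(rng.integers(2 ** 31)))
    params = _wrap_parameters(gen)
    opt = Adam(params, lr=config.lr)

    n1_deep, n3_deep = max(config.n1_range), max(config.n3_range)
    best = {"psnr": -np.inf, "epoch": 0, "gen": _detached_copy(gen)}
    history = {"batch_loss": [], "val_psnr": [], "lr": []}
    steps = 0
    for epoch in range(1, config.epochs + 1):
        if epoch in config.lr_drop_epochs:
            opt.lr *= config.lr_drop_factor
        order = rng.permutation(len(tr_clean))
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if idx.size == 0:
                continue
            n1 = int(rng.choice(config.n1_range))
            n3 = int(rng.choice(config.n3_range))
            # cheap upper bound on ||L||^2 for this step's dual step size:
            # short power iteration on W with an extra margin
            l_sq = 1.1 * gen.W.detached().sq_norm(
                (config.patch_size, config.patch_size), iters=30, tol=1e-3)
            opt.zero_grad()
            loss = training_loss(gen, tr_clean[idx], tr_noisy[idx], n1, n3,
                                 l_sq_norm=l_sq)
            lv = float(val(loss))
            if not np.isfinite(lv):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, step {steps} "
                    f"(n1={n1}, n3={n3}, lam={float(val(gen.lam)):.3e})")
            loss.backward()
            opt.step()
            _project_all(gen)
            history["batch_loss"].append(lv / idx.size)
            history["lr"].append(opt.lr)
            steps += 1
            if max_steps is not None and steps >= max_steps:
                break
        if n_val > 0:
            gd = _detached_copy(gen)
            den = unrolled_denoise(gd, val_noisy, n1_deep, n3_deep)
            vp = float(np.mean([psnr(den[i], val_clean[i]) for i in range(n_val)]))
        else:
            vp = -float(history["batch_loss"][-1])
        history["val_psnr"].append(vp)
        if vp > best["psnr"]:
            best = {"psnr": vp, "epoch": epoch, "gen": _detached_copy(gen)}
        if max_steps is not None and steps >= max_steps:
            break

    history["best_epoch"] = best["epoch"]
    history["best_val_psnr"] = best["psnr"]
    return ModelCheckpoint(best["gen"], config.scheme, config, history)


# ---------------------------------------------------------------------------
# regularization-strength fine-tuning
# ---------------------------------------------------------------------------

def _mean_psnr(gen, scheme, val_pairs, H: ForwardModel, lam: float,
               solver_config: Optional[SolverConfig]) -> float:
    cfg = replace(solver_config or SolverConfig(), lam=lam)
    scores = []
    for clean, y in val_pairs:
        x, _ = reconstruct(H, y, gen, cfg, scheme=scheme, compute_objective=False)
        scores.append(psnr(np.asarray(val(x)), clean))
    return float(np.mean(scores))


def tune_lambda(checkpoint, val_pairs: Sequence, H: ForwardModel,
                grid: Sequence[float], scheme: Optional[str] = None,
                solver_config: Optional[SolverConfig] = None,
                n_fine: int = 5) -> float:
    """Coarse-to-fine grid search of the regularization strength.

    Each candidate is scored by the mean validation PSNR of the full
    fixed-point reconstruction; a 5-point geometric refinement around the
    coarse argmax (between its grid neighbours) decides the returned value.
    """
    gen = checkpoint.gen if isinstance(checkpoint, ModelCheckpoint) else checkpoint
    scheme = scheme or gen.scheme
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("empty grid")
    if any(g <= 0 for g in grid):
        raise ValueError("grid values must be positive")
    scores = [_mean_psnr(gen, scheme, val_pairs, H, g, solver_config) for g in grid]
    i = int(np.argmax(scores))
    if len(grid) == 1:
        return grid[0]
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    fine = np.geomspace(lo, hi, n_fine)
    fine_scores = [_mean_psnr(gen, scheme, val_pairs, H, g, solver_config) for g in fine]
    cand = list(grid) + list(fine)
    cand_scores = scores + fine_scores
    return float(cand[int(np.argmax(cand_scores))])
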