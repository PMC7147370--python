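"""Catalogue of static and dynamic (learnable) activation functions.

Ten rectifier-family activations: the static ReLU, Leaky ReLU and ELU, and
the dynamic PReLU, SReLU, APLU and the Mexican-hat / Gaussian-hat families
MeLU, wMeLU, GaLU, sGaLU.  Every function comes with its exact forward map
and analytic gradients with respect to the input and to every learnable
parameter, so the functions can be dropped into a network trained by plain
backpropagation without autodiff.

The dynamic families are built from compactly supported piecewise-linear
basis functions ("Mexican hat" bumps and Gaussian-like bump/dip pairs)
whose centers ``alpha`` and half-widths ``lam`` are fixed in units of
``max_input``, a normalization constant (1 for images in [0,1], 255 for
[0,255]).  At their standard initialization all the dynamic functions
coincide exactly with ReLU, which is what makes them suitable drop-in
replacements inside a pretrained ReLU network.

Gradient conventions at breakpoints follow the ``x >= threshold`` branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ACTIVATION_NAMES",
    "STATIC_NAMES",
    "DYNAMIC_NAMES",
    "DEFAULT_POOL_NAMES",
    "ActivationSpec",
    "ActivationState",
    "GradResult",
    "relu",
    "leaky_relu",
    "elu",
    "prelu",
    "srelu",
    "aplu",
    "mexican_hat",
    "mexican_hat_dx",
    "gaussian_basis",
    "gaussian_basis_dx",
    "melu",
    "galu",
    "evaluate",
    "gradients",
    "gradient_check",
    "GradientCheckReport",
]

ACTIVATION_NAMES = (
    "ReLU", "LeakyReLU", "ELU", "PReLU", "SReLU",
    "APLU", "MeLU", "wMeLU", "GaLU", "sGaLU",
)
STATIC_NAMES = ("ReLU", "LeakyReLU", "ELU")
DYNAMIC_NAMES = tuple(n for n in ACTIVATION_NAMES if n not in STATIC_NAMES)
#: the nine non-ReLU functions used as the default replacement pool
DEFAULT_POOL_NAMES = tuple(n for n in ACTIVATION_NAMES if n != "ReLU")

# (k, centers alpha, half-widths lam) for the basis-function families;
# alpha/lam have length k-1 and are expressed in units of max_input.
_BASIS_PRESETS = {
    "MeLU": (4, (2.0, 1.0, 3.0), (2.0, 1.0, 1.0)),
    "wMeLU": (
        8,
        (2.0, 1.0, 3.0, 0.5, 1.5, 2.5, 3.5),
        (2.0, 1.0, 1.0, 0.5, 0.5, 0.5, 0.5),
    ),
    "GaLU": (4, (1.0, 0.5, 2.5), (1.0, 0.5, 0.5)),
    "sGaLU": (2, (1.0,), (1.0,)),
}


def _check_finite(x: np.ndarray, what: str = "input") -> np.ndarray:
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite values in {what}")
    return x


@dataclass(frozen=True)
class ActivationSpec:
    """Immutable definition of one activation function.

    Parameters are the fixed hyperparameters; the learnable parameters live
    in :class:`ActivationState`.  ``alpha`` and ``lam`` (length ``k - 1``)
    are only present for the MeLU/GaLU families.
    """

    name: str
    max_input: float = 1.0
    k: int = 0
    alpha: tuple = ()
    lam: tuple = ()
    leaky_a: float = 0.01
    elu_a: float = 1.0
    n_hinges: int = 3
    l2_penalty: float = 0.001

    def __post_init__(self):
        if self.name not in ACTIVATION_NAMES:
            raise ValueError(f"unknown activation name {self.name!r}")
        if not self.max_input > 0:
            raise ValueError("max_input must be positive")
        if self.name in _BASIS_PRESETS:
            if self.k not in (2, 4, 8):
                raise ValueError("k must be one of 2, 4, 8")
            if len(self.alpha) != self.k - 1 or len(self.lam) != self.k - 1:
                raise ValueError("alpha and lam must have length k - 1")
            if any(l <= 0 for l in self.lam):
                raise ValueError("basis half-widths must be positive")
        else:
            if self.alpha or self.lam:
                raise ValueError(f"{self.name} takes no basis parameters")
        if self.name == "APLU" and self.n_hinges < 1:
            raise ValueError("n_hinges must be a positive integer")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be nonnegative")

    @classmethod
    def create(cls, name: str, max_input: float = 1.0, **overrides) -> "ActivationSpec":
        """Build a spec with the standard settings for ``name``.

        MeLU/wMeLU/GaLU/sGaLU receive their fixed basis centers and widths;
        other hyperparameters (``leaky_a``, ``elu_a``, ``n_hinges``,
        ``l2_penalty``) can be overridden.
        """
        kw = dict(overrides)
        if name in _BASIS_PRESETS:
            k, alpha, lam = _BASIS_PRESETS[name]
            kw.setdefault("k", k)
            kw.setdefault("alpha", alpha)
            kw.setdefault("lam", lam)
        return cls(name=name, max_input=float(max_input), **kw)

    @property
    def learnable_params(self) -> tuple:
        """Names of the ActivationState fields this function learns."""
        if self.name in ("MeLU", "wMeLU", "GaLU", "sGaLU"):
            return ("c",)
        if self.name == "PReLU":
            return ("prelu_a",)
        if self.name == "SReLU":
            return ("srelu",)
        if self.name == "APLU":
            return ("aplu_a", "aplu_b")
        return ()


@dataclass
class ActivationState:
    """Learnable parameters of one activation layer.

    Per-channel parameters carry a leading channel axis of size
    ``n_channels``; SReLU's four knots are shared across the layer.
    Only the fields matching the owning spec's name are non-None.
    """

    c: Optional[np.ndarray] = None          # (C, k)   MeLU/GaLU coefficients
    prelu_a: Optional[np.ndarray] = None    # (C,)     PReLU slopes
    aplu_a: Optional[np.ndarray] = None     # (C, n)   APLU hinge slopes
    aplu_b: Optional[np.ndarray] = None     # (C, n)   APLU hinge positions
    srelu: Optional[np.ndarray] = None      # (4,)     (al, tl, ar, tr)

    @classmethod
    def initial(
        cls,
        spec: ActivationSpec,
        n_channels: int = 1,
        rng: Optional[np.random.Generator] = None,
    ) -> "ActivationState":
        """Standard initialization: every function starts out equal to ReLU.

        MeLU/GaLU coefficients, the PReLU slope and the APLU slopes start
        at 0; SReLU starts at ``(0, 0, 1, max_input)``.  APLU's hinge
        positions are drawn once, uniformly on ``[0, max_input]``, from
        ``rng``.
        """
        name = spec.name
        if name in ("MeLU", "wMeLU", "GaLU", "sGaLU"):
            return cls(c=np.zeros((n_channels, spec.k)))
        if name == "PReLU":
            return cls(prelu_a=np.zeros(n_channels))
        if name == "SReLU":
            return cls(srelu=np.array([0.0, 0.0, 1.0, spec.max_input]))
        if name == "APLU":
            if rng is None:
                rng = np.random.default_rng(0)
            return cls(
                aplu_a=np.zeros((n_channels, spec.n_hinges)),
                aplu_b=rng.uniform(0.0, spec.max_input, (n_channels, spec.n_hinges)),
            )
        return cls()

    def fields(self) -> dict:
        return {
            k: v
            for k, v in vars(self).items()
            if v is not None
        }

    def copy(self) -> "ActivationState":
        return ActivationState(
            **{k: np.array(v, dtype=float) for k, v in self.fields().items()}
        )


@dataclass
class GradResult:
    """Analytic gradients of an activation evaluated elementwise.

    ``d_input`` matches the input shape; ``d_params`` maps each learnable
    field name to an array of shape ``param.shape + x.shape`` holding the
    partial derivative of every output element with respect to every
    parameter component.
    """

    d_input: np.ndarray
    d_params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# static functions


def relu(x):
    """max(x, 0)."""
    x = _check_finite(x)
    return np.maximum(x, 0.0)


def relu_dx(x):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1.0, 0.0)


def leaky_relu(x, a: float = 0.01):
    """x for x >= 0, a*x otherwise (a small, 0.01 by default)."""
    x = _check_finite(x)
    if not np.isfinite(a):
        raise ValueError("non-finite slope a")
    return np.where(x >= 0, x, a * x)


def leaky_relu_dx(x, a: float = 0.01):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1.0, a)


def elu(x, a: float = 1.0):
    """x for x >= 0, a*(exp(x) - 1) otherwise."""
    x = _check_finite(x)
    if not np.isfinite(a):
        raise ValueError("non-finite scale a")
    # evaluate exp only on the negative branch to avoid overflow warnings
    return np.where(x >= 0, x, a * np.expm1(np.minimum(x, 0.0)))


def elu_dx(x, a: float = 1.0):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1.0, a * np.exp(np.minimum(x, 0.0)))


# ---------------------------------------------------------------------------
# PReLU / SReLU / APLU


def prelu(x, a):
    """x for x >= 0, a*x otherwise; ``a`` is learnable and broadcasts."""
    x = _check_finite(x)
    a = np.asarray(a, dtype=float)
    return np.where(x >= 0, x, a * x)


def prelu_dx(x, a):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1.0, np.broadcast_to(np.asarray(a, float), x.shape))


def prelu_da(x):
    """d/da of PReLU: x on the negative branch, 0 otherwise."""
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, x, 0.0)


def srelu(x, knots):
    """S-shaped rectifier with knots ``(al, tl, ar, tr)``.

    Linear with slope ``al`` below ``tl``, identity on ``[tl, tr]``,
    linear with slope ``ar`` above ``tr``.  Requires ``tl <= tr``.
    """
    x = _check_finite(x)
    al, tl, ar, tr = (float(v) for v in np.asarray(knots, dtype=float))
    if tl > tr:
        raise ValueError("SReLU requires tl <= tr")
    return np.where(x < tl, tl + al * (x - tl), np.where(x > tr, tr + ar * (x - tr), x))


def srelu_dx(x, knots):
    x = np.asarray(x, dtype=float)
    al, tl, ar, tr = (float(v) for v in np.asarray(knots, dtype=float))
    return np.where(x < tl, al, np.where(x > tr, ar, 1.0))


def srelu_dknots(x, knots):
    """Partials w.r.t. (al, tl, ar, tr), stacked on a leading axis of 4.

    Obtained by differentiating the piecewise form directly:
    d/dal = x - tl and d/dtl = 1 - al on the left branch; mirrored on the
    right branch; zero elsewhere.
    """
    x = np.asarray(x, dtype=float)
    al, tl, ar, tr = (float(v) for v in np.asarray(knots, dtype=float))
    left = x < tl
    right = x > tr
    d_al = np.where(left, x - tl, 0.0)
    d_tl = np.where(left, 1.0 - al, 0.0)
    d_ar = np.where(right, x - tr, 0.0)
    d_tr = np.where(right, 1.0 - ar, 0.0)
    return np.stack([d_al, d_tl, d_ar, d_tr])


def aplu(x, a, b):
    """Adaptive piecewise linear unit.

    ``ReLU(x) + sum_c a_c * max(0, -x + b_c)`` with learnable hinge slopes
    ``a`` and positions ``b`` (last axis indexes the hinges).  Each hinge
    contributes a ramp of slope ``-a_c`` left of ``b_c``.
    """
    x = _check_finite(x)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("APLU slope and position arrays must share a shape")
    xe = x[..., None]
    return np.maximum(x, 0.0) + np.sum(a * np.maximum(0.0, -xe + b), axis=-1)


def aplu_dx(x, a, b):
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    xe = x[..., None]
    return np.where(x >= 0, 1.0, 0.0) + np.sum(np.where(xe < b, -a, 0.0), axis=-1)


def aplu_da(x, b):
    """d/da_c = -x + b_c where x < b_c, else 0 (hinge axis last)."""
    x = np.asarray(x, dtype=float)
    b = np.asarray(b, dtype=float)
    xe = x[..., None]
    return np.where(xe < b, -xe + b, 0.0)


def aplu_db(x, a, b):
    """d/db_c of a_c * max(0, -x + b_c): a_c where x < b_c, else 0."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    xe = x[..., None]
    return np.where(xe < b, a * np.ones_like(xe), 0.0)


# ---------------------------------------------------------------------------
# Mexican-hat and Gaussian-type basis functions


def mexican_hat(x, a: float, lam: float, max_input: float = 1.0):
    """Triangular bump ``max(lam*M - |x - a*M|, 0)`` with ``M = max_input``.

    Continuous, piecewise linear, nonnegative, supported exactly on
    ``[(a - lam) * M, (a + lam) * M]`` with peak value ``lam * M`` at
    ``a * M``.
    """
    x = _check_finite(x)
    if lam <= 0:
        raise ValueError("basis half-width lam must be positive")
    if max_input <= 0:
        raise ValueError("max_input must be positive")
    M = float(max_input)
    return np.maximum(lam * M - np.abs(x - a * M), 0.0)


def mexican_hat_dx(x, a: float, lam: float, max_input: float = 1.0):
    x = np.asarray(x, dtype=float)
    M = float(max_input)
    inside = (lam * M - np.abs(x - a * M)) >= 0
    slope = np.where(x >= a * M, -1.0, 1.0)
    return np.where(inside, slope, 0.0)


def gaussian_basis(x, a: float, lam: float, max_input: float = 1.0):
    """Piecewise-linear bump/dip pair mimicking a Gaussian-derivative wavelet.

    ``max(lam*M - |x - a*M|, 0) + min(|x - a*M - 2*lam*M| - lam*M, 0)``:
    a positive triangle centered at ``a*M`` followed by a negative triangle
    centered at ``(a + 2*lam)*M``; zero outside ``[(a-lam)M, (a+3lam)M]``.
    """
    x = _check_finite(x)
    if lam <= 0:
        raise ValueError("basis half-width lam must be positive")
    if max_input <= 0:
        raise ValueError("max_input must be positive")
    M = float(max_input)
    bump = np.maximum(lam * M - np.abs(x - a * M), 0.0)
    dip = np.minimum(np.abs(x - a * M - 2 * lam * M) - lam * M, 0.0)
    return bump + dip


def gaussian_basis_dx(x, a: float, lam: float, max_input: float = 1.0):
    x = np.asarray(x, dtype=float)
    M = float(max_input)
    bump_in = (lam * M - np.abs(x - a * M)) >= 0
    d_bump = np.where(bump_in, np.where(x >= a * M, -1.0, 1.0), 0.0)
    u = x - a * M - 2 * lam * M
    dip_in = (np.abs(u) - lam * M) < 0
    d_dip = np.where(dip_in, np.where(u >= 0, 1.0, -1.0), 0.0)
    return d_bump + d_dip


def _basis_fn(spec: ActivationSpec):
    if spec.name in ("MeLU", "wMeLU"):
        return mexican_hat, mexican_hat_dx
    return gaussian_basis, gaussian_basis_dx


def _basis_sum(x, c, spec: ActivationSpec):
    """PReLU_{c0}(x) + sum_j c_j * basis_j(x); c's last axis has length k."""
    x = _check_finite(x)
    c = np.asarray(c, dtype=float)
    if c.shape[-1] != spec.k:
        raise ValueError(f"coefficient vector must have length k={spec.k}")
    fwd, _ = _basis_fn(spec)
    y = prelu(x, c[..., 0])
    for j in range(1, spec.k):
        y = y + c[..., j] * fwd(x, spec.alpha[j - 1], spec.lam[j - 1], spec.max_input)
    return y


def melu(x, c, spec: ActivationSpec):
    """Mexican ReLU: PReLU plus a learned combination of Mexican-hat bumps.

    With all coefficients zero this is exactly ReLU; ``c[..., 0]`` is the
    PReLU slope, ``c[..., j]`` weights the j-th bump.
    """
    if spec.name not in ("MeLU", "wMeLU"):
        raise ValueError("melu requires a MeLU or wMeLU spec")
    return _basis_sum(x, c, spec)


def galu(x, c, spec: ActivationSpec):
    """Gaussian ReLU: PReLU plus learned bump/dip basis combinations."""
    if spec.name not in ("GaLU", "sGaLU"):
        raise ValueError("galu requires a GaLU or sGaLU spec")
    return _basis_sum(x, c, spec)


# ---------------------------------------------------------------------------
# unified dispatch


def evaluate(spec: ActivationSpec, state: Optional[ActivationState], x):
    """Forward value of the activation described by ``spec`` at ``x``.

    ``state`` may be None for static functions; per-channel parameters in
    ``state`` must broadcast against ``x`` (use channel count 1 for plain
    vectors).
    """
    name = spec.name
    if name == "ReLU":
        return relu(x)
    if name == "LeakyReLU":
        return leaky_relu(x, spec.leaky_a)
    if name == "ELU":
        return elu(x, spec.elu_a)
    if state is None:
        raise ValueError(f"{name} requires an ActivationState")
    if name == "PReLU":
        return prelu(x, _squeeze1(state.prelu_a))
    if name == "SReLU":
        return srelu(x, state.srelu)
    if name == "APLU":
        return aplu(x, _squeeze1(state.aplu_a), _squeeze1(state.aplu_b))
    if name in ("MeLU", "wMeLU"):
        return melu(x, _squeeze1(state.c), spec)
    return galu(x, _squeeze1(state.c), spec)


def _squeeze1(p):
    """Drop a leading channel axis of size one so params broadcast with 1-D x."""
    p = np.asarray(p, dtype=float)
    if p.ndim >= 1 and p.shape[0] == 1 and p.ndim > 1:
        return p[0]
    if p.ndim == 1 and p.shape[0] == 1:
        return p[0]
    return p


def gradients(spec: ActivationSpec, state: Optional[ActivationState], x) -> GradResult:
    """Elementwise analytic gradients at ``x`` (single-channel layout).

    Intended for 1-D inputs with channel count 1; the returned
    ``d_params[name]`` has shape ``param.shape + x.shape``.
    """
    x = _check_finite(x)
    name = spec.name
    if name == "ReLU":
        return GradResult(relu_dx(x))
    if name == "LeakyReLU":
        return GradResult(leaky_relu_dx(x, spec.leaky_a))
    if name == "ELU":
        return GradResult(elu_dx(x, spec.elu_a))
    if state is None:
        raise ValueError(f"{name} requires an ActivationState")
    if name == "PReLU":
        a = _squeeze1(state.prelu_a)
        da = prelu_da(x)
        return GradResult(
            prelu_dx(x, a),
            {"prelu_a": da.reshape(state.prelu_a.shape + x.shape)},
        )
    if name == "SReLU":
        return GradResult(
            srelu_dx(x, state.srelu),
            {"srelu": srelu_dknots(x, state.srelu)},
        )
    if name == "APLU":
        a = _squeeze1(state.aplu_a)
        b = _squeeze1(state.aplu_b)
        da = np.moveaxis(aplu_da(x, b), -1, 0)       # (n, *x)
        db = np.moveaxis(aplu_db(x, a, b), -1, 0)
        return GradResult(
            aplu_dx(x, a, b),
            {
                "aplu_a": da.reshape(state.aplu_a.shape + x.shape),
                "aplu_b": db.reshape(state.aplu_b.shape + x.shape),
            },
        )
    # MeLU / wMeLU / GaLU / sGaLU
    c = _squeeze1(state.c)
    fwd, dfx = _basis_fn(spec)
    d_in = prelu_dx(x, c[..., 0])
    dc = [prelu_da(x)]
    for j in range(1, spec.k):
        aj, lj = spec.alpha[j - 1], spec.lam[j - 1]
        d_in = d_in + c[..., j] * dfx(x, aj, lj, spec.max_input)
        dc.append(fwd(x, aj, lj, spec.max_input))
    dc = np.stack(dc)                                 # (k, *x)
    return GradResult(d_in, {"c": dc.reshape(state.c.shape + x.shape)})


# ---------------------------------------------------------------------------
# finite-difference verification


@dataclass
class GradientCheckReport:
    """Outcome of comparing analytic gradients with central differences."""

    name: str
    passed: bool
    max_rel_error: float
    failures: list = field(default_factory=list)

    def __bool__(self):
        return self.passed


def _rel_err(analytic, numeric, scale=1.0):
    denom = np.maximum(np.abs(numeric), scale)
    return np.abs(analytic - numeric) / denom


def gradient_check(
    spec: ActivationSpec,
    state: Optional[ActivationState] = None,
    points: Optional[np.ndarray] = None,
    tol: float = 1e-4,
    step: float = 1e-6,
) -> GradientCheckReport:
    """Verify analytic gradients against central finite differences.

    Checks d/dx and every learnable parameter of ``spec`` at ``points``
    (which must keep a margin of at least ``10 * step`` from every
    breakpoint; the default grid does).  All arithmetic is in float64.
    Returns a report naming any (parameter, point) disagreements beyond
    ``tol`` relative error.
    """
    if state is None:
        state = ActivationState.initial(spec, n_channels=1, rng=np.random.default_rng(12345))
    if points is None:
        M = spec.max_input
        points = np.linspace(-4 * M, 4 * M, 41) + 0.13 * M  # avoid grid breakpoints
    points = np.asarray(points, dtype=np.float64)

    failures = []
    max_err = 0.0

    res = gradients(spec, state, points)
    num_dx = (evaluate(spec, state, points + step) - evaluate(spec, state, points - step)) / (2 * step)
    err = _rel_err(res.d_input, num_dx)
    max_err = max(max_err, float(err.max()))
    for i in np.nonzero(err > tol)[0]:
        failures.append(("input", float(points[i]), float(err[i])))

    for pname in spec.learnable_params:
        p = getattr(state, pname)
        analytic = res.d_params[pname].reshape(p.size, points.size)
        flat = p.reshape(-1)
        for idx in range(flat.size):
            orig = flat[idx]
            flat[idx] = orig + step
            up = evaluate(spec, state, points)
            flat[idx] = orig - step
            dn = evaluate(spec, state, points)
            flat[idx] = orig
            num = (up - dn) / (2 * step)
            err = _rel_err(analytic[idx], num)
            max_err = max(max_err, float(err.max()))
            for i in np.nonzero(err > tol)[0]:
                failures.append((f"{pname}[{idx}]", float(points[i]), float(err[i])))

    return GradientCheckReport(spec.name, not failures, max_err, failures)
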