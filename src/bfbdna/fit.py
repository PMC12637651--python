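"""Three-stage parameterization: marginal fitting, potential contrasting,
and observable-matching fine-tuning by differentiable reweighting.

Stage 1 — marginal fitting.  Each bonded term is fitted independently by
Boltzmann inversion of its marginal distribution: histogram the coordinate,
remove the geometric Jacobian (r^2 for bonds, sin(theta) for angles), take
F = -kT ln p, and least-squares fit the term's functional form.

Stage 2 — potential contrasting.  A logistic noise-contrastive objective
discriminates data configurations from noise configurations drawn from a
reference model: with logit h(x) = -beta [U_theta(x) - U_noise(x)]
+ ln(N_noise/N_data), the loss is the mean binary cross-entropy.  At its
optimum U_theta matches the data distribution's energy up to a constant.
Gradients with respect to every force-field parameter are analytic; the
configurations are featurized once, so each optimization step costs only a
parameter-array recombination.

Stage 3 — fine-tuning.  Observables under perturbed parameters theta are
estimated from a fixed reference ensemble by importance reweighting,
w_i = exp(-beta [U_1(x_i|theta) - U_0(x_i)]) (computed shift-stably), and the
squared mismatch to experimental targets plus an effective-sample-size (ESS)
regularizer is minimized by gradient descent; the ensemble is refreshed when
the ESS drops below a threshold.

Positivity-constrained parameters (stiffnesses, fan depths) are optimized
through a softplus reparameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import expit

from .constants import KB
from .energy import (FAN_PARAM_KEYS, POSITIVE_FAN_KEYS, POSITIVE_TRIMER_KEYS,
                     TRIMER_PARAM_KEYS, compute_fan_features,
                     compute_site_features, debye_huckel_batch, fan_arrays,
                     fan_from_features, seqspec_from_features, trimer_arrays)
from .forcefield import Class2Coefficients, ForceField, copy_forcefield
from .topology import DuplexTopology

__all__ = [
    "ParameterVector", "EnsembleBatch", "ReweightingState",
    "ESSRegularizerSettings", "ObservableTarget", "boltzmann_invert_marginal",
    "contrastive_loss", "optimize_contrast", "reweight_observable",
    "effective_sample_size", "ess_regularizer", "ReferenceEnsemble",
    "observable_matching_loss", "finetune",
]


# --------------------------------------------------------------------------- #
# softplus reparameterization


def softplus(x):
    return np.logaddexp(0.0, x)


def inv_softplus(y):
    y = np.asarray(y, float)
    if np.any(y <= 0):
        raise ValueError("softplus-reparameterized values must be positive")
    # x = y + log(1 - exp(-y)), stable for large and small y
    return y + np.log(-np.expm1(-y))


def dsoftplus(x):
    """d softplus / dx = sigmoid(x)."""
    return expit(x)


# --------------------------------------------------------------------------- #
# ensembles


@dataclass
class EnsembleBatch:
    """Configurations with cached features; the unit of data for contrasting."""

    configs: np.ndarray
    topo: DuplexTopology
    role: str
    site_feat: object = None
    fan_feat: object = None
    dh: np.ndarray = None

    @classmethod
    def from_configs(cls, configs: np.ndarray, topo: DuplexTopology, *,
                     role: str = "data", es=None,
                     charges: Optional[np.ndarray] = None) -> "EnsembleBatch":
        configs = np.asarray(configs, float)
        if configs.ndim != 3 or configs.shape[1] != topo.n_beads:
            raise ValueError("configs must be (n, n_beads, 3) matching the topology")
        dh = (debye_huckel_batch(configs, topo, es, charges)
              if es is not None else np.zeros(len(configs)))
        return cls(configs=configs, topo=topo, role=role,
                   site_feat=compute_site_features(configs, topo),
                   fan_feat=compute_fan_features(configs, topo), dh=dh)

    @property
    def n(self) -> int:
        return len(self.configs)


# --------------------------------------------------------------------------- #
# parameter vector


@dataclass(frozen=True)
class _Entry:
    table: str   # "trimer" | "fan"
    key: str
    slot: int

    @property
    def positive(self) -> bool:
        return (self.key in POSITIVE_TRIMER_KEYS if self.table == "trimer"
                else self.key in POSITIVE_FAN_KEYS)


class ParameterVector:
    """Flattened, named, invertible view of the trainable force-field entries.

    ``trainable`` is a sequence of ``(table, key, slot)`` with ``slot=None``
    meaning every slot of that key; default: every trimer and fan parameter.
    Positivity-constrained entries are exposed in softplus-raw coordinates.
    """

    def __init__(self, ff: ForceField,
                 trainable: Optional[Sequence[tuple]] = None):
        ff.validate()
        self._template = copy_forcefield(ff)
        self.tarr = trimer_arrays(ff)
        self.farr = fan_arrays(ff)
        self.mode = ff.fanbond_mode
        if trainable is None:
            trainable = ([("trimer", k, None) for k in TRIMER_PARAM_KEYS]
                         + [("fan", k, None) for k in FAN_PARAM_KEYS])
        self.entries: list[_Entry] = []
        for table, key, slot in trainable:
            arr = self.tarr if table == "trimer" else self.farr
            if key not in arr:
                raise KeyError(f"unknown parameter {table}.{key}")
            slots = range(len(arr[key])) if slot is None else [slot]
            for s in slots:
                self.entries.append(_Entry(table, key, s))
        self.names = [f"{e.table}.{e.key}[{e.slot}]" for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def _arr(self, e: _Entry) -> np.ndarray:
        return self.tarr[e.key] if e.table == "trimer" else self.farr[e.key]

    def vector(self) -> np.ndarray:
        """Current raw coordinates (softplus-inverse for positive entries)."""
        out = np.empty(len(self.entries))
        for k, e in enumerate(self.entries):
            v = self._arr(e)[e.slot]
            out[k] = inv_softplus(v) if e.positive else v
        return out

    def set_vector(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, float)
        if theta.shape != (len(self.entries),):
            raise ValueError(f"expected vector of length {len(self.entries)}")
        for k, e in enumerate(self.entries):
            self._arr(e)[e.slot] = softplus(theta[k]) if e.positive else theta[k]

    def chain(self, grad_arrays: dict[str, dict[str, np.ndarray]],
              theta: np.ndarray) -> np.ndarray:
        """Map gradients w.r.t. natural parameters to raw coordinates."""
        out = np.empty(len(self.entries))
        for k, e in enumerate(self.entries):
            g = grad_arrays[e.table][e.key][e.slot]
            out[k] = g * dsoftplus(theta[k]) if e.positive else g
        return out

    def to_forcefield(self) -> ForceField:
        """Write the current arrays back into a ForceField."""
        from .topology import FAN_OFFSETS, canonical_trimers

        ff = copy_forcefield(self._template)
        for s, key in enumerate(canonical_trimers()):
            r = ff.trimers[key]
            for pref, block in (("bi", r.bond_i), ("bj", r.bond_j),
                                ("ai", r.angle_i), ("aj", r.angle_j),
                                ("bc", r.bond_cross)):
                block.k2 = float(self.tarr[f"{pref}_k2"][s])
                block.k3 = float(self.tarr[f"{pref}_k3"][s])
                block.k4 = float(self.tarr[f"{pref}_k4"][s])
                block.x0 = float(self.tarr[f"{pref}_x0"][s])
            r.k_theta_cross = float(self.tarr["kth"][s])
            r.theta_m = float(self.tarr["thm"][s])
            r.theta_p = float(self.tarr["thp"][s])
            r.k_phi = float(self.tarr["kph"][s])
            r.phi_m = float(self.tarr["phm"][s])
            r.phi_p = float(self.tarr["php"][s])
        for s, l in enumerate(FAN_OFFSETS):
            rec = ff.fan[l]
            rec.depth = float(self.farr["depth"][s])
            rec.kb = float(self.farr["kb"][s])
            rec.r0 = float(self.farr["r0"][s])
            rec.k_theta = float(self.farr["kth"][s])
            rec.theta_m = float(self.farr["thm"][s])
            rec.theta_p = float(self.farr["thp"][s])
            rec.k_phi = float(self.farr["kph"][s])
            rec.phi_m = float(self.farr["phm"][s])
            rec.phi_p = float(self.farr["php"][s])
        return ff

    # -- energies and parameter gradients ----------------------------------

    def energies(self, batch: EnsembleBatch) -> np.ndarray:
        """Per-configuration total energies under the current parameters."""
        u = seqspec_from_features(batch.site_feat, self.tarr).sum(axis=1)
        u = u + fan_from_features(batch.fan_feat, self.farr, self.mode).sum(axis=1)
        return u + batch.dh

    def param_grad(self, batch: EnsembleBatch, coeff: np.ndarray,
                   theta: np.ndarray) -> np.ndarray:
        """Gradient of sum_i coeff_i U(x_i) w.r.t. the raw coordinates."""
        gt = {k: np.zeros_like(v) for k, v in self.tarr.items()}
        gf = {k: np.zeros_like(v) for k, v in self.farr.items()
              if not k.startswith("c2_")}
        c = np.asarray(coeff, float)[:, None]
        self._accumulate_trimer_grad(batch.site_feat, c, gt)
        if self.mode == "gaussian":
            self._accumulate_fan_grad(batch.fan_feat, c, gf)
        return self.chain({"trimer": gt, "fan": gf}, theta)

    def _accumulate_trimer_grad(self, f, c, g):
        t = self.tarr
        s = f.slot
        S = len(s)
        if S == 0:
            return

        def scat(key, per_site):
            np.add.at(g[key], s, (c * per_site).sum(axis=0))

        for x, pref in ((f.r1, "bi"), (f.r2, "bj"), (f.th1, "ai"),
                        (f.th2, "aj"), (f.rcs, "bc")):
            d = x - t[f"{pref}_x0"][s]
            scat(f"{pref}_k2", d**2)
            scat(f"{pref}_k3", d**3)
            scat(f"{pref}_k4", d**4)
            scat(f"{pref}_x0", -(2 * t[f"{pref}_k2"][s] * d
                                 + 3 * t[f"{pref}_k3"][s] * d**2
                                 + 4 * t[f"{pref}_k4"][s] * d**3))
        dm1 = f.a1 - t["thm"][s]
        dm2 = f.a2 - t["thm"][s]
        dp1 = f.a3 - t["thp"][s]
        dp2 = f.a4 - t["thp"][s]
        scat("kth", dm1**2 + dm2**2 + dp1**2 + dp2**2)
        scat("thm", -2 * t["kth"][s] * (dm1 + dm2))
        scat("thp", -2 * t["kth"][s] * (dp1 + dp2))
        c1 = np.cos(f.d1 + t["phm"][s])
        c2 = np.cos(f.d2 + t["php"][s])
        scat("kph", (1 + c1) + (1 + c2))
        scat("phm", -t["kph"][s] * np.sin(f.d1 + t["phm"][s]))
        scat("php", -t["kph"][s] * np.sin(f.d2 + t["php"][s]))

    def _accumulate_fan_grad(self, f, c, g):
        fa = self.farr
        s = f.lslot
        if len(s) == 0:
            return
        from .energy import fan_exponent_from_features

        u = fan_exponent_from_features(f, fa)
        expu = np.exp(-u)                     # (n_cfg, P)
        w = fa["depth"][s] * expu             # dV/d(U-param) factor

        def scat(key, per_pair):
            np.add.at(g[key], s, (c * per_pair).sum(axis=0))

        scat("depth", -expu)
        d = f.r - fa["r0"][s]
        scat("kb", w * d**2)
        scat("r0", w * (-2 * fa["kb"][s] * d))
        am1 = f.mask_a1 * (f.a1 - fa["thm"][s])
        am2 = f.mask_a2 * (f.a2 - fa["thm"][s])
        ap1 = f.mask_a3 * (f.a3 - fa["thp"][s])
        ap2 = f.mask_a4 * (f.a4 - fa["thp"][s])
        scat("kth", w * (f.mask_a1 * am1**2 + f.mask_a2 * am2**2
                         + f.mask_a3 * ap1**2 + f.mask_a4 * ap2**2))
        scat("thm", w * (-2 * fa["kth"][s] * (am1 + am2)))
        scat("thp", w * (-2 * fa["kth"][s] * (ap1 + ap2)))
        cd1 = f.mask_d1 * (1 + np.cos(f.d1 + fa["phm"][s]))
        cd2 = f.mask_d2 * (1 + np.cos(f.d2 + fa["php"][s]))
        scat("kph", w * (cd1 + cd2))
        scat("phm", w * (-fa["kph"][s] * f.mask_d1 * np.sin(f.d1 + fa["phm"][s])))
        scat("php", w * (-fa["kph"][s] * f.mask_d2 * np.sin(f.d2 + fa["php"][s])))


# --------------------------------------------------------------------------- #
# stage 1: marginal fitting


def boltzmann_invert_marginal(samples: np.ndarray, kind: str,
                              temperature: float = 300.0, *,
                              n_bins: int = 80, min_count: int = 10):
    """Fit one potential term to the marginal distribution of its coordinate.

    ``kind`` selects the Jacobian correction and the functional form:
    ``bond`` (r^2 Jacobian, Class-2 polynomial), ``angle`` (sin theta,
    Class-2), ``dihedral`` (none, k [1 + cos(phi + phase)]).

    Returns ``(params, info)`` where params is a
    :class:`~bfbdna.forcefield.Class2Coefficients` for bonds/angles or a
    ``(k, phase)`` tuple for dihedrals, and info carries the fit residual
    and warnings (multimodality, ill-conditioning).
    """
    x = np.asarray(samples, float).ravel()
    if len(x) < 500:
        raise ValueError(f"need >= 500 samples, got {len(x)}")
    if kind not in ("bond", "angle", "dihedral"):
        raise ValueError(f"unknown coordinate kind {kind!r}")
    kt = KB * temperature

    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts >= min_count
    if keep.sum() < 6:
        raise ValueError("too few occupied bins for a stable fit")
    warnings: list[str] = []

    # multimodality check on the smoothed histogram
    sm = np.convolve(counts, np.ones(5) / 5.0, mode="same")
    interior = sm[1:-1]
    peaks = np.sum((interior > sm[:-2]) & (interior > sm[2:])
                   & (interior > 0.2 * sm.max()))
    if peaks > 1:
        warnings.append("multimodal")

    p = counts[keep].astype(float)
    xc = centers[keep]
    if kind == "bond":
        p = p / xc**2
    elif kind == "angle":
        p = p / np.sin(xc)
    fe = -kt * np.log(p / p.max())
    wts = np.sqrt(counts[keep])  # weight by sampling precision

    if kind == "dihedral":
        a = np.column_stack([np.ones_like(xc), np.cos(xc), np.sin(xc)])
        sol, *_ = np.linalg.lstsq(a * wts[:, None], fe * wts, rcond=None)
        _, A, B = sol
        k = math.hypot(A, B)
        phase = math.atan2(-B, A)
        resid = float(np.sqrt(np.mean((a @ sol - fe) ** 2)))
        return (k, phase), {"residual": resid, "warnings": warnings}

    deg = 4
    coeffs = np.polynomial.polynomial.polyfit(xc, fe, deg, w=wts)
    poly = np.polynomial.Polynomial(coeffs)
    dpoly = poly.deriv()
    roots = dpoly.roots()
    real = roots[np.abs(roots.imag) < 1e-8].real
    in_range = real[(real >= xc.min() - 0.1 * np.ptp(xc))
                    & (real <= xc.max() + 0.1 * np.ptp(xc))]
    if len(in_range) == 0:
        raise ValueError("no stationary point inside the sampled range")
    x0 = float(in_range[np.argmin(poly(in_range))])
    d2, d3, d4 = poly.deriv(2)(x0), poly.deriv(3)(x0), poly.deriv(4)(x0)
    k2 = float(d2 / 2.0)
    k3 = float(d3 / 6.0)
    k4 = float(d4 / 24.0)
    resid = float(np.sqrt(np.mean((poly(xc) - fe) ** 2)))
    # flat free-energy relief over the sampled window means the curvature is
    # statistically unconstrained (a thermal well would show >~ kT of relief)
    if k2 <= 0 or float(np.ptp(poly(xc))) < kt:
        warnings.append("ill-conditioned: near-zero curvature over the "
                        "sampled range")
    # floor k4 slightly above zero: keeps the well bounded and the value
    # representable in the softplus-positive parameter coordinates
    return (Class2Coefficients(k2=k2, k3=k3, k4=max(k4, 1e-6), x0=x0),
            {"residual": resid, "warnings": warnings})


# --------------------------------------------------------------------------- #
# stage 2: potential contrasting


def _log_sigmoid(h):
    return -np.logaddexp(0.0, -h)


def contrastive_loss(theta: np.ndarray, pv: ParameterVector,
                     data: EnsembleBatch, noise: EnsembleBatch,
                     noise_energy: tuple[np.ndarray, np.ndarray],
                     beta: float, *, log_z: float = 0.0,
                     want_grad: bool = True):
    """Logistic noise-contrastive loss and its parameter gradient.

    ``noise_energy = (U_noise on data samples, U_noise on noise samples)``
    are the energies under the noise-generating model.  The logit is
    h(x) = -beta [U_theta(x) - U_noise(x)] + c + ln(N_noise / N_data) with a
    free-energy offset ``c = log_z``; the loss is -mean ln sigma(h) over data
    - mean ln(1 - sigma(h)) over noise.  The offset is essential for
    consistency: the optimal discriminator is the true log-density ratio,
    whose normalization constant an energy difference alone cannot express.
    With ``want_grad`` the return is ``(loss, grad_theta, dloss_dlogz)``.
    """
    un_d, un_n = noise_energy
    pv.set_vector(theta)
    offset = math.log(noise.n / data.n) + log_z
    h_d = -beta * (pv.energies(data) - un_d) + offset
    h_n = -beta * (pv.energies(noise) - un_n) + offset
    if not (np.all(np.isfinite(h_d)) and np.all(np.isfinite(h_n))):
        raise FloatingPointError("non-finite energies in contrastive loss")
    loss = float(-np.mean(_log_sigmoid(h_d)) - np.mean(_log_sigmoid(-h_n)))
    if not want_grad:
        return loss, None
    # dloss/dU_theta: data  +beta (1 - sigma(h)) / N_d ; noise -beta sigma(h) / N_n
    sig_d = expit(h_d)
    sig_n = expit(h_n)
    grad = pv.param_grad(data, beta * (1.0 - sig_d) / data.n, theta)
    grad -= pv.param_grad(noise, beta * sig_n / noise.n, theta)
    d_logz = float(-np.mean(1.0 - sig_d) + np.mean(sig_n))
    return loss, grad, d_logz


@dataclass
class AdamState:
    m: np.ndarray
    v: np.ndarray
    t: int = 0


def _adam_step(theta, grad, state: AdamState, lr, b1=0.9, b2=0.999, eps=1e-8):
    state.t += 1
    state.m = b1 * state.m + (1 - b1) * grad
    state.v = b2 * state.v + (1 - b2) * grad**2
    mh = state.m / (1 - b1**state.t)
    vh = state.v / (1 - b2**state.t)
    return theta - lr * mh / (np.sqrt(vh) + eps)


def optimize_contrast(pv: ParameterVector, data: EnsembleBatch,
                      noise: EnsembleBatch,
                      noise_energy: tuple[np.ndarray, np.ndarray],
                      beta: float, *, method: str = "lbfgs",
                      n_steps: int = 500, lr: float = 1e-3,
                      lr_final: Optional[float] = None,
                      patience: int = 100):
    """Minimize the contrastive loss; deterministic (full batch).

    The free-energy offset of the logit is co-optimized with theta.  The
    default quasi-Newton method (L-BFGS with the analytic gradient) handles
    the strong scale anisotropy between stiffnesses (raw units of hundreds)
    and equilibrium values (hundredths of a nm), on which first-order
    stepping stalls; ``method="adam"`` keeps a first-order adaptive
    alternative, with an optional geometric learning-rate decay to
    ``lr_final``.  Returns ``(theta_star, trace)``; raises on sustained
    divergence.
    """
    theta = pv.vector()
    ext = np.append(theta, 0.0)  # trailing entry: free-energy offset log_z

    if method == "lbfgs":
        from scipy import optimize as _sopt

        trace: list[float] = []

        def fun(x):
            loss, grad, d_logz = contrastive_loss(
                x[:-1], pv, data, noise, noise_energy, beta, log_z=float(x[-1]))
            return loss, np.append(grad, d_logz)

        def cb(x):
            trace.append(fun(x)[0])

        res = _sopt.minimize(fun, ext, jac=True, method="L-BFGS-B",
                             callback=cb,
                             options=dict(maxiter=n_steps, ftol=1e-14,
                                          gtol=1e-10))
        if not np.isfinite(res.fun):
            raise RuntimeError("contrastive optimization diverged")
        theta = res.x[:-1]
        pv.set_vector(theta)
        return theta, np.array(trace if trace else [float(res.fun)])

    if method != "adam":
        raise ValueError(f"unknown method {method!r}")
    state = AdamState(m=np.zeros_like(ext), v=np.zeros_like(ext))
    trace = []
    best = math.inf
    since_best = 0
    decay = ((lr_final / lr) ** (1.0 / max(n_steps - 1, 1))
             if lr_final is not None else 1.0)
    for step in range(n_steps):
        loss, grad, d_logz = contrastive_loss(ext[:-1], pv, data, noise,
                                              noise_energy, beta,
                                              log_z=float(ext[-1]))
        trace.append(loss)
        if loss < best - 1e-12:
            best = loss
            since_best = 0
        else:
            since_best += 1
            if since_best > patience and loss > trace[0]:
                raise RuntimeError("contrastive optimization diverged")
        ext = _adam_step(ext, np.append(grad, d_logz), state, lr * decay**step)
    theta = ext[:-1]
    pv.set_vector(theta)
    return theta, np.array(trace)


# --------------------------------------------------------------------------- #
# stage 3: reweighting and fine-tuning


@dataclass
class ReweightingState:
    """Shift-stable importance weights between a reference and a perturbed
    potential, with the effective sample size."""

    u0: np.ndarray
    u1: np.ndarray
    beta: float

    def __post_init__(self):
        self.u0 = np.asarray(self.u0, float)
        self.u1 = np.asarray(self.u1, float)
        if self.u0.shape != self.u1.shape:
            raise ValueError("u0 and u1 must have the same length")

    @property
    def log_weights(self) -> np.ndarray:
        return -self.beta * (self.u1 - self.u0)

    @property
    def weights(self) -> np.ndarray:
        lw = self.log_weights
        w = np.exp(lw - lw.max())
        if not np.any(w > 0):
            raise FloatingPointError("all reweighting weights underflowed")
        return w

    @property
    def ess(self) -> float:
        return effective_sample_size(self)


def reweight_observable(obs: np.ndarray, state: ReweightingState) -> float:
    """Importance-reweighted estimator sum O w / sum w."""
    obs = np.asarray(obs, float)
    w = state.weights
    return float(np.sum(obs * w) / np.sum(w))


def effective_sample_size(state_or_weights) -> float:
    """(sum w)^2 / sum w^2, in [1, N]; invariant to weight scaling."""
    w = (state_or_weights.weights
         if isinstance(state_or_weights, ReweightingState)
         else np.asarray(state_or_weights, float))
    return float(np.sum(w) ** 2 / np.sum(w**2))


@dataclass
class ESSRegularizerSettings:
    alpha: float = 100.0
    ess0: float = 750.0
    refresh_ratio: float = 1.5   # refresh reference when ESS < ess0/refresh_ratio

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.ess0 < 1:
            raise ValueError("ess0 must be >= 1")


def ess_regularizer(ess: float, settings: ESSRegularizerSettings) -> float:
    """(1/alpha) ln(1 + exp(alpha (ESS0 - ESS)/2)), overflow-safe.

    Smooth, monotone decreasing in ESS: ~0 for ESS >> ESS0 and asymptotically
    (ESS0 - ESS)/2 for ESS << ESS0.
    """
    settings.validate()
    return float(np.logaddexp(0.0, settings.alpha * (settings.ess0 - ess) / 2.0)
                 / settings.alpha)


def _dess_reg(ess: float, settings: ESSRegularizerSettings) -> float:
    z = settings.alpha * (settings.ess0 - ess) / 2.0
    return float(-0.5 * expit(z))


@dataclass
class ObservableTarget:
    """Experimental target driving fine-tuning."""

    sequence_id: str
    value: float
    uncertainty: Optional[float] = None

    def validate(self) -> None:
        if self.value <= 0:
            raise ValueError(f"{self.sequence_id}: target observable must be > 0")


@dataclass
class ReferenceEnsemble:
    """Fixed reference ensemble for one target: per-sample observables,
    reference energies, and a parametric energy model.

    ``energy_fn(theta) -> (U1 (N,), dU1/dtheta (N, P))``.
    """

    target: ObservableTarget
    obs: np.ndarray
    u0: np.ndarray
    energy_fn: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]
    beta: float


def observable_matching_loss(theta: np.ndarray,
                             ensembles: Sequence[ReferenceEnsemble],
                             settings: ESSRegularizerSettings, *,
                             want_grad: bool = True):
    """l_OM = sum_targets (<O>_w - O_exp)^2 + R_ESS, with analytic gradient.

    Gradients flow through the reweighting factors only (the per-sample
    observables are fixed functions of the reference configurations).
    Returns (loss, grad, diagnostics) with the minimum ESS over targets.
    """
    loss = 0.0
    grad = np.zeros_like(np.asarray(theta, float))
    min_ess = math.inf
    estimates = []
    for ens in ensembles:
        u1, du1 = ens.energy_fn(theta)
        st = ReweightingState(u0=ens.u0, u1=u1, beta=ens.beta)
        w = st.weights
        sw = w.sum()
        wn = w / sw
        o_hat = float(np.sum(ens.obs * wn))
        estimates.append(o_hat)
        ess = effective_sample_size(w)
        min_ess = min(min_ess, ess)
        mismatch = o_hat - ens.target.value
        loss += mismatch**2 + ess_regularizer(ess, settings)
        if want_grad:
            # d<O>/dtheta = -beta [ <O dU>_w - <O>_w <dU>_w ]
            mean_du = wn @ du1
            mean_odu = (wn * ens.obs) @ du1
            dg = -ens.beta * (mean_odu - o_hat * mean_du)
            grad += 2.0 * mismatch * dg
            # dESS/dtheta = 2 ESS beta ( <dU>_{w^2} - <dU>_w )
            w2n = w**2 / np.sum(w**2)
            dess = 2.0 * ess * ens.beta * (w2n @ du1 - mean_du)
            grad += _dess_reg(ess, settings) * dess
    diag = {"min_ess": min_ess, "estimates": estimates}
    return (loss, grad if want_grad else None, diag)


def finetune_step(theta: np.ndarray, ensembles: Sequence[ReferenceEnsemble],
                  settings: ESSRegularizerSettings, *, lr: float = 1e-3,
                  adam: Optional[AdamState] = None):
    """One gradient step on l_OM; flags when the ensemble needs refreshing.

    Returns (theta_new, loss, diagnostics); ``diagnostics['refresh']`` is
    True when the minimum ESS fell below ess0 / refresh_ratio.
    """
    loss, grad, diag = observable_matching_loss(theta, ensembles, settings)
    if adam is not None:
        theta_new = _adam_step(theta, grad, adam, lr)
    else:
        theta_new = theta - lr * grad
    diag["refresh"] = diag["min_ess"] < settings.ess0 / settings.refresh_ratio
    return theta_new, loss, diag


def finetune(theta0: np.ndarray,
             make_ensembles: Callable[[np.ndarray], Sequence[ReferenceEnsemble]],
             settings: ESSRegularizerSettings, *, n_steps: int = 200,
             lr: float = 1e-3, max_refresh: int = 10):
    """Fine-tuning driver: gradient steps with ensemble refresh on ESS decay.

    ``make_ensembles(theta)`` regenerates reference ensembles under the
    current parameters (U_0 snapshots are immutable within a round).
    Returns (theta_star, loss_trace, n_refreshes).
    """
    theta = np.asarray(theta0, float).copy()
    ensembles = make_ensembles(theta)
    adam = AdamState(m=np.zeros_like(theta), v=np.zeros_like(theta))
    trace = []
    refreshes = 0
    for _ in range(n_steps):
        theta, loss, diag = finetune_step(theta, ensembles, settings,
                                          lr=lr, adam=adam)
        trace.append(loss)
        if diag["refresh"]:
            refreshes += 1
            if refreshes > max_refresh:
                raise RuntimeError("ESS collapsed repeatedly; reduce the step "
                                   "size or loosen the targets")
            ensembles = make_ensembles(theta)
            adam = AdamState(m=np.zeros_like(theta), v=np.zeros_like(theta))
    return theta, np.array(trace), refreshes


# --------------------------------------------------------------------------- #
# marginal fitting of a whole force field


def fit_marginal_forcefield(frames: np.ndarray, topo: DuplexTopology,
                            template: ForceField, *,
                            temperature: float = 300.0) -> ForceField:
    """Assemble a force field by marginal fitting every term of an ensemble.

    Bonded and angular Class-2 terms and the dihedral cosine terms are fitted
    per canonical trimer by Boltzmann inversion of the pooled marginals.
    Cross-strand angle references take the sample means with the stiffness
    from second-moment matching.  Fan-bond records keep the template depths
    (a marginal distance distribution near its minimum constrains only the
    product depth*kb) and match r0 and kb to the sample mean and variance;
    angular references and phases are set to the sample means.  Trimers with
    too few samples keep the template record.
    """
    from .topology import FAN_OFFSETS, canonical_trimers

    ff = copy_forcefield(template)
    kt = KB * temperature
    sf = compute_site_features(frames, topo)
    slots = sf.slot
    keys = canonical_trimers()
    for s in np.unique(slots):
        cols = np.flatnonzero(slots == s)
        rec = ff.trimers[keys[s]]
        n_samp = sf.r1[:, cols].size
        if n_samp < 500:
            continue

        def pool(x):
            return x[:, cols].ravel()

        for attr, samp, kind in (("bond_i", pool(sf.r1), "bond"),
                                 ("bond_j", pool(sf.r2), "bond"),
                                 ("angle_i", pool(sf.th1), "angle"),
                                 ("angle_j", pool(sf.th2), "angle"),
                                 ("bond_cross", pool(sf.rcs), "bond")):
            coeffs, _ = boltzmann_invert_marginal(samp, kind, temperature)
            setattr(rec, attr, coeffs)
        am = np.concatenate([pool(sf.a1), pool(sf.a2)])
        ap = np.concatenate([pool(sf.a3), pool(sf.a4)])
        rec.theta_m = float(am.mean())
        rec.theta_p = float(ap.mean())
        rec.k_theta_cross = float(kt / (2.0 * 0.5 * (am.var() + ap.var())))
        kphis, phases = [], []
        for samp in (pool(sf.d1), pool(sf.d2)):
            (k, phase), _ = boltzmann_invert_marginal(samp, "dihedral", temperature)
            kphis.append(k)
            phases.append(phase)
        rec.k_phi = float(np.mean(kphis))
        rec.phi_m, rec.phi_p = float(phases[0]), float(phases[1])

    fanf = compute_fan_features(frames, topo)
    for s, l in enumerate(FAN_OFFSETS):
        cols = np.flatnonzero(fanf.lslot == s)
        if len(cols) == 0:
            continue
        rec = ff.fan[l]
        r = fanf.r[:, cols].ravel()
        if r.size < 500:
            continue
        rec.r0 = float(r.mean())
        rec.kb = float(kt / (2.0 * r.var() * rec.depth))
        for attr, a, b_, ma, mb in (("theta_m", fanf.a1, fanf.a2,
                                     fanf.mask_a1, fanf.mask_a2),
                                    ("theta_p", fanf.a3, fanf.a4,
                                     fanf.mask_a3, fanf.mask_a4)):
            vals = np.concatenate([a[:, cols][:, ma[cols]].ravel(),
                                   b_[:, cols][:, mb[cols]].ravel()])
            if vals.size:
                setattr(rec, attr, float(vals.mean()))
        for attr, d, md in (("phi_m", fanf.d1, fanf.mask_d1),
                            ("phi_p", fanf.d2, fanf.mask_d2)):
            vals = d[:, cols][:, md[cols]].ravel()
            if vals.size:
                # phase minimizing 1 + cos(phi + phase) at the circular mean
                ph = np.pi - np.angle(np.mean(np.exp(1j * vals)))
                setattr(rec, attr, float((ph + np.pi) % (2 * np.pi) - np.pi))
    ff.validate()
    return ff
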