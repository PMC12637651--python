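"""Synthetic fixtures and independent sampling oracles.

Everything other modules need for testing is generated here with no external
data: discrete worm-like chains with an exactly known tangent correlation,
a single-bead-move Metropolis sampler targeting exp(-V/kT) that serves as an
independent Boltzmann oracle for the Langevin integrator and the fitting
stack, and paired data/noise ensembles with a recorded ground truth for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import optimize

from .constants import KB
from .topology import DuplexTopology

__all__ = ["WLCSpec", "generate_wlc", "wlc_msee", "metropolis_oracle",
           "MetropolisResult", "make_toy_ensembles"]


# --------------------------------------------------------------------------- #
# worm-like chains


@dataclass
class WLCSpec:
    """Discrete worm-like-chain ensemble specification.

    ``persistence_length`` and ``bead_spacing`` in nm.  The polar bend angle
    between successive bonds is drawn from the exact wrapped density
    p(theta) ~ exp(kappa cos theta) sin theta with kappa chosen so that
    <cos theta> equals exp(-b/L_p) exactly; the tangent correlation is then
    <t_i . t_{i+k}> = exp(-k b / L_p) with no discretization bias.
    """

    persistence_length: float = 50.0
    bead_spacing: float = 0.34
    n_beads: int = 600
    n_chains: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.persistence_length <= 0 or self.bead_spacing <= 0:
            raise ValueError("persistence length and spacing must be positive")
        if self.n_beads < 11:
            raise ValueError("need >= 11 beads for a defined local chain angle")

    @property
    def mean_cos(self) -> float:
        return float(np.exp(-self.bead_spacing / self.persistence_length))

    @property
    def kappa(self) -> float:
        """Concentration solving the Langevin function coth(k) - 1/k = <cos>."""
        c = self.mean_cos

        def langevin(k):
            return 1.0 / np.tanh(k) - 1.0 / k - c

        return float(optimize.brentq(langevin, 1e-8, 1e8))


def _sample_bend_cos(kappa: float, size, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw of u = cos(theta) with density ~ exp(kappa u) on [-1, 1]."""
    xi = rng.random(size)
    # u = 1 + log(xi + (1-xi) e^{-2 kappa}) / kappa, computed overflow-safely
    return 1.0 + np.log(xi + (1.0 - xi) * np.exp(-2.0 * kappa)) / kappa


def generate_wlc(spec: WLCSpec) -> np.ndarray:
    """Generate chains, shape (n_chains, n_beads, 3); bit-reproducible."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    kappa = spec.kappa
    nc, nb, b = spec.n_chains, spec.n_beads, spec.bead_spacing

    t = np.zeros((nc, 3))
    t[:, 2] = 1.0
    pos = np.zeros((nc, nb, 3))
    for k in range(1, nb):
        u = _sample_bend_cos(kappa, nc, rng)
        s = np.sqrt(np.maximum(1.0 - u * u, 0.0))
        phi = rng.uniform(0.0, 2.0 * np.pi, nc)
        # orthonormal frame around the current tangent
        ref = np.where(np.abs(t[:, 2:3]) < 0.9,
                       np.tile([0.0, 0.0, 1.0], (nc, 1)),
                       np.tile([1.0, 0.0, 0.0], (nc, 1)))
        e1 = np.cross(t, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(t, e1)
        t = (u[:, None] * t
             + (s * np.cos(phi))[:, None] * e1
             + (s * np.sin(phi))[:, None] * e2)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        pos[:, k] = pos[:, k - 1] + b * t
    return pos


def wlc_msee(spec: WLCSpec) -> float:
    """Closed-form mean-squared end-to-end distance of the discrete chain."""
    n = spec.n_beads - 1  # bonds
    c = spec.mean_cos
    b = spec.bead_spacing
    return b * b * (n * (1 + c) / (1 - c) - 2 * c * (1 - c**n) / (1 - c) ** 2)


# --------------------------------------------------------------------------- #
# Metropolis oracle


@dataclass
class MetropolisResult:
    samples: np.ndarray         # (n_samples, n_walkers, n_beads, 3)
    acceptance: float
    move_size: float

    def flat(self) -> np.ndarray:
        """Samples pooled over walkers: (n_samples * n_walkers, n_beads, 3)."""
        s = self.samples
        return s.reshape(-1, s.shape[2], s.shape[3])


def metropolis_oracle(energy: Callable[[np.ndarray], np.ndarray],
                      conf0: np.ndarray, temperature: float, n_steps: int,
                      move_size: float = 0.05, seed: int = 0, *,
                      n_walkers: int = 1, burn_in: Optional[int] = None,
                      sample_every: int = 10,
                      tune: bool = True) -> MetropolisResult:
    """Single-bead random-displacement Metropolis chain targeting exp(-V/kT).

    ``energy`` must map a batch (n_walkers, n_beads, 3) to per-walker
    energies.  The move size is auto-tuned to 30-50% acceptance during
    burn-in and then frozen (preserving detailed balance for the production
    phase).  Deterministic under seed.
    """
    kt = KB * temperature
    conf0 = np.asarray(conf0, float)
    nb = conf0.shape[0]
    pos = np.tile(conf0[None], (n_walkers, 1, 1))
    rng = np.random.default_rng(seed)
    # de-correlate walkers with a tiny jitter so they explore independently
    if n_walkers > 1:
        pos += 1e-3 * move_size * rng.standard_normal(pos.shape)
    e = np.asarray(energy(pos), float)
    if not np.all(np.isfinite(e)):
        raise FloatingPointError("non-finite initial energy")
    if burn_in is None:
        burn_in = max(200, n_steps // 5)

    samples = []
    acc_count = 0
    att_count = 0
    window_acc = 0
    window_att = 0
    for step in range(n_steps + burn_in):
        bead = rng.integers(0, nb, n_walkers)
        disp = move_size * rng.uniform(-1.0, 1.0, (n_walkers, 3))
        trial = pos.copy()
        trial[np.arange(n_walkers), bead] += disp
        e_trial = np.asarray(energy(trial), float)
        log_ratio = -(e_trial - e) / kt
        accept = np.log(rng.random(n_walkers)) < log_ratio
        pos[accept] = trial[accept]
        e[accept] = e_trial[accept]
        n_acc = int(accept.sum())
        in_burn = step < burn_in
        if in_burn and tune:
            window_acc += n_acc
            window_att += n_walkers
            if window_att >= max(50, 5 * n_walkers):
                rate = window_acc / window_att
                if rate < 0.30:
                    move_size *= 0.8
                elif rate > 0.50:
                    move_size *= 1.25
                window_acc = window_att = 0
        if not in_burn:
            acc_count += n_acc
            att_count += n_walkers
            if (step - burn_in + 1) % sample_every == 0:
                samples.append(pos.copy())
    if att_count and acc_count == 0:
        raise RuntimeError("zero acceptance over the production window; "
                           "reduce move_size")
    return MetropolisResult(samples=np.array(samples),
                            acceptance=acc_count / max(att_count, 1),
                            move_size=move_size)


def duplex_batch_energy(topo: DuplexTopology, ff,
                        charges: Optional[np.ndarray] = None
                        ) -> Callable[[np.ndarray], np.ndarray]:
    """Batch energy callable for a duplex force field, for the oracle."""
    from .energy import (compute_fan_features, compute_site_features,
                         debye_huckel_batch, fan_arrays, fan_from_features,
                         seqspec_from_features, trimer_arrays)

    tarr = trimer_arrays(ff)
    farr = fan_arrays(ff)
    mode = ff.fanbond_mode
    es = ff.electrostatics

    def energy(batch: np.ndarray) -> np.ndarray:
        u = seqspec_from_features(compute_site_features(batch, topo), tarr).sum(axis=1)
        u += fan_from_features(compute_fan_features(batch, topo), farr, mode).sum(axis=1)
        u += debye_huckel_batch(batch, topo, es, charges)
        return u

    return energy


# --------------------------------------------------------------------------- #
# paired data/noise ensembles


def make_toy_ensembles(ff_true, ff_noise, sequence: str, *,
                       n_data: int = 400, n_noise: int = 400,
                       temperature: float = 300.0,
                       n_steps: int = 2500, sample_every: int = 100,
                       seed: int = 0):
    """Data sampled under ``ff_true``, noise under ``ff_noise``, both by the
    Metropolis oracle on a small duplex; returns (data, noise, manifest).

    The batches are :class:`~bfbdna.fit.EnsembleBatch` objects; the manifest
    records the generating parameters for recovery tests.
    """
    from .dynamics import build_ideal_duplex
    from .fit import EnsembleBatch
    from .topology import build_duplex_topology

    topo = build_duplex_topology(sequence)
    if topo.n_bp > 8:
        raise ValueError("toy ensembles are for small duplexes (<= 8 bp)")
    conf0 = build_ideal_duplex(topo.n_bp)

    out = []
    for tag, ff, count, sd in (("data", ff_true, n_data, seed),
                               ("noise", ff_noise, n_noise, seed + 1)):
        # many independent walkers decorrelate far faster than one long chain
        per_walker = max(1, n_steps // sample_every)
        walkers = max(4, -(-count // per_walker))
        res = metropolis_oracle(duplex_batch_energy(topo, ff), conf0,
                                temperature, n_steps, seed=sd,
                                n_walkers=walkers, sample_every=sample_every,
                                burn_in=max(1500, n_steps // 2))
        confs = res.flat()
        if len(confs) < count:
            raise RuntimeError(f"too few {tag} samples: {len(confs)} < {count}")
        sel = np.linspace(0, len(confs) - 1, count).astype(int)
        out.append(EnsembleBatch.from_configs(confs[sel], topo, role=tag,
                                              es=ff.electrostatics))
    manifest = {
        "sequence": sequence,
        "temperature": temperature,
        "seed": seed,
        "n_data": n_data,
        "n_noise": n_noise,
    }
    return out[0], out[1], manifest
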