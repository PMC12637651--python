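"""Structural and mechanical diagnostics.

* midpoint chain — virtual beads at base-pair centroids, tracking the duplex
  axis without helical wobble;
* local chain angle (LCA) — the angle at midpoint bead k formed with beads
  k-5 and k+5; pi for a straight chain, small values flag kinks;
* fan-bond length distributions and their variance broadening between linear
  and bent (nucleosomal) regimes;
* persistence length from the exponential decay of tangent-vector
  correlations, with 95% confidence intervals by block averaging;
* Kullback-Leibler divergence between sampled 1-D distributions on shared
  bins with pseudocount regularization;
* per-frame RMSD after optimal rigid superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .geometry import DegenerateGeometryError, kabsch_rmsd
from .topology import FAN_OFFSETS, DuplexTopology

__all__ = [
    "midpoint_chain",
    "local_chain_angle",
    "fan_bond_distances",
    "fan_bond_histograms",
    "variance_broadening",
    "persistence_length",
    "kl_divergence",
    "rmsd_distribution",
    "ObservableEstimate",
]


def _frames(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    return x[None] if x.ndim == 2 else x


def midpoint_chain(pos: np.ndarray, topo: DuplexTopology) -> np.ndarray:
    """Base-pair midpoints, ordered along the duplex.

    Accepts a single configuration (n_beads, 3) or a frame stack; returns
    (n_bp, 3) or (n_frames, n_bp, 3) correspondingly.
    """
    f = _frames(pos)
    if f.shape[1] != topo.n_beads:
        raise ValueError("bead count does not match topology")
    n = topo.n_bp
    mids = 0.5 * (f[:, :n, :] + f[:, 2 * n - 1 : n - 1 : -1, :])
    return mids[0] if np.asarray(pos).ndim == 2 else mids


def local_chain_angle(chain: np.ndarray, *, half_window: int = 5) -> np.ndarray:
    """Angle profile at each midpoint bead k over the triple (k-5, k, k+5).

    Defined only where both neighbours exist; returns an array of length
    ``n - 2*half_window`` (sites ``half_window .. n-half_window-1``), values
    in (0, pi].  Accepts a frame stack, returning (n_frames, n_sites).
    """
    c = _frames(chain)
    n = c.shape[1]
    w = half_window
    if n < 2 * w + 1:
        raise ValueError(f"chain too short for half-window {w}: need >= {2 * w + 1}")
    u = c[:, : n - 2 * w, :] - c[:, w : n - w, :]       # k -> k-5
    v = c[:, 2 * w :, :] - c[:, w : n - w, :]           # k -> k+5
    ru = np.linalg.norm(u, axis=2)
    rv = np.linalg.norm(v, axis=2)
    if np.any(ru < 1e-10) or np.any(rv < 1e-10):
        raise DegenerateGeometryError("coincident midpoint beads")
    cosang = np.clip(np.einsum("ijk,ijk->ij", u, v) / (ru * rv), -1.0, 1.0)
    ang = np.arccos(cosang)
    return ang[0] if np.asarray(chain).ndim == 2 else ang


def fan_bond_distances(frames: np.ndarray, topo: DuplexTopology,
                       which: Optional[int] = None) -> dict[int, np.ndarray]:
    """Per-offset fan-bond length samples pooled over frames and sites."""
    f = _frames(frames)
    out: dict[int, list] = {l: [] for l in (FAN_OFFSETS if which is None else [which])}
    idx = {l: [] for l in out}
    for k, fp in enumerate(topo.fan_pairs):
        if fp.l in idx:
            idx[fp.l].append((fp.i, fp.m))
    res = {}
    for l, pairs in idx.items():
        if not pairs:
            res[l] = np.zeros(0)
            continue
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        d = f[:, a, :] - f[:, b, :]
        res[l] = np.sqrt(np.einsum("ijk,ijk->ij", d, d)).ravel()
    return res


def fan_bond_histograms(samples_by_l: dict[int, np.ndarray], n_bins: int = 50,
                        rng: Optional[tuple[float, float]] = None):
    """Shared-bin histograms (density) across offsets."""
    pooled = np.concatenate([s for s in samples_by_l.values() if len(s)])
    lo, hi = rng if rng is not None else (pooled.min(), pooled.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    return {l: np.histogram(s, bins=edges, density=True)[0]
            for l, s in samples_by_l.items()}, edges


def variance_broadening(linear: dict[int, np.ndarray],
                        nucleosomal: dict[int, np.ndarray]) -> dict[int, float]:
    """Delta-variance of fan-bond lengths, bent minus linear, per offset."""
    out = {}
    for l in linear:
        if len(linear[l]) == 0 or len(nucleosomal.get(l, ())) == 0:
            raise ValueError(f"empty sample set for offset {l}")
        out[l] = float(np.var(nucleosomal[l]) - np.var(linear[l]))
    return out


# --------------------------------------------------------------------------- #
# persistence length


@dataclass
class ObservableEstimate:
    """Point estimate with a block-averaged 95% confidence half-width."""

    value: float
    ci95: float
    n_blocks: int
    block_values: np.ndarray = field(default_factory=lambda: np.zeros(0))
    flag: Optional[str] = None


def _tangent_correlation(chains: np.ndarray, stride: int):
    """Mean tangent autocorrelation versus separation.

    Tangents are unit chords between beads ``stride`` apart (smoothing out
    helical wobble); separations are in tangent-index steps.
    """
    c = _frames(chains)
    t = c[:, stride:, :] - c[:, :-stride, :]
    t /= np.linalg.norm(t, axis=2, keepdims=True)
    nt = t.shape[1]
    max_sep = nt - 1
    corr = np.empty(max_sep + 1)
    corr[0] = 1.0
    for d in range(1, max_sep + 1):
        corr[d] = float(np.mean(np.einsum("ijk,ijk->ij", t[:, :-d, :], t[:, d:, :])))
    return corr


def persistence_length(chains: np.ndarray, *, stride: int = 5,
                       fit_corr_range: tuple[float, float] = (0.3, 0.95),
                       n_blocks: int = 5) -> ObservableEstimate:
    """Persistence length of a chain ensemble by tangent-correlation decay.

    ``chains``: (n_frames, n_beads, 3) midpoint chains (use
    :func:`midpoint_chain` first for a duplex trajectory).  The decay
    <t(s).t(0)> = exp(-s/L_p) is fitted by least squares on the log of the
    mean correlation over the separations whose correlation lies in
    ``fit_corr_range``; contour length per bead is the mean bond length.
    The point estimate pools all frames; the CI comes from Student-t on
    ``n_blocks`` equal blocks of frames.
    """
    c = _frames(chains)
    if c.shape[0] < n_blocks:
        raise ValueError(f"need >= {n_blocks} frames for {n_blocks} blocks")
    b = float(np.mean(np.linalg.norm(np.diff(c, axis=1), axis=2)))

    def estimate(frames: np.ndarray) -> tuple[float, Optional[str]]:
        corr = _tangent_correlation(frames, stride)
        sep = np.arange(len(corr)) * b
        lo, hi = fit_corr_range
        window = np.flatnonzero((corr >= lo) & (corr <= hi) & (np.arange(len(corr)) > 0))
        if len(window) == 0:
            if np.all(corr > hi):
                return float("inf"), "rod-like"
            raise ValueError("no separations fall in the fit range; adjust fit_corr_range")
        cw = corr[window]
        if np.any(cw <= 0):
            raise ValueError("non-positive correlation inside the fit range")
        # delta-method weights: Var(ln C) ~ Var(C)/C^2 with Var(C) ~ (1-C^2),
        # so the noisy far tail does not dominate the slope
        wts = cw**2 / (1.0 - cw**2 + 1e-12)
        slope = np.polyfit(sep[window], np.log(cw), 1, w=np.sqrt(wts))[0]
        if slope >= 0:
            return float("inf"), "rod-like"
        return -1.0 / slope, None

    value, flag = estimate(c)
    edges = np.linspace(0, c.shape[0], n_blocks + 1).astype(int)
    blocks = []
    for k in range(n_blocks):
        bv, bflag = estimate(c[edges[k]:edges[k + 1]])
        blocks.append(bv)
    blocks = np.array(blocks)
    if flag == "rod-like" or not np.all(np.isfinite(blocks)):
        return ObservableEstimate(value=value, ci95=float("nan"),
                                  n_blocks=n_blocks, block_values=blocks,
                                  flag=flag or "rod-like")
    half = float(stats.t.ppf(0.975, n_blocks - 1) * blocks.std(ddof=1)
                 / np.sqrt(n_blocks))
    return ObservableEstimate(value=float(value), ci95=half, n_blocks=n_blocks,
                              block_values=blocks, flag=flag)


def persistence_length_duplex(frames: np.ndarray, topo: DuplexTopology,
                              **kw) -> ObservableEstimate:
    """Persistence length of a duplex trajectory via its midpoint chains."""
    return persistence_length(midpoint_chain(_frames(frames), topo), **kw)


# --------------------------------------------------------------------------- #
# distribution comparison


def kl_divergence(p_samples: np.ndarray, q_samples: np.ndarray, *,
                  n_bins: int = 50,
                  edges: Optional[np.ndarray] = None) -> float:
    """KL(p || q) over shared equal-width bins with pseudocount 1/N per bin.

    Non-negative up to pseudocount tolerance, asymmetric in its arguments.
    """
    p = np.asarray(p_samples, float).ravel()
    q = np.asarray(q_samples, float).ravel()
    if len(p) == 0 or len(q) == 0:
        raise ValueError("empty sample set")
    if edges is None:
        lo = min(p.min(), q.min())
        hi = max(p.max(), q.max())
        if hi == lo:
            hi = lo + 1e-12
        edges = np.linspace(lo, hi, n_bins + 1)
    cp = np.histogram(p, bins=edges)[0].astype(float) + 1.0 / len(p)
    cq = np.histogram(q, bins=edges)[0].astype(float) + 1.0 / len(q)
    cp /= cp.sum()
    cq /= cq.sum()
    return float(np.sum(cp * np.log(cp / cq)))


def kl_from_histograms(p: np.ndarray, q: np.ndarray) -> float:
    """KL between two explicit normalized histograms on identical bins."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def rmsd_distribution(frames: np.ndarray, reference: np.ndarray, *,
                      superpose: bool = True) -> np.ndarray:
    """Optimal-superposition RMSD of every frame to a reference structure."""
    f = _frames(frames)
    ref = np.asarray(reference, float)
    return np.array([kabsch_rmsd(fr, ref, superpose=superpose) for fr in f])
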