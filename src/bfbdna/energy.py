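"""Energy terms, analytic forces and parameter derivatives for the duplex model.

The total potential decomposes as

    V(r) = V_seqspec + V_dhelix + V_elec

* ``V_seqspec``: per-base-pair trimer potential — intra-strand Class-2 bonds
  and angles, a cross-strand Class-2 bond, four harmonic cross-strand angles
  (references theta_m on the 5' side, theta_p on the 3' side) and two cosine
  dihedrals with phases phi_m, phi_p.  Terminal pairs lacking the required
  neighbours contribute nothing.
* ``V_dhelix``: breakable fan bonds.  Each bead i interacts with the
  l = +/-1..5 neighbours of its partner through ``-k_l * exp(-U_pair)`` where
  the dimensionless exponent U_pair holds a harmonic bond plus angular and
  dihedral modulation.  The term is bounded in [-k_l, 0]: rupture costs the
  finite depth k_l and the restoring force plateaus at large extension.  The
  ``class2`` comparison mode replaces this with an unbounded polynomial in
  the pair distance, the form that produces kinked nucleosomal geometries.
* ``V_elec``: Debye-Hückel screened electrostatics over all bead pairs with
  a cutoff at a configurable number of Debye lengths (default 4, truncation
  error < e^-4 of the pair scale).

Feature extraction is batch-first: a stack of configurations is flattened to
one large "system" so every internal coordinate of every frame is computed in
a single vectorized call.  The same features serve the energy, the per-term
ledgers and the parameter gradients used by the fitting stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol

import numpy as np

from .constants import COULOMB
from .forcefield import Class2Coefficients, ForceField
from .geometry import DegenerateGeometryError, angles, dihedrals, distances
from .topology import FAN_OFFSETS, DuplexTopology

__all__ = [
    "class2",
    "seq_specific_energy",
    "bfb_energy",
    "class2_fanbond_energy",
    "debye_huckel_energy",
    "total_energy",
    "forces",
    "EnergyBreakdown",
    "CompiledDuplex",
    "Potential",
]

# trimer parameter keys, fixed order (defines the ParameterVector layout)
TRIMER_PARAM_KEYS = (
    "bi_k2", "bi_k3", "bi_k4", "bi_x0",
    "bj_k2", "bj_k3", "bj_k4", "bj_x0",
    "ai_k2", "ai_k3", "ai_k4", "ai_x0",
    "aj_k2", "aj_k3", "aj_k4", "aj_x0",
    "bc_k2", "bc_k3", "bc_k4", "bc_x0",
    "kth", "thm", "thp", "kph", "phm", "php",
)
FAN_PARAM_KEYS = ("depth", "kb", "r0", "kth", "thm", "thp", "kph", "phm", "php")

#: parameters constrained strictly positive (softplus-reparameterized in fits)
POSITIVE_TRIMER_KEYS = frozenset({"bi_k2", "bj_k2", "ai_k2", "aj_k2", "bc_k2",
                                  "bi_k4", "bj_k4", "ai_k4", "aj_k4", "bc_k4",
                                  "kth", "kph"})
POSITIVE_FAN_KEYS = frozenset({"depth", "kb", "kth", "kph"})


def class2(x, c: Class2Coefficients):
    """Class-2 polynomial: k2 d^2 + k3 d^3 + k4 d^4 with d = x - x0."""
    d = np.asarray(x, dtype=float) - c.x0
    out = c.k2 * d**2 + c.k3 * d**3 + c.k4 * d**4
    return float(out) if np.isscalar(x) else out


def _c2(x, k2, k3, k4, x0):
    d = x - x0
    return k2 * d**2 + k3 * d**3 + k4 * d**4


def _dc2_dx(x, k2, k3, k4, x0):
    d = x - x0
    return 2.0 * k2 * d + 3.0 * k3 * d**2 + 4.0 * k4 * d**3


# --------------------------------------------------------------------------- #
# parameter tables as slot-indexed arrays


def trimer_arrays(ff: ForceField) -> dict[str, np.ndarray]:
    """Trimer table as 26 arrays of shape (32,), slot-indexed in canonical
    lexicographic order."""
    from .topology import canonical_trimers

    keys = canonical_trimers()
    out = {k: np.empty(len(keys)) for k in TRIMER_PARAM_KEYS}
    for s, key in enumerate(keys):
        r = ff.trimers[key]
        for prefix, c2 in (("bi", r.bond_i), ("bj", r.bond_j),
                           ("ai", r.angle_i), ("aj", r.angle_j),
                           ("bc", r.bond_cross)):
            out[f"{prefix}_k2"][s] = c2.k2
            out[f"{prefix}_k3"][s] = c2.k3
            out[f"{prefix}_k4"][s] = c2.k4
            out[f"{prefix}_x0"][s] = c2.x0
        out["kth"][s] = r.k_theta_cross
        out["thm"][s] = r.theta_m
        out["thp"][s] = r.theta_p
        out["kph"][s] = r.k_phi
        out["phm"][s] = r.phi_m
        out["php"][s] = r.phi_p
    return out


def fan_arrays(ff: ForceField) -> dict[str, np.ndarray]:
    """Fan-bond table as arrays of shape (10,), indexed in FAN_OFFSETS order;
    the class2 comparison coefficients ride along under 'c2_*'."""
    out = {k: np.empty(len(FAN_OFFSETS)) for k in FAN_PARAM_KEYS}
    for k in ("c2_k2", "c2_k3", "c2_k4", "c2_x0"):
        out[k] = np.empty(len(FAN_OFFSETS))
    for s, l in enumerate(FAN_OFFSETS):
        r = ff.fan[l]
        out["depth"][s] = r.depth
        out["kb"][s] = r.kb
        out["r0"][s] = r.r0
        out["kth"][s] = r.k_theta
        out["thm"][s] = r.theta_m
        out["thp"][s] = r.theta_p
        out["kph"][s] = r.k_phi
        out["phm"][s] = r.phi_m
        out["php"][s] = r.phi_p
        out["c2_k2"][s] = r.class2.k2
        out["c2_k3"][s] = r.class2.k3
        out["c2_k4"][s] = r.class2.k4
        out["c2_x0"][s] = r.class2.x0
    return out


# --------------------------------------------------------------------------- #
# index bookkeeping


@dataclass
class _SiteIndex:
    """Oriented trimer-site index arrays (S,)."""

    c: np.ndarray
    cp: np.ndarray
    cs: np.ndarray
    p: np.ndarray
    pp: np.ndarray
    ps: np.ndarray
    slot: np.ndarray


@dataclass
class _FanIndex:
    """Fan-pair index arrays (P,) with masked neighbour terms.

    a1 = theta(i, m, m-1) [ref theta_m], a2 = theta(i-1, i, m) [theta_m],
    a3 = theta(i, m, m+1) [theta_p],     a4 = theta(i+1, i, m) [theta_p],
    d1 = phi(m-1, m, i, i-1) [+phi_m],   d2 = phi(m+1, m, i, i+1) [+phi_p].
    Neighbour indices are clipped in the arrays; masks mark which terms exist.
    """

    i: np.ndarray
    m: np.ndarray
    lslot: np.ndarray
    im1: np.ndarray
    ip1: np.ndarray
    mm1: np.ndarray
    mp1: np.ndarray
    mask_a1: np.ndarray
    mask_a2: np.ndarray
    mask_a3: np.ndarray
    mask_a4: np.ndarray
    mask_d1: np.ndarray
    mask_d2: np.ndarray


def _site_index(topo: DuplexTopology) -> _SiteIndex:
    idx = getattr(topo, "_site_index_cache", None)
    if idx is not None:
        return idx
    sites = topo.sites
    if sites:
        arr = np.array([[s.c, s.c_pred, s.c_succ, s.p, s.p_pred, s.p_succ, s.slot]
                        for s in sites], dtype=np.intp)
    else:
        arr = np.zeros((0, 7), dtype=np.intp)
    idx = _SiteIndex(c=arr[:, 0], cp=arr[:, 1], cs=arr[:, 2],
                     p=arr[:, 3], pp=arr[:, 4], ps=arr[:, 5], slot=arr[:, 6])
    topo._site_index_cache = idx  # type: ignore[attr-defined]
    return idx


def _fan_index(topo: DuplexTopology) -> _FanIndex:
    idx = getattr(topo, "_fan_index_cache", None)
    if idx is not None:
        return idx
    n = topo.n_bp
    lmap = {l: s for s, l in enumerate(FAN_OFFSETS)}
    rows = [(fp.i, fp.m, lmap[fp.l]) for fp in topo.fan_pairs]
    arr = np.array(rows, dtype=np.intp) if rows else np.zeros((0, 3), dtype=np.intp)
    i, m, lslot = arr[:, 0], arr[:, 1], arr[:, 2]
    has_im1 = i - 1 >= 0
    has_ip1 = i + 1 <= n - 1
    has_mm1 = m - 1 >= n
    has_mp1 = m + 1 <= 2 * n - 1
    idx = _FanIndex(
        i=i, m=m, lslot=lslot,
        im1=np.clip(i - 1, 0, None), ip1=np.clip(i + 1, 0, 2 * n - 1),
        mm1=np.clip(m - 1, 0, None), mp1=np.clip(m + 1, 0, 2 * n - 1),
        mask_a1=has_mm1, mask_a2=has_im1, mask_a3=has_mp1, mask_a4=has_ip1,
        mask_d1=has_mm1 & has_im1, mask_d2=has_mp1 & has_ip1,
    )
    topo._fan_index_cache = idx  # type: ignore[attr-defined]
    return idx


def _batchify(pos: np.ndarray, topo: DuplexTopology) -> tuple[np.ndarray, int]:
    """Flatten (n_cfg, n_beads, 3) or (n_beads, 3) into one stacked system."""
    pos = np.asarray(pos, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    if pos.shape[1] != topo.n_beads or pos.shape[2] != 3:
        raise ValueError(f"positions {pos.shape} do not match topology "
                         f"({topo.n_beads} beads)")
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite coordinates")
    return pos, pos.shape[0]


def _tile(idx: np.ndarray, n_cfg: int, n_beads: int) -> np.ndarray:
    return (idx[None, :] + (np.arange(n_cfg) * n_beads)[:, None]).ravel()


# --------------------------------------------------------------------------- #
# features


@dataclass
class SiteFeatures:
    """Internal coordinates of every trimer site in every frame; (n_cfg, S)."""

    slot: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    th1: np.ndarray
    th2: np.ndarray
    rcs: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    a3: np.ndarray
    a4: np.ndarray
    d1: np.ndarray
    d2: np.ndarray


@dataclass
class FanFeatures:
    """Internal coordinates of every fan pair in every frame; (n_cfg, P)."""

    lslot: np.ndarray
    r: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    a3: np.ndarray
    a4: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    mask_a1: np.ndarray
    mask_a2: np.ndarray
    mask_a3: np.ndarray
    mask_a4: np.ndarray
    mask_d1: np.ndarray
    mask_d2: np.ndarray


def compute_site_features(pos: np.ndarray, topo: DuplexTopology) -> SiteFeatures:
    pos, n_cfg = _batchify(pos, topo)
    si = _site_index(topo)
    nb = topo.n_beads
    flat = pos.reshape(-1, 3)
    S = len(si.c)

    def T(a):
        return _tile(a, n_cfg, nb)

    def R(x):
        return x.reshape(n_cfg, S)

    if S == 0:
        z = np.zeros((n_cfg, 0))
        return SiteFeatures(si.slot, z, z, z, z, z, z, z, z, z, z, z)
    return SiteFeatures(
        slot=si.slot,
        r1=R(distances(flat, T(si.c), T(si.cs))),
        r2=R(distances(flat, T(si.p), T(si.pp))),
        th1=R(angles(flat, T(si.cp), T(si.c), T(si.cs))),
        th2=R(angles(flat, T(si.pp), T(si.p), T(si.ps))),
        rcs=R(distances(flat, T(si.c), T(si.p))),
        a1=R(angles(flat, T(si.c), T(si.p), T(si.pp))),
        a2=R(angles(flat, T(si.cp), T(si.c), T(si.p))),
        a3=R(angles(flat, T(si.c), T(si.p), T(si.ps))),
        a4=R(angles(flat, T(si.cs), T(si.c), T(si.p))),
        d1=R(dihedrals(flat, T(si.pp), T(si.p), T(si.c), T(si.cp))),
        d2=R(dihedrals(flat, T(si.ps), T(si.p), T(si.c), T(si.cs))),
    )


def compute_fan_features(pos: np.ndarray, topo: DuplexTopology) -> FanFeatures:
    pos, n_cfg = _batchify(pos, topo)
    fi = _fan_index(topo)
    nb = topo.n_beads
    flat = pos.reshape(-1, 3)
    P = len(fi.i)

    def T(a):
        return _tile(a, n_cfg, nb)

    def masked_angle(a, b, c, mask):
        out = np.zeros((n_cfg, P))
        if mask.any():
            sel = np.flatnonzero(mask)
            out[:, sel] = angles(
                flat, _tile(a[sel], n_cfg, nb), _tile(b[sel], n_cfg, nb),
                _tile(c[sel], n_cfg, nb)).reshape(n_cfg, len(sel))
        return out

    def masked_dihedral(a, b, c, d, mask):
        out = np.zeros((n_cfg, P))
        if mask.any():
            sel = np.flatnonzero(mask)
            out[:, sel] = dihedrals(
                flat, _tile(a[sel], n_cfg, nb), _tile(b[sel], n_cfg, nb),
                _tile(c[sel], n_cfg, nb), _tile(d[sel], n_cfg, nb)).reshape(n_cfg, len(sel))
        return out

    if P == 0:
        z = np.zeros((n_cfg, 0))
        zm = np.zeros(0, dtype=bool)
        return FanFeatures(fi.lslot, z, z, z, z, z, z, z, zm, zm, zm, zm, zm, zm)
    return FanFeatures(
        lslot=fi.lslot,
        r=distances(flat, T(fi.i), T(fi.m)).reshape(n_cfg, P),
        a1=masked_angle(fi.i, fi.m, fi.mm1, fi.mask_a1),
        a2=masked_angle(fi.im1, fi.i, fi.m, fi.mask_a2),
        a3=masked_angle(fi.i, fi.m, fi.mp1, fi.mask_a3),
        a4=masked_angle(fi.ip1, fi.i, fi.m, fi.mask_a4),
        d1=masked_dihedral(fi.mm1, fi.m, fi.i, fi.im1, fi.mask_d1),
        d2=masked_dihedral(fi.mp1, fi.m, fi.i, fi.ip1, fi.mask_d2),
        mask_a1=fi.mask_a1, mask_a2=fi.mask_a2, mask_a3=fi.mask_a3,
        mask_a4=fi.mask_a4, mask_d1=fi.mask_d1, mask_d2=fi.mask_d2,
    )


# --------------------------------------------------------------------------- #
# energies from features


def seqspec_from_features(f: SiteFeatures, t: dict[str, np.ndarray]):
    """Per-site sequence-specific energies, shape (n_cfg, S)."""
    s = f.slot
    u = _c2(f.r1, t["bi_k2"][s], t["bi_k3"][s], t["bi_k4"][s], t["bi_x0"][s])
    u += _c2(f.r2, t["bj_k2"][s], t["bj_k3"][s], t["bj_k4"][s], t["bj_x0"][s])
    u += _c2(f.th1, t["ai_k2"][s], t["ai_k3"][s], t["ai_k4"][s], t["ai_x0"][s])
    u += _c2(f.th2, t["aj_k2"][s], t["aj_k3"][s], t["aj_k4"][s], t["aj_x0"][s])
    u += _c2(f.rcs, t["bc_k2"][s], t["bc_k3"][s], t["bc_k4"][s], t["bc_x0"][s])
    u += t["kth"][s] * ((f.a1 - t["thm"][s]) ** 2 + (f.a2 - t["thm"][s]) ** 2
                        + (f.a3 - t["thp"][s]) ** 2 + (f.a4 - t["thp"][s]) ** 2)
    u += t["kph"][s] * ((1.0 + np.cos(f.d1 + t["phm"][s]))
                        + (1.0 + np.cos(f.d2 + t["php"][s])))
    return u


def fan_exponent_from_features(f: FanFeatures, fa: dict[str, np.ndarray]):
    """Dimensionless exponent U_pair per fan pair, shape (n_cfg, P)."""
    s = f.lslot
    u = fa["kb"][s] * (f.r - fa["r0"][s]) ** 2
    u += fa["kth"][s] * (f.mask_a1 * (f.a1 - fa["thm"][s]) ** 2
                         + f.mask_a2 * (f.a2 - fa["thm"][s]) ** 2
                         + f.mask_a3 * (f.a3 - fa["thp"][s]) ** 2
                         + f.mask_a4 * (f.a4 - fa["thp"][s]) ** 2)
    u += fa["kph"][s] * (f.mask_d1 * (1.0 + np.cos(f.d1 + fa["phm"][s]))
                         + f.mask_d2 * (1.0 + np.cos(f.d2 + fa["php"][s])))
    return u


def fan_from_features(f: FanFeatures, fa: dict[str, np.ndarray], mode: str):
    """Per-fan-pair energies, shape (n_cfg, P)."""
    s = f.lslot
    if mode == "gaussian":
        return -fa["depth"][s] * np.exp(-fan_exponent_from_features(f, fa))
    if mode == "class2":
        return _c2(f.r, fa["c2_k2"][s], fa["c2_k3"][s], fa["c2_k4"][s], fa["c2_x0"][s])
    raise ValueError(f"unknown fan-bond mode {mode!r}")


# --------------------------------------------------------------------------- #
# electrostatics


def debye_huckel_batch(pos: np.ndarray, topo: DuplexTopology, es,
                       charges: Optional[np.ndarray] = None) -> np.ndarray:
    """Debye-Hückel energy per frame, shape (n_cfg,)."""
    pos, n_cfg = _batchify(pos, topo)
    nb = topo.n_beads
    q = np.full(nb, es.charge) if charges is None else np.asarray(charges, float)
    iu, ju = np.triu_indices(nb, k=1)
    lam = es.debye_length
    cutoff = es.cutoff_debye_lengths * lam
    d = pos[:, iu, :] - pos[:, ju, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    if np.any(r < 1e-10):
        raise DegenerateGeometryError("coincident charged beads")
    qq = q[iu] * q[ju]
    v = np.where(r < cutoff,
                 COULOMB * qq / (es.dielectric * r) * np.exp(-r / lam), 0.0)
    return v.sum(axis=1)


# --------------------------------------------------------------------------- #
# public energy API


@dataclass
class EnergyBreakdown:
    """Energy decomposition; per-term ledgers are optional."""

    v_seqspec: float
    v_dhelix: float
    v_elec: float
    site_ledger: Optional[np.ndarray] = None
    fan_ledger: Optional[np.ndarray] = None

    @property
    def v_total(self) -> float:
        return self.v_seqspec + self.v_dhelix + self.v_elec


def seq_specific_energy(pos, topo, ff, *, ledger: bool = False):
    """V_seqspec; with ``ledger=True`` also the per-site energies."""
    f = compute_site_features(pos, topo)
    per = seqspec_from_features(f, trimer_arrays(ff))
    tot = float(per.sum())
    return (tot, per[0]) if ledger else tot


def bfb_energy(pos, topo, ff, *, ledger: bool = False):
    """Breakable (Gaussian) fan-bond energy; bounded in [-sum k_l, 0]."""
    f = compute_fan_features(pos, topo)
    per = fan_from_features(f, fan_arrays(ff), "gaussian")
    tot = float(per.sum())
    return (tot, per[0]) if ledger else tot


def class2_fanbond_energy(pos, topo, ff):
    """Unbreakable polynomial fan-bond energy (comparison mode)."""
    pos_b, _ = _batchify(pos, topo)
    fi = _fan_index(topo)
    nb = topo.n_beads
    flat = pos_b.reshape(-1, 3)
    n_cfg = pos_b.shape[0]
    r = distances(flat, _tile(fi.i, n_cfg, nb), _tile(fi.m, n_cfg, nb))
    fa = fan_arrays(ff)
    s = np.tile(fi.lslot, n_cfg)
    return float(np.sum(_c2(r, fa["c2_k2"][s], fa["c2_k3"][s], fa["c2_k4"][s],
                            fa["c2_x0"][s])))


def debye_huckel_energy(pos, topo, es, charges=None) -> float:
    """Screened electrostatic energy over all bead pairs within the cutoff."""
    return float(debye_huckel_batch(pos, topo, es, charges).sum())


def total_energy(pos, topo, ff, *, charges=None, ledger: bool = False) -> EnergyBreakdown:
    """Full decomposition V = V_seqspec + V_dhelix + V_elec."""
    sf = compute_site_features(pos, topo)
    site_per = seqspec_from_features(sf, trimer_arrays(ff))
    fanf = compute_fan_features(pos, topo)
    fan_per = fan_from_features(fanf, fan_arrays(ff), ff.fanbond_mode)
    v_elec = float(debye_huckel_batch(pos, topo, ff.electrostatics, charges).sum())
    return EnergyBreakdown(
        v_seqspec=float(site_per.sum()),
        v_dhelix=float(fan_per.sum()),
        v_elec=v_elec,
        site_ledger=site_per[0] if ledger else None,
        fan_ledger=fan_per[0] if ledger else None,
    )


# --------------------------------------------------------------------------- #
# forces


class Potential(Protocol):
    """Anything the integrator can propagate."""

    def energy_forces(self, pos: np.ndarray) -> tuple[float, np.ndarray]: ...


class CompiledDuplex:
    """Duplex potential with cached index and parameter arrays.

    ``charges`` overrides the uniform per-bead charge (nucleosome mode uses
    -1 per nucleotide instead of the linear-DNA -0.6).
    """

    def __init__(self, topo: DuplexTopology, ff: ForceField,
                 charges: Optional[np.ndarray] = None,
                 excluded_volume: Optional[tuple[float, float]] = None):
        ff.validate()
        self.topo = topo
        self.ff = ff
        self.mode = ff.fanbond_mode
        self.t = trimer_arrays(ff)
        self.f = fan_arrays(ff)
        self.si = _site_index(topo)
        self.fi = _fan_index(topo)
        es = ff.electrostatics
        nb = topo.n_beads
        self.q = np.full(nb, es.charge) if charges is None else np.asarray(charges, float)
        self.iu, self.ju = np.triu_indices(nb, k=1)
        self.lam = es.debye_length
        self.cutoff = es.cutoff_debye_lengths * self.lam
        self.kappa = es.dielectric
        # optional WCA bead-bead repulsion (sigma, epsilon); off in DNA-only
        # mode, enabled for crowded fixtures such as the nucleosome wrap
        self.excluded_volume = excluded_volume

    def energy(self, pos: np.ndarray) -> float:
        return self.energy_forces(pos, want_forces=False)[0]

    def energy_forces(self, pos: np.ndarray, want_forces: bool = True):
        pos = np.asarray(pos, dtype=float)
        nb = self.topo.n_beads
        F = np.zeros((nb, 3)) if want_forces else None
        self._pend_idx: list = []
        self._pend_val: list = []
        e = 0.0
        e += self._seqspec(pos, F)
        e += self._fan(pos, F)
        e += self._elec(pos, F)
        if want_forces and self._pend_idx:
            idx = np.concatenate(self._pend_idx)
            val = np.concatenate(self._pend_val)
            for k in range(3):
                F[:, k] += np.bincount(idx, weights=val[:, k], minlength=nb)
        return e, F

    # -- internals ---------------------------------------------------------

    def _acc(self, F, idx, g, w):
        """Queue force contribution F[idx] -= w[:,None] * g (flushed once)."""
        self._pend_idx.append(idx)
        self._pend_val.append(-w[:, None] * g)

    def _seqspec(self, pos, F):
        si, t = self.si, self.t
        if len(si.c) == 0:
            return 0.0
        s = si.slot
        e = 0.0
        grad = F is not None
        # intra-strand + cross bonds
        for a, b, pref in ((si.c, si.cs, "bi"), (si.p, si.pp, "bj"), (si.c, si.p, "bc")):
            out = distances(pos, a, b, grad=grad)
            r = out[0] if grad else out
            k2, k3, k4, x0 = (t[f"{pref}_{k}"][s] for k in ("k2", "k3", "k4", "x0"))
            e += float(_c2(r, k2, k3, k4, x0).sum())
            if grad:
                du = _dc2_dx(r, k2, k3, k4, x0)
                self._acc(F, a, out[1], du)
                self._acc(F, b, -out[1], du)
        # intra-strand angles
        for a, b, c, pref in ((si.cp, si.c, si.cs, "ai"), (si.pp, si.p, si.ps, "aj")):
            out = angles(pos, a, b, c, grad=grad)
            th = out[0] if grad else out
            k2, k3, k4, x0 = (t[f"{pref}_{k}"][s] for k in ("k2", "k3", "k4", "x0"))
            e += float(_c2(th, k2, k3, k4, x0).sum())
            if grad:
                du = _dc2_dx(th, k2, k3, k4, x0)
                for idx, g in zip((a, b, c), out[1:]):
                    self._acc(F, idx, g, du)
        # cross-strand angles
        for a, b, c, ref in ((si.c, si.p, si.pp, "thm"), (si.cp, si.c, si.p, "thm"),
                             (si.c, si.p, si.ps, "thp"), (si.cs, si.c, si.p, "thp")):
            out = angles(pos, a, b, c, grad=grad)
            th = out[0] if grad else out
            dev = th - t[ref][s]
            e += float((t["kth"][s] * dev**2).sum())
            if grad:
                du = 2.0 * t["kth"][s] * dev
                for idx, g in zip((a, b, c), out[1:]):
                    self._acc(F, idx, g, du)
        # cross-strand dihedrals
        for a, b, c, d, ph in ((si.pp, si.p, si.c, si.cp, "phm"),
                               (si.ps, si.p, si.c, si.cs, "php")):
            out = dihedrals(pos, a, b, c, d, grad=grad)
            phi = out[0] if grad else out
            e += float((t["kph"][s] * (1.0 + np.cos(phi + t[ph][s]))).sum())
            if grad:
                du = -t["kph"][s] * np.sin(phi + t[ph][s])
                for idx, g in zip((a, b, c, d), out[1:]):
                    self._acc(F, idx, g, du)
        return e

    def _fan(self, pos, F):
        fi, fa = self.fi, self.f
        P = len(fi.i)
        if P == 0:
            return 0.0
        s = fi.lslot
        grad = F is not None

        if self.mode == "class2":
            out = distances(pos, fi.i, fi.m, grad=grad)
            r = out[0] if grad else out
            k2, k3, k4, x0 = fa["c2_k2"][s], fa["c2_k3"][s], fa["c2_k4"][s], fa["c2_x0"][s]
            e = float(_c2(r, k2, k3, k4, x0).sum())
            if grad:
                du = _dc2_dx(r, k2, k3, k4, x0)
                self._acc(F, fi.i, out[1], du)
                self._acc(F, fi.m, -out[1], du)
            return e

        # gaussian mode: U_pair assembled term by term, then V = -k_l exp(-U)
        u = np.zeros(P)
        terms = []  # (sel, dU/dcoord over sel, [(bead idx over sel, dcoord/dx)])
        all_sel = np.arange(P)

        out = distances(pos, fi.i, fi.m, grad=grad)
        r = out[0] if grad else out
        u += fa["kb"][s] * (r - fa["r0"][s]) ** 2
        if grad:
            du = 2.0 * fa["kb"][s] * (r - fa["r0"][s])
            terms.append((all_sel, du, [(fi.i, out[1]), (fi.m, -out[1])]))

        for a, b, c, mask, ref in (
            (fi.i, fi.m, fi.mm1, fi.mask_a1, "thm"),
            (fi.im1, fi.i, fi.m, fi.mask_a2, "thm"),
            (fi.i, fi.m, fi.mp1, fi.mask_a3, "thp"),
            (fi.ip1, fi.i, fi.m, fi.mask_a4, "thp"),
        ):
            if not mask.any():
                continue
            sel = np.flatnonzero(mask)
            out = angles(pos, a[sel], b[sel], c[sel], grad=grad)
            th = out[0] if grad else out
            dev = th - fa[ref][s[sel]]
            u[sel] += fa["kth"][s[sel]] * dev**2
            if grad:
                du = 2.0 * fa["kth"][s[sel]] * dev
                terms.append((sel, du, [(a[sel], out[1]), (b[sel], out[2]),
                                        (c[sel], out[3])]))

        for a, b, c, d, mask, ph in (
            (fi.mm1, fi.m, fi.i, fi.im1, fi.mask_d1, "phm"),
            (fi.mp1, fi.m, fi.i, fi.ip1, fi.mask_d2, "php"),
        ):
            if not mask.any():
                continue
            sel = np.flatnonzero(mask)
            out = dihedrals(pos, a[sel], b[sel], c[sel], d[sel], grad=grad)
            phi = out[0] if grad else out
            u[sel] += fa["kph"][s[sel]] * (1.0 + np.cos(phi + fa[ph][s[sel]]))
            if grad:
                du = -fa["kph"][s[sel]] * np.sin(phi + fa[ph][s[sel]])
                terms.append((sel, du, [(a[sel], out[1]), (b[sel], out[2]),
                                        (c[sel], out[3]), (d[sel], out[4])]))

        expu = np.exp(-u)
        e = float((-fa["depth"][s] * expu).sum())
        if grad:
            # force = -dV/dx with dV/dx = k_l exp(-U) dU/dq dq/dx
            w_all = fa["depth"][s] * expu
            for sel, du, pieces in terms:
                w = (w_all[sel] * du)[:, None]
                for idx, g in pieces:
                    self._pend_idx.append(idx)
                    self._pend_val.append(-w * g)
        return e

    def _elec(self, pos, F):
        d = pos[self.iu] - pos[self.ju]
        r2 = np.einsum("ij,ij->i", d, d)
        if np.any(r2 < 1e-20):
            raise DegenerateGeometryError("coincident charged beads")
        within = np.flatnonzero(r2 < self.cutoff**2)
        r = np.sqrt(r2[within])
        qq = self.q[self.iu[within]] * self.q[self.ju[within]]
        v = COULOMB * qq / (self.kappa * r) * np.exp(-r / self.lam)
        if F is not None:
            dv = -v * (1.0 / r + 1.0 / self.lam)
            g = d[within] / r[:, None]
            self._pend_idx.append(self.iu[within])
            self._pend_val.append(-dv[:, None] * g)
            self._pend_idx.append(self.ju[within])
            self._pend_val.append(dv[:, None] * g)
        e = float(v.sum())
        if self.excluded_volume is not None:
            sig, eps = self.excluded_volume
            rc2 = (sig * 2.0 ** (1.0 / 6.0)) ** 2
            close = np.flatnonzero(r2 < rc2)
            if len(close):
                rr = np.sqrt(r2[close])
                sr6 = (sig / rr) ** 6
                e += float(np.sum(4 * eps * (sr6**2 - sr6) + eps))
                if F is not None:
                    dv = 4 * eps * (-12 * sr6**2 + 6 * sr6) / rr
                    g = d[close] / rr[:, None]
                    self._pend_idx.append(self.iu[close])
                    self._pend_val.append(-dv[:, None] * g)
                    self._pend_idx.append(self.ju[close])
                    self._pend_val.append(dv[:, None] * g)
        return e


def forces(pos, topo, ff, *, charges=None) -> np.ndarray:
    """Forces -grad V, kJ/mol/nm, shape (n_beads, 3)."""
    return CompiledDuplex(topo, ff, charges=charges).energy_forces(pos)[1]


def energy_forces(pos, topo, ff, *, charges=None) -> tuple[float, np.ndarray]:
    return CompiledDuplex(topo, ff, charges=charges).energy_forces(pos)
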