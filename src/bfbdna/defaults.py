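"""Shipped default parameter set.

The defaults are a *plausibility* set, not a trained force field: equilibrium
bond lengths, angles and dihedral phases are measured from the ideal B-form
builder geometry (so an ideal duplex sits at a minimum of every bonded term),
and stiffnesses are uniform, physically reasonable magnitudes for a
one-bead-per-nucleotide model.  All 32 trimer records are identical until a
fitting run differentiates them; tests and examples either use this set or
parameters fitted on synthetic ensembles within the package itself.

Stiffness choices (kJ/mol, nm, rad):

* intra- and cross-strand bonds: k2 = 200 kJ/mol/nm^2 (thermal width
  ~0.08 nm at 300 K), k4 = 100 for a stiffer outer wall;
* strand angles: k2 = 50 kJ/mol/rad^2 (~9 deg thermal width), k4 = 25;
* cross-strand angles: 25 kJ/mol/rad^2 per angle; dihedrals 12 kJ/mol;
* fan depths k_l taper from 14 kJ/mol (|l|=1) to 6 kJ/mol (|l|=5) — a few
  k_B T per contact, ~100 kJ/mol of helical cohesion per bead in total;
* fan exponent: kb = 20 nm^-2, k_theta = 2 rad^-2, k_phi = 1 (dimensionless).

The Class-2 comparison coefficients for each fan offset match the curvature
of the Gaussian well at its minimum (k2 = depth * kb) with a quartic term of
the same magnitude, mimicking the steep unbreakable fan bonds of earlier
models.
"""

from __future__ import annotations

import numpy as np

from .forcefield import (Class2Coefficients, ElectrostaticsSettings,
                         FanOffsetRecord, ForceField, TrimerRecord)
from .topology import FAN_OFFSETS, build_duplex_topology, canonical_trimers

_FAN_DEPTH = {1: 14.0, 2: 12.0, 3: 10.0, 4: 8.0, 5: 6.0}  # kJ/mol by |l|
_FAN_KB = 20.0      # nm^-2
_FAN_KTH = 2.0      # rad^-2
_FAN_KPH = 1.0


def _wrap_pi(x: float) -> float:
    return float((x + np.pi) % (2 * np.pi) - np.pi)


def _ideal_geometry() -> dict:
    """Measure every internal coordinate of the ideal B-form helix at an
    interior site far from both ends."""
    from .dynamics import build_ideal_duplex
    from .energy import compute_fan_features, compute_site_features

    n = 31
    topo = build_duplex_topology("A" * n)
    pos = build_ideal_duplex(n)
    sf = compute_site_features(pos, topo)
    mid = len(topo.sites) // 2
    out = {k: float(getattr(sf, k)[0, mid])
           for k in ("r1", "r2", "th1", "th2", "rcs", "a1", "a2", "a3", "a4",
                     "d1", "d2")}
    ff_fan = {}
    fanf = compute_fan_features(pos, topo)
    lmap = {l: s for s, l in enumerate(FAN_OFFSETS)}
    # pick, for each offset, a pair whose centre bead is interior
    for fp_idx, fp in enumerate(topo.fan_pairs):
        if 8 <= fp.i <= n - 9 and fp.l not in ff_fan:
            ff_fan[fp.l] = {
                "r": float(fanf.r[0, fp_idx]),
                "a1": float(fanf.a1[0, fp_idx]),
                "a2": float(fanf.a2[0, fp_idx]),
                "a3": float(fanf.a3[0, fp_idx]),
                "a4": float(fanf.a4[0, fp_idx]),
                "d1": float(fanf.d1[0, fp_idx]),
                "d2": float(fanf.d2[0, fp_idx]),
            }
    out["fan"] = ff_fan
    return out


def plausibility_forcefield(*, fanbond_mode: str = "gaussian") -> ForceField:
    """Build the default parameter set (see module docstring)."""
    g = _ideal_geometry()

    def bond(x0):
        return Class2Coefficients(k2=200.0, k3=0.0, k4=100.0, x0=x0)

    def angle(x0):
        return Class2Coefficients(k2=50.0, k3=0.0, k4=25.0, x0=x0)

    rec = TrimerRecord(
        bond_i=bond(g["r1"]),
        bond_j=bond(g["r2"]),
        angle_i=angle(g["th1"]),
        angle_j=angle(g["th2"]),
        bond_cross=bond(g["rcs"]),
        k_theta_cross=25.0,
        theta_m=0.5 * (g["a1"] + g["a2"]),
        theta_p=0.5 * (g["a3"] + g["a4"]),
        k_phi=12.0,
        phi_m=_wrap_pi(np.pi - g["d1"]),   # 1 + cos(phi + phase) minimal at ideal
        phi_p=_wrap_pi(np.pi - g["d2"]),
    )
    import dataclasses

    trimers = {key: dataclasses.replace(
        rec,
        bond_i=dataclasses.replace(rec.bond_i),
        bond_j=dataclasses.replace(rec.bond_j),
        angle_i=dataclasses.replace(rec.angle_i),
        angle_j=dataclasses.replace(rec.angle_j),
        bond_cross=dataclasses.replace(rec.bond_cross),
    ) for key in canonical_trimers()}

    fan = {}
    for l in FAN_OFFSETS:
        geo = g["fan"][l]
        depth = _FAN_DEPTH[abs(l)]
        fan[l] = FanOffsetRecord(
            depth=depth,
            kb=_FAN_KB,
            r0=geo["r"],
            k_theta=_FAN_KTH,
            theta_m=0.5 * (geo["a1"] + geo["a2"]),
            theta_p=0.5 * (geo["a3"] + geo["a4"]),
            k_phi=_FAN_KPH,
            phi_m=_wrap_pi(np.pi - geo["d1"]),
            phi_p=_wrap_pi(np.pi - geo["d2"]),
            class2=Class2Coefficients(k2=depth * _FAN_KB, k3=0.0,
                                      k4=depth * _FAN_KB, x0=geo["r"]),
        )

    ff = ForceField(trimers=trimers, fan=fan,
                    electrostatics=ElectrostaticsSettings(),
                    fanbond_mode=fanbond_mode)
    ff.validate()
    return ff
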