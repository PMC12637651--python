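"""Force-field parameter containers, validation and serialization.

The energy of a configuration decomposes into three parts: a sequence-specific
term built from per-trimer bonded, angular and cross-strand interactions; a
sequence-independent double-helix term made of fan bonds between a nucleotide
and the +/-1..5 neighbours of its base-pair partner; and screened Debye-Hückel
electrostatics.  This module holds every tunable symbol of those terms.

Trimer parameters are stored once per canonical trimer (32 records); queries
for the non-canonical member of a class are served by the same record, with
the strand roles exchanged, so a sequence and its reverse complement see
identical physics.

Two fan-bond functional forms are supported:

``gaussian``
    the breakable fan bond, ``-k_l * exp(-U_pair)`` with a harmonic bond plus
    angular/dihedral modulation inside the dimensionless exponent; bounded
    below by ``-k_l``, so rupture costs a finite ``k_l``.
``class2``
    a quadratic+cubic+quartic polynomial in the pair distance, the form used
    by earlier fan-bond models; the penalty grows without bound.  Kept as a
    comparison mode for kink diagnostics.

Parameter files are plain structured text (YAML mapping with a versioned
header) and round-trip bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .topology import FAN_OFFSETS, canonical_trimer, canonical_trimers, complement

FORMAT_VERSION = 1


class ForceFieldError(ValueError):
    """Malformed, incomplete or inconsistent parameter sets."""


# --------------------------------------------------------------------------- #
# containers


@dataclass
class Class2Coefficients:
    """Polynomial stiffnesses k2, k3, k4 about the equilibrium value x0.

    U(x) = k2 (x-x0)^2 + k3 (x-x0)^3 + k4 (x-x0)^4.  k2 > 0 gives local
    stability at x0 and k4 >= 0 keeps the well bounded from below at large
    deviation; k3 encodes anharmonic asymmetry and may take either sign.
    """

    k2: float
    k3: float
    k4: float
    x0: float

    def validate(self, name: str = "class2") -> None:
        if not self.k2 > 0:
            raise ForceFieldError(f"{name}: k2 must be > 0, got {self.k2}")
        if self.k4 < 0:
            raise ForceFieldError(f"{name}: k4 must be >= 0, got {self.k4}")


@dataclass
class TrimerRecord:
    """All sequence-specific parameters of one canonical trimer.

    Roles: ``bond_i``/``angle_i`` act on the centre strand (the strand whose
    5'->3' reading of the trimer is canonical), ``bond_j``/``angle_j`` on its
    complement.  The cross-strand block couples the paired beads: a Class-2
    bond, four harmonic angles sharing the references ``theta_m`` (5'-side)
    and ``theta_p`` (3'-side), and two cosine dihedrals with phases ``phi_m``
    and ``phi_p``.
    """

    bond_i: Class2Coefficients
    bond_j: Class2Coefficients
    angle_i: Class2Coefficients
    angle_j: Class2Coefficients
    bond_cross: Class2Coefficients
    k_theta_cross: float
    theta_m: float
    theta_p: float
    k_phi: float
    phi_m: float
    phi_p: float

    def validate(self, key: str) -> None:
        for nm in ("bond_i", "bond_j", "angle_i", "angle_j", "bond_cross"):
            getattr(self, nm).validate(f"trimer {key}.{nm}")
        if self.k_theta_cross < 0:
            raise ForceFieldError(f"trimer {key}: k_theta_cross must be >= 0")
        if self.k_phi < 0:
            raise ForceFieldError(f"trimer {key}: k_phi must be >= 0")
        for nm in ("theta_m", "theta_p"):
            v = getattr(self, nm)
            if not 0.0 < v < np.pi:
                raise ForceFieldError(f"trimer {key}: {nm} must lie in (0, pi), got {v}")
        for nm in ("phi_m", "phi_p"):
            v = getattr(self, nm)
            if not -np.pi < v <= np.pi:
                raise ForceFieldError(f"trimer {key}: {nm} must lie in (-pi, pi], got {v}")


@dataclass
class FanOffsetRecord:
    """Breakable fan-bond parameters for one offset l.

    ``depth`` (k_l, kJ/mol) is the finite rupture cost.  The exponent is
    dimensionless: ``kb`` carries nm^-2, the angular and dihedral stiffnesses
    rad^-2 and 1 respectively.  ``class2`` holds the coefficients used by the
    unbreakable comparison mode (energy units, as a plain distance potential).
    """

    depth: float
    kb: float
    r0: float
    k_theta: float
    theta_m: float
    theta_p: float
    k_phi: float
    phi_m: float
    phi_p: float
    class2: Class2Coefficients

    def validate(self, l: int) -> None:
        if not self.depth > 0:
            raise ForceFieldError(f"fan l={l}: depth k_l must be > 0")
        for nm in ("kb", "k_theta", "k_phi"):
            if getattr(self, nm) < 0:
                raise ForceFieldError(f"fan l={l}: {nm} must be >= 0")
        self.class2.validate(f"fan l={l}.class2")


@dataclass
class ElectrostaticsSettings:
    """Debye-Hückel settings: per-bead charge, solvent and screening state.

    The default charge of -0.6 e per nucleotide accounts for counterion
    condensation on free linear DNA; nucleosome-mode simulations override it
    to -1.  Ionic strength is in mM (mol/m^3).
    """

    charge: float = -0.6
    ionic_strength_mM: float = 150.0
    temperature: float = 300.0
    dielectric: float = 78.5
    cutoff_debye_lengths: float = 4.0

    def validate(self) -> None:
        if self.ionic_strength_mM <= 0 or self.temperature <= 0 or self.dielectric <= 0:
            raise ForceFieldError("ionic strength, temperature, dielectric must be > 0")

    @property
    def debye_length(self) -> float:
        from .constants import debye_length

        return debye_length(self.ionic_strength_mM, self.temperature, self.dielectric)


@dataclass
class ForceField:
    """Complete parameter set: 32 trimer records, 10 fan-offset records,
    electrostatics, and the fan-bond mode flag."""

    trimers: dict[str, TrimerRecord]
    fan: dict[int, FanOffsetRecord]
    electrostatics: ElectrostaticsSettings = field(default_factory=ElectrostaticsSettings)
    fanbond_mode: str = "gaussian"

    def validate(self) -> None:
        canon = canonical_trimers()
        for key in canon:
            if key not in self.trimers:
                raise ForceFieldError(f"missing canonical trimer record: {key}")
        for key in self.trimers:
            if canonical_trimer(key) != key:
                raise ForceFieldError(
                    f"trimer table must be keyed by canonical trimers; {key} "
                    f"canonicalizes to {canonical_trimer(key)}"
                )
        for key, rec in self.trimers.items():
            rec.validate(key)
        for l in FAN_OFFSETS:
            if l not in self.fan:
                raise ForceFieldError(f"missing fan-bond record for offset l={l}")
            self.fan[l].validate(l)
        if self.fanbond_mode not in ("gaussian", "class2"):
            raise ForceFieldError(f"unknown fanbond_mode {self.fanbond_mode!r}")
        self.electrostatics.validate()

    def trimer_record(self, trimer: str) -> tuple[TrimerRecord, bool]:
        """Record for any of the 64 raw trimers.

        Returns ``(record, flipped)``: the canonical record and whether the
        query was the non-canonical member of its class, in which case the
        caller must exchange the i/j strand roles when applying it.
        """
        canon = canonical_trimer(trimer)
        return self.trimers[canon], canon != trimer.upper()

    def with_mode(self, mode: str) -> "ForceField":
        ff = copy_forcefield(self)
        ff.fanbond_mode = mode
        ff.validate()
        return ff


def expand_symmetry(ff: ForceField, trimer: str) -> TrimerRecord:
    """Effective record for a raw trimer with the strand-role swap applied.

    For the canonical member of a class the stored record is returned
    unchanged; for its reverse complement a copy with ``bond_i``/``bond_j``
    and ``angle_i``/``angle_j`` exchanged is returned (the cross-strand block
    is role-symmetric: under strand exchange the two theta_m angles swap with
    each other, as do the theta_p angles and the dihedrals).
    """
    rec, flipped = ff.trimer_record(trimer)
    if not flipped:
        return rec
    return dataclasses.replace(
        rec, bond_i=rec.bond_j, bond_j=rec.bond_i, angle_i=rec.angle_j, angle_j=rec.angle_i
    )


def copy_forcefield(ff: ForceField) -> ForceField:
    import copy

    return copy.deepcopy(ff)


# --------------------------------------------------------------------------- #
# serialization


def _c2_to_list(c: Class2Coefficients) -> list[float]:
    return [float(c.k2), float(c.k3), float(c.k4), float(c.x0)]


def _c2_from_list(v: list, name: str) -> Class2Coefficients:
    if not isinstance(v, (list, tuple)) or len(v) != 4:
        raise ForceFieldError(f"{name}: expected [k2, k3, k4, x0]")
    return Class2Coefficients(*(float(x) for x in v))


def save_forcefield(ff: ForceField, path: str | Path) -> None:
    """Write a parameter file (structured text, versioned header)."""
    ff.validate()
    doc: dict = {
        "format": "bfbdna-forcefield",
        "version": FORMAT_VERSION,
        "fanbond_mode": ff.fanbond_mode,
        "electrostatics": {
            "charge": float(ff.electrostatics.charge),
            "ionic_strength_mM": float(ff.electrostatics.ionic_strength_mM),
            "temperature": float(ff.electrostatics.temperature),
            "dielectric": float(ff.electrostatics.dielectric),
            "cutoff_debye_lengths": float(ff.electrostatics.cutoff_debye_lengths),
        },
        "trimers": {},
        "fan_bonds": {},
    }
    for key in sorted(ff.trimers):
        r = ff.trimers[key]
        doc["trimers"][key] = {
            "bond_i": _c2_to_list(r.bond_i),
            "bond_j": _c2_to_list(r.bond_j),
            "angle_i": _c2_to_list(r.angle_i),
            "angle_j": _c2_to_list(r.angle_j),
            "bond_cross": _c2_to_list(r.bond_cross),
            "k_theta_cross": float(r.k_theta_cross),
            "theta_m": float(r.theta_m),
            "theta_p": float(r.theta_p),
            "k_phi": float(r.k_phi),
            "phi_m": float(r.phi_m),
            "phi_p": float(r.phi_p),
        }
    for l in sorted(ff.fan):
        r = ff.fan[l]
        doc["fan_bonds"][int(l)] = {
            "depth": float(r.depth),
            "kb": float(r.kb),
            "r0": float(r.r0),
            "k_theta": float(r.k_theta),
            "theta_m": float(r.theta_m),
            "theta_p": float(r.theta_p),
            "k_phi": float(r.k_phi),
            "phi_m": float(r.phi_m),
            "phi_p": float(r.phi_p),
            "class2": _c2_to_list(r.class2),
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, default_flow_style=None))


def load_forcefield(path: str | Path) -> ForceField:
    """Read a parameter file; the inverse of :func:`save_forcefield`."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or doc.get("format") != "bfbdna-forcefield":
        raise ForceFieldError(f"{path}: not a bfbdna force-field file")
    if doc.get("version") != FORMAT_VERSION:
        raise ForceFieldError(f"{path}: unsupported format version {doc.get('version')}")

    raw_trimers = doc.get("trimers", {})
    trimers: dict[str, TrimerRecord] = {}
    seen_class: dict[str, str] = {}
    for key, rec in raw_trimers.items():
        canon = canonical_trimer(str(key))
        if canon in seen_class:
            raise ForceFieldError(
                f"conflicting records: {key} and {seen_class[canon]} describe the "
                f"same trimer class {canon}"
            )
        seen_class[canon] = str(key)
        trimers[canon] = TrimerRecord(
            bond_i=_c2_from_list(rec["bond_i"], f"{key}.bond_i"),
            bond_j=_c2_from_list(rec["bond_j"], f"{key}.bond_j"),
            angle_i=_c2_from_list(rec["angle_i"], f"{key}.angle_i"),
            angle_j=_c2_from_list(rec["angle_j"], f"{key}.angle_j"),
            bond_cross=_c2_from_list(rec["bond_cross"], f"{key}.bond_cross"),
            k_theta_cross=float(rec["k_theta_cross"]),
            theta_m=float(rec["theta_m"]),
            theta_p=float(rec["theta_p"]),
            k_phi=float(rec["k_phi"]),
            phi_m=float(rec["phi_m"]),
            phi_p=float(rec["phi_p"]),
        )
        # keys written non-canonically must not silently flip roles
        if str(key) != canon:
            trimers[canon] = dataclasses.replace(
                trimers[canon],
                bond_i=trimers[canon].bond_j,
                bond_j=trimers[canon].bond_i,
                angle_i=trimers[canon].angle_j,
                angle_j=trimers[canon].angle_i,
            )

    fan: dict[int, FanOffsetRecord] = {}
    for l, rec in doc.get("fan_bonds", {}).items():
        fan[int(l)] = FanOffsetRecord(
            depth=float(rec["depth"]),
            kb=float(rec["kb"]),
            r0=float(rec["r0"]),
            k_theta=float(rec["k_theta"]),
            theta_m=float(rec["theta_m"]),
            theta_p=float(rec["theta_p"]),
            k_phi=float(rec["k_phi"]),
            phi_m=float(rec["phi_m"]),
            phi_p=float(rec["phi_p"]),
            class2=_c2_from_list(rec["class2"], f"fan {l}.class2"),
        )

    es = doc.get("electrostatics", {})
    ff = ForceField(
        trimers=trimers,
        fan=fan,
        electrostatics=ElectrostaticsSettings(
            charge=float(es.get("charge", -0.6)),
            ionic_strength_mM=float(es.get("ionic_strength_mM", 150.0)),
            temperature=float(es.get("temperature", 300.0)),
            dielectric=float(es.get("dielectric", 78.5)),
            cutoff_debye_lengths=float(es.get("cutoff_debye_lengths", 4.0)),
        ),
        fanbond_mode=str(doc.get("fanbond_mode", "gaussian")),
    )
    ff.validate()
    return ff
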