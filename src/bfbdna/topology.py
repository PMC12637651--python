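"""Duplex topology: strands, Watson-Crick pairing, trimer contexts, fan pairs.

A double-stranded DNA molecule of ``n_bp`` base pairs is represented by
``2 * n_bp`` beads, one per nucleotide.  Strand A carries the input sequence
and occupies bead indices ``0 .. n_bp-1`` in 5'->3' order; strand B carries
the reverse complement and occupies ``n_bp .. 2*n_bp-1``, also stored 5'->3'
in its own frame.  With this layout the Watson-Crick partner of bead ``i`` is
``2*n_bp - 1 - i``, and the antiparallel property "if i pairs with j then
i+1 pairs with j-1" is plain index arithmetic.

Each interior base pair is assigned a trimer context: the three strand-A
bases centred on the pair.  A trimer and its reverse complement describe the
same physical motif read from the opposite strand, so the 64 raw trimers
collapse to 32 canonical classes (e.g. AGC and GCT are the same class).
Sites whose strand-A trimer is not the canonical representative are evaluated
in the flipped orientation, with the complementary strand playing the role of
the "centre" strand; this makes every energy term manifestly invariant under
relabelling the duplex by its reverse complement.

Fan pairs connect bead ``i`` to the neighbours of its partner at offsets
``l in {-5..-1, 1..5}`` along the partner strand's own 5'->3' ordering;
offsets that fall off the strand are simply absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
_VALID = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: fan-bond offsets, partner-strand steps in its own 5'->3' frame
FAN_OFFSETS: tuple[int, ...] = tuple(range(-5, 0)) + tuple(range(1, 6))


class SequenceError(ValueError):
    """Raised for sequences containing symbols outside {A, C, G, T}."""


def validate_sequence(seq: str) -> str:
    """Return the upper-cased sequence, rejecting invalid symbols by position."""
    s = str(seq).strip().upper()
    if len(s) < 1:
        raise SequenceError("empty sequence")
    for pos, base in enumerate(s):
        if base not in _VALID:
            raise SequenceError(f"invalid symbol {base!r} at position {pos}")
    return s


def complement(seq: str) -> str:
    """Reverse complement, read 5'->3'.  An involution."""
    s = validate_sequence(seq)
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def canonical_trimer(trimer: str) -> str:
    """Canonical representative of a trimer class under reverse-complement symmetry.

    Returns the lexicographically smaller of the trimer and its reverse
    complement.  Exactly 32 canonical keys exist over the 64 raw trimers
    (no trimer is its own reverse complement since the central base would
    have to be self-complementary).
    """
    t = validate_sequence(trimer)
    if len(t) != 3:
        raise SequenceError(f"trimer must have length 3, got {len(t)}")
    return min(t, complement(t))


def all_trimers() -> list[str]:
    """All 64 raw trimers in lexicographic order."""
    bases = "ACGT"
    return [a + b + c for a in bases for b in bases for c in bases]


def canonical_trimers() -> list[str]:
    """The 32 canonical trimer keys in lexicographic order."""
    return sorted({canonical_trimer(t) for t in all_trimers()})


@dataclass(frozen=True)
class OrientedSite:
    """A base-paired trimer site in its canonical orientation.

    ``c`` is the centre bead on the strand whose 5'->3' trimer reading is
    canonical; ``p`` is its Watson-Crick partner.  ``*_pred``/``*_succ`` are
    the 5'- and 3'-side neighbours within each bead's own strand frame.
    ``slot`` indexes the canonical trimer table; ``flipped`` records whether
    the orientation was reversed relative to strand A.
    """

    c: int
    c_pred: int
    c_succ: int
    p: int
    p_pred: int
    p_succ: int
    slot: int
    trimer: str
    flipped: bool


@dataclass(frozen=True)
class FanPair:
    """Fan-bond pair (i, m) at offset l: m is the l-th partner-strand neighbour."""

    i: int
    m: int
    l: int


@dataclass
class DuplexTopology:
    """Bead indexing, pairing map, trimer assignments and fan pairs for a duplex."""

    sequence: str
    n_bp: int = field(init=False)
    trimers: dict[int, str] = field(init=False)
    sites: list[OrientedSite] = field(init=False)
    fan_pairs: list[FanPair] = field(init=False)

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence)
        n = len(self.sequence)
        self.n_bp = n
        slots = {t: k for k, t in enumerate(canonical_trimers())}
        comp = complement(self.sequence)  # strand B, 5'->3'

        self.trimers = {}
        self.sites = []
        for i in range(1, n - 1):
            j = self.partner(i)
            tri_a = self.sequence[i - 1 : i + 2]
            canon = canonical_trimer(tri_a)
            self.trimers[i] = canon
            if tri_a == canon:
                site = OrientedSite(
                    c=i, c_pred=i - 1, c_succ=i + 1,
                    p=j, p_pred=j - 1, p_succ=j + 1,
                    slot=slots[canon], trimer=canon, flipped=False,
                )
            else:
                # evaluate from strand B: its local 5'->3' is increasing global
                # index, and the partner of j+1 is i-1
                site = OrientedSite(
                    c=j, c_pred=j - 1, c_succ=j + 1,
                    p=i, p_pred=i - 1, p_succ=i + 1,
                    slot=slots[canon], trimer=canon, flipped=True,
                )
            self.sites.append(site)

        self.fan_pairs = []
        for i in range(n):
            j = self.partner(i)
            for l in FAN_OFFSETS:
                m = j + l
                if n <= m < 2 * n:
                    self.fan_pairs.append(FanPair(i=i, m=m, l=l))

        # sanity: strand B sequence consistency
        assert comp == "".join(
            _COMPLEMENT[self.sequence[self.partner(b)]] for b in range(n, 2 * n)
        )

    # ------------------------------------------------------------------ #

    @property
    def n_beads(self) -> int:
        return 2 * self.n_bp

    def partner(self, i: int) -> int:
        """Watson-Crick partner index; an involution."""
        if not 0 <= i < self.n_beads:
            raise IndexError(f"bead index {i} out of range")
        return 2 * self.n_bp - 1 - i

    def strand(self, i: int) -> str:
        return "A" if i < self.n_bp else "B"

    def base(self, i: int) -> str:
        """Base identity of bead i (strand B reads the complement)."""
        if i < self.n_bp:
            return self.sequence[i]
        return _COMPLEMENT[self.sequence[self.partner(i)]]

    def fan_pairs_of(self, i: int) -> list[FanPair]:
        return [fp for fp in self.fan_pairs if fp.i == i]

    def reverse_complement(self) -> "DuplexTopology":
        return DuplexTopology(complement(self.sequence))

    # ------------------------------------------------------------------ #

    def dump(self) -> str:
        """Structured-text topology table for debugging."""
        lines = [f"# duplex {self.sequence} n_bp={self.n_bp}",
                 "# bead strand base partner trimer fan_offsets"]
        for i in range(self.n_beads):
            tri = self.trimers.get(i if i < self.n_bp else self.partner(i), "-")
            offs = ",".join(str(fp.l) for fp in self.fan_pairs_of(i)) or "-"
            lines.append(
                f"{i}\t{self.strand(i)}\t{self.base(i)}\t{self.partner(i)}\t{tri}\t{offs}"
            )
        return "\n".join(lines) + "\n"


def build_duplex_topology(seq: str) -> DuplexTopology:
    """Build the full duplex topology for a sequence (strand A, 5'->3')."""
    return DuplexTopology(seq)


def read_fasta(path: str | Path) -> str:
    """Read the first record of a FASTA file as the strand-A sequence."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return validate_sequence(str(records[0].seq))
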