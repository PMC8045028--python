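"""Sequence representation and charge assignment for histatin-like peptides.

A chain is a necklace of one bead per residue plus two explicit terminal
charge sites (the amino and carboxy termini carry their own charge but no
excluded volume).  Charges are assigned either as integers at the working
pH or as Henderson–Hasselbalch fractional charges from a pKa table.

The module also builds the arginine-content variants used to probe
arginine–phosphate interactions: R→K swaps that conserve the linear charge
density, K→A swaps that lower the net charge, and sequence shuffles.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Canonical mature histatin 5 (24 residues; 3 Arg, 4 Lys, 7 His, 1 Asp, 1 Glu).
HST5_WT = "DSHAKRHHGYKRKFHEKHHSHRGY"

#: Average molecular weight of the histatin 5 monomer, Da.
HST5_MW = 3036.3

DEFAULT_BEAD_RADIUS = 2.0  # Å

#: Side-chain / terminal pKa values used for charge assignment.  Groups with
#: pKa far from the working pH window of interest are treated as neutral and
#: are simply absent from the table; pass a custom table to override.
DEFAULT_PKA = {
    "D": 4.0,
    "E": 4.4,
    "H": 6.3,
    "K": 10.4,
    "R": 12.0,
    "NT": 8.0,
    "CT": 3.6,
}

ACIDIC = {"D", "E", "CT"}
BASIC = {"K", "R", "H", "NT"}


@dataclass(frozen=True)
class ResidueBead:
    """One coarse-grained site: an amino-acid bead or a terminal charge point.

    Terminal sites ("NT"/"CT") have zero radius — they carry charge but no
    excluded volume and sit on top of the first/last residue bead.
    """

    code: str
    radius: float
    charge: float = 0.0

    def __post_init__(self) -> None:
        if self.code in ("NT", "CT"):
            if self.radius != 0.0:
                raise ValueError("terminal charge sites are point charges (radius 0)")
        else:
            if self.code not in AMINO_ACIDS:
                raise ValueError(f"unknown residue code {self.code!r}")
            if self.radius <= 0:
                raise ValueError("bead radius must be positive")
        if abs(self.charge) > 2:
            raise ValueError("per-site charge magnitude must not exceed 2")

    @property
    def is_arginine(self) -> bool:
        return self.code == "R"


@dataclass(frozen=True)
class ChainTopology:
    """Ordered bead chain with explicit termini.

    `beads` holds the residue beads in N→C order; `n_term`/`c_term` are the
    terminal charge sites.  `bonds` is the simple path (i, i+1) over residue
    beads.  The total number of charge sites is ``len(beads) + 2``.
    """

    beads: tuple[ResidueBead, ...]
    n_term: ResidueBead
    c_term: ResidueBead
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.beads) < 2:
            raise ValueError("a chain needs at least two residues")
        if self.n_term.code != "NT" or self.c_term.code != "CT":
            raise ValueError("termini must be NT/CT sites")

    @property
    def bonds(self) -> tuple[tuple[int, int], ...]:
        return tuple((i, i + 1) for i in range(len(self.beads) - 1))

    @property
    def sequence(self) -> str:
        return "".join(b.code for b in self.beads)

    @property
    def n_charge_sites(self) -> int:
        return len(self.beads) + 2

    @property
    def net_charge(self) -> float:
        return (
            sum(b.charge for b in self.beads) + self.n_term.charge + self.c_term.charge
        )

    @property
    def arginine_count(self) -> int:
        return sum(b.is_arginine for b in self.beads)

    @property
    def arginine_positions(self) -> tuple[int, ...]:
        """0-based positions of arginine residues."""
        return tuple(i for i, b in enumerate(self.beads) if b.is_arginine)


def load_sequence(
    source: str | os.PathLike,
    name: str = "",
    bead_radius: float = DEFAULT_BEAD_RADIUS,
) -> ChainTopology:
    """Build a :class:`ChainTopology` from a raw sequence string or FASTA file.

    One bead per residue (radius `bead_radius`) plus the two terminal charge
    sites; charges are all zero until :func:`assign_charges` is applied.
    """
    seq: str
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and os.path.exists(source)
    ):
        records = list(SeqIO.parse(os.fspath(source), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {source}")
        seq = str(records[0].seq).upper()
        name = name or records[0].id
    else:
        seq = str(source).strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    for ch in seq:
        if ch not in AMINO_ACIDS:
            raise ValueError(f"unknown residue code {ch!r} in sequence")
    beads = tuple(ResidueBead(code=c, radius=bead_radius) for c in seq)
    return ChainTopology(
        beads=beads,
        n_term=ResidueBead("NT", 0.0),
        c_term=ResidueBead("CT", 0.0),
        name=name,
    )


def hst5_wild_type(bead_radius: float = DEFAULT_BEAD_RADIUS, pH: float = 8.4,
                   scheme: str = "integer") -> ChainTopology:
    """The histatin 5 wild-type chain, charged at the working pH (8.4)."""
    topo = load_sequence(HST5_WT, name="Hst5 WT", bead_radius=bead_radius)
    return assign_charges(topo, pH=pH, scheme=scheme)


def _integer_charge(code: str, pH: float, pka: dict[str, float]) -> float:
    if code in ("D", "E"):
        return -1.0
    if code in ("K", "R"):
        return 1.0
    if code == "H":
        return 1.0 if pH < pka["H"] else 0.0
    if code == "NT":
        return 1.0
    if code == "CT":
        return -1.0
    return 0.0


def _average_charge(code: str, pH: float, pka: dict[str, float]) -> float:
    if code not in pka:
        return 0.0
    if code in BASIC:
        return 1.0 / (1.0 + 10.0 ** (pH - pka[code]))
    if code in ACIDIC:
        return -1.0 / (1.0 + 10.0 ** (pka[code] - pH))
    return 0.0


def assign_charges(
    topology: ChainTopology,
    pH: float,
    scheme: str = "integer",
    pka_table: dict[str, float] | None = None,
) -> ChainTopology:
    """Return a copy of `topology` with per-site charges set at `pH`.

    ``integer``: D/E −1, K/R +1, H +1 below its pKa else 0, N-terminus +1,
    C-terminus −1.  ``average``: Henderson–Hasselbalch fractional charges
    from `pka_table` (default :data:`DEFAULT_PKA`).  Idempotent at fixed
    (pH, scheme).
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    if scheme not in ("integer", "average"):
        raise ValueError(f"unknown charge scheme {scheme!r}")
    pka = dict(DEFAULT_PKA)
    if pka_table:
        pka.update(pka_table)
    fn = _integer_charge if scheme == "integer" else _average_charge
    beads = tuple(
        dataclasses.replace(b, charge=fn(b.code, pH, pka)) for b in topology.beads
    )
    return dataclasses.replace(
        topology,
        beads=beads,
        n_term=dataclasses.replace(topology.n_term, charge=fn("NT", pH, pka)),
        c_term=dataclasses.replace(topology.c_term, charge=fn("CT", pH, pka)),
    )


# Default arginine positions retained by the reduced-Arg variants.  Hst5 WT
# has Arg at 0-based positions 5 (N-proximal), 11 (mid) and 21 (C-proximal);
# which positions a named variant keeps is configurable via `keep_positions`.
_VARIANT_DEFAULT_KEEP = {
    "0R": (),
    "1R": (11,),
    "2R": (5, 21),
    "Ra": (5,),
    "Rb": (11,),
    "Rc": (21,),
}


def make_variant(
    topology: ChainTopology,
    spec: str,
    seed: int | None = None,
    keep_positions: Sequence[int] | None = None,
    pH: float = 8.4,
    scheme: str = "integer",
) -> ChainTopology:
    """Construct a named sequence variant and re-assign charges.

    spec ∈ {"0R", "1R", "2R", "Ra", "Rb", "Rc"}: replace arginines by lysine
    except at `keep_positions` (defaults chosen per variant), preserving the
    per-position charge.  "0K": replace every lysine by alanine (lowers the
    net charge).  "shuffle": permute the residues reproducibly with `seed`.
    """
    seq = list(topology.sequence)
    radius = topology.beads[0].radius
    if spec in _VARIANT_DEFAULT_KEEP:
        keep = tuple(keep_positions) if keep_positions is not None else _VARIANT_DEFAULT_KEEP[spec]
        arg_positions = [i for i, c in enumerate(seq) if c == "R"]
        n_keep = {"0R": 0, "1R": 1, "2R": 2, "Ra": 1, "Rb": 1, "Rc": 1}[spec]
        if len(keep) != n_keep:
            raise ValueError(f"variant {spec} keeps {n_keep} Arg, got {len(keep)} positions")
        for p in keep:
            if p not in arg_positions:
                raise ValueError(f"position {p} is not an arginine in {topology.name or 'chain'}")
        for i in arg_positions:
            if i not in keep:
                seq[i] = "K"
        name = f"{topology.name or 'chain'} {spec}"
    elif spec == "0K":
        seq = ["A" if c == "K" else c for c in seq]
        name = f"{topology.name or 'chain'} 0K"
    elif spec == "shuffle":
        if seed is None:
            raise ValueError("shuffle requires a seed")
        rng = np.random.default_rng(seed)
        seq = [seq[i] for i in rng.permutation(len(seq))]
        name = f"{topology.name or 'chain'} shuffled(seed={seed})"
    else:
        raise ValueError(f"unknown variant spec {spec!r}")
    topo = load_sequence("".join(seq), name=name, bead_radius=radius)
    return assign_charges(topo, pH=pH, scheme=scheme)


def write_fasta(topology: ChainTopology, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f">{topology.name or 'chain'}\n{topology.sequence}\n")
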