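"""Register-permuted coiled-coil barrel sequence design.

Six-helix alpha-helical barrels built from an acidic (A) / basic (B)
heterohexamer use a fixed heptad signature at the helix-helix interface
positions -- g = Ser, a = Leu, d = Ile, e = Ala -- while the flanking b and c
positions carry the complementary charges (b = c = Glu on acidic chains,
b = c = Lys on basic chains).  The f positions face solvent and take
solubilising / chromophore residues.  A peptide variant is then fully
specified by its chain type, its number of heptads, the f-position residues,
and the *register*: the heptad letter occupied by the first residue.  Cyclic
permutation of the start register slides the interface signature along the
helix without changing its composition, which is the design axis this
package explores.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

REGISTERS = "abcdefg"

#: Interface signature shared by both chain types.
CORE_RULES = {"a": "L", "d": "I", "e": "A", "g": "S"}

#: b/c residue per chain type (complementary charged flanks).
FLANK_RULES = {"acidic": "E", "basic": "K"}

#: Single-character extension codes for the unnatural reporter residues:
#: 4-cyanophenylalanine (fluorophore) and selenomethionine (quencher).
#: The validator accepts them only at b, c or g positions, the substitution
#: sites used for the quenching assays; they carry no charge and no mass /
#: extinction data.
EXTENSION_CODES = {"Δ": "4CF", "Ω": "MSe"}

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Ideal alpha-helix geometry: 3.6 residues per turn puts consecutive heptad
#: positions 360 * 2 / 7 degrees apart on the helical wheel.
WHEEL_STEP_DEG = 360.0 * 2.0 / 7.0


class SequenceError(ValueError):
    """Invalid sequence-design input."""


def register_of_position(index: int, start_register: str) -> str:
    """Heptad letter at a 0-based position under cyclic a..g continuation.

    >>> register_of_position(3, "a")
    'd'
    """
    if start_register not in REGISTERS:
        raise SequenceError(
            f"start_register must be one of {REGISTERS!r}, got {start_register!r}"
        )
    if index < 0:
        raise SequenceError(f"position index must be >= 0, got {index}")
    return REGISTERS[(REGISTERS.index(start_register) + index) % 7]


@dataclass(frozen=True)
class HeptadSequence:
    """A designed barrel peptide with per-position register annotation.

    Parameters
    ----------
    residues : str
        One-letter amino-acid string (extension codes permitted).
    start_register : str
        Heptad letter (a..g) of the first residue.
    chain_type : str
        ``"acidic"`` (b = c = Glu) or ``"basic"`` (b = c = Lys).
    n_terminus, c_terminus : str
        ``"acetyl"``/``"free"`` and ``"amide"``/``"free"``.  Synthetic barrel
        peptides are capped (Ac-/-NH2) by default.
    name : str
        Optional label used in FASTA headers and reports.
    """

    residues: str
    start_register: str
    chain_type: str
    n_terminus: str = "acetyl"
    c_terminus: str = "amide"
    name: str = ""

    def __post_init__(self) -> None:
        if self.start_register not in REGISTERS:
            raise SequenceError(f"invalid start register {self.start_register!r}")
        if self.chain_type not in FLANK_RULES:
            raise SequenceError(
                f"chain_type must be 'acidic' or 'basic', got {self.chain_type!r}"
            )
        if self.n_terminus not in ("acetyl", "free"):
            raise SequenceError(f"invalid n_terminus {self.n_terminus!r}")
        if self.c_terminus not in ("amide", "free"):
            raise SequenceError(f"invalid c_terminus {self.c_terminus!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_heptads(self) -> int:
        if len(self.residues) == 0 or len(self.residues) % 7:
            raise SequenceError("sequence length not a multiple of 7")
        return len(self.residues) // 7

    @property
    def register_of(self) -> str:
        """Register letter per position, cyclic with period 7."""
        return "".join(
            register_of_position(i, self.start_register)
            for i in range(len(self.residues))
        )


def build_register_sequence(
    start_register: str,
    n_heptads: int,
    chain_type: str,
    f_residues: Sequence[str],
    *,
    n_terminus: str = "acetyl",
    c_terminus: str = "amide",
    name: str = "",
) -> HeptadSequence:
    """Construct a register-permuted barrel sequence from the position rules.

    The k-th f position (N to C) carries ``f_residues[k]``; all other
    positions follow the fixed signature (a=L, d=I, e=A, g=S, b=c=E or K).

    >>> build_register_sequence("g", 3, "acidic", "QKW").residues
    'SLEEIAQSLEEIAKSLEEIAW'
    """
    if n_heptads < 1:
        raise SequenceError(f"n_heptads must be >= 1, got {n_heptads}")
    if chain_type not in FLANK_RULES:
        raise SequenceError(f"unknown chain_type {chain_type!r}")
    if len(f_residues) != n_heptads:
        raise SequenceError(
            f"need one f residue per heptad: got {len(f_residues)} for "
            f"{n_heptads} heptads"
        )
    flank = FLANK_RULES[chain_type]
    out = []
    f_seen = 0
    for i in range(7 * n_heptads):
        reg = register_of_position(i, start_register)
        if reg == "f":
            out.append(f_residues[f_seen])
            f_seen += 1
        elif reg in "bc":
            out.append(flank)
        else:
            out.append(CORE_RULES[reg])
    return HeptadSequence(
        residues="".join(out),
        start_register=start_register,
        chain_type=chain_type,
        n_terminus=n_terminus,
        c_terminus=c_terminus,
        name=name or f"CC-Hex2-{'A' if chain_type == 'acidic' else 'B'}-"
        f"{n_heptads}-{start_register}",
    )


@dataclass
class ValidationReport:
    """Outcome of checking a sequence against the barrel design rules."""

    passed: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def validate_barrel_signature(seq: HeptadSequence) -> ValidationReport:
    """Check every position against the g/a/d/e signature and b/c charge rule.

    Report-only: one violation string per offending position.  Extension
    codes (reporter residues) are tolerated at b, c and g positions only.
    """
    violations: list[str] = []
    n = len(seq.residues)
    if n == 0 or n % 7:
        violations.append(f"length not multiple of 7 (got {n})")
        return ValidationReport(False, violations)
    flank = FLANK_RULES[seq.chain_type]
    for i, res in enumerate(seq.residues):
        reg = register_of_position(i, seq.start_register)
        if res in EXTENSION_CODES:
            if reg not in "bcg":
                violations.append(
                    f"position {i} ({reg}): extension code {res!r} only "
                    f"allowed at b, c or g sites"
                )
            continue
        if reg in CORE_RULES and res != CORE_RULES[reg]:
            violations.append(
                f"position {i} ({reg}): expected {CORE_RULES[reg]}, got {res}"
            )
        elif reg in "bc" and res != flank:
            violations.append(
                f"position {i} ({reg}): expected {flank} for {seq.chain_type} "
                f"chain, got {res}"
            )
    return ValidationReport(not violations, violations)


def helical_wheel(seq: HeptadSequence) -> list[tuple[str, str, float]]:
    """Project the sequence onto a helical wheel.

    Returns ``(residue, register, angle_deg)`` per position; consecutive
    residues are 360 * 2/7 ~ 102.857 deg apart, angles reported modulo 360
    with residue 0 at the origin.
    """
    if len(seq.residues) == 0:
        raise SequenceError("cannot project an empty sequence")
    regs = seq.register_of
    return [
        (res, regs[i], (i * WHEEL_STEP_DEG) % 360.0)
        for i, res in enumerate(seq.residues)
    ]


def net_charge(seq: HeptadSequence) -> int:
    """Formal net charge at neutral pH: count(K, R) - count(D, E).

    Acetyl/amide caps contribute nothing; free termini are also counted as
    zero under this integer convention.  Extension codes are uncharged.
    """
    charge = 0
    for i, res in enumerate(seq.residues):
        if res in "KR":
            charge += 1
        elif res in "DE":
            charge -= 1
        elif res in EXTENSION_CODES:
            continue
        elif res not in STANDARD_AA:
            raise SequenceError(f"nonstandard residue {res!r} at position {i}")
    return charge


def design_pair(
    start_register: str,
    n_heptads: int = 3,
    f_acidic: Sequence[str] = ("Q", "K", "W"),
    f_basic: Sequence[str] = ("Q", "K", "Y"),
) -> tuple[HeptadSequence, HeptadSequence]:
    """Acidic + basic chain pair for one register.

    Defaults give each chain one chromophore (Trp on the acidic chain, Tyr on
    the basic one) plus Gln and Lys at the remaining f sites.
    """
    return (
        build_register_sequence(start_register, n_heptads, "acidic", f_acidic),
        build_register_sequence(start_register, n_heptads, "basic", f_basic),
    )


def write_fasta(sequences: Iterable[HeptadSequence], path: str | Path) -> None:
    """Write designed sequences to FASTA; the header encodes name, register
    and chain type."""
    import biotite.sequence.io.fasta as fasta

    ff = fasta.FastaFile()
    for seq in sequences:
        header = (
            f"{seq.name or 'design'}|register={seq.start_register}"
            f"|chain_type={seq.chain_type}"
        )
        ff[header] = seq.residues
    ff.write(str(path))


def write_wheel_csv(seq: HeptadSequence, path: str | Path) -> None:
    """Export the helical-wheel projection as CSV (position, residue,
    register, angle_deg)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["position", "residue", "register", "angle_deg"])
        for i, (res, reg, ang) in enumerate(helical_wheel(seq)):
            w.writerow([i, res, reg, f"{ang:.6f}"])
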