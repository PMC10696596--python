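"""Monoisotopic mass arithmetic for peptides and their modifications.

Sulfotyrosine (sY, +SO3 = 79.956815 Da) and phosphotyrosine
(pY, +HPO3 = 79.966331 Da) differ by ~9.5 mDa, so every mass in this
module is computed from a hard-coded table of current NIST monoisotopic
atomic masses rather than from rounded residue constants.  All positions
are 1-based within the peptide, matching the bracket display convention
(``EDFED[sY]EFDGK``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import yaml

# Monoisotopic atomic masses (NIST/CODATA), Da.
ATOMIC_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "S": 31.97207100,
    "P": 30.97376163,
}

PROTON_MASS = 1.00727646688  # charge carrier; not the H-atom mass
WATER_MASS = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]  # 18.010565


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of a simple elemental formula, e.g. ``'C2H5NO2'``.

    Single-letter elements only (H, C, N, O, S, P); counts default to 1.
    """
    mass = 0.0
    seen = False
    for sym, count in re.findall(r"([A-Z])(\d*)", formula):
        if sym not in ATOMIC_MASS:
            raise ValueError(f"unknown element {sym!r} in formula {formula!r}")
        mass += ATOMIC_MASS[sym] * (int(count) if count else 1)
        seen = True
    if not seen and formula.strip():
        raise ValueError(f"cannot parse formula {formula!r}")
    return mass


# Residue (amino-acid minus water) elemental compositions, standard 20.
_RESIDUE_FORMULA: Mapping[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

RESIDUE_MASS: Mapping[str, float] = {
    aa: formula_mass(f) for aa, f in _RESIDUE_FORMULA.items()
}

BASIC_RESIDUES = frozenset("HKR")


@dataclass(frozen=True)
class Modification:
    """A covalent modification: mass delta, residue targets, losable neutrals.

    ``neutral_losses`` are the monoisotopic masses of neutral species the
    modified residue can shed during activation (e.g. SO3 = 79.956815 and
    H2SO4 = 97.967380 for sulfation).
    """

    name: str
    targets: frozenset[str]
    delta_mass: float
    neutral_losses: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        bound = self.delta_mass + WATER_MASS
        for nl in self.neutral_losses:
            if not (0.0 < nl <= bound + 1e-9):
                raise ValueError(
                    f"neutral loss {nl} of {self.name!r} outside (0, delta+water]"
                )


def _mod(name: str, targets: str, formula: str, nl_formulas: Sequence[str] = ()) -> Modification:
    return Modification(
        name=name,
        targets=frozenset(targets),
        delta_mass=formula_mass(formula),
        neutral_losses=tuple(formula_mass(f) for f in nl_formulas),
    )


# Registry of the variable/fixed modifications used throughout: sulfation
# and phosphorylation (the near-isobaric pair), Met oxidation,
# Cys carbamidomethylation and Asn/Gln deamidation.
MODIFICATIONS: dict[str, Modification] = {}


def register_modification(mod: Modification) -> None:
    MODIFICATIONS[mod.name] = mod


def _init_registry() -> None:
    register_modification(_mod("sulfo", "STY", "SO3", ("SO3", "H2SO4")))
    register_modification(_mod("phospho", "STY", "HPO3", ("HPO3", "H3PO4")))
    register_modification(_mod("oxidation", "MW", "O"))
    register_modification(_mod("carbamidomethyl", "C", "C2H3NO"))
    # deamidation: NH -> OH, delta = O - N - H
    register_modification(
        Modification(
            name="deamidation",
            targets=frozenset("NQ"),
            delta_mass=ATOMIC_MASS["O"] - ATOMIC_MASS["N"] - ATOMIC_MASS["H"],
        )
    )


_init_registry()

# neutral-loss species masses, shared with the discriminator
SO3_MASS = MODIFICATIONS["sulfo"].delta_mass               # 79.956815
HPO3_MASS = MODIFICATIONS["phospho"].delta_mass            # 79.966331
H2SO4_MASS = SO3_MASS + WATER_MASS                         # 97.967380
H3PO4_MASS = HPO3_MASS + WATER_MASS                        # 97.976896


def mod_delta_mass(name: str) -> float:
    """Monoisotopic mass delta of a registered modification (0.0 for none)."""
    if name in ("", "none", None):
        return 0.0
    try:
        return MODIFICATIONS[name].delta_mass
    except KeyError:
        raise KeyError(
            f"unregistered modification {name!r}; known: {sorted(MODIFICATIONS)}"
        ) from None


def load_modifications(path) -> list[Modification]:
    """Load extra modifications from a YAML config and register them.

    Each entry: ``name``, ``targets`` (residue string), and either
    ``formula`` or ``delta_mass``; optional ``neutral_losses`` as formulas
    or masses.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh) or []
    loaded = []
    for e in entries:
        if "formula" in e:
            delta = formula_mass(e["formula"])
        else:
            delta = float(e["delta_mass"])
        nls = tuple(
            formula_mass(x) if isinstance(x, str) else float(x)
            for x in e.get("neutral_losses", ())
        )
        mod = Modification(e["name"], frozenset(e["targets"]), delta, nls)
        register_modification(mod)
        loaded.append(mod)
    return loaded


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications (1-based)."""

    sequence: str
    mods: tuple[tuple[int, Modification], ...] = ()

    def __post_init__(self) -> None:
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in RESIDUE_MASS:
                raise ValueError(f"invalid residue {aa!r} at position {i}")
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        seen: set[int] = set()
        for pos, mod in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside peptide")
            if pos in seen:
                raise ValueError(f"multiple modifications at position {pos}")
            seen.add(pos)
            aa = self.sequence[pos - 1]
            if aa not in mod.targets:
                raise ValueError(
                    f"{mod.name} does not target {aa!r} (position {pos})"
                )

    @property
    def n_basic(self) -> int:
        """Count of basic residues (H/K/R); the mobile-proton reference."""
        return sum(1 for aa in self.sequence if aa in BASIC_RESIDUES)

    def mod_at(self, pos: int) -> Modification | None:
        for p, m in self.mods:
            if p == pos:
                return m
        return None

    def mod_positions(self, *names: str) -> tuple[int, ...]:
        """Positions carrying any of the named modifications (all if none given)."""
        return tuple(
            p for p, m in self.mods if not names or m.name in names
        )

    def unmodified(self) -> "ModifiedPeptide":
        return ModifiedPeptide(self.sequence)

    def __str__(self) -> str:
        return write_peptide(self)


def peptide_neutral_mass(p: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    mass = WATER_MASS + sum(RESIDUE_MASS[aa] for aa in p.sequence)
    mass += sum(mod.delta_mass for _, mod in p.mods)
    return mass


def mz_from_mass(neutral_mass: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * PROTON_MASS) / z


def mass_from_mz(mz: float, z: int) -> float:
    """Neutral mass from observed m/z and charge (inverse of mz_from_mass)."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return mz * z - z * PROTON_MASS


def ppm_window(center: float, tol_ppm: float) -> tuple[float, float]:
    """Symmetric relative mass window ``center * (1 -/+ tol*1e-6)``."""
    if center <= 0 or tol_ppm <= 0:
        raise ValueError("center and tolerance must be positive")
    return center * (1 - tol_ppm * 1e-6), center * (1 + tol_ppm * 1e-6)


def ppm_error(observed: float, expected: float) -> float:
    """Signed relative error in parts per million."""
    return (observed - expected) / expected * 1e6


# ---------------------------------------------------------------------------
# Bracket notation: "[sY]" = sulfated Tyr, "[pS]" = phospho-Ser, a residue
# followed by "[ox]"/"[cam]"/"[deam]" carries that modification, e.g.
# "D[Y]oxMGW..." style oxidation is written "DYM[ox]GW...".
# ---------------------------------------------------------------------------

_PREFIX_MODS = {"s": "sulfo", "p": "phospho"}
_SUFFIX_MODS = {"ox": "oxidation", "cam": "carbamidomethyl", "deam": "deamidation"}
_SUFFIX_FOR = {v: k for k, v in _SUFFIX_MODS.items()}

_TOKEN = re.compile(r"\[([a-z]+)([A-Z]?)\]|([A-Z])")


def parse_peptide(text: str) -> ModifiedPeptide:
    """Parse bracket notation into a :class:`ModifiedPeptide`.

    ``"EDFED[sY]EFDGK"`` -> sulfo at position 6;
    ``"DYM[ox]GWMDFGR"`` -> oxidation on the Met at position 3.
    """
    seq: list[str] = []
    mods: list[tuple[int, Modification]] = []
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.group(3):
            seq.append(m.group(3))
            continue
        tag, residue = m.group(1), m.group(2)
        if residue:  # e.g. [sY]: prefixed modification on an explicit residue
            if tag not in _PREFIX_MODS:
                raise ValueError(f"unknown modification prefix {tag!r} in {text!r}")
            seq.append(residue)
            mods.append((len(seq), MODIFICATIONS[_PREFIX_MODS[tag]]))
        else:  # e.g. K[ox]-style suffix on the preceding residue
            if tag not in _SUFFIX_MODS:
                raise ValueError(f"unknown modification tag {tag!r} in {text!r}")
            if not seq:
                raise ValueError(f"{tag!r} tag with no preceding residue in {text!r}")
            mods.append((len(seq), MODIFICATIONS[_SUFFIX_MODS[tag]]))
    covered = sum(m.end() - m.start() for m in _TOKEN.finditer(text))
    if covered != len(text):
        raise ValueError(f"unparseable characters in peptide {text!r}")
    return ModifiedPeptide("".join(seq), tuple(sorted(mods)))


def write_peptide(p: ModifiedPeptide) -> str:
    """Inverse of :func:`parse_peptide`."""
    by_pos = dict(p.mods)
    out = []
    for i, aa in enumerate(p.sequence, start=1):
        mod = by_pos.get(i)
        if mod is None:
            out.append(aa)
        elif mod.name in ("sulfo", "phospho"):
            out.append(f"[{mod.name[0]}{aa}]")
        else:
            out.append(aa + f"[{_SUFFIX_FOR.get(mod.name, mod.name)}]")
    return "".join(out)
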