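"""TMAB isotopologue mass arithmetic.

The 4-trimethylammoniumbutyryl (TMAB) tag is an amine-reactive label carrying a
fixed quaternary-ammonium charge.  Five isotopologues — D0, D3, D6, D9 (0/3/6/9
deuterium atoms) and D12 (9 deuteriums plus three 13C) — are chemically
identical but differ in mass, so up to five samples can be pooled and compared
within one LC-MS run.  Tags react with free peptide N-termini and lysine
side-chain amines (tyrosine adducts are reversed with hydroxylamine during
sample work-up and are therefore not modelled).

Everything downstream — the spectrum simulator and the peak-group detector —
shares the arithmetic in this module, so the two sides of every round-trip test
agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

from pyteomics import mass as _pmass

__all__ = [
    "TAG_NAMES",
    "TmabTag",
    "TAGS",
    "Peptide",
    "MassConstants",
    "DEFAULT_CONSTANTS",
    "ChargeDeficitError",
    "count_tmab_labels",
    "tag_mass_shift",
    "peakgroup_spacing",
    "peptide_neutral_mass",
    "theoretical_mz",
]

#: Canonical tag order, lightest to heaviest.
TAG_NAMES: Tuple[str, ...] = ("D0", "D3", "D6", "D9", "D12")

_DEUTERIUM = {"D0": 0, "D3": 3, "D6": 6, "D9": 9, "D12": 9}
_C13 = {"D0": 0, "D3": 0, "D6": 0, "D9": 0, "D12": 3}

# Exact isotope mass differences (u), from the NIST atomic mass tables that
# pyteomics also uses.
D_MINUS_H = _pmass.nist_mass["H"][2][0] - _pmass.nist_mass["H"][1][0]
C13_MINUS_C12 = _pmass.nist_mass["C"][13][0] - _pmass.nist_mass["C"][12][0]
ELECTRON_MASS = _pmass.nist_mass["e*"][0][0]
PROTON_MASS = _pmass.nist_mass["H"][1][0] - ELECTRON_MASS
WATER_MASS = _pmass.calculate_mass(formula="H2O")
ACETYL_MASS = _pmass.calculate_mass(formula="C2H2O")

#: Mass of the TMAB acyl cation (C7H14NO+) transferred to an amine: the group
#: replaces one amine hydrogen and carries the tag's fixed positive charge.
TMAB_D0_CATION_MASS = _pmass.calculate_mass(formula="C7H14NO") - ELECTRON_MASS

_STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class TmabTag:
    """One TMAB isotopologue channel."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in TAG_NAMES:
            raise ValueError(f"unknown TMAB tag {self.name!r}; expected one of {TAG_NAMES}")

    @property
    def deuterium_count(self) -> int:
        return _DEUTERIUM[self.name]

    @property
    def c13_count(self) -> int:
        return _C13[self.name]

    @property
    def index(self) -> int:
        return TAG_NAMES.index(self.name)

    @property
    def mass_shift(self) -> float:
        """Monoisotopic mass shift (Da) relative to the D0 tag."""
        return self.deuterium_count * D_MINUS_H + self.c13_count * C13_MINUS_C12


#: Ready-made tag instances keyed by name.
TAGS: Mapping[str, TmabTag] = {name: TmabTag(name) for name in TAG_NAMES}


@dataclass(frozen=True)
class Peptide:
    """An identified peptide: the unit of quantification.

    ``mods`` holds variable modifications as ``(position, mass_delta)`` pairs
    with 1-based positions (e.g. Met oxidation +15.9949, Cys cyanylation
    +24.9952); they shift the neutral mass but never the number of TMAB labels.
    """

    sequence: str
    n_term_acetylated: bool = False
    mods: Tuple[Tuple[int, float], ...] = ()
    protein_id: str | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - _STANDARD_RESIDUES
        if bad:
            raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
        object.__setattr__(self, "mods", tuple(self.mods))
        for pos, _ in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"mod position {pos} outside sequence of length {len(self.sequence)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MassConstants:
    """Physical constants used by the simulator and the detector.

    ``tag_base_mass`` is the mass of the D0 acyl cation added per label; the
    default is the elemental monoisotopic mass of C7H14NO+ (the trimethyl-
    ammoniumbutyryl group replacing one amine hydrogen, minus an electron for
    the fixed charge).  Ratio quantification does not depend on its exact
    value, but group/identity matching does, so it is configurable.
    """

    tag_base_mass: float = TMAB_D0_CATION_MASS
    proton_mass: float = PROTON_MASS
    c13_minus_c12: float = C13_MINUS_C12
    d_minus_h: float = D_MINUS_H
    water_mass: float = WATER_MASS
    acetyl_mass: float = ACETYL_MASS
    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(_pmass.std_aa_mass)
    )

    def __post_init__(self) -> None:
        for name in ("tag_base_mass", "proton_mass", "c13_minus_c12", "d_minus_h", "water_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONSTANTS = MassConstants()


class ChargeDeficitError(ValueError):
    """Raised when a charge state below the number of fixed-charge tags is requested."""


def count_tmab_labels(p: Peptide) -> int:
    """Number of TMAB labels a peptide carries.

    One label on the free N-terminal amine (none if acetylated) plus one per
    lysine side chain.  Variable modifications do not change the count.
    """
    return (0 if p.n_term_acetylated else 1) + p.sequence.count("K")


def tag_mass_shift(tag: TmabTag, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Monoisotopic mass shift of ``tag`` relative to D0, in Da."""
    return tag.deuterium_count * constants.d_minus_h + tag.c13_count * constants.c13_minus_c12


def peakgroup_spacing(
    n_labels: int,
    tag_a: TmabTag,
    tag_b: TmabTag,
    z: int,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> float:
    """m/z offset between the ``tag_a`` and ``tag_b`` channels of one peptide.

    Equal to ``n_labels * (shift_b - shift_a) / z`` and antisymmetric in the
    tag pair.  Note the D9→D12 step is three 13C (3.0101 Da), not three 2H
    (3.0188 Da): channel spacing must be computed per tag pair, never assumed
    to be a uniform 3.02 Da.
    """
    if n_labels < 1:
        raise ValueError("n_labels must be >= 1")
    if z < 1:
        raise ValueError("charge must be >= 1")
    return n_labels * (tag_mass_shift(tag_b, constants) - tag_mass_shift(tag_a, constants)) / z


def peptide_neutral_mass(p: Peptide, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Monoisotopic neutral mass of the unlabeled peptide (mods included)."""
    m = sum(constants.residue_masses[aa] for aa in p.sequence) + constants.water_mass
    m += sum(delta for _, delta in p.mods)
    if p.n_term_acetylated:
        m += constants.acetyl_mass
    return m


def theoretical_mz(
    p: Peptide,
    tag: TmabTag,
    z: int,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> float:
    """Monoisotopic m/z of the fully TMAB-labeled peptide at charge ``z``.

    Each tag contributes one fixed positive charge; the remaining
    ``z - n_labels`` charges are protons, so ``z >= n_labels`` is required
    (and ``n_labels >= 1``: an acetylated, lysine-free peptide is never
    observed as a tagged species).
    """
    n = count_tmab_labels(p)
    if n < 1:
        raise ChargeDeficitError(
            f"peptide {p.sequence!r} carries no TMAB label and is not observable as a tagged species"
        )
    if z < n:
        raise ChargeDeficitError(
            f"charge {z} below the {n} fixed-charge tags of {p.sequence!r}"
        )
    m = peptide_neutral_mass(p, constants)
    m += n * (constants.tag_base_mass + tag_mass_shift(tag, constants))
    m += (z - n) * constants.proton_mass
    return m / z
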