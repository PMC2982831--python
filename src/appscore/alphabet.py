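"""Residue alphabets, PTM variants, enzyme rules and the discretized mass grid.

Every dynamic-programming computation in this package runs on an integer
mass grid: each residue's monoisotopic mass is rounded (half-up) to the
nearest multiple of the grid resolution (default 1 Da).  An :class:`Alphabet`
couples the residue set with per-residue emission probabilities, which act
as the weights of the all-possible-peptide (APP) background ensemble.
Post-translationally modified residues are ordinary alphabet members whose
``parent_token`` points at the unmodified residue they derive from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "WATER_MONO",
    "PROTON",
    "DEFAULT_RESOLUTION",
    "STANDARD_RESIDUE_MASSES",
    "ROBINSON_ROBINSON",
    "Residue",
    "Alphabet",
    "EnzymeRule",
    "MassWindow",
    "TRYPSIN",
    "NO_ENZYME",
    "mass_to_index",
    "build_alphabet",
    "load_residue_table",
]

#: Monoisotopic mass of water; a neutral peptide weighs the sum of its
#: residue masses plus one water.
WATER_MONO = 18.010565

#: Proton mass; converts a neutral mass M to the singly protonated MH+.
PROTON = 1.007276

#: Default mass-grid width, Da per grid unit.  Slightly above 1 Da to
#: compensate the average mass defect of peptide fragments, so that rounded
#: residue masses accumulate with near-zero-mean error along a peptide.
DEFAULT_RESOLUTION = 1.0005079

#: Monoisotopic residue (amino-acid minus water) masses, Da.
STANDARD_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Robinson–Robinson amino-acid background frequencies.  I and L share a
#: mass but stay distinct tokens with their own frequencies.
ROBINSON_ROBINSON: dict[str, float] = {
    "A": 0.078,
    "R": 0.051,
    "N": 0.045,
    "D": 0.053,
    "C": 0.019,
    "Q": 0.042,
    "E": 0.063,
    "G": 0.072,
    "H": 0.022,
    "I": 0.053,
    "L": 0.091,
    "K": 0.059,
    "M": 0.022,
    "F": 0.039,
    "P": 0.052,
    "S": 0.068,
    "T": 0.059,
    "W": 0.014,
    "Y": 0.032,
    "V": 0.066,
}


def mass_to_index(mass: float, resolution: float = 1.0) -> int:
    """Map a non-negative mass (Da) to its grid index, rounding half-up.

    Half-up ties make the mapping deterministic and monotone:
    ``mass_to_index(128.5, 1.0) == 129``.
    """
    if mass < 0:
        raise ValueError(f"mass must be non-negative, got {mass!r}")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return int(math.floor(mass / resolution + 0.5))


@dataclass(frozen=True)
class Residue:
    """One alphabet member: a standard residue or a PTM variant of one."""

    token: str
    monoisotopic_mass: float
    grid_mass: int
    emission_probability: float
    parent_token: str

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"non-positive mass for residue {self.token!r}")
        if not 0.0 <= self.emission_probability <= 1.0:
            raise ValueError(
                f"emission probability of {self.token!r} outside [0, 1]"
            )

    @property
    def is_modified(self) -> bool:
        return self.parent_token != self.token


@dataclass(frozen=True)
class Alphabet:
    """Residue set plus the mass-grid resolution (Da per grid unit)."""

    residues: tuple[Residue, ...]
    resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        tokens = [r.token for r in self.residues]
        if len(tokens) != len(set(tokens)):
            raise ValueError("duplicate residue tokens in alphabet")
        total = sum(r.emission_probability for r in self.residues)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"emission probabilities sum to {total!r}, expected 1"
            )

    def __iter__(self):
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def by_token(self) -> dict[str, Residue]:
        return {r.token: r for r in self.residues}

    def mass(self, token: str) -> float:
        return self.by_token[token].monoisotopic_mass

    def grid_mass(self, token: str) -> int:
        return self.by_token[token].grid_mass

    def emission_probability(self, token: str) -> float:
        return self.by_token[token].emission_probability

    @property
    def min_grid_mass(self) -> int:
        return min(r.grid_mass for r in self.residues)

    @property
    def max_grid_mass(self) -> int:
        return max(r.grid_mass for r in self.residues)

    def peptide_mass(self, peptide) -> float:
        """Neutral monoisotopic mass of a token sequence (adds one water)."""
        table = self.by_token
        return sum(table[t].monoisotopic_mass for t in peptide) + WATER_MONO

    def peptide_grid_mass(self, peptide) -> int:
        """Sum of rounded residue grid masses (the DP mass coordinate)."""
        table = self.by_token
        return sum(table[t].grid_mass for t in peptide)

    def with_frequencies(self, frequencies: dict[str, float]) -> "Alphabet":
        """Same residues, new emission probabilities (renormalized)."""
        total = sum(frequencies.get(r.token, 0.0) for r in self.residues)
        if total <= 0:
            raise ValueError("frequencies must have positive total mass")
        residues = tuple(
            Residue(
                token=r.token,
                monoisotopic_mass=r.monoisotopic_mass,
                grid_mass=r.grid_mass,
                emission_probability=frequencies.get(r.token, 0.0) / total,
                parent_token=r.parent_token,
            )
            for r in self.residues
        )
        return Alphabet(residues=residues, resolution=self.resolution)


@dataclass(frozen=True)
class EnzymeRule:
    """C-terminal cleavage constraint applied to the APP ensemble.

    Inside the APP dynamic programming only the C-terminus is constrainable
    (an all-possible-peptide has no N-terminal protein context), so the rule
    restricts the final DP transition to residues whose parent token is in
    ``cterm_residues``.
    """

    name: str
    cterm_residues: frozenset[str] = frozenset()
    none_flag: bool = False

    def allows_cterm(self, residue: Residue) -> bool:
        if self.none_flag:
            return True
        return residue.parent_token in self.cterm_residues


TRYPSIN = EnzymeRule("trypsin", frozenset({"K", "R"}), False)
NO_ENZYME = EnzymeRule("none", frozenset(), True)


@dataclass(frozen=True)
class MassWindow:
    """Parent-mass acceptance window on the residue-mass grid axis.

    ``center_mass`` is the neutral peptide mass M; peptides qualify when
    their mass lies in [M − tolerance, M + tolerance].  The grid indices are
    expressed on the residue-mass axis (water subtracted), because the DP
    propagates sums of residue masses.
    """

    center_mass: float
    tolerance: float
    resolution: float = DEFAULT_RESOLUTION
    lo_index: int = field(init=False)
    hi_index: int = field(init=False)

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        lo = max(0.0, self.center_mass - self.tolerance - WATER_MONO)
        hi = max(0.0, self.center_mass + self.tolerance - WATER_MONO)
        object.__setattr__(self, "lo_index", mass_to_index(lo, self.resolution))
        object.__setattr__(self, "hi_index", mass_to_index(hi, self.resolution))
        if self.lo_index > self.hi_index:
            raise ValueError("empty mass window")

    @classmethod
    def from_grid(cls, lo_index: int, hi_index: int,
                  resolution: float = DEFAULT_RESOLUTION):
        """Window specified directly by residue-mass grid indices."""
        center = 0.5 * (lo_index + hi_index) * resolution + WATER_MONO
        tol = 0.5 * (hi_index - lo_index) * resolution
        win = cls(center_mass=center, tolerance=tol, resolution=resolution)
        # Re-pin the indices exactly (rounding of center could shift by one).
        object.__setattr__(win, "lo_index", lo_index)
        object.__setattr__(win, "hi_index", hi_index)
        return win

    @property
    def mass_lo(self) -> float:
        return self.center_mass - self.tolerance

    @property
    def mass_hi(self) -> float:
        return self.center_mass + self.tolerance


def build_alphabet(
    residue_table: dict[str, float] | None = None,
    frequencies: dict[str, float] | None = None,
    resolution: float = DEFAULT_RESOLUTION,
    parents: dict[str, str] | None = None,
) -> Alphabet:
    """Assemble an :class:`Alphabet` from mass and frequency tables.

    With no arguments, returns the 20 standard residues at their
    monoisotopic masses with Robinson–Robinson frequencies on a 1-Da grid.
    Frequencies are renormalized to sum exactly to 1.  ``parents`` maps PTM
    variant tokens to their unmodified residue (absent tokens parent
    themselves).
    """
    if residue_table is None:
        residue_table = dict(STANDARD_RESIDUE_MASSES)
    if frequencies is None:
        frequencies = {
            t: ROBINSON_ROBINSON.get(t, 0.0) for t in residue_table
        }
    parents = parents or {}
    missing = set(residue_table) - set(frequencies)
    if missing:
        raise ValueError(f"no frequency given for residues {sorted(missing)}")
    total = sum(frequencies[t] for t in residue_table)
    if total <= 0:
        raise ValueError("frequencies must have positive total mass")
    residues = []
    for token, mass in residue_table.items():
        if mass <= 0:
            raise ValueError(f"non-positive mass for residue {token!r}")
        residues.append(
            Residue(
                token=token,
                monoisotopic_mass=float(mass),
                grid_mass=mass_to_index(mass, resolution),
                emission_probability=frequencies[token] / total,
                parent_token=parents.get(token, token),
            )
        )
    return Alphabet(residues=tuple(residues), resolution=resolution)


def load_residue_table(path) -> tuple[dict, dict, dict]:
    """Read a residue/PTM config TSV: token, mass, frequency[, parent].

    Returns ``(residue_table, frequencies, parents)`` suitable for
    :func:`build_alphabet`.  Lines starting with '#' are skipped.
    """
    residue_table: dict[str, float] = {}
    frequencies: dict[str, float] = {}
    parents: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed residue table line: {line!r}")
            token, mass, freq = parts[0], float(parts[1]), float(parts[2])
            residue_table[token] = mass
            frequencies[token] = freq
            if len(parts) >= 4 and parts[3]:
                parents[token] = parts[3]
    return residue_table, frequencies, parents
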