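"""Tryptic in-silico digestion and monoisotopic peptide masses.

Digestion follows the constraints used for the database searches that this
pipeline feeds: tryptic specificity with up to 2 missed cleavages, peptide
length 7-50 residues and monoisotopic mass 500-5000 Da. Two cleavage rules
are provided: ``trypsin_p`` (cleave after K/R, including before proline)
and ``trypsin_strict`` (no cleavage before proline); which one a search
used is a configuration matter, so both are explicit.

Masses are monoisotopic residue masses (pyteomics values) plus water, plus
any fixed-modification deltas (default: carbamidomethylation of cysteine,
+57.02146 Da, matching the alkylation chemistry of the sample preparation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from pyteomics import mass as _ptmass

WATER_MONO = 18.0105646863
CARBAMIDOMETHYL = 57.02146

__all__ = [
    "WATER_MONO",
    "CARBAMIDOMETHYL",
    "DigestConfig",
    "ResidueMassTable",
    "Peptide",
    "default_mass_table",
    "digest",
    "peptide_mass",
    "residue_delta",
    "theoretical_peptide_count",
]


@dataclass(frozen=True)
class DigestConfig:
    enzyme: str = "trypsin_p"  # or "trypsin_strict"
    max_missed: int = 2
    min_len: int = 7
    max_len: int = 50
    min_mass: float = 500.0
    max_mass: float = 5000.0

    def __post_init__(self):
        if self.enzyme not in ("trypsin_p", "trypsin_strict"):
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses plus fixed-modification deltas."""

    masses: Mapping[str, float]
    fixed_mods: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.masses)
        if missing:
            raise ValueError(f"mass table missing residues {sorted(missing)}")
        if any(m <= 0 for m in self.masses.values()):
            raise ValueError("residue masses must be positive")

    def residue_mass(self, aa: str) -> float:
        return self.masses[aa] + self.fixed_mods.get(aa, 0.0)


def default_mass_table(carbamidomethyl_c: bool = True) -> ResidueMassTable:
    masses = {aa: _ptmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}
    fixed = {"C": CARBAMIDOMETHYL} if carbamidomethyl_c else {}
    return ResidueMassTable(masses, fixed)


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide located within its parent protein (1-based, inclusive)."""

    sequence: str
    protein_label: str
    start: int
    end: int
    missed_cleavages: int
    monoisotopic_mass: float

    def covers(self, residue_index: int) -> bool:
        return self.start <= residue_index <= self.end


def peptide_mass(sequence: str, table: ResidueMassTable | None = None) -> float:
    """Monoisotopic peptide mass: residue masses + water + fixed mods."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    if table is None:
        table = default_mass_table()
    total = WATER_MONO
    for i, aa in enumerate(sequence, start=1):
        if aa not in table.masses:
            raise ValueError(f"unknown residue {aa!r} at position {i}")
        total += table.residue_mass(aa)
    return total


def residue_delta(
    from_aa: str, to_aa: str, table: ResidueMassTable | None = None
) -> float:
    """Monoisotopic mass change of the substitution ``from_aa -> to_aa``."""
    if table is None:
        table = default_mass_table()
    return table.residue_mass(to_aa) - table.residue_mass(from_aa)


def cleavage_boundaries(protein: str, enzyme: str) -> list[int]:
    """0-based boundary indices: a cut occurs between i-1 and i for each i.

    Includes 0 and len(protein) so consecutive boundaries delimit the base
    fragments of a complete digest.
    """
    cuts = [0]
    for i in range(1, len(protein)):
        if protein[i - 1] in "KR":
            if enzyme == "trypsin_strict" and protein[i] == "P":
                continue
            cuts.append(i)
    cuts.append(len(protein))
    return cuts


def digest(
    protein: str,
    protein_label: str = "",
    config: DigestConfig | None = None,
    table: ResidueMassTable | None = None,
) -> list[Peptide]:
    """Tryptic digest with missed cleavages and length/mass filters.

    Peptides are the maximal fragments between cleavage points plus
    concatenations of up to ``max_missed`` adjacent fragments; the length
    and mass filters are applied last. Output is ordered by (start, end).
    """
    if not protein:
        raise ValueError("empty protein")
    if config is None:
        config = DigestConfig()
    if table is None:
        table = default_mass_table()
    for i, aa in enumerate(protein, start=1):
        if aa not in table.masses:
            raise ValueError(f"unknown residue {aa!r} at position {i}")
    bounds = cleavage_boundaries(protein, config.enzyme)
    out: list[Peptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for missed in range(min(config.max_missed, n_frag - 1 - i) + 1):
            start, end = bounds[i], bounds[i + missed + 1]
            seq = protein[start:end]
            if not config.min_len <= len(seq) <= config.max_len:
                continue
            m = peptide_mass(seq, table)
            if not config.min_mass <= m <= config.max_mass:
                continue
            out.append(
                Peptide(seq, protein_label, start + 1, end, missed, m)
            )
    out.sort(key=lambda p: (p.start, p.end))
    return out


def theoretical_peptide_count(
    protein: str,
    config: DigestConfig | None = None,
    max_missed: int = 0,
) -> int:
    """Number of theoretically observable fully-tryptic peptides.

    Used as the iBAQ denominator: fully tryptic peptides with at most
    ``max_missed`` (default 0) missed cleavages inside the configured
    length window. The mass filter is not applied here.
    """
    if config is None:
        config = DigestConfig()
    wide = DigestConfig(
        enzyme=config.enzyme,
        max_missed=max_missed,
        min_len=config.min_len,
        max_len=config.max_len,
        min_mass=0.0,
        max_mass=float("inf"),
    )
    return len(digest(protein, config=wide))
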