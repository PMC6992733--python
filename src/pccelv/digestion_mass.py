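"""In-silico tryptic digestion and peptide / fragment mass arithmetic.

Trypsin cleaves C-terminal to K or R except when the next residue is
proline.  A *semi-tryptic* peptide has one terminus produced by trypsin and
the other by a biological cleavage event; detecting such a peptide (e.g.
the polycystin-1 GPS product ``TAFGASLFVPPSHVR``) is direct evidence of in
vivo proteolysis, which is why this module is the verification arm of the
cleavage analysis.

Monoisotopic masses are used for m/z (mass spectrometers resolve isotopes);
average masses are used for gel-scale kDa arithmetic (SDS-PAGE measures the
isotope-averaged ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from .sequence_model import (
    CANONICAL_RESIDUES,
    CleavageSite,
    GlycanAnnotation,
    ProteinRecord,
    SequenceError,
)

__all__ = [
    "Peptide",
    "PeptideMass",
    "MONOISOTOPIC",
    "AVERAGE",
    "WATER_MONO",
    "WATER_AVG",
    "PROTON",
    "tryptic_boundaries",
    "digest",
    "semi_tryptic_products",
    "peptide_mass",
    "mz",
    "fragment_mass",
]

# Residue (amino-acid *residue*, i.e. minus water) masses in Da.
MONOISOTOPIC = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MONO = 18.010565
WATER_AVG = 18.0153
PROTON = 1.007276
#: Mass added by carbamidomethylation of cysteine (iodoacetamide alkylation).
CARBAMIDOMETHYL_MONO = 57.02146
CARBAMIDOMETHYL_AVG = 57.0519


@dataclass(frozen=True)
class PeptideMass:
    monoisotopic_Da: float
    average_Da: float


@dataclass(frozen=True)
class Peptide:
    """A (semi-)tryptic subsequence with 1-based inclusive coordinates."""

    protein_id: str
    sequence: str
    start: int
    stop: int
    missed_cleavages: int = 0
    termini: str = "fully_tryptic"  # or semi_tryptic_N / semi_tryptic_C

    def __post_init__(self) -> None:
        if self.stop - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"peptide {self.sequence!r}: stop - start + 1 != length "
                f"({self.start}..{self.stop})"
            )
        if self.termini not in ("fully_tryptic", "semi_tryptic_N", "semi_tryptic_C"):
            raise ValueError(f"unknown termini flag {self.termini!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def peptide_mass(sequence: str, *, carbamidomethyl: bool = False) -> PeptideMass:
    """Monoisotopic and average mass of a peptide (residue sum + water).

    ``carbamidomethyl`` adds the fixed Cys alkylation mass; off by default
    (no fixed modifications are assumed).
    """
    if not sequence:
        raise SequenceError("cannot compute the mass of an empty peptide")
    mono = WATER_MONO
    avg = WATER_AVG
    for i, aa in enumerate(sequence, start=1):
        if aa not in CANONICAL_RESIDUES:
            raise SequenceError(f"non-canonical residue {aa!r} at position {i}")
        mono += MONOISOTOPIC[aa]
        avg += AVERAGE[aa]
        if carbamidomethyl and aa == "C":
            mono += CARBAMIDOMETHYL_MONO
            avg += CARBAMIDOMETHYL_AVG
    return PeptideMass(monoisotopic_Da=mono, average_Da=avg)


def mz(mass: PeptideMass | float, charge: int) -> float:
    """m/z of the ``[M + charge*H]^{charge+}`` ion, full precision.

    Round to two decimals for display, e.g. ``round(mz(m, 2), 2)``.
    """
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    mono = mass.monoisotopic_Da if isinstance(mass, PeptideMass) else float(mass)
    return (mono + charge * PROTON) / charge


@lru_cache(maxsize=256)
def tryptic_boundaries(sequence: str) -> tuple[int, ...]:
    """1-based stop positions of fully tryptic peptides (including C-terminus).

    A boundary at ``p`` means trypsin cuts between residues ``p`` and
    ``p + 1`` (K/R at ``p`` not followed by P), plus the protein C-terminus.
    """
    cuts = [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    cuts.append(len(sequence))
    return tuple(cuts)


def _mass_in_range(seq: str, mass_range: tuple[float, float] | None) -> bool:
    if mass_range is None:
        return True
    lo, hi = mass_range
    return lo <= peptide_mass(seq).monoisotopic_Da <= hi


def digest(
    protein: ProteinRecord,
    max_missed: int = 2,
    mass_range: tuple[float, float] | None = None,
) -> list[Peptide]:
    """All fully tryptic peptides with at most ``max_missed`` missed cleavages.

    ``mass_range`` optionally filters to a monoisotopic detectability window
    (e.g. ``(700, 4000)`` Da for a typical LC-MS/MS setup).  Peptides are
    returned sorted by start, then stop.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = tryptic_boundaries(protein.sequence)
    starts = (1,) + tuple(b + 1 for b in bounds[:-1])
    peptides = []
    for i, start in enumerate(starts):
        for k in range(max_missed + 1):
            if i + k >= len(bounds):
                break
            stop = bounds[i + k]
            seq = protein.sequence[start - 1 : stop]
            if _mass_in_range(seq, mass_range):
                peptides.append(
                    Peptide(
                        protein_id=protein.id,
                        sequence=seq,
                        start=start,
                        stop=stop,
                        missed_cleavages=k,
                    )
                )
    peptides.sort(key=lambda p: (p.start, p.stop))
    return peptides


def semi_tryptic_products(
    protein: ProteinRecord,
    sites: Sequence[CleavageSite],
    max_missed: int = 0,
) -> list[Peptide]:
    """Peptides whose non-tryptic terminus is a biological cleavage site.

    For a site at ``p`` this emits, per missed-cleavage count up to
    ``max_missed``:

    * the product starting at ``p + 1`` and ending at the following tryptic
      boundaries (``semi_tryptic_N``: the N-terminus is non-tryptic), and
    * the product ending at ``p`` and starting after the preceding tryptic
      boundaries (``semi_tryptic_C``).

    When the site coincides with a tryptic boundary the products are
    ordinary tryptic peptides and are flagged ``fully_tryptic``.  A site at
    the protein terminus simply yields no product on the empty side.
    """
    bounds = tryptic_boundaries(protein.sequence)
    out: list[Peptide] = []
    for site in sites:
        p = site.position
        if not (1 <= p < protein.length):
            raise ValueError(
                f"cleavage site {p} out of range for {protein.id} "
                f"(length {protein.length})"
            )
        site_is_tryptic = p in bounds
        # C-terminal side product(s): start at p+1, end at next boundaries.
        following = [b for b in bounds if b > p]
        for k in range(min(max_missed + 1, len(following))):
            stop = following[k]
            out.append(
                Peptide(
                    protein_id=protein.id,
                    sequence=protein.sequence[p : stop],
                    start=p + 1,
                    stop=stop,
                    missed_cleavages=k,
                    termini="fully_tryptic" if site_is_tryptic else "semi_tryptic_N",
                )
            )
        # N-terminal side product(s): end at p, start after previous boundaries.
        preceding = [b for b in bounds if b < p]
        prev_starts = [1] + [b + 1 for b in preceding]
        for k in range(min(max_missed + 1, len(prev_starts))):
            start = prev_starts[len(prev_starts) - 1 - k]
            out.append(
                Peptide(
                    protein_id=protein.id,
                    sequence=protein.sequence[start - 1 : p],
                    start=start,
                    stop=p,
                    missed_cleavages=k,
                    termini="fully_tryptic" if site_is_tryptic else "semi_tryptic_C",
                )
            )
    out.sort(key=lambda pep: (pep.start, pep.stop))
    return out


def fragment_mass(
    protein: ProteinRecord,
    start: int,
    stop: int,
    glycans: Iterable[GlycanAnnotation] = (),
    deglyc: str = "none",
) -> float:
    """Average mass in kDa of residues ``start..stop`` plus surviving glycans.

    ``deglyc`` selects the enzymatic treatment: ``"none"`` keeps every
    glycan, ``"endoH"`` removes Endo H sensitive (high-mannose) chains only,
    and ``"pngaseF"`` removes all N-linked chains.  Only glycans whose
    sequon lies inside the range contribute.
    """
    if deglyc not in ("none", "endoH", "pngaseF"):
        raise ValueError(f"unknown deglycosylation treatment {deglyc!r}")
    seq = protein.subsequence(start, stop)
    mass_da = WATER_AVG + sum(AVERAGE[aa] for aa in seq)
    mass = mass_da / 1000.0
    for g in glycans:
        if not (start <= g.sequon_position <= stop):
            continue
        removed = deglyc == "pngaseF" or (
            deglyc == "endoH" and g.state == "endoH_sensitive"
        )
        if not removed:
            mass += g.mass_kDa
    return mass
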