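"""Protein sequences, feature annotations and sequon scanning.

This module is the shared coordinate frame for the whole pipeline.  All
residue coordinates are **1-based and inclusive**, matching the way ranges
such as ``3049..4302`` are written in the membrane-protein literature.  A
cleavage site at position ``p`` means the peptide bond between residues
``p`` and ``p + 1`` is hydrolysed: the N-terminal product is ``[1..p]`` and
the C-terminal product ``[p+1..length]``.  For example the GPS/GAIN
autoproteolysis of polycystin-1 (the ``HL|T`` site, with the T starting the
C-terminal fragment at 3049) is represented as a :class:`CleavageSite` at
position 3048.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO

__all__ = [
    "CANONICAL_RESIDUES",
    "ProteinRecord",
    "ProteinFeature",
    "CleavageSite",
    "GlycanAnnotation",
    "ProteinAnnotations",
    "FEATURE_KINDS",
    "GLYCAN_STATES",
    "read_fasta",
    "load_features",
    "save_features",
    "find_sequons",
]

#: The 20 canonical amino acids.  Ambiguity/rare codes (B, J, O, U, X, Z)
#: are rejected: peptide and fragment masses would be undefined for them.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

FEATURE_KINDS = ("TM", "signal_peptide", "coiled_coil", "sequon",
                 "annotated_cleavage", "domain")
GLYCAN_STATES = ("endoH_sensitive", "mature")


class SequenceError(ValueError):
    """Invalid sequence content or malformed sequence input."""


class FeatureError(ValueError):
    """Feature annotation inconsistent with its protein."""


def _validate_sequence(seq: str, *, context: str = "") -> None:
    if not seq:
        raise SequenceError(f"empty sequence{' for ' + context if context else ''}")
    for i, aa in enumerate(seq, start=1):
        if aa not in CANONICAL_RESIDUES:
            raise SequenceError(
                f"non-canonical residue {aa!r} at position {i}"
                f"{' in ' + context if context else ''}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an accession-like id and a free-text name."""

    id: str
    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        _validate_sequence(self.sequence, context=self.id)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, stop: int) -> str:
        """Residues ``start..stop`` (1-based, inclusive)."""
        if not (1 <= start <= stop <= self.length):
            raise FeatureError(
                f"range {start}..{stop} outside protein {self.id} "
                f"(length {self.length})"
            )
        return self.sequence[start - 1 : stop]


@dataclass(frozen=True)
class ProteinFeature:
    kind: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise FeatureError(
                f"unknown feature kind {self.kind!r}; expected one of {FEATURE_KINDS}"
            )
        if not (1 <= self.start <= self.end):
            raise FeatureError(
                f"feature {self.label or self.kind}: need 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class CleavageSite:
    """Position of the *last* residue of the N-terminal cleavage product."""

    position: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FeatureError(f"cleavage position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class GlycanAnnotation:
    """An occupied N-glycosylation sequon and the mass of its glycan.

    ``endoH_sensitive`` glycans are ER-type high-mannose chains removed by
    both Endo H and PNGase F; ``mature`` (complex, post-Golgi) chains are
    removed by PNGase F only.
    """

    sequon_position: int
    state: str
    mass_kDa: float

    def __post_init__(self) -> None:
        if self.state not in GLYCAN_STATES:
            raise FeatureError(
                f"unknown glycan state {self.state!r}; expected one of {GLYCAN_STATES}"
            )
        if self.mass_kDa < 0:
            raise FeatureError(f"glycan mass must be >= 0, got {self.mass_kDa}")


@dataclass
class ProteinAnnotations:
    """Features, glycans and annotated cleavage sites for one protein."""

    features: list[ProteinFeature] = field(default_factory=list)
    glycans: list[GlycanAnnotation] = field(default_factory=list)
    cleavage_sites: list[CleavageSite] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[ProteinFeature]:
        return [f for f in self.features if f.kind == kind]

    @property
    def tm_count(self) -> int:
        return len(self.of_kind("TM"))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (multi-record) FASTA file into :class:`ProteinRecord` objects.

    The first whitespace-separated token of the description becomes the id,
    the remainder the name.  Sequences are uppercased and validated against
    the canonical alphabet.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description or rec.id
        parts = desc.split(None, 1)
        name = parts[1] if len(parts) > 1 else ""
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq), name=name))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def _check_range(protein: ProteinRecord, start: int, end: int, what: str) -> None:
    if not (1 <= start <= end <= protein.length):
        raise FeatureError(
            f"{what} {start}..{end} out of range for protein {protein.id} "
            f"(length {protein.length})"
        )


def _check_tm_overlap(protein_id: str, features: Sequence[ProteinFeature]) -> None:
    tms = sorted((f for f in features if f.kind == "TM"), key=lambda f: f.start)
    for a, b in zip(tms, tms[1:]):
        if b.start <= a.end:
            raise FeatureError(
                f"overlapping TM features in {protein_id}: "
                f"{a.start}..{a.end} and {b.start}..{b.end}"
            )


def validate_annotations(
    protein: ProteinRecord, ann: ProteinAnnotations
) -> ProteinAnnotations:
    for f in ann.features:
        _check_range(protein, f.start, f.end, f"feature {f.label or f.kind}")
    _check_tm_overlap(protein.id, ann.features)
    for g in ann.glycans:
        _check_range(protein, g.sequon_position, g.sequon_position, "glycan sequon")
    for s in ann.cleavage_sites:
        if not (1 <= s.position < protein.length):
            raise FeatureError(
                f"cleavage site {s.label or s.position} must satisfy "
                f"1 <= position < length for {protein.id}"
            )
    return ann


def load_features(
    path: str | Path, proteins: Iterable[ProteinRecord]
) -> dict[str, ProteinAnnotations]:
    """Load a YAML feature config and attach annotations per protein id.

    Expected layout::

        proteins:
          PC1SYN:
            features:
              - {kind: TM, start: 3060, end: 3080, label: TM-I}
            glycans:
              - {position: 3738, state: endoH_sensitive, mass_kDa: 2.0}
            cleavage_sites:
              - {position: 3048, label: GPS}

    Every referenced protein id must exist and every coordinate must lie
    within the protein.  Proteins absent from the file get empty
    annotations (valid).
    """
    by_id = {p.id: p for p in proteins}
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, ProteinAnnotations] = {pid: ProteinAnnotations() for pid in by_id}
    for pid, block in (raw.get("proteins") or {}).items():
        if pid not in by_id:
            raise FeatureError(f"feature config references unknown protein id {pid!r}")
        block = block or {}
        ann = ProteinAnnotations(
            features=[ProteinFeature(**f) for f in block.get("features") or []],
            glycans=[
                GlycanAnnotation(
                    sequon_position=g["position"],
                    state=g["state"],
                    mass_kDa=float(g["mass_kDa"]),
                )
                for g in block.get("glycans") or []
            ],
            cleavage_sites=[
                CleavageSite(position=s["position"], label=s.get("label", ""))
                for s in block.get("cleavage_sites") or []
            ],
        )
        out[pid] = validate_annotations(by_id[pid], ann)
    return out


def save_features(
    path: str | Path, annotations: Mapping[str, ProteinAnnotations]
) -> None:
    """Serialize annotations back to the YAML layout read by :func:`load_features`."""
    doc: dict = {"proteins": {}}
    for pid, ann in annotations.items():
        doc["proteins"][pid] = {
            "features": [
                {"kind": f.kind, "start": f.start, "end": f.end, "label": f.label}
                for f in ann.features
            ],
            "glycans": [
                {
                    "position": g.sequon_position,
                    "state": g.state,
                    "mass_kDa": g.mass_kDa,
                }
                for g in ann.glycans
            ],
            "cleavage_sites": [
                {"position": s.position, "label": s.label}
                for s in ann.cleavage_sites
            ],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def find_sequons(
    protein: ProteinRecord,
    region: tuple[int, int] | None = None,
    *,
    exclude_proline: bool = True,
    allow_cys: bool = True,
) -> list[int]:
    """1-based positions of N in every N-X-[S/T/C] glycosylation sequon.

    ``exclude_proline`` applies the standard biochemical rule that proline
    in the X position blocks glycosylation (on by default; switch off to
    scan the bare N-X-[S/T/C] motif).  ``allow_cys`` includes the rare
    N-X-C sequon (on by default).  ``region`` restricts the scan so that the
    whole three-residue motif lies inside ``(start, stop)`` inclusive.
    """
    if region is None:
        start, stop = 1, protein.length
    else:
        start, stop = region
        _check_range(protein, start, stop, "sequon scan region")
    x = "[^P]" if exclude_proline else "."
    third = "[STC]" if allow_cys else "[ST]"
    pattern = re.compile(f"(?=N{x}{third})")
    window = protein.sequence[start - 1 : stop]
    return [start + m.start() for m in pattern.finditer(window)]
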