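"""Synthetic peptide-intensity cohorts with planted proteolytic structure.

The generator emulates the statistical structure of a two-cohort gel-slice
LC-MS/MS peptide dataset (13 mutant vs 18 normal urine vesicle samples):

* each synthetic protein is digested in silico; detectable tryptic
  peptides (default 700-4000 Da monoisotopic) are the observable units;
* proteoform *populations* (cleavage-site sets with molar fractions)
  determine which fragment a peptide reports on and hence the gel slice it
  appears in - the slice is assigned from the fragment's glycosylated
  average mass via the shared slice scheme, so generated placements agree
  with :func:`pccelv.slice_quant.assign_expected_slice` by construction;
* planted *regional multipliers* set relative molar abundances along the
  chain (ectodomain excess, post-cleavage deficits, residual tails);
* a per-protein cohort fold-change multiplies the mutant samples;
* each observation carries multiplicative log-normal noise and is thinned
  by a per-(peptide, sample) detection probability.

Per-peptide ion currents span two decades (log-uniform), mimicking the
large dynamic range of real peptide responses; the draws are arithmetic-
mean-normalized within each multiplier region so that planted regional
ratios are exact in the noise-free limit rather than being distorted by
which peptides happened to draw large responses.

Ground truth (sites, fractions, multipliers, expected statistics) is
returned alongside every table so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import json

import numpy as np
import pandas as pd

from .cleavage_inference import (
    Fragment,
    RegionSpec,
    fragment_model,
    region_intensity_ratio,
    tail_depletion,
)
from .digestion_mass import digest
from .sequence_model import (
    CleavageSite,
    GlycanAnnotation,
    ProteinAnnotations,
    ProteinFeature,
    ProteinRecord,
)
from .slice_quant import DEFAULT_SCHEME, GelSliceScheme, IntensityTable, TABLE_COLUMNS

__all__ = [
    "Population",
    "RegionMultiplier",
    "SyntheticProtein",
    "SyntheticConfig",
    "PlantedCheck",
    "ProteinTruth",
    "GroundTruth",
    "simulate_dataset",
    "simulate_preset",
    "preset",
    "PRESET_NAMES",
    "random_protein_sequence",
    "evaluate_planted_checks",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Population:
    """One proteoform population: a cleavage-site set and its molar fraction."""

    sites: tuple[int, ...]
    fraction: float


@dataclass(frozen=True)
class RegionMultiplier:
    """Relative molar abundance multiplier for peptides starting in [start..stop]."""

    start: int
    stop: int
    multiplier: float
    label: str = ""


@dataclass
class SyntheticProtein:
    record: ProteinRecord
    annotations: ProteinAnnotations = field(default_factory=ProteinAnnotations)
    populations: tuple[Population, ...] = (Population(sites=(), fraction=1.0),)
    region_multipliers: tuple[RegionMultiplier, ...] = ()
    cohort_effect: float = 1.0  # PKD1 / normal fold-change


@dataclass
class SyntheticConfig:
    proteins: list[SyntheticProtein]
    seed: int
    cohort_sizes: tuple[int, int] = (13, 18)  # (PKD1, normal)
    noise_sd_log2: float = 0.4
    detect_prob: float = 0.8
    abundance_decades: float = 2.0
    mass_range: tuple[float, float] = (700.0, 4000.0)
    base_scale: float = 1.0e6
    scheme: GelSliceScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def validate(self) -> "SyntheticConfig":
        if self.noise_sd_log2 < 0:
            raise ConfigError("noise_sd_log2 must be >= 0")
        if not (0 < self.detect_prob <= 1):
            raise ConfigError("detect_prob must be in (0, 1]")
        if min(self.cohort_sizes) < 1:
            raise ConfigError("cohort sizes must be >= 1")
        for sp in self.proteins:
            total = sum(p.fraction for p in sp.populations)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"population fractions for {sp.record.id} sum to {total}, not 1"
                )
            for p in sp.populations:
                if p.fraction < 0:
                    raise ConfigError("population fractions must be >= 0")
            for rm in sp.region_multipliers:
                if rm.multiplier < 0:
                    raise ConfigError("region multipliers must be >= 0")
                if not (1 <= rm.start <= rm.stop <= sp.record.length):
                    raise ConfigError(
                        f"multiplier region {rm.start}..{rm.stop} out of range "
                        f"for {sp.record.id}"
                    )
        return self


@dataclass(frozen=True)
class PlantedCheck:
    """A planted statistic and the pipeline call that should recover it."""

    name: str
    kind: str  # "region_ratio" or "tail_depletion"
    protein_id: str
    expected: float
    boundary: int | None = None
    numerator: RegionSpec | None = None
    denominator: RegionSpec | None = None
    tail_start: int | None = None
    reference: RegionSpec | None = None


@dataclass
class ProteinTruth:
    populations: tuple[Population, ...]
    region_multipliers: tuple[RegionMultiplier, ...]
    cohort_effect: float
    fragments: list[Fragment]
    primary_site: int | None = None


@dataclass
class GroundTruth:
    seed: int
    proteins: dict[str, ProteinTruth]
    checks: list[PlantedCheck] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "proteins": {
                pid: {
                    "populations": [
                        {"sites": list(p.sites), "fraction": p.fraction}
                        for p in t.populations
                    ],
                    "region_multipliers": [
                        {
                            "start": m.start,
                            "stop": m.stop,
                            "multiplier": m.multiplier,
                            "label": m.label,
                        }
                        for m in t.region_multipliers
                    ],
                    "cohort_effect": t.cohort_effect,
                    "primary_site": t.primary_site,
                }
                for pid, t in self.proteins.items()
            },
            "checks": [
                {"name": c.name, "protein_id": c.protein_id, "expected": c.expected}
                for c in self.checks
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Sequence synthesis

#: Filler alphabet (weights ~ natural frequencies) excludes K/R (tryptic
#: sites are planted explicitly), P (would suppress planted sites) and N
#: (sequons are planted explicitly).
_FILLER = "ACDEFGHILMQSTVWY"
_FILLER_W = np.array(
    [8.3, 1.4, 5.4, 6.8, 3.9, 7.1, 2.3, 6.0, 9.7, 2.4, 3.9, 6.6, 5.3, 6.9, 1.1, 2.9]
)
_FILLER_P = _FILLER_W / _FILLER_W.sum()


def random_protein_sequence(
    length: int,
    seed: int,
    segments: Sequence[tuple[int, int, int, int]] | None = None,
    overrides: Mapping[int, str] | None = None,
) -> str:
    """Deterministic pseudo-random sequence with planted K/R spacing.

    ``segments`` is a list of ``(start, stop, gap_min, gap_max)`` regions;
    within each, K/R residues are planted at uniform random gaps in
    ``[gap_min, gap_max]`` so mean tryptic peptide length is controllable
    (default: one segment covering the protein with gaps 7..16, i.e.
    ~11-12 aa peptides, mostly inside a 700-4000 Da window).  ``overrides``
    maps 1-based positions to fixed residues and is applied last, allowing
    exact motifs (sequons, single detectable peptides) to be planted.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(list(_FILLER), size=length, p=_FILLER_P)
    if segments is None:
        segments = [(1, length, 7, 16)]
    for seg_start, seg_stop, gap_lo, gap_hi in segments:
        pos = seg_start - 1
        while True:
            pos += int(rng.integers(gap_lo, gap_hi + 1))
            if pos > seg_stop or pos >= length:  # never at the C-terminus
                break
            seq[pos - 1] = "K" if rng.random() < 0.5 else "R"
    for p, aa in (overrides or {}).items():
        seq[p - 1] = aa
    return "".join(seq)


# ---------------------------------------------------------------------------
# Simulation

def _sample_ids(cohort_sizes: tuple[int, int]) -> tuple[list[str], list[str]]:
    n_pkd, n_norm = cohort_sizes
    return (
        [f"PKD1_{i:02d}" for i in range(1, n_pkd + 1)],
        [f"NORM_{i:02d}" for i in range(1, n_norm + 1)],
    )


@lru_cache(maxsize=64)
def _digest_cached(record: ProteinRecord, mass_range: tuple[float, float]):
    peptides = digest(record, max_missed=0, mass_range=mass_range)
    starts = np.array([p.start for p in peptides])
    stops = np.array([p.stop for p in peptides])
    seqs = np.array([p.sequence for p in peptides], dtype=object)
    return starts, stops, seqs


def simulate_dataset(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[IntensityTable, GroundTruth]:
    """Generate an :class:`IntensityTable` plus its :class:`GroundTruth`.

    Deterministic given the seed (``seed`` overrides ``config.seed``).
    """
    config.validate()
    use_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    pkd_ids, norm_ids = _sample_ids(config.cohort_sizes)
    samples = np.array(pkd_ids + norm_ids)
    is_pkd = np.array([1.0] * len(pkd_ids) + [0.0] * len(norm_ids))

    frames = []
    truth_proteins: dict[str, ProteinTruth] = {}
    for sp in config.proteins:
        record = sp.record
        starts, stops, seqs = _digest_cached(record, tuple(config.mass_range))
        n_pep = len(starts)
        # Base ion currents: log-uniform over `abundance_decades`, mean-
        # normalized within each multiplier region (see module docstring).
        base = 10.0 ** rng.uniform(0.0, config.abundance_decades, size=n_pep)
        mult = np.ones(n_pep)
        group = np.full(n_pep, -1)
        for gi, rm in enumerate(sp.region_multipliers):
            in_region = (starts >= rm.start) & (starts <= rm.stop)
            mult[in_region] = rm.multiplier
            group[in_region] = gi

        fragments = fragment_model(
            record,
            [tuple(CleavageSite(p) for p in pop.sites) for pop in sp.populations],
            glycans=sp.annotations.glycans,
            scheme=config.scheme,
            annotations=sp.annotations,
        )
        # peptide x slice molar weight, summed over populations
        slice_weight: dict[str, np.ndarray] = {}
        for frag in fragments:
            lab = frag.expected_slice["glyc"]
            if lab == "out_of_range":
                continue
            inside = (starts >= frag.start) & (stops <= frag.stop)
            if not inside.any():
                continue
            w = slice_weight.setdefault(lab, np.zeros(n_pep))
            w[inside] += sp.populations[frag.population].fraction

        # Mean-normalize base draws within each multiplier region, over the
        # peptides that are actually observable (inside a retained fragment;
        # site-spanning peptides never appear and must not skew the mean).
        observable = np.zeros(n_pep, dtype=bool)
        for w in slice_weight.values():
            observable |= w > 0
        for gi in np.unique(group):
            sel = (group == gi) & observable
            if sel.any():
                base[sel] /= base[sel].mean()

        cohort_factor = np.where(is_pkd == 1.0, sp.cohort_effect, 1.0)
        for lab in sorted(slice_weight):
            w = slice_weight[lab]
            present = w > 0
            idx = np.nonzero(present)[0]
            amp = config.base_scale * base[idx] * mult[idx] * w[idx]
            noise = 2.0 ** rng.normal(
                0.0, config.noise_sd_log2, size=(len(idx), len(samples))
            )
            detected = rng.random((len(idx), len(samples))) < config.detect_prob
            inten = amp[:, None] * cohort_factor[None, :] * noise
            pi, si = np.nonzero(detected)
            frames.append(
                pd.DataFrame(
                    {
                        "protein_id": record.id,
                        "peptide_seq": seqs[idx][pi],
                        "start": starts[idx][pi],
                        "stop": stops[idx][pi],
                        "slice": lab,
                        "sample": samples[si],
                        "cohort": np.where(is_pkd[si] == 1.0, "PKD1", "normal"),
                        "intensity": inten[pi, si],
                    }
                )
            )
        primary = min(sp.populations[0].sites) if sp.populations[0].sites else None
        truth_proteins[record.id] = ProteinTruth(
            populations=sp.populations,
            region_multipliers=sp.region_multipliers,
            cohort_effect=sp.cohort_effect,
            fragments=fragments,
            primary_site=primary,
        )

    data = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TABLE_COLUMNS)
    )
    table = IntensityTable(data=data, scheme=config.scheme)
    return table, GroundTruth(seed=use_seed, proteins=truth_proteins)


def evaluate_planted_checks(
    table: IntensityTable, checks: Sequence[PlantedCheck]
) -> pd.DataFrame:
    """Run each planted check's pipeline statistic and tabulate recovery."""
    rows = []
    for c in checks:
        if c.kind == "region_ratio":
            res = region_intensity_ratio(
                table, c.protein_id, c.numerator, c.denominator, boundary=c.boundary
            )
            value, n = res.ratio, res.n_numerator + res.n_denominator
        elif c.kind == "tail_depletion":
            res = tail_depletion(table, c.protein_id, c.tail_start, c.reference)
            value, n = res.ratio, res.n_tail + res.n_reference
        else:
            raise ConfigError(f"unknown check kind {c.kind!r}")
        rows.append(
            dict(
                name=c.name,
                protein_id=c.protein_id,
                expected=c.expected,
                measured=value,
                rel_error=(value - c.expected) / c.expected if c.expected else np.nan,
                n_peptides=n,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibrated presets (study conditions frozen to the published values)

PRESET_NAMES = (
    "pc1_fig1",
    "pc1_fig2",
    "fibrocystin_ppc",
    "pc2_tail",
    "cemip2_null",
)

# Internal sequence seeds: fixed so every preset's proteins (hence peptide
# maps) are frozen; the dataset seed only drives abundances and noise.
_SEQ_SEEDS = {"PC1": 11, "PC2": 12, "FCYS": 13, "CEMIP2": 14}

# Planted biology (residue coordinates on the synthetic homologues):
_GPS = 3048          # PC1 GPS/GAIN autoproteolysis (HL|T, T at 3049)
_PC1_TM45 = 3475     # cut at the TM-IV/TM-V hairpin
_PC1_TOP = 3760      # cut in the TM-VI/VII (TOP) loop between sequons 1 and 2
_PC1_CT_TRIM = 4202  # C-terminal ~11 kDa trim removing the coiled-coil
_PPC = 3616          # fibrocystin proprotein convertase site
_FCYS_TM = 3859      # fibrocystin single TM start; tail cut just after it
_PC2_CT = 806        # PC2 C-tail cut (leaves the last 17.8 kDa)

_ECTODOMAIN_EXCESS = 1.4   # PC1 ectodomain : C-terminal fragment
_FCYS_POST_PPC = 0.58      # pooled post-PPC : pre-PPC slice-A level
_FCYS_TAIL = 0.051         # residual fibrocystin C-tail level
_PC2_TAIL_RATIO = 0.13     # PC2 tail peptides: slices I-J vs A-D
_COHORT_EFFECTS = {"PC1": 0.5, "PC2": 0.5, "FCYS": 0.67, "CEMIP2": 2.0}


def _pc1_tms() -> list[ProteinFeature]:
    # Eleven TM segments in the C-terminal region, then the coiled-coil.
    tm_starts = [3060, 3150, 3260, 3370, 3490, 3560, 3870, 3960, 4020, 4080, 4140]
    feats = [
        ProteinFeature(kind="TM", start=s, end=s + 20, label=f"TM-{i+1}")
        for i, s in enumerate(tm_starts)
    ]
    feats.append(ProteinFeature(kind="coiled_coil", start=4240, end=4280))
    return feats


@lru_cache(maxsize=None)
def _pc1_protein() -> tuple[ProteinRecord, ProteinAnnotations]:
    # Sequons planted in the TOP domain (TM-VI/VII loop): one Endo H
    # sensitive (2 kDa) then two mature chains (5 kDa each, 10 total).
    overrides = {}
    for pos in (3738, 3790, 3845):
        overrides[pos] = "N"
        overrides[pos + 1] = "A"
        overrides[pos + 2] = "T"
    seq = random_protein_sequence(4302, _SEQ_SEEDS["PC1"], overrides=overrides)
    record = ProteinRecord(id="PC1", sequence=seq, name="polycystin-1 (synthetic)")
    ann = ProteinAnnotations(
        features=_pc1_tms()
        + [
            ProteinFeature(kind="sequon", start=p, end=p + 2, label=f"sequon-{p}")
            for p in (3738, 3790, 3845)
        ],
        glycans=[
            GlycanAnnotation(sequon_position=3738, state="endoH_sensitive", mass_kDa=2.0),
            GlycanAnnotation(sequon_position=3790, state="mature", mass_kDa=5.0),
            GlycanAnnotation(sequon_position=3845, state="mature", mass_kDa=5.0),
        ],
        cleavage_sites=[
            CleavageSite(position=_GPS, label="GPS"),
            CleavageSite(position=_PC1_TM45, label="TM45_hairpin"),
            CleavageSite(position=_PC1_TOP, label="TOP_loop"),
            CleavageSite(position=_PC1_CT_TRIM, label="ct_trim"),
        ],
    )
    return record, ann


@lru_cache(maxsize=None)
def _fcys_protein() -> tuple[ProteinRecord, ProteinAnnotations]:
    # The C-terminal tail (after the TM) is built so that exactly ONE tail
    # peptide falls in the detectable mass window, mirroring the single
    # quantifiable C-tail peptide in the dataset this emulates: tail K/R
    # spacing is dense (3-mers, < 700 Da) except for one planted 11-mer.
    overrides: dict[int, str] = {3920: "R", 3931: "R"}
    for pos, aa in zip(range(3921, 3931), "EDTVVGEDMA"):
        overrides[pos] = aa
    seq = random_protein_sequence(
        4074,
        _SEQ_SEEDS["FCYS"],
        segments=[(1, 3859, 7, 16), (3860, 4074, 3, 3)],
        overrides=overrides,
    )
    record = ProteinRecord(id="FCYS", sequence=seq, name="fibrocystin (synthetic)")
    ann = ProteinAnnotations(
        features=[ProteinFeature(kind="TM", start=3860, end=3880, label="TM")],
        cleavage_sites=[
            CleavageSite(position=_PPC, label="PPC"),
            CleavageSite(position=_FCYS_TM, label="tail_release"),
        ],
    )
    return record, ann


@lru_cache(maxsize=None)
def _pc2_protein() -> tuple[ProteinRecord, ProteinAnnotations]:
    seq = random_protein_sequence(968, _SEQ_SEEDS["PC2"])
    record = ProteinRecord(id="PC2", sequence=seq, name="polycystin-2 (synthetic)")
    ann = ProteinAnnotations(
        features=[
            ProteinFeature(kind="domain", start=750, end=785, label="EF-hand"),
            ProteinFeature(kind="coiled_coil", start=833, end=872),
        ],
        cleavage_sites=[CleavageSite(position=_PC2_CT, label="ct_trim")],
    )
    return record, ann


@lru_cache(maxsize=None)
def _cemip2_protein() -> tuple[ProteinRecord, ProteinAnnotations]:
    seq = random_protein_sequence(1383, _SEQ_SEEDS["CEMIP2"])
    record = ProteinRecord(
        id="CEMIP2", sequence=seq, name="cell-surface hyaluronidase (synthetic)"
    )
    return record, ProteinAnnotations()


def _fcys_calibrated_mid_multiplier(mass_range: tuple[float, float]) -> float:
    """Post-PPC multiplier calibrated so the pooled stop>3616 statistic is 0.58.

    The pooled ratio averages over *all* peptides stopping after the PPC
    site, which includes the single residual-tail peptide at 5.1%; the
    multiplier for the PPC..TM region is solved from the frozen peptide
    counts so the planted statistic equals the published pooled value.
    """
    record, _ = _fcys_protein()
    starts, stops, _ = _digest_cached(record, mass_range)
    n_mid = int(((starts >= _PPC + 1) & (stops <= _FCYS_TM)).sum())
    n_tail = int(((starts >= _FCYS_TM + 1)).sum())
    if n_mid == 0 or n_tail == 0:
        raise ConfigError("fibrocystin preset lost its mid/tail peptides")
    return (_FCYS_POST_PPC * (n_mid + n_tail) - _FCYS_TAIL * n_tail) / n_mid


def _bj(scheme: GelSliceScheme) -> tuple[str, ...]:
    return scheme.slice_range("B", "J")


def preset(name: str, seed: int = 1) -> tuple[SyntheticConfig, list[PlantedCheck]]:
    """A frozen, documented configuration plus its planted-statistic checks.

    Presets encode the study conditions: cohort sizes 13 vs 18, the
    published cleavage coordinates, the published pooled intensity ratios
    (ectodomain excess 1.4, post-PPC 58%, residual fibrocystin tail 5.1%,
    PC2 tail 13%) and direction-of-effect cohort fold-changes.
    """
    if name not in PRESET_NAMES:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    scheme = DEFAULT_SCHEME
    mass_range = (700.0, 4000.0)
    checks: list[PlantedCheck] = []

    if name in ("pc1_fig1", "pc1_fig2"):
        record, ann = _pc1_protein()
        if name == "pc1_fig1":
            populations = (Population(sites=(_GPS,), fraction=1.0),)
        else:
            # ~60% of C-terminal molecules undergo the three further cuts.
            populations = (
                Population(sites=(_GPS,), fraction=0.4),
                Population(
                    sites=(_GPS, _PC1_TM45, _PC1_TOP, _PC1_CT_TRIM), fraction=0.6
                ),
            )
        protein = SyntheticProtein(
            record=record,
            annotations=ann,
            populations=populations,
            region_multipliers=(
                RegionMultiplier(1, _GPS, _ECTODOMAIN_EXCESS, "ectodomain"),
                RegionMultiplier(_GPS + 1, record.length, 1.0, "CTF"),
            ),
            cohort_effect=_COHORT_EFFECTS["PC1"],
        )
        checks.append(
            PlantedCheck(
                name="pc1_ectodomain_vs_ctf",
                kind="region_ratio",
                protein_id="PC1",
                expected=_ECTODOMAIN_EXCESS,
                boundary=_GPS,
                numerator=RegionSpec(slices=("A",), stop_lt=_GPS),
                denominator=RegionSpec(slices=_bj(scheme), stop_gt=_GPS),
            )
        )
    elif name == "fibrocystin_ppc":
        record, ann = _fcys_protein()
        m_mid = _fcys_calibrated_mid_multiplier(mass_range)
        protein = SyntheticProtein(
            record=record,
            annotations=ann,
            populations=(Population(sites=(_PPC, _FCYS_TM), fraction=1.0),),
            region_multipliers=(
                RegionMultiplier(1, _PPC, 1.0, "ectodomain"),
                RegionMultiplier(_PPC + 1, _FCYS_TM, m_mid, "post_PPC"),
                RegionMultiplier(_FCYS_TM + 1, record.length, _FCYS_TAIL, "tail"),
            ),
            cohort_effect=_COHORT_EFFECTS["FCYS"],
        )
        checks.extend(
            [
                PlantedCheck(
                    name="fcys_post_ppc_vs_ecto",
                    kind="region_ratio",
                    protein_id="FCYS",
                    expected=_FCYS_POST_PPC,
                    boundary=_PPC,
                    numerator=RegionSpec(slices=_bj(scheme), stop_gt=_PPC),
                    denominator=RegionSpec(slices=("A",), stop_lt=_PPC),
                ),
                PlantedCheck(
                    name="fcys_tail_vs_sliceA",
                    kind="tail_depletion",
                    protein_id="FCYS",
                    expected=_FCYS_TAIL,
                    tail_start=_FCYS_TM + 1,
                    reference=RegionSpec(slices=("A",), stop_lt=_PPC),
                ),
            ]
        )
    elif name == "pc2_tail":
        record, ann = _pc2_protein()
        f_cleaved = _PC2_TAIL_RATIO / (1.0 + _PC2_TAIL_RATIO)
        protein = SyntheticProtein(
            record=record,
            annotations=ann,
            populations=(
                Population(sites=(), fraction=1.0 - f_cleaved),
                Population(sites=(_PC2_CT,), fraction=f_cleaved),
            ),
            cohort_effect=_COHORT_EFFECTS["PC2"],
        )
        checks.append(
            PlantedCheck(
                name="pc2_tail_IJ_vs_AD",
                kind="region_ratio",
                protein_id="PC2",
                expected=_PC2_TAIL_RATIO,
                boundary=_PC2_CT,
                numerator=RegionSpec(
                    slices=scheme.slice_range("I", "J"), start_ge=_PC2_CT + 1
                ),
                denominator=RegionSpec(
                    slices=scheme.slice_range("A", "D"), start_ge=_PC2_CT + 1
                ),
            )
        )
    else:  # cemip2_null
        record, ann = _cemip2_protein()
        protein = SyntheticProtein(
            record=record,
            annotations=ann,
            populations=(Population(sites=(), fraction=1.0),),
            cohort_effect=_COHORT_EFFECTS["CEMIP2"],
        )

    config = SyntheticConfig(proteins=[protein], seed=seed, scheme=scheme,
                             mass_range=mass_range).validate()
    return config, checks


def simulate_preset(
    name: str, seed: int = 1
) -> tuple[IntensityTable, GroundTruth]:
    """Convenience: build a preset and simulate it in one call."""
    config, checks = preset(name, seed=seed)
    table, truth = simulate_dataset(config)
    truth.checks = checks
    return table, truth
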