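"""Gel-slice scheme, peptide-intensity tables and cohort differential tests.

The experimental design emulated here is GeLC-MS/MS: each sample's vesicle
proteome is run down an SDS-PAGE lane, the lane is cut into ordered
molecular-weight windows (slices A..J, A heaviest), and each slice is
trypsin-digested and quantified by LC-MS/MS.  A peptide observation is
therefore a (protein, peptide, slice, sample) ion current, and the slice
carries the apparent mass of whatever proteoform the peptide came from.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "GelSliceScheme",
    "DEFAULT_SCHEME",
    "IntensityTable",
    "TABLE_COLUMNS",
    "COHORTS",
    "read_intensity_table",
    "assign_expected_slice",
    "differential_peptides",
    "slice_consistency",
]

COHORTS = ("PKD1", "normal")

TABLE_COLUMNS = [
    "protein_id",
    "peptide_seq",
    "start",
    "stop",
    "slice",
    "sample",
    "cohort",
    "intensity",
]


class SchemeError(ValueError):
    pass


class TableError(ValueError):
    pass


@dataclass(frozen=True)
class GelSliceScheme:
    """Ordered molecular-weight windows, heaviest first.

    Windows are half-open on the light side: a mass on a shared boundary
    belongs to the heavier window (gels cannot resolve boundary masses, so
    the convention is arbitrary but fixed).  The heaviest window includes
    its own upper bound.
    """

    windows: tuple[tuple[str, float, float], ...]
    comment: str = ""

    def __post_init__(self) -> None:
        if not self.windows:
            raise SchemeError("scheme needs at least one window")
        prev_min = None
        for label, lo, hi in self.windows:
            if not lo < hi:
                raise SchemeError(f"window {label}: need min < max, got {lo}..{hi}")
            if prev_min is not None and hi > prev_min:
                raise SchemeError(
                    f"windows must be ordered high to low and non-overlapping; "
                    f"window {label} ({lo}-{hi} kDa) overlaps or follows out of order"
                )
            prev_min = lo

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(w[0] for w in self.windows)

    def window(self, label: str) -> tuple[float, float]:
        for lab, lo, hi in self.windows:
            if lab == label:
                return lo, hi
        raise SchemeError(f"unknown slice label {label!r}")

    def assign(self, mass_kDa: float) -> str:
        """Slice label containing ``mass_kDa``, or ``"out_of_range"``."""
        for i, (label, lo, hi) in enumerate(self.windows):
            if lo <= mass_kDa < hi or (i == 0 and mass_kDa == hi):
                return label
        return "out_of_range"

    def slice_range(self, first: str, last: str) -> tuple[str, ...]:
        """Labels from ``first`` to ``last`` inclusive, in scheme order."""
        labels = self.labels
        i, j = labels.index(first), labels.index(last)
        if i > j:
            i, j = j, i
        return labels[i : j + 1]


#: The ten-slice scheme used throughout (A heaviest).  The source legend
#: prints window B as "140 kDa-27 kDa", an obvious typo for 140-270 kDa
#: (the windows must tile 10-500 kDa); the corrected value is shipped and
#: the raw legend text is preserved in the comment.
DEFAULT_SCHEME = GelSliceScheme(
    windows=(
        ("A", 270.0, 500.0),
        ("B", 140.0, 270.0),
        ("C", 90.0, 140.0),
        ("D", 70.0, 90.0),
        ("E", 55.0, 70.0),
        ("F", 40.0, 55.0),
        ("G", 32.0, 40.0),
        ("H", 24.0, 32.0),
        ("I", 15.0, 24.0),
        ("J", 10.0, 15.0),
    ),
    comment=(
        "as published: A 270-500; B '140-27' (typo, corrected to 140-270); "
        "C 90-140; D 70-90; E 55-70; F 40-55; G 32-40; H 24-32; I 15-24; J 10-15"
    ),
)


def assign_expected_slice(mass_kDa: float, scheme: GelSliceScheme = DEFAULT_SCHEME) -> str:
    return scheme.assign(mass_kDa)


@dataclass
class IntensityTable:
    """Long-format peptide x slice x sample ion-current observations.

    Backed by a pandas DataFrame with columns
    ``protein_id, peptide_seq, start, stop, slice, sample, cohort, intensity``.
    Each (protein, start, stop, slice, sample) key appears at most once.
    """

    data: pd.DataFrame
    scheme: GelSliceScheme = field(default=DEFAULT_SCHEME)

    KEY = ["protein_id", "start", "stop", "slice", "sample"]

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise TableError(f"intensity table missing columns: {missing}")
        self.data = self.data[TABLE_COLUMNS].reset_index(drop=True)
        if self.data.duplicated(subset=self.KEY).any():
            raise TableError("duplicate (protein, peptide, slice, sample) keys")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def cohort_sizes(self) -> dict[str, int]:
        return (
            self.data.groupby("cohort")["sample"].nunique().to_dict()
        )

    def for_protein(self, protein_id: str) -> pd.DataFrame:
        return self.data[self.data["protein_id"] == protein_id]

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index=False, float_format="%.6g")


def read_intensity_table(
    path: str | Path | io.TextIOBase,
    scheme: GelSliceScheme = DEFAULT_SCHEME,
    sep: str | None = None,
) -> IntensityTable:
    """Read a delimited intensity table, dropping (and logging) invalid rows.

    The delimiter is sniffed from the header line (tab preferred over
    comma) unless given.  Rows with unknown slice labels, unknown cohorts,
    or negative / non-finite intensities are rejected; their count is
    logged at WARNING level.  A missing required column is a hard error.
    """
    if sep is None:
        if hasattr(path, "read"):
            head = path.readline()
            path.seek(0)
        else:
            with open(path) as fh:
                head = fh.readline()
        sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"intensity table missing columns: {missing}")
    n0 = len(df)
    valid_slices = set(scheme.labels)
    bad_slices = sorted(set(df["slice"]) - valid_slices)
    ok = (
        df["slice"].isin(valid_slices)
        & df["cohort"].isin(COHORTS)
        & np.isfinite(df["intensity"])
        & (df["intensity"] >= 0)
        & (df["start"] >= 1)
        & (df["stop"] >= df["start"])
    )
    rejected = int((~ok).sum())
    if rejected:
        log.warning(
            "rejected %d/%d rows (invalid slice/cohort/intensity/coordinates)%s",
            rejected,
            n0,
            f"; unknown slice labels: {bad_slices}" if bad_slices else "",
        )
    return IntensityTable(data=df[ok].reset_index(drop=True), scheme=scheme)


def differential_peptides(
    table: IntensityTable,
    alpha: float = 0.01,
    *,
    equal_var: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per peptide-slice cohort comparison on log2 intensities.

    For every (protein_id, start, stop, slice) key a two-sample t-test
    (Welch by default; Student with ``equal_var=True``) compares log2
    intensities between the two cohorts, and the effect is reported as
    ``log2_ratio = mean(log2 PKD1) - mean(log2 normal)`` so that negative
    values mean *decreased in the mutant cohort*.  Zero intensities are
    treated as not-detected (censored) and excluded from the log transform.
    P-values are deliberately left uncorrected (``passes_threshold`` is
    ``p < alpha``); ``fdr=True`` adds a Benjamini-Hochberg ``q_value``
    column without changing the threshold flag.

    Keys with fewer than two detected samples in either cohort get
    ``p_value = NaN`` and ``passes_threshold = False``.
    """
    df = table.data[table.data["intensity"] > 0].copy()
    if df.empty:
        return pd.DataFrame(
            columns=[
                "protein_id", "start", "stop", "slice",
                "log2_ratio", "p_value", "n_PKD1", "n_normal",
                "total_intensity", "passes_threshold",
            ]
        )
    df["log2_intensity"] = np.log2(df["intensity"])
    rows = []
    for key, grp in df.groupby(["protein_id", "start", "stop", "slice"], sort=True):
        a = grp.loc[grp["cohort"] == "PKD1", "log2_intensity"].to_numpy()
        b = grp.loc[grp["cohort"] == "normal", "log2_intensity"].to_numpy()
        ratio = (
            a.mean() - b.mean() if len(a) and len(b) else np.nan
        )
        if len(a) >= 2 and len(b) >= 2:
            _, p = stats.ttest_ind(a, b, equal_var=equal_var)
        else:
            p = np.nan
        rows.append(
            dict(
                protein_id=key[0],
                start=key[1],
                stop=key[2],
                slice=key[3],
                log2_ratio=ratio,
                p_value=p,
                n_PKD1=len(a),
                n_normal=len(b),
                total_intensity=grp["intensity"].sum(),
            )
        )
    out = pd.DataFrame(rows)
    out["passes_threshold"] = out["p_value"] < alpha
    if fdr:
        mask = out["p_value"].notna()
        q = np.full(len(out), np.nan)
        if mask.any():
            q[mask.to_numpy()] = stats.false_discovery_control(
                out.loc[mask, "p_value"].to_numpy()
            )
        out["q_value"] = q
    return out


def slice_consistency(
    table: IntensityTable,
    fragments: Iterable,
    *,
    treatment: str = "glyc",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Check each peptide observation against a fragment model.

    An observation is *consistent* when its residue range lies within at
    least one fragment whose expected slice (for ``treatment``) equals the
    observed slice.  Returns the per-observation table with a ``consistent``
    column and the fraction consistent per protein.  Proteins without any
    fragment in the model are skipped with a warning.
    """
    frags = list(fragments)
    by_protein: dict[str, list] = {}
    for f in frags:
        by_protein.setdefault(f.protein_id, []).append(f)
    parts = []
    summary: dict[str, float] = {}
    for pid, df in table.data.groupby("protein_id"):
        if pid not in by_protein:
            log.warning("no fragment model for protein %s; skipped", pid)
            continue
        df = df.copy()
        flags = np.zeros(len(df), dtype=bool)
        for f in by_protein[pid]:
            exp = f.expected_slice.get(treatment)
            inside = (
                (df["start"] >= f.start)
                & (df["stop"] <= f.stop)
                & (df["slice"] == exp)
            )
            flags |= inside.to_numpy()
        df["consistent"] = flags
        parts.append(df)
        summary[pid] = float(flags.mean()) if len(flags) else float("nan")
    detail = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    return detail, summary
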