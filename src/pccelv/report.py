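"""Positional differential reports and the end-to-end pipeline driver.

The positional report is the peptide-map view of the cohort comparison:
one point per peptide-slice passing the significance filter, with the
peptide start position, the log2 mutant/normal intensity ratio, the total
ion current (point size) and the gel slice (point colour).  Negative
ratios mean the peptide is depleted in the mutant cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cleavage_inference import RegionSpec, infer_cleavage_positions, region_intensity_ratio
from .sequence_model import read_fasta, load_features
from .slice_quant import (
    DEFAULT_SCHEME,
    GelSliceScheme,
    IntensityTable,
    differential_peptides,
    read_intensity_table,
)
from .synthetic_data import PRESET_NAMES, preset, simulate_dataset

log = logging.getLogger(__name__)

__all__ = ["positional_report", "run_pipeline", "PipelineError"]

POINT_COLUMNS = [
    "protein_id", "start", "log2_ratio", "total_intensity", "slice", "p_value",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def positional_report(
    differential: pd.DataFrame,
    alpha: float = 0.01,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Points for the peptide-position vs log2-ratio view.

    Keeps one point per peptide-slice with an uncorrected p-value below
    ``alpha`` (mirroring the deliberately uncorrected selection used for
    this kind of exploratory peptide map).  Optionally renders the scatter
    to ``plot_path``.
    """
    if differential.empty:
        points = pd.DataFrame(columns=POINT_COLUMNS)
    else:
        sel = differential[differential["p_value"] < alpha]
        points = sel.rename(columns={})[
            ["protein_id", "start", "log2_ratio", "total_intensity", "slice", "p_value"]
        ].reset_index(drop=True)
    if plot_path is not None:
        _plot_points(points, plot_path)
    return points


def _plot_points(points: pd.DataFrame, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    proteins = sorted(points["protein_id"].unique()) if len(points) else []
    n = max(len(proteins), 1)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 5), squeeze=False)
    cmap = plt.get_cmap("tab10")
    for ax, pid in zip(axes[0], proteins or [""]):
        sub = points[points["protein_id"] == pid]
        slices = sorted(sub["slice"].unique())
        for i, lab in enumerate(slices):
            s = sub[sub["slice"] == lab]
            size = 5 + 40 * s["total_intensity"] / max(points["total_intensity"].max(), 1)
            ax.scatter(s["log2_ratio"], s["start"], s=size, color=cmap(i % 10),
                       label=f"slice {lab}", alpha=0.7)
        ax.axvline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("log2 ratio PKD1/normal")
        ax.set_ylabel("peptide start (aa)")
        ax.set_title(pid)
        if slices:
            ax.legend(fontsize=7)
        ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return config
    p = Path(config)
    if not p.exists():
        raise PipelineError(f"config: file not found: {p}")
    with open(p) as fh:
        return yaml.safe_load(fh) or {}


def _scheme_from_config(cfg: dict) -> GelSliceScheme:
    if "scheme" not in cfg:
        return DEFAULT_SCHEME
    return GelSliceScheme(
        windows=tuple(
            (w["label"], float(w["min_kDa"]), float(w["max_kDa"]))
            for w in cfg["scheme"]
        )
    )


def run_pipeline(
    config: str | Path | dict,
    out_dir: str | Path,
    seed: int | None = None,
    file_format: str = "tsv",
) -> dict:
    """Execute simulate/load -> differential -> ratios -> cleavage -> report.

    The config (YAML file or dict) provides either a synthetic ``preset``
    (plus ``seed``) or an input ``table`` path (with optional ``fasta`` and
    ``features``), plus optional ``alpha``, ``scheme`` and ``ratios``
    entries.  All outputs are delimited text under ``out_dir`` along with a
    ``manifest.json`` recording inputs, parameters and output hashes; runs
    are byte-reproducible for a fixed seed.  Returns the manifest.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sep = "\t" if file_format == "tsv" else ","
    ext = file_format
    alpha = float(cfg.get("alpha", 0.01))
    scheme = _scheme_from_config(cfg)
    use_seed = seed if seed is not None else cfg.get("seed", 1)
    manifest: dict = {
        "pccelv_version": __version__,
        "seed": use_seed,
        "alpha": alpha,
        "config": {k: v for k, v in cfg.items() if k != "scheme"},
        "outputs": {},
    }

    # --- stage: input -----------------------------------------------------
    checks = []
    truth = None
    if "preset" in cfg:
        name = cfg["preset"]
        if name not in PRESET_NAMES:
            raise PipelineError(f"input: unknown preset {name!r}")
        sim_cfg, checks = preset(name, seed=int(use_seed))
        table, truth = simulate_dataset(sim_cfg)
    elif "table" in cfg:
        tpath = Path(cfg["table"])
        if not tpath.exists():
            raise PipelineError(f"input: table file not found: {tpath}")
        table = read_intensity_table(tpath, scheme=scheme)
        if "fasta" in cfg:
            fpath = Path(cfg["fasta"])
            if not fpath.exists():
                raise PipelineError(f"input: FASTA file not found: {fpath}")
            proteins = read_fasta(fpath)
            if "features" in cfg:
                gpath = Path(cfg["features"])
                if not gpath.exists():
                    raise PipelineError(f"input: feature config not found: {gpath}")
                load_features(gpath, proteins)
    else:
        raise PipelineError("input: config needs either 'preset' or 'table'")

    table_path = out / f"intensity_table.{ext}"
    table.write(table_path, sep=sep)

    # --- stage: differential ---------------------------------------------
    try:
        diff = differential_peptides(table, alpha=alpha)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"differential: {exc}") from exc
    diff_path = out / f"differential.{ext}"
    diff.to_csv(diff_path, sep=sep, index=False, float_format="%.6g")

    # --- stage: ratios ----------------------------------------------------
    ratio_rows = []
    ratio_specs = cfg.get("ratios", [])
    for spec in ratio_specs:
        res = region_intensity_ratio(
            table,
            spec["protein_id"],
            RegionSpec(**spec["numerator"]),
            RegionSpec(**spec["denominator"]),
            boundary=spec.get("boundary"),
        )
        ratio_rows.append(res.__dict__)
    for c in checks:
        if c.kind == "region_ratio":
            res = region_intensity_ratio(
                table, c.protein_id, c.numerator, c.denominator, boundary=c.boundary
            )
            ratio_rows.append({**res.__dict__, "planted": c.expected})
    ratios_path = out / f"ratios.{ext}"
    pd.DataFrame(ratio_rows).to_csv(ratios_path, sep=sep, index=False,
                                    float_format="%.6g")

    # --- stage: cleavage inference ---------------------------------------
    call_rows = []
    for pid in sorted(table.data["protein_id"].unique()):
        for call in infer_cleavage_positions(table, pid, scheme):
            call_rows.append(call.__dict__)
    calls_path = out / f"cleavage_calls.{ext}"
    pd.DataFrame(
        call_rows,
        columns=["protein_id", "position", "interval_start", "interval_end",
                 "score", "n_nterm", "n_cterm", "resolution"],
    ).to_csv(calls_path, sep=sep, index=False, float_format="%.6g")

    # --- stage: report ----------------------------------------------------
    points = positional_report(
        diff, alpha=alpha,
        plot_path=(out / "positional_report.png") if cfg.get("plot") else None,
    )
    points_path = out / f"positional_report.{ext}"
    points.to_csv(points_path, sep=sep, index=False, float_format="%.6g")

    if truth is not None:
        truth.checks = checks
        truth.to_json(out / "ground_truth.json")

    for p in (table_path, diff_path, ratios_path, calls_path, points_path):
        manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %d outputs in %s", len(manifest["outputs"]), out)
    return manifest
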