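"""Reproducible pipeline over the analysis stages, with a run report.

A run is described by a JSON config: a list of stages, per-stage parameter
blocks, a global seed and an output directory.  Identical (config, seed,
inputs) give byte-identical TSV/JSON outputs.  Every filter applied anywhere
is tallied in the report, and per stage rows_in = rows_out + rows_filtered.

Simulation stages write the same TSV schemas the analysis stages read, plus
a ``truth`` table per simulation, so a simulate-then-analyze round trip
needs no path wiring: an analysis stage without an explicit input path uses
the simulated table from the same run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from granulescope import io as gio
from granulescope.foci import (
    CellFoci,
    build_demograph,
    count_fractions,
    match_foci_channels,
    normalize_positions,
    paired_position_correlation,
    spacing_deviation,
)
from granulescope.screen import ScreenConfig, run_screen
from granulescope.synthetic import (
    FociSimConfig,
    PsmSimConfig,
    TemSimConfig,
    simulate_foci_cells,
    simulate_psm,
    simulate_tem,
)
from granulescope.tem import compare_groups, ecdf_bootstrap, summarize_cells

__all__ = [
    "run_pipeline",
    "foci_cells_to_table",
    "table_to_foci_cells",
    "analyze_foci",
    "analyze_tem",
]

ARTIFACT_VERSION = "granulescope-0.1.0"

STAGES = ("simulate_psm", "simulate_foci", "simulate_tem",
          "screen", "foci", "tem")


# ---------------------------------------------------------------------------
# CellFoci <-> TSV
# ---------------------------------------------------------------------------

def foci_cells_to_table(cells: list[CellFoci]) -> pd.DataFrame:
    """Long foci table (cell_id, channel, length_um, position_um, intensity).

    Zero-foci cells emit one sentinel row per channel with NaN position so
    they survive the round trip (the table is per-focus otherwise).
    """
    rows = []
    for cell in cells:
        for channel, items in cell.foci.items():
            if not items:
                rows.append((cell.cell_id, channel, cell.length,
                             np.nan, np.nan))
            for pos, intensity in items:
                rows.append((cell.cell_id, channel, cell.length,
                             pos, intensity))
    return pd.DataFrame(rows, columns=[
        "cell_id", "channel", "length_um", "position_um", "intensity",
    ])


def table_to_foci_cells(table: pd.DataFrame) -> list[CellFoci]:
    """Rebuild per-cell foci objects from a long foci table."""
    cells = []
    for cell_id, cell_rows in table.groupby("cell_id", sort=False):
        length = float(cell_rows["length_um"].iloc[0])
        foci: dict[str, list[tuple[float, float]]] = {}
        for channel, ch_rows in cell_rows.groupby("channel", sort=False):
            observed = ch_rows.dropna(subset=["position_um"])
            foci[channel] = sorted(
                zip(observed["position_um"].astype(float),
                    observed["intensity"].astype(float))
            )
        cells.append(CellFoci(cell_id=str(cell_id), length=length, foci=foci))
    return cells


# ---------------------------------------------------------------------------
# Stage drivers
# ---------------------------------------------------------------------------

def analyze_foci(
    cells: list[CellFoci],
    channels: tuple[str, str] = ("dapi", "mapple"),
    max_dist_frac: float = 0.1,
    ideal_model: str = "equal_gap",
    n_bins: int = 50,
) -> dict:
    """Foci statistics over a cell population.

    Returns a dict with the per-cell spacing table, the pooled match-pair
    table, per-channel count fractions, and the cross-channel position
    correlation (NaN when fewer than 3 pairs match).
    """
    spacing_rows, match_rows = [], []
    results = []
    for cell in cells:
        for channel in channels:
            rel = np.sort(normalize_positions(cell, channel))
            if rel.size == 0:
                continue
            spacing_rows.append((
                cell.cell_id, channel, cell.length, rel.size,
                "|".join(f"{r:.6f}" for r in rel),
                spacing_deviation(rel, ideal_model),
            ))
        if channels[0] in cell.foci and channels[1] in cell.foci:
            match = match_foci_channels(cell, channels[0], channels[1],
                                        max_dist_frac)
            results.append(match)
            for pa, pb in match.pairs:
                match_rows.append((cell.cell_id, pa, pb, True))
            for pa in match.unmatched_a:
                match_rows.append((cell.cell_id, pa, np.nan, False))
            for pb in match.unmatched_b:
                match_rows.append((cell.cell_id, np.nan, pb, False))
    spacing = pd.DataFrame(spacing_rows, columns=[
        "cell_id", "channel", "length_um", "n_foci", "rel_positions",
        "spacing_deviation",
    ])
    matches = pd.DataFrame(match_rows, columns=[
        "cell_id", "rel_position_a", "rel_position_b", "matched",
    ])
    n_pairs = int(matches["matched"].sum()) if not matches.empty else 0
    correlation = (paired_position_correlation(results)
                   if n_pairs >= 3 else float("nan"))
    fractions = {}
    for channel in channels:
        try:
            summary = count_fractions(cells, channel)
            fractions[channel] = {
                "n_cells_with_foci": summary.n_cells_with_foci,
                "f1": summary.f1, "f2": summary.f2, "f_gt2": summary.f_gt2,
            }
        except ValueError:
            fractions[channel] = None
    return {
        "spacing": spacing,
        "matches": matches,
        "count_fractions": fractions,
        "pair_correlation": correlation,
        "n_pairs": n_pairs,
        "ideal_model": ideal_model,
        "max_dist_frac": max_dist_frac,
    }


def analyze_tem(
    granules: pd.DataFrame,
    cells: pd.DataFrame | None,
    metrics: tuple[str, ...] = ("count", "largest_volume", "total_volume"),
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Per-cell summaries, per-group ECDF bands and group comparisons."""
    summary = summarize_cells(granules, cells)
    groups = sorted(summary["group"].unique())
    ecdf_rows = []
    tests = {}
    for metric in metrics:
        samples = {}
        for group in groups:
            sub = summary[summary["group"] == group]
            values = sub[metric]
            if metric != "count":
                values = values.dropna()  # zero-granule cells have no volume
            values = values.to_numpy(dtype=float)
            samples[group] = values
            if values.size >= 5:
                band = ecdf_bootstrap(values, n_boot=n_boot,
                                      ci_level=ci_level, seed=seed)
                for g, e, lo, hi in zip(band.grid, band.ecdf,
                                        band.lower, band.upper):
                    ecdf_rows.append((metric, group, g, e, lo, hi))
        if len(groups) >= 2 and all(v.size >= 3 for v in samples.values()):
            report = compare_groups(samples)
            tests[metric] = {
                "test": report.test,
                "statistic": report.statistic,
                "p_value": report.p_value,
                "pairwise": (report.pairwise.to_dict("records")
                             if report.pairwise is not None else None),
                "warning": report.warning,
            }
    ecdf = pd.DataFrame(ecdf_rows, columns=[
        "metric", "group", "value", "ecdf", "lower", "upper",
    ])
    return {"summary": summary, "ecdf": ecdf, "tests": tests,
            "volume_model": "sphere: V = pi*d^3/6"}


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage_report(rows_in: int, rows_out: int, tallies: dict,
                  outputs: dict[str, str]) -> dict:
    return {
        "rows_in": int(rows_in),
        "rows_out": int(rows_out),
        "rows_filtered": int(rows_in - rows_out),
        "tallies": {k: int(v) for k, v in tallies.items()},
        "outputs": outputs,
    }


def _write_outputs(out_dir: Path, tables: dict[str, pd.DataFrame]) -> dict:
    digests = {}
    for name, df in tables.items():
        path = gio.write_tsv(df, out_dir / name)
        digests[name] = gio.file_digest(path)
    return digests


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the selected stages in dependency order; return the report.

    ``config`` keys: ``stages`` (list), ``seed`` (int), ``out_dir``
    (optional if given as argument), and one parameter block per stage.
    Raises :class:`granulescope.io.SchemaError` before writing anything if
    a referenced input table is invalid or missing.
    """
    out_dir = Path(out_dir if out_dir is not None else config["out_dir"])
    seed = int(config.get("seed", 0))
    stages = config.get("stages", list(STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]  # dependency order

    # validate all external inputs up front: fail before writing anything
    inputs: dict[str, pd.DataFrame] = {}
    blocks = {s: dict(config.get(s, {})) for s in stages}
    if "screen" in blocks and "psm" in blocks["screen"]:
        inputs["psm"] = gio.validate_table(blocks["screen"]["psm"],
                                           gio.PSM_SCHEMA)
    if "screen" in blocks and blocks["screen"].get("annotations"):
        inputs["annotations"] = gio.validate_table(
            blocks["screen"]["annotations"], gio.ANNOTATION_SCHEMA)
    if "foci" in blocks and "foci" in blocks["foci"]:
        inputs["foci"] = gio.validate_table(blocks["foci"]["foci"],
                                            gio.FOCI_SCHEMA)
    if "tem" in blocks and "granules" in blocks["tem"]:
        inputs["granules"] = gio.validate_table(blocks["tem"]["granules"],
                                                gio.GRANULE_SCHEMA)
    if "tem" in blocks and blocks["tem"].get("cells"):
        inputs["cells"] = gio.validate_table(blocks["tem"]["cells"],
                                             gio.CELLS_SCHEMA)
    if "screen" in stages and "psm" not in inputs \
            and "simulate_psm" not in stages:
        raise gio.SchemaError("screen stage needs a 'psm' input table")
    if "foci" in stages and "foci" not in inputs \
            and "simulate_foci" not in stages:
        raise gio.SchemaError("foci stage needs a 'foci' input table")
    if "tem" in stages and "granules" not in inputs \
            and "simulate_tem" not in stages:
        raise gio.SchemaError("tem stage needs a 'granules' input table")

    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "artifact_version": ARTIFACT_VERSION,
        "seed": seed,
        "config": config,
        "stages": {},
    }
    sim_cells: list[CellFoci] | None = None

    for stage in stages:
        block = blocks[stage]
        if stage == "simulate_psm":
            cfg = PsmSimConfig(**{**block, "seed": block.get("seed", seed)})
            table, truth = simulate_psm(cfg)
            truth_df = pd.DataFrame({"protein_id": sorted(truth)})
            digests = _write_outputs(out_dir, {
                "psm.tsv": table, "psm_truth.tsv": truth_df,
            })
            inputs["psm"] = table
            report["stages"][stage] = _stage_report(
                len(table), len(table),
                {"n_proteins": cfg.n_proteins, "n_enriched": len(truth)},
                digests)
        elif stage == "simulate_foci":
            block = dict(block)
            if "foci_count_weights" in block:
                block["foci_count_weights"] = tuple(block["foci_count_weights"])
            if "channels" in block:
                block["channels"] = tuple(block["channels"])
            cfg = FociSimConfig(**{**block, "seed": block.get("seed", seed)})
            sim_cells = simulate_foci_cells(cfg)
            table = foci_cells_to_table(sim_cells)
            truth_df = pd.DataFrame(
                [(c.cell_id, c.length,
                  "|".join(f"{r:.6f}" for r in c.truth))
                 for c in sim_cells],
                columns=["cell_id", "length_um", "true_rel_positions"])
            digests = _write_outputs(out_dir, {
                "foci.tsv": table, "foci_truth.tsv": truth_df,
            })
            inputs["foci"] = table
            report["stages"][stage] = _stage_report(
                len(table), len(table), {"n_cells": cfg.n_cells}, digests)
        elif stage == "simulate_tem":
            group_blocks = block.get("groups") or [block]
            granule_tables, cell_tables = [], []
            for i, gblock in enumerate(group_blocks):
                cfg = TemSimConfig(**{
                    **{k: v for k, v in gblock.items() if k != "groups"},
                    "seed": gblock.get("seed", seed + i),
                })
                granules, tem_cells = simulate_tem(cfg)
                granule_tables.append(granules)
                cell_tables.append(tem_cells)
            granules = pd.concat(granule_tables, ignore_index=True)
            tem_cells = pd.concat(cell_tables, ignore_index=True)
            digests = _write_outputs(out_dir, {
                "granules.tsv": granules,
                "tem_cells.tsv": tem_cells[["cell_id", "group", "count",
                                            "pre_fusion_count"]],
                "tem_truth.tsv": tem_cells,
            })
            inputs["granules"] = granules
            inputs["cells"] = tem_cells[["cell_id", "group"]]
            report["stages"][stage] = _stage_report(
                len(granules), len(granules),
                {"n_cells": len(tem_cells)}, digests)
        elif stage == "screen":
            cfg = ScreenConfig(**{k: v for k, v in block.items()
                                  if k not in ("psm", "annotations")})
            result = run_screen(inputs["psm"], inputs.get("annotations"), cfg)
            candidates = result[result["is_candidate"]].reset_index()
            digests = _write_outputs(out_dir, {
                "screen.tsv": result.reset_index(),
                "candidates.tsv": candidates,
            })
            report["stages"][stage] = _stage_report(
                len(result), len(result) - int(result["excluded"].sum()),
                {"proteins": len(result),
                 "excluded_ribosomal": int(result["excluded"].sum()),
                 "candidates": len(candidates)},
                digests)
        elif stage == "foci":
            cells = (sim_cells if sim_cells is not None
                     else table_to_foci_cells(inputs["foci"]))
            channels = tuple(block.get("channels", ("dapi", "mapple")))
            result = analyze_foci(
                cells, channels=channels,
                max_dist_frac=float(block.get("max_dist", 0.1)),
                ideal_model=block.get("ideal", "equal_gap"),
            )
            summary = {
                "count_fractions": result["count_fractions"],
                "pair_correlation": result["pair_correlation"],
                "n_pairs": result["n_pairs"],
                "ideal_model": result["ideal_model"],
                "max_dist_frac": result["max_dist_frac"],
            }
            digests = _write_outputs(out_dir, {
                "foci_spacing.tsv": result["spacing"],
                "foci_matches.tsv": result["matches"],
            })
            summary_path = out_dir / "foci_summary.json"
            summary_path.write_text(
                json.dumps(summary, indent=2, sort_keys=True) + "\n")
            digests["foci_summary.json"] = gio.file_digest(summary_path)
            n_cells = len(cells)
            with_foci = sum(
                1 for c in cells if any(c.n_foci(ch) > 0 for ch in channels))
            report["stages"][stage] = _stage_report(
                n_cells, with_foci,
                {"cells": n_cells, "cells_zero_foci": n_cells - with_foci},
                digests)
        elif stage == "tem":
            result = analyze_tem(
                inputs["granules"], inputs.get("cells"),
                metrics=tuple(block.get(
                    "metrics", ("count", "largest_volume", "total_volume"))),
                n_boot=int(block.get("n_boot", 1000)),
                ci_level=float(block.get("ci_level", 0.95)),
                seed=seed,
            )
            digests = _write_outputs(out_dir, {
                "tem_summary.tsv": result["summary"],
                "tem_ecdf.tsv": result["ecdf"],
            })
            tests_path = out_dir / "tem_tests.json"
            tests_path.write_text(
                json.dumps({"tests": result["tests"],
                            "volume_model": result["volume_model"]},
                           indent=2, sort_keys=True) + "\n")
            digests["tem_tests.json"] = gio.file_digest(tests_path)
            n_cells = len(result["summary"])
            zero = int((result["summary"]["count"] == 0).sum())
            report["stages"][stage] = _stage_report(
                n_cells, n_cells - zero,
                {"cells": n_cells, "cells_zero_granules": zero},
                digests)

    report_path = out_dir / "run_report.json"
    report_path.write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return report
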