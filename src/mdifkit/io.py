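"""Readers and writers for on-disk artifacts, plus the end-to-end pipeline.

Curve tables are delimited text; times on disk are seconds (PET
convention), converted to minutes on read. Dynamic volumes are NIfTI-1 with
a frame-timing sidecar (JSON with ``FrameTimesStart``/``FrameDuration`` in
seconds, BIDS-style, or a delimited table). Results are JSON for machines
plus an aligned-text summary for humans.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .fitting import CmrgluConfig, compare_curves, fit_standalone, make_weights, patlak
from .kinetics import TAC, TimeGrid
from .sime import AnchorSample, SimeProblem, fit_sime_idif, fit_sime_mdif

logger = logging.getLogger(__name__)

__all__ = [
    "read_tac_table",
    "write_tac_table",
    "read_anchors",
    "write_anchors",
    "read_timing",
    "write_timing",
    "read_dynamic_image",
    "write_dynamic_image",
    "run_pipeline",
]

_TIMING_COLS = ("frame_start_s", "frame_duration_s")


# ---------------------------------------------------------------------------
# TAC tables
# ---------------------------------------------------------------------------


def read_tac_table(path) -> tuple[TimeGrid, list[TAC]]:
    """Read a delimited TAC table.

    Wide format: columns ``frame_start_s``, ``frame_duration_s`` and one
    column per region. Long format additionally allowed: columns
    ``frame_start_s``, ``frame_duration_s``, ``region``, ``value_kBq_per_mL``.
    Rows may be unordered; they are sorted by frame start. Overlapping
    frames and non-numeric cells are rejected with the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    for col in _TIMING_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "region" in df.columns and "value_kBq_per_mL" in df.columns:
        wide = df.pivot_table(
            index=_TIMING_COLS[0],
            columns="region",
            values="value_kBq_per_mL",
            aggfunc="first",
        )
        dur = df.drop_duplicates(_TIMING_COLS[0]).set_index(_TIMING_COLS[0])[_TIMING_COLS[1]]
        df = wide.join(dur).reset_index()
    df = df.sort_values(_TIMING_COLS[0]).reset_index(drop=True)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise ValueError(f"{path}: non-numeric cell in column {col!r}, row {bad.idxmax()}")
        if df[col].isna().any():
            raise ValueError(f"{path}: missing value in column {col!r}")
    start = df[_TIMING_COLS[0]].to_numpy(float)
    dur = df[_TIMING_COLS[1]].to_numpy(float)
    ends = start + dur
    overlap = np.flatnonzero(start[1:] < ends[:-1] - 1e-9)
    if overlap.size:
        raise ValueError(f"{path}: frame at row {overlap[0] + 1} overlaps the previous frame")
    grid = TimeGrid.from_seconds(start, dur)
    tacs = [
        TAC(grid, df[col].to_numpy(float), label=str(col))
        for col in df.columns
        if col not in _TIMING_COLS
    ]
    if not tacs:
        raise ValueError(f"{path}: no region columns found")
    return grid, tacs


def write_tac_table(path, grid: TimeGrid, tacs: list[TAC]) -> None:
    data = {
        _TIMING_COLS[0]: np.round(grid.frame_start * 60.0, 9),
        _TIMING_COLS[1]: np.round(grid.frame_duration * 60.0, 9),
    }
    for tac in tacs:
        data[tac.label or f"region{len(data) - 1}"] = tac.values
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Anchors
# ---------------------------------------------------------------------------


def read_anchors(path) -> list[AnchorSample]:
    """Anchor table: columns ``time_min``, ``conc_kBq_per_mL`` (optional ``weight``)."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("time_min", "conc_kBq_per_mL"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out = []
    for _, row in df.iterrows():
        out.append(
            AnchorSample(
                time=float(row["time_min"]),
                concentration=float(row["conc_kBq_per_mL"]),
                weight=float(row.get("weight", 1.0)),
            )
        )
    return out


def write_anchors(path, anchors: list[AnchorSample]) -> None:
    pd.DataFrame(
        {
            "time_min": [a.time for a in anchors],
            "conc_kBq_per_mL": [a.concentration for a in anchors],
            "weight": [a.weight for a in anchors],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Frame timing and NIfTI volumes
# ---------------------------------------------------------------------------


def read_timing(path) -> TimeGrid:
    """Frame timing from BIDS-style JSON (seconds) or a delimited table."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        meta = json.loads(path.read_text())
        try:
            return TimeGrid.from_seconds(meta["FrameTimesStart"], meta["FrameDuration"])
        except KeyError as exc:
            raise ValueError(f"{path}: missing timing key {exc}") from None
    df = pd.read_csv(path, sep=None, engine="python")
    for col in _TIMING_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return TimeGrid.from_seconds(df[_TIMING_COLS[0]], df[_TIMING_COLS[1]])


def write_timing(path, grid: TimeGrid) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "FrameTimesStart": (grid.frame_start * 60.0).tolist(),
                "FrameDuration": (grid.frame_duration * 60.0).tolist(),
            },
            indent=1,
        )
    )


def read_dynamic_image(pet_path, timing_path, mask_paths: dict | None = None):
    """4D NIfTI volume + timing sidecar (+ named 3D NIfTI masks)."""
    import nibabel as nib

    from .clustering import DynamicImage

    nii = nib.load(str(pet_path))
    data = np.asanyarray(nii.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{pet_path}: expected a 4-D volume, got shape {data.shape}")
    grid = read_timing(timing_path)
    voxel = tuple(float(z) for z in nii.header.get_zooms()[:3])
    masks = {}
    for name, mpath in (mask_paths or {}).items():
        m = np.asanyarray(nib.load(str(mpath)).dataobj)
        masks[name] = m > 0.5
    return DynamicImage(data=data, grid=grid, voxel_size=voxel, masks=masks)


def write_dynamic_image(img, pet_path, timing_path=None, mask_dir=None) -> None:
    import nibabel as nib

    affine = np.diag(list(img.voxel_size) + [1.0])
    nib.Nifti1Image(img.data.astype(np.float32), affine).to_filename(str(pet_path))
    if timing_path is not None:
        write_timing(timing_path, img.grid)
    if mask_dir is not None:
        mask_dir = Path(mask_dir)
        mask_dir.mkdir(parents=True, exist_ok=True)
        for name, m in img.masks.items():
            nib.Nifti1Image(m.astype(np.uint8), affine).to_filename(
                str(mask_dir / f"{name.lower()}.nii.gz")
            )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    config: RunConfig,
    wb_tac: TAC,
    region_tacs: list[TAC],
    anchors: list[AnchorSample],
    true_input: TAC | None = None,
    mode: str = "mdif",
) -> dict:
    """SIME -> standalone refits -> Patlak/CMRGlu -> comparison report.

    Returns a JSON-serializable report carrying every constant, bound and
    seed used, per-region parameters, Ki (mL/100 g/min), optional CMRGlu,
    CV of Ki, windowed goodness-of-fit, and input-function comparisons
    (against ``true_input`` when provided).
    """
    logger.info("pipeline start: mode=%s config=%s", mode, config.provenance())
    problem = SimeProblem(
        wb_tac=wb_tac, region_tacs=region_tacs, anchors=anchors, R=config.R, mode=mode
    )
    fit_fn = fit_sime_mdif if mode == "mdif" else fit_sime_idif
    sime = fit_fn(problem, n_starts=config.sime_starts, seed=config.seed)
    cp = sime.input_function
    weights = make_weights(wb_tac.grid, wb_tac)
    cmr_cfg = (
        CmrgluConfig(config.lumped_constant, config.plasma_glucose)
        if config.compute_cmrglu
        else None
    )
    regions = []
    for tac in region_tacs:
        fit = fit_standalone(tac, cp, weights=weights, R=config.R)
        pat = patlak(tac, cp, t_star=config.t_star, cmrglu=cmr_cfg)
        p = fit.params
        regions.append(
            {
                "label": tac.label,
                "K1": p.K1,
                "k2": p.k2,
                "k3": p.k3,
                "Vb": p.Vb,
                "Ki_2tcm_mL_per_100g_min": 100.0 * p.Ki,
                "Ki_patlak_mL_per_100g_min": pat.Ki,
                "CMRGlu_umol_per_100g_min": pat.cmrglu,
                "cv_ki_pct": fit.cv_ki,
                "wrss": fit.wrss,
                "wrss_0_3min": fit.wrss_0_3min,
                "wrss_0_60min": fit.wrss_0_60min,
            }
        )
    report = {
        "config": config.provenance(),
        "mode": mode,
        "sime": sime.to_dict(),
        "regions": regions,
    }
    if true_input is not None:
        cmp_res = compare_curves(cp, true_input)
        report["input_function_vs_truth"] = {
            "auc_ratios": cmp_res.auc_ratios,
            "percent_difference": cmp_res.percent_difference,
        }
    return report


def write_report(report: dict, json_path, text_path=None) -> None:
    Path(json_path).write_text(json.dumps(report, indent=1, default=_jsonify))
    if text_path is not None:
        Path(text_path).write_text(summarize_report(report))


def summarize_report(report: dict) -> str:
    lines = ["mdifkit pipeline report", "=" * 32]
    lines.append("config: " + json.dumps(report["config"], default=_jsonify))
    sime = report["sime"]
    lines.append(
        f"SIME mode={sime['mode']} cost={sime['cost']:.4g} "
        f"n_params={sime['n_parameters']} converged={sime['converged']}"
    )
    hdr = f"{'region':<12}{'K1':>8}{'k2':>8}{'k3':>8}{'Vb':>8}{'Ki':>9}{'CV%':>8}"
    lines.append(hdr)
    for r in report["regions"]:
        lines.append(
            f"{r['label']:<12}{r['K1']:>8.4f}{r['k2']:>8.4f}{r['k3']:>8.4f}"
            f"{r['Vb']:>8.4f}{r['Ki_2tcm_mL_per_100g_min']:>9.3f}"
            f"{(r['cv_ki_pct'] if r['cv_ki_pct'] == r['cv_ki_pct'] else 0.0):>8.2f}"
        )
    if "input_function_vs_truth" in report:
        cmp_res = report["input_function_vs_truth"]
        lines.append(f"input function vs truth: AUC ratios {cmp_res['auc_ratios']}")
        lines.append(f"overall AUC percent difference: {cmp_res['percent_difference']:.3f}%")
    return "\n".join(lines) + "\n"


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
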