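"""File I/O, run configuration and the end-to-end pipeline.

Formats: MGF (BEGIN IONS / PEPMASS / RTINSECONDS dialect, via pyteomics) and
long-format CSV for spectra; CSV for assay tables, activity matrices and all
outputs; newick for dendrograms. Numeric formatting follows the reporting
conventions of the annotation tables: m/z at 4 decimals, ppm at 1,
percentages at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from . import __version__
from .activity_ranking import (
    ActivityMatrix,
    average_linkage,
    correlation_distance,
    heatmap_matrix,
    raci,
)
from .bioassay_metrics import DoseResponse, OracCurve, estimate_id50, orac_auc, orac_normalize
from .spectral_annotation import (
    MsmsSpectrum,
    Peak,
    annotate_library,
    class_relative_abundance,
    load_compound_library,
)

__all__ = [
    "RunConfig",
    "read_spectra",
    "write_mgf",
    "write_spectra_csv",
    "read_dose_response_csv",
    "read_orac_csv",
    "read_activity_matrix_csv",
    "write_activity_matrix_csv",
    "run_pipeline",
]

logger = logging.getLogger("teaphenol")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, resolved up front."""

    input_spectra: Optional[Path] = None
    spectra_format: str = "mgf"
    dose_response: Optional[Path] = None
    orac: Optional[Path] = None
    activity_matrix: Optional[Path] = None
    library: Optional[Path] = None     # None = shipped library
    out_dir: Path = Path("teaphenol_out")
    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.02
    id50_method: str = "interp"
    seed: int = 0
    run_label: str = "run"

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        for name in ("input_spectra", "dose_response", "orac",
                     "activity_matrix", "library"):
            p = getattr(self, name)
            if p is not None:
                setattr(self, name, Path(p).resolve())
        self.out_dir = Path(self.out_dir)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def read_spectra(path, format: str = "mgf") -> list[MsmsSpectrum]:
    """Read MS/MS spectra from MGF or long-format CSV.

    CSV columns: ``spectrum_id, precursor_mz, rt_min, mz, intensity`` (one row
    per fragment peak). Malformed records are skipped with a logged warning;
    zero parsable spectra is an error. The result is sorted by retention time,
    then precursor m/z.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mgf":
        spectra = _read_mgf(path)
    elif format == "csv":
        spectra = _read_spectra_csv(path)
    else:
        raise ValueError("format must be 'mgf' or 'csv'")
    if not spectra:
        raise ValueError(f"no parsable spectra in {path}")
    spectra.sort(key=lambda s: (s.rt if s.rt is not None else float("inf"),
                                s.precursor_mz))
    return spectra


def _read_mgf(path: Path) -> list[MsmsSpectrum]:
    spectra = []
    skipped = 0
    with _mgf.MGF(str(path)) as reader:
        for record in reader:
            try:
                params = record["params"]
                precursor = float(np.atleast_1d(params["pepmass"])[0])
                rt = params.get("rtinseconds")
                rt_min = float(rt) / 60.0 if rt is not None else None
                peaks = [Peak(float(mz), float(inten))
                         for mz, inten in zip(record["m/z array"],
                                              record["intensity array"])]
                title = str(params.get("title", ""))
                spectra.append(MsmsSpectrum(precursor, peaks, rt=rt_min,
                                            sample_id=title))
            except (KeyError, ValueError, TypeError) as exc:
                skipped += 1
                logger.warning("skipping malformed MGF block: %s", exc)
    if skipped:
        logger.warning("skipped %d malformed MGF block(s)", skipped)
    return spectra


def _read_spectra_csv(path: Path) -> list[MsmsSpectrum]:
    table = pd.read_csv(path)
    required = {"spectrum_id", "precursor_mz", "mz", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"spectra CSV missing column(s): {sorted(missing)}")
    spectra = []
    for sid, group in table.groupby("spectrum_id", sort=False):
        try:
            precursor = float(group["precursor_mz"].iloc[0])
            rt = float(group["rt_min"].iloc[0]) if "rt_min" in group else None
            peaks = [Peak(float(r.mz), float(r.intensity))
                     for r in group.itertuples(index=False)]
            spectra.append(MsmsSpectrum(precursor, peaks, rt=rt, sample_id=str(sid)))
        except (ValueError, TypeError) as exc:
            logger.warning("skipping malformed spectrum %r: %s", sid, exc)
    return spectra


def write_mgf(spectra: Sequence[MsmsSpectrum], path) -> None:
    """Write spectra as MGF (BEGIN IONS / PEPMASS / RTINSECONDS dialect)."""
    lines = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.sample_id}")
        lines.append(f"PEPMASS={s.precursor_mz:.6f}")
        if s.rt is not None:
            lines.append(f"RTINSECONDS={s.rt * 60.0:.3f}")
        for p in s.peaks:
            lines.append(f"{p.mz:.6f} {p.intensity:.6f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_spectra_csv(spectra: Sequence[MsmsSpectrum], path) -> None:
    rows = []
    for s in spectra:
        for p in s.peaks:
            rows.append({"spectrum_id": s.sample_id,
                         "precursor_mz": f"{s.precursor_mz:.6f}",
                         "rt_min": "" if s.rt is None else f"{s.rt:.4f}",
                         "mz": f"{p.mz:.6f}", "intensity": f"{p.intensity:.6f}"})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# assay tables
# ---------------------------------------------------------------------------

def read_dose_response_csv(path) -> list[DoseResponse]:
    """Long-format CSV: sample, assay, dose, response[, sd] → DoseResponse list."""
    table = pd.read_csv(path)
    missing = {"sample", "assay", "dose", "response"} - set(table.columns)
    if missing:
        raise ValueError(f"dose-response CSV missing column(s): {sorted(missing)}")
    out = []
    for (sample, assay), group in table.groupby(["sample", "assay"], sort=False):
        group = group.sort_values("dose")
        sds = group["sd"].to_numpy(float) if "sd" in group else None
        out.append(DoseResponse(sample_id=str(sample), assay=str(assay),
                                doses=group["dose"].to_numpy(float),
                                responses=group["response"].to_numpy(float),
                                sds=sds))
    return out


def read_orac_csv(path) -> list[OracCurve]:
    """Long-format CSV: sample, conc, time_min, fluorescence → OracCurve list."""
    table = pd.read_csv(path)
    missing = {"sample", "conc", "time_min", "fluorescence"} - set(table.columns)
    if missing:
        raise ValueError(f"ORAC CSV missing column(s): {sorted(missing)}")
    out = []
    for (sample, conc), group in table.groupby(["sample", "conc"], sort=False):
        group = group.sort_values("time_min")
        out.append(OracCurve(sample_id=str(sample), concentration=float(conc),
                             times=group["time_min"].to_numpy(float),
                             fluorescence=group["fluorescence"].to_numpy(float)))
    return out


_ORIENTATION_ROW = "orientation"


def read_activity_matrix_csv(path) -> ActivityMatrix:
    """Activity matrix CSV whose first data row declares metric orientations."""
    table = pd.read_csv(path, index_col=0)
    if _ORIENTATION_ROW not in table.index:
        raise ValueError("activity matrix CSV needs an 'orientation' row")
    orientation = table.loc[_ORIENTATION_ROW].to_dict()
    values = table.drop(index=_ORIENTATION_ROW).astype(float)
    return ActivityMatrix(values=values, orientation=orientation)


def write_activity_matrix_csv(m: ActivityMatrix, path) -> None:
    header = pd.DataFrame([m.orientation], index=[_ORIENTATION_ROW])
    pd.concat([header, m.values]).to_csv(path)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> Path:
    """Run the requested stages and write the artifact directory.

    Stages run in order: spectrum annotation (+ class relative abundance),
    assay metrics (ID50 per sample/assay), ORAC AUCs, RACI and clustering.
    Each stage failure aborts with a stage-tagged message. Outputs are
    deterministic for a fixed config.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"teaphenol {__version__}", f"label: {cfg.run_label}",
                 f"seed: {cfg.seed}",
                 f"precursor_tol_ppm: {cfg.precursor_tol_ppm}",
                 f"fragment_tol_da: {cfg.fragment_tol_da}",
                 f"id50_method: {cfg.id50_method}"]

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"[{name}] {exc}") from exc
        return wrap

    if cfg.input_spectra is not None:
        spectra = stage("read-spectra")(read_spectra, cfg.input_spectra,
                                        cfg.spectra_format)
        library = (stage("library")(load_compound_library, cfg.library)
                   if cfg.library else load_compound_library())
        table = stage("annotate")(annotate_library, spectra, library,
                                  cfg.precursor_tol_ppm,
                                  fragment_tol=cfg.fragment_tol_da)
        table.to_csv(out / "annotations.csv", index=False)
        log_lines.append(f"annotated spectra: {len(table)}")
        abundances = [(row["class"], 1.0) for _, row in table.iterrows()]
        shares = stage("class-abundance")(class_relative_abundance, abundances)
        pd.DataFrame(sorted(shares.items()), columns=["class", "percent"]) \
            .assign(percent=lambda d: d["percent"].round(1)) \
            .to_csv(out / "class_abundance.csv", index=False)

    if cfg.dose_response is not None:
        curves = stage("read-assays")(read_dose_response_csv, cfg.dose_response)
        rows = []
        for dr in curves:
            est = stage("id50")(estimate_id50, dr, method=cfg.id50_method)
            rows.append({"sample": dr.sample_id, "assay": dr.assay,
                         "id50": round(est.value, 4), "method": est.method,
                         "bracketed": est.bracketed})
        pd.DataFrame(rows).to_csv(out / "id50.csv", index=False)
        log_lines.append(f"dose-response curves: {len(curves)}")

    if cfg.orac is not None:
        curves = stage("read-orac")(read_orac_csv, cfg.orac)
        blanks = [c for c in curves if c.sample_id == "blank"]
        blank = blanks[0] if blanks else None
        rows = []
        for c in curves:
            normalized = orac_normalize(c, blank) if blank is not None else c
            auc = stage("orac")(orac_auc, normalized)
            net = auc - orac_auc(blank) if blank is not None else np.nan
            rows.append({"sample": c.sample_id, "conc": c.concentration,
                         "auc": round(auc, 4), "net_auc": round(net, 4)})
        pd.DataFrame(rows).to_csv(out / "orac_auc.csv", index=False)
        log_lines.append(f"ORAC curves: {len(curves)}")

    if cfg.activity_matrix is not None:
        matrix = stage("read-matrix")(read_activity_matrix_csv, cfg.activity_matrix)
        result = stage("raci")(raci, matrix)
        report = result.z.copy()
        report["RACI"] = result.raci
        report.round(4).to_csv(out / "raci.csv")
        scaled, row_order, col_order = stage("cluster")(heatmap_matrix, matrix)
        scaled.round(6).to_csv(out / "scaled_matrix.csv")
        in_order = scaled.loc[matrix.sample_ids, matrix.metric_ids]
        row_tree = average_linkage(correlation_distance(in_order.to_numpy()))
        col_tree = average_linkage(correlation_distance(in_order.to_numpy().T))
        (out / "rows.nwk").write_text(
            row_tree.to_newick([str(i) for i in matrix.sample_ids]) + "\n")
        (out / "columns.nwk").write_text(
            col_tree.to_newick([str(c) for c in matrix.metric_ids]) + "\n")
        log_lines.append(f"activity matrix: {matrix.values.shape[0]}x"
                         f"{matrix.values.shape[1]}")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
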