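"""Readers and writers for the clinical text and DICOM formats touched.

Conventions
-----------
* All doses are Gy internally; percent appears only at the CLI boundary.
* Grid coordinates are physical mm with the origin at the first voxel
  center; axis order is fixed with the slowest axis first (slice, row,
  column).  Non-axis-aligned DICOM orientations are rejected.
* Every reader rejects malformed input rather than silently coercing it.

Supported formats: the delimited DVH table dialect (see
:func:`read_dvh_table`), two-column beam MU tables, a plain-text dose-grid
format, DICOM RT Dose (dose-grid scaling and frame offsets applied) and
DICOM RT Plan (beam metersets only), YAML plan manifests, and JSON report
bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pydicom
import yaml
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .dvh import DVH
from .errors import ValidationError
from .gamma import DoseGrid
from .transition import (
    Beam,
    DecisionOutcome,
    PlanRecord,
    TransitionReport,
)

# ---------------------------------------------------------------------------
# DVH tables


def read_dvh_table(path: str | Path) -> DVH:
    """Read the delimited DVH dialect.

    Metadata lines: ``# structure=<label>``, ``# kind=cumulative|differential``,
    ``# volume_units=fraction|percent|cc`` (cc requires ``# total_cc=<v>``),
    followed by a ``dose_gy,volume`` header row and comma-separated data.
    Percent and cc volumes are normalized to fractions.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    line_numbers: list[int] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
            continue
        if not header_seen:
            if line.replace(" ", "") != "dose_gy,volume":
                raise ValidationError(
                    f"{path}:{lineno}: expected header 'dose_gy,volume', got {line!r}"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected two columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: non-numeric value") from exc
        line_numbers.append(lineno)
    if "kind" not in meta:
        raise ValidationError(f"{path}: missing '# kind=' metadata line")
    kind = meta["kind"]
    units = meta.get("volume_units", "fraction")
    dose = np.array([r[0] for r in rows])
    vol = np.array([r[1] for r in rows])
    if units == "percent":
        vol = vol / 100.0
    elif units == "cc":
        if "total_cc" not in meta:
            raise ValidationError(f"{path}: volume_units=cc requires '# total_cc='")
        total = float(meta["total_cc"])
        if total <= 0:
            raise ValidationError(f"{path}: total_cc must be positive")
        vol = vol / total
    elif units != "fraction":
        raise ValidationError(f"{path}: unknown volume_units {units!r}")
    if kind == "cumulative":
        bad = np.nonzero(np.diff(vol) > 1e-9)[0]
        if bad.size:
            raise ValidationError(
                f"{path}:{line_numbers[int(bad[0]) + 1]}: cumulative volume increases"
            )
    try:
        return DVH(
            structure_id=meta.get("structure", path.stem),
            kind=kind,  # type: ignore[arg-type]
            dose_bins=dose,
            volume=vol,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_dvh_table(dvh: DVH, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# structure={dvh.structure_id}",
        f"# kind={dvh.kind}",
        "# volume_units=fraction",
        "dose_gy,volume",
    ]
    lines += [f"{d:.10g},{v:.12g}" for d, v in zip(dvh.dose_bins, dvh.volume)]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Beam MU tables


def read_mu_table(path: str | Path) -> list[Beam]:
    """Read a two-column ``beam_id,mu`` table (optional header row)."""
    path = Path(path)
    beams: list[Beam] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected two columns")
        if lineno == 1 and parts == ["beam_id", "mu"]:
            continue
        bid = parts[0]
        try:
            mu = float(parts[1])
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: non-numeric MU") from exc
        if mu <= 0:
            raise ValidationError(f"{path}:{lineno}: MU must be positive")
        if bid in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate beam_id {bid!r}")
        seen.add(bid)
        beams.append(Beam(beam_id=bid, mu=mu))
    if not beams:
        raise ValidationError(f"{path}: no beams found")
    return beams


def write_mu_table(beams: list[Beam], path: str | Path) -> None:
    lines = ["beam_id,mu"] + [f"{b.beam_id},{b.mu:.10g}" for b in beams]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Plain-text dose grids


def read_grid_text(path: str | Path) -> DoseGrid:
    """Read the plain-text grid dialect: ``# shape=``, ``# spacing_mm=``,
    ``# origin_mm=`` headers then whitespace-separated row-major values."""
    path = Path(path)
    meta: dict[str, str] = {}
    values: list[float] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
            continue
        values.extend(float(tok) for tok in line.split())
    for key in ("shape", "spacing_mm", "origin_mm"):
        if key not in meta:
            raise ValidationError(f"{path}: missing '# {key}=' header")
    shape = tuple(int(x) for x in meta["shape"].split(","))
    spacing = tuple(float(x) for x in meta["spacing_mm"].split(","))
    origin = tuple(float(x) for x in meta["origin_mm"].split(","))
    arr = np.array(values)
    if arr.size != int(np.prod(shape)):
        raise ValidationError(
            f"{path}: expected {int(np.prod(shape))} values for shape {shape}, got {arr.size}"
        )
    return DoseGrid(values=arr.reshape(shape), spacing=spacing, origin=origin)


def write_grid_text(grid: DoseGrid, path: str | Path) -> None:
    lines = [
        "# shape=" + ",".join(str(n) for n in grid.values.shape),
        "# spacing_mm=" + ",".join(f"{s:.10g}" for s in grid.spacing),
        "# origin_mm=" + ",".join(f"{o:.10g}" for o in grid.origin),
    ]
    flat = grid.values.reshape(-1, grid.values.shape[-1])
    lines += [" ".join(f"{v:.10g}" for v in row) for row in flat]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# DICOM RT Dose / RT Plan

_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_RTPLAN_SOP = "1.2.840.10008.5.1.4.1.1.481.5"
_AXIAL_ORIENT = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]


def read_rtdose(path: str | Path) -> DoseGrid:
    """Read a DICOM RT Dose file into a :class:`DoseGrid` in Gy.

    Applies DoseGridScaling to the stored pixel values; spacing comes from
    PixelSpacing plus the GridFrameOffsetVector (which must be uniform);
    origin from ImagePositionPatient.  Only axis-aligned axial orientation
    is supported.  Single-frame files yield a 2-D grid.
    """
    ds = pydicom.dcmread(str(path))
    for tag in ("DoseGridScaling", "PixelSpacing", "ImagePositionPatient"):
        if tag not in ds:
            raise ValidationError(f"{path}: RT Dose missing required tag {tag}")
    orient = [float(x) for x in ds.get("ImageOrientationPatient", _AXIAL_ORIENT)]
    if not np.allclose(orient, _AXIAL_ORIENT):
        raise ValidationError(f"{path}: unsupported non-axial ImageOrientationPatient")
    scaling = float(ds.DoseGridScaling)
    values = ds.pixel_array.astype(float) * scaling
    row_sp, col_sp = (float(x) for x in ds.PixelSpacing)
    ipp = [float(x) for x in ds.ImagePositionPatient]
    if values.ndim == 3:
        if "GridFrameOffsetVector" not in ds:
            raise ValidationError(f"{path}: RT Dose missing required tag GridFrameOffsetVector")
        offsets = np.asarray([float(x) for x in ds.GridFrameOffsetVector])
        steps = np.diff(offsets)
        if steps.size == 0 or not np.allclose(steps, steps[0]):
            raise ValidationError(
                f"{path}: non-uniform GridFrameOffsetVector is an unsupported dialect"
            )
        spacing = (float(steps[0]), row_sp, col_sp)
        origin = (ipp[2] + offsets[0], ipp[1], ipp[0])
        return DoseGrid(values=values, spacing=spacing, origin=origin)
    return DoseGrid(values=values, spacing=(row_sp, col_sp), origin=(ipp[1], ipp[0]))


def write_rtdose(
    grid: DoseGrid, path: str | Path, dose_grid_scaling: float = 1e-4
) -> None:
    """Write a minimal axial RT Dose file (32-bit stored values).

    Doses are quantized to ``dose_grid_scaling`` Gy steps (default 0.1 mGy),
    so write/read round-trips are exact for already-quantized values.
    """
    values = grid.values
    stored = np.round(values / dose_grid_scaling).astype(np.uint32)
    if np.any(values / dose_grid_scaling > np.iinfo(np.uint32).max):
        raise ValidationError("dose exceeds the representable range at this scaling")

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_SOP
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _RTDOSE_SOP
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseGridScaling = dose_grid_scaling
    ds.ImageOrientationPatient = _AXIAL_ORIENT
    if values.ndim == 3:
        nz, ny, nx = values.shape
        ds.NumberOfFrames = nz
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [grid.spacing[1], grid.spacing[2]]
        ds.GridFrameOffsetVector = [i * grid.spacing[0] for i in range(nz)]
        ds.ImagePositionPatient = [grid.origin[2], grid.origin[1], grid.origin[0]]
    else:
        ny, nx = values.shape
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [grid.spacing[0], grid.spacing[1]]
        ds.ImagePositionPatient = [grid.origin[1], grid.origin[0], 0.0]
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_rtplan_mu(path: str | Path) -> list[Beam]:
    """Extract per-beam metersets from a DICOM RT Plan."""
    ds = pydicom.dcmread(str(path))
    if "FractionGroupSequence" not in ds:
        raise ValidationError(f"{path}: RT Plan missing FractionGroupSequence")
    names: dict[int, str] = {}
    for beam in ds.get("BeamSequence", []):
        names[int(beam.BeamNumber)] = str(getattr(beam, "BeamName", beam.BeamNumber))
    beams: list[Beam] = []
    for ref in ds.FractionGroupSequence[0].ReferencedBeamSequence:
        number = int(ref.ReferencedBeamNumber)
        mu = float(ref.BeamMeterset)
        if mu <= 0:
            raise ValidationError(f"{path}: beam {number} has non-positive meterset")
        beams.append(Beam(beam_id=names.get(number, str(number)), mu=mu))
    if not beams:
        raise ValidationError(f"{path}: RT Plan holds no referenced beams")
    return beams


def read_plan_mu(path: str | Path) -> list[Beam]:
    """Read per-beam MUs from either a DICOM RT Plan or a two-column table."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        return read_rtplan_mu(path)
    return read_mu_table(path)


def write_rtplan(beams: list[Beam], path: str | Path) -> None:
    """Write a minimal RT Plan carrying only beam names and metersets."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTPLAN_SOP
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _RTPLAN_SOP
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = "doseshift"
    beam_seq = []
    ref_seq = []
    for i, b in enumerate(beams, start=1):
        bd = Dataset()
        bd.BeamNumber = i
        bd.BeamName = b.beam_id
        beam_seq.append(bd)
        rd = Dataset()
        rd.ReferencedBeamNumber = i
        rd.BeamMeterset = b.mu
        ref_seq.append(rd)
    ds.BeamSequence = beam_seq
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.ReferencedBeamSequence = ref_seq
    ds.FractionGroupSequence = [fg]
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Plan manifests


def read_plan_manifest(path: str | Path) -> PlanRecord:
    """Read a YAML plan manifest into a :class:`PlanRecord`.

    Keys: ``label``, ``algorithm``, ``dose_mode``, ``dpr``, ``diso``,
    ``mu_table`` (path to MU table or RT Plan), ``dvhs`` (structure -> DVH
    file path) and optional ``dose_grid`` (text grid or RT Dose).  Relative
    paths resolve against the manifest's directory.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: manifest must be a mapping")
    for key in ("label", "algorithm", "dose_mode", "dpr", "diso", "mu_table", "dvhs"):
        if key not in data:
            raise ValidationError(f"{path}: manifest missing key {key!r}")
    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    mu_path = resolve(data["mu_table"])
    if mu_path.suffix.lower() == ".dcm":
        beams = read_rtplan_mu(mu_path)
    else:
        beams = read_mu_table(mu_path)
    dvhs = {s: read_dvh_table(resolve(p)) for s, p in data["dvhs"].items()}
    grid = None
    if data.get("dose_grid"):
        gp = resolve(data["dose_grid"])
        grid = read_rtdose(gp) if gp.suffix.lower() == ".dcm" else read_grid_text(gp)
    return PlanRecord(
        label=data["label"],
        algorithm=str(data["algorithm"]),
        dose_mode=data["dose_mode"],
        dpr=float(data["dpr"]),
        diso=float(data["diso"]),
        beams=tuple(beams),
        dvhs=dvhs,
        dose_grid=grid,
    )


def write_plan_manifest(
    plan: PlanRecord,
    directory: str | Path,
    name: str,
    grid_format: str = "text",
) -> Path:
    """Write a plan and its referenced data files under ``directory``.

    Returns the manifest path.  ``grid_format`` selects ``"text"`` or
    ``"dicom"`` for the dose grid (DVHs and MUs are always delimited text).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mu_file = f"{name}_mu.csv"
    write_mu_table(list(plan.beams), directory / mu_file)
    dvh_files = {}
    for s, d in plan.dvhs.items():
        fname = f"{name}_dvh_{s.replace(' ', '_').replace('/', '_')}.csv"
        write_dvh_table(d, directory / fname)
        dvh_files[s] = fname
    manifest: dict[str, Any] = {
        "label": plan.label,
        "algorithm": plan.algorithm,
        "dose_mode": plan.dose_mode,
        "dpr": float(plan.dpr),
        "diso": float(plan.diso),
        "mu_table": mu_file,
        "dvhs": dvh_files,
    }
    if plan.dose_grid is not None:
        if grid_format == "dicom":
            grid_file = f"{name}_dose.dcm"
            write_rtdose(plan.dose_grid, directory / grid_file)
        else:
            grid_file = f"{name}_dose.txt"
            write_grid_text(plan.dose_grid, directory / grid_file)
        manifest["dose_grid"] = grid_file
    out = directory / f"{name}.yaml"
    out.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


# ---------------------------------------------------------------------------
# Report bundles


def report_to_dict(report: TransitionReport) -> dict[str, Any]:
    """Serialize a transition report to plain JSON-compatible types."""

    def structure_rows(deltas):
        rows = {}
        for s, sd in deltas.items():
            row: dict[str, Any] = {
                name: {
                    "ref": md.ref,
                    "test": md.test,
                    "delta": md.delta,
                    "delta_percent": md.delta_percent,
                }
                for name, md in sd.metrics.items()
            }
            if sd.eud is not None:
                row["EUD"] = {"ref": sd.eud.ref, "test": sd.eud.test, "delta": sd.eud.delta}
                row[sd.probability_kind.upper()] = {
                    "ref": sd.probability.ref,
                    "test": sd.probability.test,
                    "delta": sd.probability.delta,
                }
            row["model_missing"] = sd.model_missing
            rows[s] = row
        return rows

    out: dict[str, Any] = {
        "target_structure": report.target_structure,
        "wilcoxon_p": report.wilcoxon_p,
        "wilcoxon_note": report.wilcoxon_note,
        "spearman_rho": report.spearman,
        "d95_delta_percent": report.d95_delta_percent,
        "d95_flag": report.d95_flag,
        "plan3_diso": report.plan3_diso,
        "gamma": [asdict(g) for g in report.gamma_summaries],
        "dvh_deltas_same_dpr": structure_rows(report.dvh_deltas_same_dpr),
        "dvh_deltas_same_mu": structure_rows(report.dvh_deltas_same_mu),
    }
    if report.delta_mu is not None:
        out["delta_mu"] = {
            "per_beam": report.delta_mu.per_beam,
            "per_beam_percent": report.delta_mu.per_beam_percent,
            "total_plan1": report.delta_mu.total_plan1,
            "total_plan2": report.delta_mu.total_plan2,
            "total": report.delta_mu.total,
            "total_percent": report.delta_mu.total_percent,
        }
    if report.decision is not None:
        out["decision"] = asdict(report.decision)
        out["decision"]["reasons"] = list(report.decision.reasons)
    return out


def write_report(report: TransitionReport, path: str | Path, **metadata: Any) -> None:
    payload = {"metadata": metadata, "report": report_to_dict(report)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")


def format_report_summary(report: TransitionReport) -> str:
    """Short human-readable summary of a transition report."""
    lines = []
    if report.delta_mu is not None:
        lines.append(
            f"Total MU: plan1 {report.delta_mu.total_plan1:.1f}, "
            f"plan2 {report.delta_mu.total_plan2:.1f} "
            f"(dMU {report.delta_mu.total:+.1f}, {report.delta_mu.total_percent:+.2f}%)"
        )
    if report.plan3_diso is not None:
        lines.append(f"Predicted plan3 Diso: {report.plan3_diso:.2f} Gy")
    if report.wilcoxon_p is not None:
        note = f" ({report.wilcoxon_note})" if report.wilcoxon_note else ""
        lines.append(f"Wilcoxon signed-rank p = {report.wilcoxon_p:.4g}{note}")
    if report.spearman is not None:
        lines.append(f"Spearman rho = {report.spearman:.3f}")
    if report.d95_delta_percent is not None:
        lines.append(
            f"Target D95% shift: {report.d95_delta_percent:+.2f}% -> {report.d95_flag}"
        )
    for g in report.gamma_summaries:
        lines.append(
            f"Gamma {g.dd_percent:g}%/{g.dta_mm:g}mm: pass rate {100 * g.pass_rate:.1f}% "
            f"({g.evaluated_count} points)"
        )
    if report.decision is not None:
        d = report.decision
        lines.append(f"Decision: {d.decision}")
        if d.suggested_dpr is not None:
            band = " (within the 5-10% band)" if d.in_5_10_band else ""
            lines.append(
                f"  suggested Dpr = {d.suggested_dpr:.2f} Gy "
                f"({d.percent_change:+.1f}%){band}"
            )
        for r in d.reasons:
            lines.append(f"  - {r}")
    return "\n".join(lines)
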