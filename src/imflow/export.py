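"""Spreadsheet export of image and object measurements with provenance.

One workbook (or one per job) collects: an "Images" sheet, one sheet per
object class, optional per-image summary statistics, and a "Configuration"
sheet holding the serialized workflow verbatim — so the exact workflow that
produced a result can be recovered from the result file itself.

Missing values become empty cells (never 0 or "NaN"). Column order is fixed
(metadata, id, timepoint, measurements sorted by name, relationships sorted
by class) so repeated runs diff cleanly.
"""

from __future__ import annotations

import csv
import datetime
import os
from dataclasses import dataclass, field

from openpyxl import Workbook, load_workbook

from .engine import Workflow, serialize_workflow
from .model import ObjectSet
from .workspace import Workspace

__all__ = [
    "ExportSpec",
    "summarise_image_measurements",
    "export_results",
    "read_configuration_text",
    "read_sheet_rows",
]

# fixed document timestamps keep repeated exports comparable
_EPOCH = datetime.datetime(2000, 1, 1)


@dataclass
class ExportSpec:
    """How results should be written.

    mode "combined" makes one workbook for the whole batch; "per-file" makes
    one per job. ``measurements`` is "all" or an explicit list of names.
    """

    output_path: str = "results.xlsx"
    mode: str = "combined"
    include_summary: bool = True
    measurements: object = "all"
    csv_mirror: bool = False


def _selected(names: list[str], spec: ExportSpec) -> list[str]:
    if spec.measurements == "all":
        return names
    wanted = set(spec.measurements)
    return [n for n in names if n in wanted]


def summarise_image_measurements(ws: Workspace) -> list[dict]:
    """Per-workspace summary statistics of every object-set measurement.

    Returns one row per (object set, measurement) with mean, min, max,
    sample standard deviation (n-1; missing when n < 2), sum and count.
    Empty sets yield a count of 0 and missing statistics.
    """
    rows: list[dict] = []
    for set_name in sorted(ws.objectsets):
        objects = ws.objectsets[set_name]
        names = objects.measurement_names()
        if not names and len(objects) == 0:
            rows.append({
                "object_set": set_name, "measurement": None,
                "mean": None, "min": None, "max": None, "std": None,
                "sum": None, "count": 0,
            })
            continue
        for name in names:
            values = [
                float(o.measurements[name])
                for o in objects
                if o.measurements.get(name) is not None
            ]
            n = len(values)
            if n == 0:
                stats = dict(mean=None, min=None, max=None, std=None, sum=None)
            else:
                mean = sum(values) / n
                std = (
                    (sum((v - mean) ** 2 for v in values) / (n - 1)) ** 0.5
                    if n > 1 else None
                )
                stats = dict(mean=mean, min=min(values), max=max(values),
                             std=std, sum=sum(values))
            rows.append({"object_set": set_name, "measurement": name,
                         "count": n, **stats})
    return rows


def _sheet_title(name: str) -> str:
    for ch in "[]:*?/\\":
        name = name.replace(ch, "_")
    return name[:31]


def _metadata_cells(ws: Workspace) -> list:
    m = ws.metadata
    return [m.filename, m.folder, m.series_name]


def _object_sheet_columns(sets: list[ObjectSet], spec: ExportSpec):
    measurements: set[str] = set()
    parent_classes: set[str] = set()
    partner_classes: set[str] = set()
    for objects in sets:
        measurements.update(objects.measurement_names())
        for obj in objects:
            parent_classes.update(obj.parents)
            partner_classes.update(obj.partners)
    return (_selected(sorted(measurements), spec), sorted(parent_classes),
            sorted(partner_classes))


def _build_workbook(workspaces: list[Workspace], workflow: Workflow,
                    spec: ExportSpec) -> Workbook:
    wb = Workbook()
    wb.properties.created = _EPOCH
    wb.properties.modified = _EPOCH

    # ---- image sheet
    sheet = wb.active
    sheet.title = "Images"
    image_measurements: set[str] = set()
    for ws in workspaces:
        for image in ws.images.values():
            image_measurements.update(image.measurements)
    image_cols = _selected(sorted(image_measurements), spec)
    sheet.append(["Filename", "Folder", "Series", "Image"] + image_cols)
    for ws in sorted(workspaces, key=lambda w: w.metadata.job_index):
        for name in sorted(ws.images):
            image = ws.images[name]
            sheet.append(
                _metadata_cells(ws) + [name]
                + [image.measurements.get(c) for c in image_cols]
            )

    # ---- one sheet per object class
    class_names = sorted({name for ws in workspaces for name in ws.objectsets})
    for class_name in class_names:
        sets = [ws.objectsets[class_name] for ws in workspaces
                if class_name in ws.objectsets]
        meas_cols, parent_cols, partner_cols = _object_sheet_columns(sets, spec)
        osheet = wb.create_sheet(_sheet_title(class_name))
        osheet.append(
            ["Filename", "Folder", "Series", "Object ID", "Timepoint"]
            + meas_cols
            + [f"PARENT_{c}_ID" for c in parent_cols]
            + [f"N_PARTNERS_{c}" for c in partner_cols]
        )
        for ws in sorted(workspaces, key=lambda w: w.metadata.job_index):
            objects = ws.objectsets.get(class_name)
            if objects is None:
                continue
            for obj in objects:
                row = _metadata_cells(ws) + [obj.id, obj.timepoint]
                row += [obj.measurements.get(c) for c in meas_cols]
                row += [
                    obj.parents[c].id if c in obj.parents else None
                    for c in parent_cols
                ]
                row += [len(obj.partners.get(c, {})) for c in partner_cols]
                osheet.append(row)

    # ---- optional per-image summary statistics
    if spec.include_summary:
        ssheet = wb.create_sheet("Summary")
        ssheet.append(["Filename", "Object set", "Measurement",
                       "Mean", "Min", "Max", "Std", "Sum", "Count"])
        for ws in sorted(workspaces, key=lambda w: w.metadata.job_index):
            for row in summarise_image_measurements(ws):
                ssheet.append([
                    ws.metadata.filename, row["object_set"], row["measurement"],
                    row["mean"], row["min"], row["max"], row["std"],
                    row["sum"], row["count"],
                ])

    # ---- embedded workflow configuration (verbatim, one line per row)
    csheet = wb.create_sheet("Configuration")
    for line in serialize_workflow(workflow).splitlines():
        csheet.append([line])
    return wb


def _write_csv_mirror(wb: Workbook, xlsx_path: str) -> None:
    stem = os.path.splitext(xlsx_path)[0]
    for sheet in wb.worksheets:
        path = f"{stem}_{_sheet_title(sheet.title)}.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for row in sheet.iter_rows(values_only=True):
                writer.writerow(["" if v is None else v for v in row])


def export_results(workspaces: list[Workspace], workflow: Workflow,
                   spec: ExportSpec) -> list[str]:
    """Write measurement workbooks and return the paths produced."""
    if not workspaces:
        raise ValueError("export_results needs at least one workspace")
    paths: list[str] = []
    if spec.mode == "combined":
        folder = os.path.dirname(spec.output_path)
        if folder:
            os.makedirs(folder, exist_ok=True)
        wb = _build_workbook(workspaces, workflow, spec)
        wb.save(spec.output_path)
        if spec.csv_mirror:
            _write_csv_mirror(wb, spec.output_path)
        paths.append(spec.output_path)
    elif spec.mode == "per-file":
        os.makedirs(spec.output_path, exist_ok=True)
        for ws in workspaces:
            stem = (os.path.splitext(ws.metadata.filename)[0]
                    or f"job{ws.metadata.job_index}")
            path = os.path.join(spec.output_path, f"{stem}_results.xlsx")
            wb = _build_workbook([ws], workflow, spec)
            wb.save(path)
            if spec.csv_mirror:
                _write_csv_mirror(wb, path)
            paths.append(path)
    else:
        raise ValueError(f"unknown export mode {spec.mode!r}")
    return paths


def read_configuration_text(xlsx_path: str) -> str:
    """Recover the serialized workflow embedded in an exported workbook."""
    wb = load_workbook(xlsx_path, read_only=True)
    try:
        sheet = wb["Configuration"]
        lines = [str(row[0]) if row[0] is not None else ""
                 for row in sheet.iter_rows(values_only=True)]
    finally:
        wb.close()
    return "\n".join(lines) + "\n"


def read_sheet_rows(xlsx_path: str, sheet_name: str) -> list[tuple]:
    """All rows of one sheet as value tuples (header first)."""
    wb = load_workbook(xlsx_path, read_only=True)
    try:
        sheet = wb[sheet_name]
        return [tuple(row) for row in sheet.iter_rows(values_only=True)]
    finally:
        wb.close()
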