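"""Batch processing: job discovery with name filters and isolated execution.

Pointing a run at a folder turns every valid image file in it (and its
subfolders) into an independent job with its own workspace. Filters on file,
folder and series names select which files participate; they combine
conjunctively. A failing job is recorded and the batch carries on.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

from .engine import RunOutcome, Workflow, execute_workflow
from .errors import ConfigurationError, ImflowError
from .export import ExportSpec, export_results
from .workspace import JobMetadata, Workspace

__all__ = ["JobFilter", "BatchReport", "discover_jobs", "run_batch",
           "DEFAULT_EXTENSIONS"]

DEFAULT_EXTENSIONS = (".tif", ".tiff")

_TARGETS = ("filename", "folder", "series")
_KINDS = ("contains", "not-contains", "matches-pattern")


@dataclass
class JobFilter:
    """One conjunctive filter on job metadata."""

    target: str  # filename | folder | series
    kind: str    # contains | not-contains | matches-pattern
    value: str

    def __post_init__(self):
        if self.target not in _TARGETS:
            raise ConfigurationError(f"unknown filter target {self.target!r}")
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown filter kind {self.kind!r}")

    @classmethod
    def parse(cls, text: str) -> "JobFilter":
        """Parse the CLI form TARGET:KIND:VALUE."""
        parts = text.split(":", 2)
        if len(parts) != 3:
            raise ConfigurationError(
                f"filter {text!r} must have the form TARGET:KIND:VALUE"
            )
        return cls(*parts)

    def accepts(self, job: JobMetadata) -> bool:
        subject = {
            "filename": job.filename,
            "folder": job.folder,
            "series": job.series_name,
        }[self.target]
        if self.kind == "contains":
            return self.value in subject
        if self.kind == "not-contains":
            return self.value not in subject
        return re.search(self.value, subject) is not None


@dataclass
class BatchReport:
    outcomes: list[RunOutcome] = field(default_factory=list)
    jobs: list[JobMetadata] = field(default_factory=list)
    output_paths: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    @property
    def n_completed(self) -> int:
        return sum(1 for o in self.outcomes if o.status == "completed")

    @property
    def n_terminated(self) -> int:
        return sum(1 for o in self.outcomes if o.status == "terminated")

    @property
    def n_failed(self) -> int:
        return sum(1 for o in self.outcomes if o.status == "failed")


def discover_jobs(root: str, filters: list[JobFilter] = (),
                  extensions: tuple[str, ...] = DEFAULT_EXTENSIONS) -> list[JobMetadata]:
    """Recursively list jobs under ``root`` in lexicographic order.

    A single-file root yields exactly one job (extension and filters still
    apply). Zero filters accept everything.
    """
    root = os.fspath(root)
    if not os.path.exists(root):
        raise IOError(f"no such input path: {root}")
    if os.path.isfile(root):
        candidates = [root]
    else:
        candidates = []
        for dirpath, dirnames, filenames in os.walk(root):
            dirnames.sort()
            for fn in sorted(filenames):
                candidates.append(os.path.join(dirpath, fn))
        candidates.sort()
    jobs: list[JobMetadata] = []
    for path in candidates:
        if os.path.splitext(path)[1].lower() not in extensions:
            continue
        job = JobMetadata.from_path(path, job_index=len(jobs))
        if all(f.accepts(job) for f in filters):
            job.job_index = len(jobs)
            jobs.append(job)
    for i, job in enumerate(jobs):
        job.job_index = i
    return jobs


def run_batch(workflow: Workflow, jobs: list[JobMetadata], spec: ExportSpec,
              context: dict | None = None) -> BatchReport:
    """Run each job in a fresh workspace and export the results.

    Job workspaces never interact, so job order cannot change any
    measurement. Jobs that fail (including structural validation surfaced at
    run time by a bad file) are recorded and skipped at export.
    """
    report = BatchReport()
    if not jobs:
        report.log.append("no jobs to process")
        return report
    exportable: list[Workspace] = []
    for job in jobs:
        ws = Workspace(metadata=job)
        job_context = dict(context or {})
        try:
            outcome = execute_workflow(workflow, ws, job_context)
        except ImflowError as exc:
            outcome = RunOutcome("failed", ["failed"] * len(workflow.modules),
                                 [str(exc)])
        report.jobs.append(job)
        report.outcomes.append(outcome)
        report.log.extend(f"{job.filename}: {line}" for line in outcome.log)
        if outcome.status in ("completed", "terminated"):
            exportable.append(ws)
    if exportable:
        report.output_paths = export_results(exportable, workflow, spec)
    else:
        report.log.append("no successful jobs; nothing exported")
    return report
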