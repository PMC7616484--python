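"""Workflow engine: module registry, reactive enablement, execution, text I/O.

A workflow is an ordered list of module invocations. Each invocation
(:class:`ModuleSpec`) names a registered module type, carries its parameters
(with per-parameter visibility flags for the simplified end-user view) and a
user enable flag. Execution is single-pass and linear; workflow-handling
modules may skip forward to a labelled module or terminate the run based on
workspace state.

Enablement is *reactive*: disabling a module effectively disables every
downstream module whose chain of named inputs is broken, without editing the
user flags. Workflows serialize to a canonical, versioned JSON dialect
(``.wf.json``) whose round trip is byte-stable, which is what allows the full
configuration to be embedded in exported spreadsheets and recovered later.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

from .errors import ConfigurationError, ImflowError, ValidationError, WorkflowParseError
from .workspace import Workspace

__all__ = [
    "Parameter",
    "ModuleSpec",
    "Workflow",
    "WorkflowModule",
    "ControlAction",
    "RunOutcome",
    "register_module",
    "registered_modules",
    "create_module_spec",
    "validate_workflow",
    "effective_enablement",
    "execute_workflow",
    "evaluate_condition",
    "serialize_workflow",
    "deserialize_workflow",
    "FORMAT_VERSION",
]

FORMAT_VERSION = 1

PARAMETER_KINDS = (
    "text", "number", "boolean", "choice",
    "input-image", "input-objects", "output-image", "output-objects",
    "file-path",
)

_INPUT_KINDS = ("input-image", "input-objects")
_OUTPUT_KINDS = ("output-image", "output-objects")


@dataclass
class Parameter:
    name: str
    kind: str
    value: object = None
    visible: bool = False
    options: tuple | None = None  # for kind == "choice"

    def __post_init__(self):
        if self.kind not in PARAMETER_KINDS:
            raise ConfigurationError(f"unknown parameter kind {self.kind!r}")

    def copy(self) -> "Parameter":
        return Parameter(self.name, self.kind, self.value, self.visible, self.options)


@dataclass
class ModuleSpec:
    """One module invocation in a workflow."""

    module_id: str
    nickname: str = ""
    enabled: bool = True
    parameters: list[Parameter] = field(default_factory=list)

    def __post_init__(self):
        if not self.nickname:
            self.nickname = self.module_id

    def param(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise ConfigurationError(f"module {self.module_id!r} has no parameter {name!r}")

    def get(self, name: str):
        return self.param(name).value

    def set(self, name: str, value) -> None:
        self.param(name).value = value

    def input_names(self) -> list[str]:
        return [str(p.value) for p in self.parameters if p.kind in _INPUT_KINDS and p.value]

    def output_names(self) -> list[str]:
        return [str(p.value) for p in self.parameters if p.kind in _OUTPUT_KINDS and p.value]


@dataclass
class Workflow:
    modules: list[ModuleSpec] = field(default_factory=list)
    format_version: int = FORMAT_VERSION

    def add(self, spec: ModuleSpec) -> "Workflow":
        self.modules.append(spec)
        return self


@dataclass
class ControlAction:
    """Returned by workflow-handling modules to redirect execution."""

    action: str  # "continue" | "skip_to" | "terminate"
    label: str = ""


@dataclass
class RunOutcome:
    """Result of executing one workflow on one workspace."""

    status: str  # "completed" | "terminated" | "failed"
    module_statuses: list[str]  # per module: executed|skipped|disabled|failed
    log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# module registry


class WorkflowModule(ABC):
    """Base class for executable module types.

    Subclasses declare a unique ``module_id``, their default parameters, and
    a ``run`` method operating on the workspace. Third-party modules extend
    the framework simply by registering additional subclasses.
    """

    module_id: str = ""
    #: set for modules whose effect is to delete their named inputs
    removes_inputs: bool = False

    @classmethod
    @abstractmethod
    def defaults(cls) -> list[Parameter]:
        """Fresh copies of the module's parameters with default values."""

    @abstractmethod
    def run(self, spec: ModuleSpec, ws: Workspace, context: dict) -> ControlAction | None:
        """Execute on a workspace; may return a control action."""


_REGISTRY: dict[str, type[WorkflowModule]] = {}


def register_module(cls: type[WorkflowModule]) -> type[WorkflowModule]:
    """Class decorator adding a module type to the global registry."""
    if not cls.module_id:
        raise ConfigurationError(f"{cls.__name__} declares no module_id")
    if cls.module_id in _REGISTRY:
        raise ConfigurationError(f"module id {cls.module_id!r} already registered")
    _REGISTRY[cls.module_id] = cls
    return cls


def registered_modules() -> dict[str, type[WorkflowModule]]:
    return dict(_REGISTRY)


def get_module(module_id: str) -> type[WorkflowModule]:
    try:
        return _REGISTRY[module_id]
    except KeyError:
        raise ConfigurationError(f"unknown module id {module_id!r}") from None


def create_module_spec(module_id: str, nickname: str = "", enabled: bool = True,
                       **values) -> ModuleSpec:
    """Build a ModuleSpec from a module's defaults, overriding given values."""
    cls = get_module(module_id)
    params = [p.copy() for p in cls.defaults()]
    spec = ModuleSpec(module_id, nickname or module_id, enabled, params)
    for name, value in values.items():
        p = spec.param(name)
        if p.kind == "choice" and p.options and value not in p.options:
            raise ConfigurationError(
                f"{module_id}.{name}: {value!r} not in options {p.options}"
            )
        p.value = value
    return spec


# ---------------------------------------------------------------------------
# validation and reactive enablement


def validate_workflow(workflow: Workflow) -> list[str]:
    """Structural validation, independent of enable flags.

    Reports unknown module ids, illegal choice values, and input names that
    no earlier module in the list could produce (so the reference could never
    be satisfied, whatever the enablement).
    """
    errors: list[str] = []
    producible: set[str] = set()
    for i, spec in enumerate(workflow.modules):
        where = f"module {i} ({spec.nickname!r})"
        if spec.module_id not in _REGISTRY:
            errors.append(f"{where}: unknown module id {spec.module_id!r}")
            continue
        for p in spec.parameters:
            if p.kind == "choice" and p.options and p.value not in p.options:
                errors.append(
                    f"{where}: parameter {p.name!r} value {p.value!r} "
                    f"not in options {p.options}"
                )
            if p.kind in _INPUT_KINDS:
                if not p.value:
                    errors.append(f"{where}: input parameter {p.name!r} is empty")
                elif str(p.value) not in producible:
                    errors.append(
                        f"{where}: input {p.value!r} is not produced by any "
                        f"earlier module"
                    )
        producible.update(spec.output_names())
    return errors


def effective_enablement(workflow: Workflow) -> list[bool]:
    """Per-module effective enabled flags.

    A module is effectively enabled iff its user flag is on and every named
    input is available: produced (or updated in place) by an effectively
    enabled earlier module and not removed since.
    """
    available: set[str] = set()
    flags: list[bool] = []
    for spec in workflow.modules:
        inputs = spec.input_names()
        eff = bool(spec.enabled) and all(name in available for name in inputs)
        flags.append(eff)
        if eff:
            cls = _REGISTRY.get(spec.module_id)
            if cls is not None and cls.removes_inputs:
                available.difference_update(inputs)
            else:
                available.update(spec.output_names())
    return flags


# ---------------------------------------------------------------------------
# condition evaluation (workflow-handling predicates)


_COMPARATORS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


def evaluate_condition(cond: dict, ws: Workspace) -> ControlAction:
    """Evaluate a workflow-handling predicate against the workspace.

    ``cond`` fields: ``test`` ("object-count" or "image-measurement"),
    ``target`` (object set / image name), ``measurement`` (for images),
    ``comparison`` (one of < <= > >= == !=), ``value`` (threshold),
    ``action`` ("skip_to" or "terminate") and ``label`` (for skip_to).
    Returns the action when the predicate holds, else "continue".
    """
    test = cond.get("test", "object-count")
    comparison = cond.get("comparison", "==")
    if comparison not in _COMPARATORS:
        raise ConfigurationError(f"unknown comparison {comparison!r}")
    threshold = float(cond.get("value", 0))
    if test == "object-count":
        actual = float(len(ws.get_objects(str(cond["target"]))))
    elif test == "image-measurement":
        image = ws.get_image(str(cond["target"]))
        name = str(cond.get("measurement", ""))
        if name not in image.measurements or image.measurements[name] is None:
            raise ValidationError(
                f"image {image.name!r} has no measurement {name!r}"
            )
        actual = float(image.measurements[name])
    else:
        raise ConfigurationError(f"unknown condition test {test!r}")
    if _COMPARATORS[comparison](actual, threshold):
        return ControlAction(cond.get("action", "terminate"), str(cond.get("label", "")))
    return ControlAction("continue")


# ---------------------------------------------------------------------------
# execution


def execute_workflow(workflow: Workflow, ws: Workspace,
                     context: dict | None = None) -> RunOutcome:
    """Run a workflow over a workspace.

    Structural validation failures raise :class:`ValidationError` before
    anything runs; exceptions raised *by* modules are caught and reported in
    the outcome so a batch can carry on with its other jobs.
    """
    errors = validate_workflow(workflow)
    if errors:
        raise ValidationError("; ".join(errors))
    if context is None:
        context = {}
    n = len(workflow.modules)
    eff = effective_enablement(workflow)
    statuses = ["pending"] * n
    log: list[str] = []
    status = "completed"
    skip_label: str | None = None

    for i, spec in enumerate(workflow.modules):
        if skip_label is not None:
            if spec.nickname == skip_label:
                skip_label = None  # resume from the labelled module
            else:
                statuses[i] = "skipped"
                continue
        if not eff[i]:
            statuses[i] = "disabled"
            if spec.enabled:
                log.append(
                    f"{spec.nickname}: disabled automatically (missing inputs)"
                )
            continue
        module = get_module(spec.module_id)()
        try:
            action = module.run(spec, ws, context)
        except Exception as exc:  # noqa: BLE001 - surfaced in the outcome
            statuses[i] = "failed"
            status = "failed"
            log.append(f"{spec.nickname}: failed: {exc}")
            break
        statuses[i] = "executed"
        if action is None or action.action == "continue":
            continue
        if action.action == "terminate":
            status = "terminated"
            log.append(f"{spec.nickname}: terminated workflow")
            break
        if action.action == "skip_to":
            later = [m.nickname for m in workflow.modules[i + 1:]]
            if action.label not in later:
                statuses[i] = "failed"
                status = "failed"
                log.append(
                    f"{spec.nickname}: skip_to label {action.label!r} not found "
                    f"later in the workflow"
                )
                break
            skip_label = action.label
            log.append(f"{spec.nickname}: skipping forward to {action.label!r}")

    for i in range(n):
        if statuses[i] == "pending":
            statuses[i] = "skipped"
    return RunOutcome(status, statuses, log)


# ---------------------------------------------------------------------------
# text serialization (canonical, versioned JSON dialect)


def workflow_to_dict(workflow: Workflow) -> dict:
    return {
        "format_version": workflow.format_version,
        "modules": [
            {
                "module_id": spec.module_id,
                "nickname": spec.nickname,
                "enabled": bool(spec.enabled),
                "parameters": [
                    {
                        "name": p.name,
                        "value": p.value,
                        "visible": bool(p.visible),
                    }
                    for p in sorted(spec.parameters, key=lambda p: p.name)
                ],
            }
            for spec in workflow.modules
        ],
    }


def serialize_workflow(workflow: Workflow) -> str:
    """Canonical text form: sorted keys, two-space indent, trailing newline."""
    return json.dumps(workflow_to_dict(workflow), sort_keys=True, indent=2) + "\n"


def deserialize_workflow(text: str) -> Workflow:
    """Parse the canonical text form back into a Workflow.

    Unknown module ids are a hard error naming the offending id; malformed
    documents raise :class:`WorkflowParseError` with line/column.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise WorkflowParseError(
            f"malformed workflow document at line {exc.lineno}, "
            f"column {exc.colno}: {exc.msg}"
        ) from None
    if not isinstance(doc, dict) or "modules" not in doc:
        raise WorkflowParseError("workflow document must be an object with 'modules'")
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise WorkflowParseError(
            f"unsupported format_version {version!r} (expected {FORMAT_VERSION})"
        )
    wf = Workflow(format_version=version)
    for i, entry in enumerate(doc["modules"]):
        module_id = entry.get("module_id")
        if module_id not in _REGISTRY:
            raise WorkflowParseError(
                f"module {i}: unknown module id {module_id!r}"
            )
        spec = create_module_spec(
            module_id,
            nickname=entry.get("nickname", module_id),
            enabled=bool(entry.get("enabled", True)),
        )
        declared = {p.name for p in spec.parameters}
        for pentry in entry.get("parameters", []):
            name = pentry.get("name")
            if name not in declared:
                raise WorkflowParseError(
                    f"module {i} ({module_id}): unknown parameter {name!r}"
                )
            p = spec.param(name)
            p.value = pentry.get("value")
            p.visible = bool(pentry.get("visible", False))
        wf.add(spec)
    return wf
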