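"""Workflow engine: reactive enablement, control flow, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import imflow.modules  # noqa: F401 - ensure registry is populated
from imflow.engine import (ControlAction, Parameter, Workflow, WorkflowModule,
                           create_module_spec, deserialize_workflow,
                           effective_enablement, execute_workflow,
                           evaluate_condition, register_module,
                           serialize_workflow, validate_workflow)
from imflow.errors import (ConfigurationError, ValidationError,
                           WorkflowParseError)
from imflow.model import ImageStack, ObjectSet
from imflow.workspace import Workspace

from .conftest import nucleus_workflow


def chain_workflow():
    """Load -> Threshold -> Identify, each consuming the previous output."""
    wf = Workflow()
    wf.add(create_module_spec("load_image", nickname="Load"))
    wf.add(create_module_spec("apply_threshold", nickname="Threshold",
                              input="Raw", output="Binary"))
    wf.add(create_module_spec("identify_objects", nickname="Identify",
                              input="Binary", output="Nuclei"))
    return wf


# ---------------------------------------------------------------------------
# reactive enablement


def test_disabling_a_module_disables_downstream_consumers():
    wf = chain_workflow()
    wf.modules[1].enabled = False
    assert effective_enablement(wf) == [True, False, False]


def test_disabling_a_leaf_module_affects_only_itself():
    wf = chain_workflow()
    wf.add(create_module_spec("measure_object_shape", input="Nuclei"))
    wf.modules[3].enabled = False
    assert effective_enablement(wf) == [True, True, True, False]


def test_re_enabling_restores_downstream():
    wf = chain_workflow()
    wf.modules[1].enabled = False
    wf.modules[1].enabled = True
    assert effective_enablement(wf) == [True, True, True]


def test_in_place_update_keeps_name_available():
    wf = chain_workflow()
    wf.modules.insert(2, create_module_spec("fill_holes", nickname="Fill",
                                            input="Binary", output=""))
    assert effective_enablement(wf) == [True, True, True, True]
    # but disabling the producer still cascades past the in-place step
    wf.modules[1].enabled = False
    assert effective_enablement(wf) == [True, False, False, False]


def test_remove_module_breaks_downstream_availability():
    wf = chain_workflow()
    wf.modules.insert(2, create_module_spec("remove_image", nickname="Drop",
                                            name="Binary"))
    assert effective_enablement(wf) == [True, True, True, False]


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_enablement_reactivity_is_monotone(seed):
    """Enabling one more module never effectively disables another."""
    rng = np.random.default_rng(seed)
    wf = nucleus_workflow()
    flags = rng.random(len(wf.modules)) < 0.6
    for spec, flag in zip(wf.modules, flags):
        spec.enabled = bool(flag)
    base = effective_enablement(wf)
    disabled = [i for i, f in enumerate(flags) if not f]
    if not disabled:
        return
    i = int(rng.choice(disabled))
    wf.modules[i].enabled = True
    grown = effective_enablement(wf)
    assert all(b <= g for b, g in zip(base, grown))


# ---------------------------------------------------------------------------
# validation


def test_validation_reports_unsatisfiable_input_before_run():
    wf = Workflow()
    wf.add(create_module_spec("apply_threshold", input="Raw", output="Binary"))
    errors = validate_workflow(wf)
    assert any("Raw" in e for e in errors)
    with pytest.raises(ValidationError):
        execute_workflow(wf, Workspace())


def test_validation_rejects_unknown_choice_value():
    wf = chain_workflow()
    wf.modules[1].param("algorithm").value = "triangle"
    assert any("triangle" in e for e in validate_workflow(wf))


def test_valid_workflow_has_no_errors():
    assert validate_workflow(nucleus_workflow()) == []


# ---------------------------------------------------------------------------
# conditions and control flow


def test_condition_on_object_count():
    ws = Workspace()
    ws.put_objects(ObjectSet("Nuclei"))
    action = evaluate_condition(
        {"test": "object-count", "target": "Nuclei", "comparison": "==",
         "value": 0, "action": "terminate"}, ws)
    assert action.action == "terminate"
    ws.get_objects("Nuclei").new_object()
    action = evaluate_condition(
        {"test": "object-count", "target": "Nuclei", "comparison": ">=",
         "value": 1, "action": "terminate"}, ws)
    assert action.action == "terminate"  # predicate holds -> act
    action = evaluate_condition(
        {"test": "object-count", "target": "Nuclei", "comparison": "==",
         "value": 0, "action": "terminate"}, ws)
    assert action.action == "continue"


def test_condition_on_image_measurement_and_missing_reference():
    ws = Workspace()
    img = ImageStack("Raw", np.zeros((1, 1, 1, 2, 2), np.uint8))
    img.add_measurement("MEAN_INTENSITY", 7.0)
    ws.put_image(img)
    action = evaluate_condition(
        {"test": "image-measurement", "target": "Raw",
         "measurement": "MEAN_INTENSITY", "comparison": ">", "value": 5,
         "action": "skip_to", "label": "Export"}, ws)
    assert (action.action, action.label) == ("skip_to", "Export")
    with pytest.raises(ValidationError):
        evaluate_condition(
            {"test": "image-measurement", "target": "Raw",
             "measurement": "NOPE", "comparison": ">", "value": 0}, ws)


@register_module
class _Marker(WorkflowModule):
    """Test helper: records its nickname in the context."""

    module_id = "_test_marker"

    @classmethod
    def defaults(cls):
        return [Parameter("fail", "boolean", False)]

    def run(self, spec, ws, context):
        if spec.get("fail"):
            raise RuntimeError("deliberate failure")
        context.setdefault("ran", []).append(spec.nickname)
        return None


def _handling(nickname="Gate", **values):
    return create_module_spec("workflow_handling", nickname=nickname, **values)


def test_terminate_marks_remaining_modules_skipped():
    ws = Workspace()
    ws.put_objects(ObjectSet("Nuclei"))  # empty set
    wf = Workflow()
    wf.add(create_module_spec("_test_marker", nickname="A"))
    wf.add(_handling(test="object-count", target="Nuclei", comparison="==",
                     value=0, action="terminate"))
    wf.add(create_module_spec("_test_marker", nickname="B"))
    context = {}
    outcome = execute_workflow(wf, ws, context)
    assert outcome.status == "terminated"
    assert outcome.module_statuses == ["executed", "executed", "skipped"]
    assert context.get("ran") == ["A"]


def test_skip_to_jumps_over_intermediate_modules_only():
    ws = Workspace()
    ws.put_objects(ObjectSet("Nuclei"))
    wf = Workflow()
    wf.add(_handling(test="object-count", target="Nuclei", comparison="==",
                     value=0, action="skip_to", label="After"))
    wf.add(create_module_spec("_test_marker", nickname="Middle"))
    wf.add(create_module_spec("_test_marker", nickname="After"))
    context = {}
    outcome = execute_workflow(wf, ws, context)
    assert outcome.status == "completed"
    assert outcome.module_statuses == ["executed", "skipped", "executed"]
    assert context.get("ran") == ["After"]


def test_module_exception_surfaces_as_failed_outcome():
    wf = Workflow()
    wf.add(create_module_spec("_test_marker", nickname="Boom", fail=True))
    outcome = execute_workflow(wf, Workspace())
    assert outcome.status == "failed"
    assert outcome.module_statuses == ["failed"]
    assert any("deliberate failure" in line for line in outcome.log)


def test_missing_condition_target_fails_the_job():
    wf = Workflow()
    wf.add(_handling(test="object-count", target="Ghost", comparison="==",
                     value=0))
    outcome = execute_workflow(wf, Workspace())
    assert outcome.status == "failed"


# ---------------------------------------------------------------------------
# serialization


def test_serialize_round_trip_is_byte_identical():
    wf = nucleus_workflow()
    wf.modules[1].param("manual_value").visible = True
    text = serialize_workflow(wf)
    again = serialize_workflow(deserialize_workflow(text))
    assert again == text


def test_visibility_and_enabled_flags_survive_round_trip():
    wf = nucleus_workflow()
    wf.modules[2].enabled = False
    wf.modules[5].param("threshold").visible = True
    wf2 = deserialize_workflow(serialize_workflow(wf))
    assert wf2.modules[2].enabled is False
    assert wf2.modules[5].param("threshold").visible is True


def test_unknown_module_id_is_named_in_the_error():
    text = serialize_workflow(nucleus_workflow()).replace(
        '"load_image"', '"warp_drive"')
    with pytest.raises(WorkflowParseError, match="warp_drive"):
        deserialize_workflow(text)


def test_malformed_document_reports_position():
    with pytest.raises(WorkflowParseError, match="line"):
        deserialize_workflow("{ not json")


def test_unknown_parameter_kind_rejected():
    with pytest.raises(ConfigurationError):
        Parameter("x", "matrix")
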