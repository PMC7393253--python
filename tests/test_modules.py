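import random
from datetime import datetime
from pathlib import Path

import pytest

from expipe import (
    ExpipeError,
    ObjectExistsError,
    ObjectNotFoundError,
    PathConflictError,
    Quantity,
)

TRACKING = {"box_shape": "square", "box_side": Quantity(1, "m")}


class TestModules:
    def test_create_module_writes_yaml(self, action, project):
        action.create_module("tracking", TRACKING)
        path = project.path / "actions/ecephys-1/modules/tracking.yaml"
        assert path.is_file()
        assert action.modules["tracking"].contents == TRACKING

    def test_duplicate_module_rejected(self, action):
        action.create_module("tracking", TRACKING)
        with pytest.raises(ObjectExistsError, match="module exists"):
            action.create_module("tracking", {})

    def test_project_level_module(self, project):
        project.create_module("lab", {"institute": "UiO"})
        assert (project.path / "modules/lab.yaml").is_file()
        assert project.modules["lab"]["institute"] == "UiO"

    def test_entity_module(self, project):
        e = project.create_entity("0007")
        e.create_module("subject", {"species": "rat"})
        assert (project.path / "entities/0007/modules/subject.yaml").is_file()


class TestUpdateKey:
    def test_nested_quantity_update(self, action):
        m = action.create_module("tracking", TRACKING)
        m.update_key(["box_side", "value"], 2)
        assert m.contents["box_side"] == {"value": 2, "unit": "m"}

    def test_intermediate_mappings_auto_created(self, action):
        m = action.create_module("m", {})
        m.update_key(["new", "deep", "key"], "x")
        assert m.contents == {"new": {"deep": {"key": "x"}}}

    def test_scalar_in_path_conflicts(self, action):
        m = action.create_module("tracking", TRACKING)
        with pytest.raises(PathConflictError, match="path conflict"):
            m.update_key(["box_shape", "value"], 1)

    def test_single_key_setitem_persists(self, action):
        m = action.create_module("m", {"a": 1})
        m["b"] = 2
        assert action.modules["m"].contents == {"a": 1, "b": 2}


class TestTemplates:
    def test_module_from_template_copies_contents(self, project, action):
        project.create_template("tracking", TRACKING)
        m = action.create_module(template="tracking")
        assert m.name == "tracking"  # name defaults to the template's
        assert m.contents == TRACKING

    def test_missing_template(self, action):
        with pytest.raises(ObjectNotFoundError, match="template not found"):
            action.create_module(template="ghost")

    def test_snapshot_template_edit_leaves_module_alone(self, project, action):
        tpl = project.create_template("tracking", TRACKING)
        m = action.create_module(template="tracking")
        before = (project.path / "actions/ecephys-1/modules/tracking.yaml").read_bytes()
        tpl.update_key(["box_side", "value"], 99)
        assert (
            project.path / "actions/ecephys-1/modules/tracking.yaml"
        ).read_bytes() == before

    def test_snapshot_module_edit_leaves_template_alone(self, project, action):
        project.create_template("tracking", TRACKING)
        m = action.create_module(template="tracking")
        before = (project.path / "templates/tracking.yaml").read_bytes()
        m.update_key(["box_side", "value"], 99)
        assert (project.path / "templates/tracking.yaml").read_bytes() == before

    @pytest.mark.parametrize("seed", range(10))
    def test_snapshot_independence_randomized(self, project, seed, tmp_path):
        from expipe import random_module_contents

        rng = random.Random(seed)
        tpl_name = f"tpl-{seed}"
        tpl = project.create_template(tpl_name, random_module_contents(rng, 3))
        a = project.create_action(f"a-{seed}")
        m = a.create_module(template=tpl_name)
        tpl_path = project.path / "templates" / f"{tpl_name}.yaml"
        mod_path = project.path / "actions" / f"a-{seed}" / "modules" / f"{tpl_name}.yaml"
        tpl_bytes, mod_bytes = tpl_path.read_bytes(), mod_path.read_bytes()
        if rng.random() < 0.5:
            tpl.update_key([f"k{seed}"], rng.randint(0, 9))
            assert mod_path.read_bytes() == mod_bytes
        else:
            m.update_key([f"k{seed}"], rng.randint(0, 9))
            assert tpl_path.read_bytes() == tpl_bytes


class TestMessages:
    def test_message_gets_creation_time_by_default(self, action):
        before = datetime.now()
        msg = action.create_message("channel 3 noisy", "alice")
        assert before <= msg.datetime <= datetime.now()
        stored = action.messages[msg.id]
        assert stored.text == "channel 3 noisy" and stored.user == "alice"

    def test_explicit_datetime_stored(self, action):
        msg = action.create_message("note", "bob", datetime="2020-07-24T12:00:00")
        assert msg.datetime == datetime(2020, 7, 24, 12)
        assert msg.id.startswith("20200724T120000")

    def test_empty_text_rejected(self, action):
        with pytest.raises(ExpipeError, match="empty message"):
            action.create_message("", "alice")

    def test_same_timestamp_gets_collision_suffix(self, action):
        dt = "2020-07-24T12:00:00"
        m1 = action.create_message("first", "alice", datetime=dt)
        m2 = action.create_message("second", "alice", datetime=dt)
        assert m2.id == f"{m1.id}-1"
        assert len(action.messages) == 2

    def test_listing_is_chronological(self, action):
        rng = random.Random(11)
        stamps = [datetime(2020, 1, 1 + rng.randrange(300) // 12, 1 + rng.randrange(23))
                  for _ in range(8)]
        for i, dt in enumerate(stamps):
            action.create_message(f"note {i}", "alice", datetime=dt)
        listed = [action.messages[id].datetime for id in action.messages]
        assert listed == sorted(listed)

    def test_entity_messages(self, project):
        e = project.create_entity("0007")
        e.create_message("weighed 412 g", "carol", datetime="2020-03-01T09:00:00")
        assert len(e.messages) == 1


class TestDataRegistry:
    def test_register_and_resolve_relative(self, action, project):
        action.register_data("tracking", "main.exdir")
        assert action.data == {"tracking": "main.exdir"}
        path = action.data_path("tracking")
        assert path == (project.path / "actions/ecephys-1/data/main.exdir").absolute()

    def test_opaque_server_string_returned_unchanged(self, action):
        action.register_data("raw", "/server/share/raw.dat")
        assert action.data_path("raw") == Path("/server/share/raw.dat")
        action.register_data("remote", "ssh://server/share/raw.dat")
        assert action.data_path("remote") == "ssh://server/share/raw.dat"

    def test_reregister_overwrites(self, action):
        action.register_data("k", "one.dat")
        action.register_data("k", "two.dat")
        assert action.data["k"] == "two.dat"

    def test_unknown_key(self, action):
        with pytest.raises(ObjectNotFoundError, match="data key not found"):
            action.data_path("ghost")

    @pytest.mark.parametrize("locator", ["../outside.dat", "a/../../b", "../../x"])
    def test_escaping_locator_rejected(self, action, locator):
        with pytest.raises(ExpipeError, match="escapes"):
            action.register_data("k", locator)

    def test_nested_relative_locator_stays_inside(self, action):
        action.register_data("k", "sub/dir/file.dat")
        path = action.data_path("k")
        data_dir = (action.project.path / "actions/ecephys-1/data").absolute()
        assert str(path).startswith(str(data_dir))
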