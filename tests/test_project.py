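from datetime import datetime

import pytest

import expipe
from expipe import (
    ExpipeError,
    InvalidIdentifierError,
    NotAProjectError,
    ObjectExistsError,
    ObjectNotFoundError,
    ObjectKind,
    ProjectExistsError,
    set_attribute,
)


class TestProjectLifecycle:
    def test_create_project_builds_tree(self, tmp_path):
        p = expipe.create_project(tmp_path / "project-x")
        assert (tmp_path / "project-x" / "expipe.yaml").is_file()
        assert len(p.actions) == len(p.entities) == len(p.templates) == 0

    def test_create_twice_fails(self, tmp_path):
        expipe.create_project(tmp_path / "project-x")
        with pytest.raises(ProjectExistsError):
            expipe.create_project(tmp_path / "project-x")

    def test_require_project_is_open_or_create(self, tmp_path):
        p1 = expipe.require_project(tmp_path / "p")
        p1.create_entity("0007")
        p2 = expipe.require_project(tmp_path / "p")
        assert "0007" in p2.entities

    def test_require_project_rejects_foreign_directory(self, tmp_path):
        d = tmp_path / "stuff"
        d.mkdir()
        (d / "unrelated.txt").write_text("hi")
        with pytest.raises(NotAProjectError, match="not an expipe project"):
            expipe.require_project(d)

    def test_get_project_requires_marker(self, tmp_path):
        with pytest.raises(NotAProjectError):
            expipe.get_project(tmp_path / "nothing")


class TestCreateObjects:
    def test_create_entity_makes_folder(self, project):
        project.create_entity("0007")
        assert (project.path / "entities" / "0007" / "attributes.yaml").is_file()

    def test_create_action_makes_folder_and_data_dir(self, project):
        a = project.create_action("ecephys-1")
        assert (project.path / "actions" / "ecephys-1" / "attributes.yaml").is_file()
        assert (project.path / "actions" / "ecephys-1" / "data").is_dir()
        assert a.entities == [] and a.data == {}

    @pytest.mark.parametrize("method", ["create_action", "create_entity"])
    def test_duplicate_id_rejected(self, project, method):
        getattr(project, method)("x1")
        with pytest.raises(ObjectExistsError, match="exists"):
            getattr(project, method)("x1")

    def test_invalid_id_rejected(self, project):
        with pytest.raises(InvalidIdentifierError):
            project.create_action("a/b")

    def test_new_objects_have_empty_attributes(self, project):
        e = project.create_entity("0007")
        assert e.tags == set() and e.users == set()
        assert e.location is None and e.type is None and e.datetime is None


class TestAttributes:
    def test_tags_persist_to_yaml(self, action, project):
        action.tags = {"11hz-stim", "open-field"}
        text = (project.path / "actions/ecephys-1/attributes.yaml").read_text()
        assert "- 11hz-stim" in text and "- open-field" in text

    def test_sets_deduplicate(self, action):
        action.users = ["alice", "alice", "bob"]
        assert action.users == {"alice", "bob"}

    def test_datetime_stored_iso(self, action, project):
        action.datetime = "2020-07-24T12:00:00"
        assert action.datetime == datetime(2020, 7, 24, 12)
        text = (project.path / "actions/ecephys-1/attributes.yaml").read_text()
        assert "'2020-07-24T12:00:00'" in text

    def test_entities_only_on_actions(self, project):
        entity = project.create_entity("0007")
        with pytest.raises(ExpipeError, match="attribute not applicable"):
            set_attribute(entity, "entities", ["0007"])

    def test_unknown_attribute_rejected(self, action):
        with pytest.raises(ExpipeError, match="unknown attribute"):
            set_attribute(action, "favourite_color", "blue")

    def test_empty_tag_rejected(self, action):
        with pytest.raises(ExpipeError):
            action.tags = {"ok", ""}

    def test_set_attribute_by_name(self, action):
        set_attribute(action, "location", "room-2")
        assert action.location == "room-2"

    def test_normalization_idempotent_on_disk(self, action, project):
        action.tags = {"b", "a"}
        path = project.path / "actions/ecephys-1/attributes.yaml"
        before = path.read_bytes()
        action.tags = {"a", "b"}
        assert path.read_bytes() == before


class TestWriteThrough:
    def test_second_handle_sees_committed_writes(self, tmp_path):
        p1 = expipe.create_project(tmp_path / "p")
        p2 = expipe.get_project(tmp_path / "p")
        a = p1.create_action("a1")
        a.tags = {"t"}
        assert p2.actions["a1"].tags == {"t"}

    def test_hand_edited_file_is_picked_up(self, action, project):
        path = project.path / "actions/ecephys-1/attributes.yaml"
        path.write_text(path.read_text().replace("location: null", "location: room-9"))
        assert action.location == "room-9"


class TestCollections:
    def test_mapping_protocol_and_order(self, project):
        project.create_action("a2")
        project.create_action("a1")
        actions = project.actions
        assert list(actions.keys()) == ["a1", "a2"]
        assert [id for id, _ in actions.items()] == ["a1", "a2"]
        assert len(actions) == 2
        assert "a1" in actions and "zz" not in actions
        assert actions["a1"].id == "a1"

    def test_empty_collection(self, project):
        assert len(project.templates) == 0
        assert list(project.templates) == []

    def test_unknown_id_raises(self, project):
        with pytest.raises(ObjectNotFoundError, match="not found"):
            project.actions["ghost"]

    def test_collection_keys_match_backend_listing(self, tmp_path):
        from expipe import FixtureSpec, generate_project

        manifest = generate_project(FixtureSpec(seed=3, n_actions=8), tmp_path / "fx")
        project = expipe.get_project(tmp_path / "fx")
        assert set(project.actions.keys()) == set(manifest.actions)
        assert set(project.actions.keys()) == project._backend.list_ids(
            ObjectKind.ACTION
        )


class TestDeletion:
    def test_delete_removes_object(self, project):
        project.create_entity("0007")
        project.delete_entity("0007")
        assert "0007" not in project.entities
        with pytest.raises(ObjectNotFoundError):
            project.entities["0007"]

    def test_delete_unknown_raises(self, project):
        with pytest.raises(ObjectNotFoundError):
            project.delete_action("ghost")

    def test_dangling_entity_reference_survives(self, project):
        project.create_entity("0007")
        a = project.create_action("a1")
        a.entities = ["0007"]
        project.delete_entity("0007")
        assert a.entities == ["0007"]  # relaxed integrity: no cascade

    def test_delete_object_dispatch(self, project):
        project.create_action("a1")
        expipe.delete_object(project, "action", "a1")
        assert len(project.actions) == 0
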