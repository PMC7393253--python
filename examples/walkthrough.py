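"""Canonical session: set up a small electrophysiology project.

Creates a project with one experimental subject (rat 0007) and one recording
action, tags the action, snapshots a tracking template into a module, logs a
lab-notebook message and registers the raw-data location.  Prints the
resulting tree and counts.
"""

import tempfile
from pathlib import Path

import expipe

workdir = Path(tempfile.mkdtemp())
project = expipe.create_project(workdir / "project-x")

rat = project.create_entity("0007")
rat.type = "rat"

action = project.create_action("ecephys-1")
action.tags = {"open-field", "11hz-stim"}
action.users = {"alice"}
action.datetime = "2020-07-24T12:00:00"
action.entities = ["0007"]

# a template describes the open-field arena once; each session snapshots it
project.create_template(
    "tracking", {"box_shape": "square", "box_side": expipe.Quantity(1, "m")}
)
module = action.create_module(template="tracking")
module.update_key(["box_side", "value"], 1.5)  # this session used a bigger box

action.create_message("channel 3 noisy", "alice")
action.register_data("main", "main.exdir")

print("project tree:")
for path in sorted(project.path.rglob("*")):
    print("  " + str(path.relative_to(workdir)))

print("\ntracking module contents:", module.contents)
print("data resolves to:", action.data_path("main"))
print("summary counts:", expipe.summarize(project))
# The tree is plain YAML under project-x/; the summary counts one action,
# one entity, one template, one message and one registered data key.
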