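# expipe

Lightweight, semi-structured metadata management for experimental projects
— built for laboratories (the design target is experimental neuroscience)
where the experimental pipeline evolves faster than any database schema
could be planned.

A project is nothing more than a conventional directory tree of
human-readable YAML files, so it can be hand-edited, grepped, diffed and
version-controlled (Git/Git-LFS/GIN) without any server or database
installation. The object model has five concepts:

- **Action** — an event at a point in time (a recording, a surgery, an
  analysis run) with the common attributes `tags`, `users`, `location`,
  `type`, `datetime` and a list of referenced `entities`.
- **Entity** — a long-lived thing used by actions, typically an
  experimental subject. Actions refer to entities by identifier only;
  integrity is deliberately relaxed (no foreign-key checks).
- **Module** — a nested key-value metadata record (one YAML file) attached
  to the project, an action, or an entity; e.g. the geometry of an
  open-field arena, with `{value, unit}` leaves for physical quantities.
- **Template** — a module blueprint stored at project level. Creating a
  module from a template takes a *snapshot* (a deep copy, never a link):
  later edits to either side cannot silently change the other, which keeps
  the recorded state of equipment trustworthy.
- **Message** — a timestamped, user-attributed note, i.e. a virtual
  lab-notebook entry.

Each action additionally carries a **data registry**: a map from string
keys to locators of the raw-data payloads (paths under the action's `data/`
folder, or opaque server paths/URIs). Payloads themselves are never parsed
— any file format goes.

## Worked example

```python
import expipe

project = expipe.create_project("project-x")
rat = project.create_entity("0007")

action = project.create_action("ecephys-1")
action.tags = {"open-field", "11hz-stim"}
action.datetime = "2020-07-24T12:00:00"
action.entities = ["0007"]

project.create_template("tracking",
    {"box_shape": "square", "box_side": expipe.Quantity(1, "m")})
module = action.create_module(template="tracking")   # snapshot copy
module.update_key(["box_side", "value"], 1.5)

action.create_message("channel 3 noisy", "alice")
action.register_data("main", "main.exdir")

print(module.contents)
print(action.data_path("main"))
print(expipe.summarize(project))
```

prints

```
{'box_shape': 'square', 'box_side': Quantity(1.5, 'm')}
/abs/path/project-x/actions/ecephys-1/data/main.exdir
{'actions': 1, 'entities': 1, 'templates': 1, 'project_modules': 0,
 'messages': 1, 'data_keys': 1}
```

The module contents are the template snapshot with this session's box size
filled in; the data path resolves the registered key under the action's
`data/` folder; the summary counts every stored object. On disk this is
`project-x/actions/ecephys-1/modules/tracking.yaml` and friends — open them
in a text editor and edits are picked up on the next read.

Exploration works on an indexed table (one row per action; multi-valued
columns `;`-joined):

```python
index = expipe.build_index(project)
ids = expipe.filter_actions(index, expipe.QuerySpec(tags_any={"11hz-stim"}))
expipe.export_csv(index, "actions.csv")   # RFC-4180, loads into pandas
```

The `examples/` directory contains runnable narrative scripts:
`walkthrough.py` (the session above), `explore_and_export.py`
(index/query/CSV on a generated 30-action project) and
`cli_and_plugins.py` (the command-line surface).

## Command line

```
expipe create <name>                              # new project in cwd
expipe list <actions|entities|templates> [--path] # one id per line
expipe export <dest.csv> [--path]                 # action index as CSV
expipe config global --add plugin <package>       # register a CLI plugin
```

Any installed package exposing `attach_to_cli(cli)` (or an `IPlugin`
subclass) can contribute subcommands; a broken plugin degrades to a warning
and never disturbs core commands. Try the bundled demo:

```
expipe config global --add plugin expipe.demo_plugin
expipe my_extension     # -> Welcome to Expipe!
```

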