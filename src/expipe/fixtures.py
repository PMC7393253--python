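"""Deterministic synthetic-project generator.

Builds randomized but fully reproducible project trees through the public
API only, together with a ground-truth manifest recording everything that
was generated.  The manifest is the oracle for property tests: any question
answerable from the project tree must be answerable identically from the
manifest.

Determinism: a single integer seed drives one explicit ``random.Random``
threaded through generation (message and action timestamps included — the
wall clock is never consulted), so the same spec always yields a
byte-identical tree.  Generated datetimes span a fixed two-year window
(2019-2020) so that date-range queries have non-degenerate selectivity.
"""

from __future__ import annotations

import os
import random
import string
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Any

from .project import Project, require_project
from .serialize import Quantity

__all__ = ["FixtureSpec", "FixtureManifest", "generate_project", "random_module_contents"]

_WINDOW_START = datetime(2019, 1, 1)
_WINDOW_SECONDS = int(timedelta(days=730).total_seconds())

_KEY_ALPHABET = string.ascii_lowercase + string.digits + "_"
_UNITS = ("m", "s", "Hz", "uV", "mm", "kg", "deg")
_LOCATIONS = ("room-1", "room-2", "rig-A", "rig-B")
_TYPES = ("recording", "surgery", "analysis", "simulation")


@dataclass
class FixtureSpec:
    """Knobs of the generator; the defaults model a small rodent
    electrophysiology project (a handful of subjects, tens of sessions)."""

    seed: int = 0
    n_entities: int = 4
    n_actions: int = 12
    n_templates: int = 3
    tag_pool: tuple = ("open-field", "11hz-stim", "sleep", "maze", "control", "opto")
    user_pool: tuple = ("alice", "bob", "carol")
    p_tag: float = 0.5
    p_module: float = 0.7
    p_message: float = 0.5
    p_data: float = 0.5
    max_module_depth: int = 3


@dataclass
class FixtureManifest:
    """Exact record of everything the generator created."""

    root: str
    entities: dict[str, dict] = field(default_factory=dict)
    actions: dict[str, dict] = field(default_factory=dict)
    templates: dict[str, dict] = field(default_factory=dict)
    project_modules: dict[str, dict] = field(default_factory=dict)


def _random_key(rng: random.Random) -> str:
    return "".join(rng.choice(_KEY_ALPHABET) for _ in range(rng.randint(3, 10)))


def _random_scalar(rng: random.Random):
    choice = rng.randrange(4)
    if choice == 0:
        return rng.randint(-1000, 1000)
    if choice == 1:
        return round(rng.uniform(-100, 100), 6)
    if choice == 2:
        return rng.random() < 0.5
    return "".join(rng.choice(string.ascii_letters + string.digits + " -_")
                   for _ in range(rng.randint(1, 20)))


def random_module_contents(rng: random.Random, max_depth: int) -> dict[str, Any]:
    """Random nested mapping with scalars, lists, quantities and sub-mappings.

    Depth is at most *max_depth*; ``max_depth=1`` yields a flat mapping.
    Keys come from a YAML-safe alphabet so output is round-trip friendly.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    contents: dict[str, Any] = {}
    for _ in range(rng.randint(1, 5)):
        key = _random_key(rng)
        roll = rng.random()
        if roll < 0.35 or max_depth == 1:
            contents[key] = _random_scalar(rng)
        elif roll < 0.55:
            contents[key] = [_random_scalar(rng) for _ in range(rng.randint(0, 4))]
        elif roll < 0.75:
            contents[key] = Quantity(round(rng.uniform(0, 100), 3), rng.choice(_UNITS))
        else:
            contents[key] = random_module_contents(rng, max_depth - 1)
    return contents


def _random_datetime(rng: random.Random) -> datetime:
    return _WINDOW_START + timedelta(seconds=rng.randrange(_WINDOW_SECONDS))


def _subset(rng: random.Random, pool, p: float) -> set[str]:
    return {item for item in pool if rng.random() < p}


def generate_project(spec: FixtureSpec, destination: str | os.PathLike) -> FixtureManifest:
    """Generate a project tree at *destination* and return its manifest.

    All objects are created through the public API — the generator doubles
    as an end-to-end exercise of it — and a given spec always produces a
    byte-identical tree.
    """
    rng = random.Random(spec.seed)
    project = require_project(destination)
    manifest = FixtureManifest(root=str(project.path))

    for i in range(spec.n_templates):
        name = f"template-{i:02d}"
        contents = random_module_contents(rng, spec.max_module_depth)
        project.create_template(name, contents)
        manifest.templates[name] = contents

    if rng.random() < spec.p_module and spec.n_templates + spec.n_actions > 0:
        contents = random_module_contents(rng, spec.max_module_depth)
        project.create_module("lab-info", contents)
        manifest.project_modules["lab-info"] = contents

    entity_ids = [f"{i:04d}" for i in range(1, spec.n_entities + 1)]
    for id in entity_ids:
        entity = project.create_entity(id)
        record = _populate_common(rng, spec, entity)
        record["modules"], record["messages"] = _populate_owned(rng, spec, project, entity)
        manifest.entities[id] = record

    for i in range(spec.n_actions):
        id = f"action-{i:03d}"
        action = project.create_action(id)
        record = _populate_common(rng, spec, action)
        refs = sorted(_subset(rng, entity_ids, 0.3))
        action.entities = refs
        record["entities"] = refs
        record["modules"], record["messages"] = _populate_owned(rng, spec, project, action)
        record["data"] = {}
        if rng.random() < spec.p_data:
            for key in ("main", "tracking", "raw")[: rng.randint(1, 3)]:
                locator = f"{key}.exdir" if rng.random() < 0.8 else f"/server/share/{id}/{key}.dat"
                action.register_data(key, locator)
                record["data"][key] = locator
                path = action.data_path(key)
                if not str(path).startswith("/server"):
                    path.parent.mkdir(parents=True, exist_ok=True)
                    path.write_text(f"synthetic placeholder payload for {id}/{key}\n")
        manifest.actions[id] = record

    return manifest


def _populate_common(rng: random.Random, spec: FixtureSpec, obj) -> dict:
    record: dict[str, Any] = {}
    tags = _subset(rng, spec.tag_pool, spec.p_tag)
    users = _subset(rng, spec.user_pool, 0.5)
    obj.tags = tags
    obj.users = users
    record["tags"] = tags
    record["users"] = users
    record["type"] = rng.choice(_TYPES) if rng.random() < 0.8 else None
    record["location"] = rng.choice(_LOCATIONS) if rng.random() < 0.6 else None
    record["datetime"] = _random_datetime(rng) if rng.random() < 0.9 else None
    if record["type"] is not None:
        obj.type = record["type"]
    if record["location"] is not None:
        obj.location = record["location"]
    if record["datetime"] is not None:
        obj.datetime = record["datetime"]
    return record


def _populate_owned(rng: random.Random, spec: FixtureSpec, project: Project, obj):
    modules: dict[str, dict] = {}
    messages: list[dict] = []
    if rng.random() < spec.p_module:
        for j in range(rng.randint(1, 2)):
            template_names = sorted(project.templates.keys())
            if template_names and rng.random() < 0.5:
                # exercise template-snapshot creation
                tpl = rng.choice(template_names)
                name = f"from-{tpl}-{j}"
                module = obj.create_module(name=name, template=tpl)
                modules[name] = module.contents
            else:
                name = f"module-{j}"
                contents = random_module_contents(rng, spec.max_module_depth)
                obj.create_module(name=name, contents=contents)
                modules[name] = contents
    if rng.random() < spec.p_message:
        for _ in range(rng.randint(1, 3)):
            text = f"note {_random_key(rng)}"
            user = rng.choice(spec.user_pool)
            dt = _random_datetime(rng)
            msg = obj.create_message(text, user, datetime=dt)
            messages.append({"id": msg.id, "text": text, "user": user, "datetime": dt})
    messages.sort(key=lambda m: (m["datetime"], m["id"]))
    return modules, messages
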