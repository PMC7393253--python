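"""Per-user global configuration.

A single YAML mapping (currently just the ``plugins`` list) stored in the
user configuration directory; the ``EXPIPE_CONFIG_PATH`` environment
variable overrides the location, which keeps tests and scripted use away
from the real user config.
"""

from __future__ import annotations

import os
from pathlib import Path

import click
import yaml

__all__ = ["config_path", "load_config", "save_config", "add_plugin", "remove_plugin"]


def config_path() -> Path:
    override = os.environ.get("EXPIPE_CONFIG_PATH")
    if override:
        return Path(override)
    return Path(click.get_app_dir("expipe")) / "config.yaml"


def load_config() -> dict:
    path = config_path()
    if not path.is_file():
        return {"plugins": []}
    data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        data = {}
    plugins = data.get("plugins") or []
    data["plugins"] = [p for p in plugins if isinstance(p, str)]
    return data


def save_config(config: dict) -> None:
    path = config_path()
    path.parent.mkdir(parents=True, exist_ok=True)
    text = yaml.safe_dump(dict(config), default_flow_style=False, sort_keys=False)
    path.write_text(text, encoding="utf-8")


def add_plugin(package: str) -> None:
    """Register *package* as a CLI plugin (idempotent)."""
    config = load_config()
    if package not in config["plugins"]:
        config["plugins"].append(package)
    save_config(config)


def remove_plugin(package: str) -> None:
    config = load_config()
    config["plugins"] = [p for p in config["plugins"] if p != package]
    save_config(config)
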