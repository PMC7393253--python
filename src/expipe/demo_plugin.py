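"""Bundled demonstration plugin.

Register it and invoke its subcommand::

    expipe config global --add plugin expipe.demo_plugin
    expipe my_extension

which prints a greeting — the minimal template for writing real plugins.
"""

import click

from .cli import IPlugin


class DemoPlugin(IPlugin):
    def attach_to_cli(self, cli: click.Group) -> None:
        @cli.command("my_extension")
        def my_extension():
            """Minimal demonstration subcommand."""
            click.echo("Welcome to Expipe!")
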