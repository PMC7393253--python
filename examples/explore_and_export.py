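"""Index, query and export a populated project.

Generates a synthetic 30-action project, builds the action index, filters it
by tag and by date range, and exports the table to CSV.
"""

import tempfile
from datetime import datetime
from pathlib import Path

import expipe

workdir = Path(tempfile.mkdtemp())
spec = expipe.FixtureSpec(seed=7, n_actions=30)
manifest = expipe.generate_project(spec, workdir / "fixture")
project = expipe.get_project(workdir / "fixture")

index = expipe.build_index(project)
print(f"indexed {len(index)} actions; first row: {index[0]}")

stim = expipe.filter_actions(index, expipe.QuerySpec(tags_any={"11hz-stim"}))
print(f"{len(stim)} actions carry the 11hz-stim tag: {stim[:5]} ...")

in_2019 = expipe.filter_actions(
    index,
    expipe.QuerySpec(
        datetime_from=datetime(2019, 1, 1), datetime_to=datetime(2019, 12, 31)
    ),
)
print(f"{len(in_2019)} actions are dated in 2019")

dest = workdir / "actions.csv"
expipe.export_csv(index, dest)
print(f"wrote {dest} ({dest.read_text().count(chr(10))} lines: header + one per action)")
# Each CSV row is one action; multi-valued columns (tags, users, entities,
# data keys) are ';'-joined, so the file loads directly into pandas.
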