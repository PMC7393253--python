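"""Independent brute-force oracles used by the property tests.

These operate directly on the fixture generator's manifest (the ground
truth), never through the index/filter code paths they are checking.
"""

from __future__ import annotations

import random
from datetime import timedelta

from expipe import QuerySpec
from expipe.fixtures import _WINDOW_SECONDS, _WINDOW_START


def brute_force_filter(manifest, query: QuerySpec) -> list[str]:
    """Scan manifest action records and apply the query semantics by hand."""
    hits = []
    for id in sorted(manifest.actions):
        rec = manifest.actions[id]
        tags = set(rec["tags"])
        users = set(rec["users"])
        entities = set(rec.get("entities", []))
        dt = rec["datetime"]
        if query.tags_any is not None and not (tags & set(query.tags_any)):
            continue
        if query.tags_all is not None and not set(query.tags_all) <= tags:
            continue
        if query.users_any is not None and not (users & set(query.users_any)):
            continue
        if query.entities_any is not None and not (entities & set(query.entities_any)):
            continue
        if query.datetime_from is not None or query.datetime_to is not None:
            if dt is None:
                continue
            if query.datetime_from is not None and dt < query.datetime_from:
                continue
            if query.datetime_to is not None and dt > query.datetime_to:
                continue
        if query.type_equals is not None and rec["type"] != query.type_equals:
            continue
        hits.append(id)
    return hits


def random_query(rng: random.Random, spec) -> QuerySpec:
    """A random, always-satisfiable-interval query over the fixture pools."""
    kwargs = {}
    if rng.random() < 0.4:
        kwargs["tags_any"] = set(rng.sample(spec.tag_pool, rng.randint(1, 3)))
    if rng.random() < 0.3:
        kwargs["tags_all"] = set(rng.sample(spec.tag_pool, rng.randint(1, 2)))
    if rng.random() < 0.3:
        kwargs["users_any"] = set(rng.sample(spec.user_pool, rng.randint(1, 2)))
    if rng.random() < 0.3:
        kwargs["entities_any"] = {f"{rng.randint(1, max(1, spec.n_entities)):04d}"}
    if rng.random() < 0.4:
        a = _WINDOW_START + timedelta(seconds=rng.randrange(_WINDOW_SECONDS))
        b = _WINDOW_START + timedelta(seconds=rng.randrange(_WINDOW_SECONDS))
        lo, hi = sorted((a, b))
        kwargs["datetime_from"] = lo
        kwargs["datetime_to"] = hi
    if rng.random() < 0.3:
        kwargs["type_equals"] = rng.choice(
            ("recording", "surgery", "analysis", "simulation")
        )
    return QuerySpec(**kwargs)
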