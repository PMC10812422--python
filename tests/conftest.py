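"""Shared fixtures: representative profiles, the level grid, event matching."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import HealthCheck, settings

from caninescore.taxonomy import BehaviorKind, CategoryProfile, category_profile

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


#: numeric values lying at the core (full membership) of each ordinal level
LEVEL_VALUES = {
    BehaviorKind.SCRATCH: {0: 26, 1: 80, 2: 200, 3: 320},
    BehaviorKind.LICK: {0: 3, 1: 12, 2: 30, 3: 50},
    BehaviorKind.SWALLOW: {0: 45, 1: 15, 2: 70},
    BehaviorKind.SLEEP: {0: 14.0, 1: 8.0, 2: 2.0},
}

#: published per-breed averages: (scratch/h, lick/h, swallow/h, sleep h)
BREED_ROWS = {
    "retriever": (122, 18, 42, 9.7),
    "siberian_husky": (42, 8, 58, 12.5),
    "jindo": (130, 22, 34, 8.7),
    "poodle": (53, 5, 74, 13.0),
    "beagle": (37, 9, 26, 13.2),
    "maltese": (40, 7, 61, 14.2),
    "shih_tzu": (144, 6, 50, 10.2),
    "other": (46, 3, 23, 12.4),
}

#: published breed weights and size classes
BREED_WEIGHTS = {
    "retriever": (26.2, "large"),
    "siberian_husky": (26.6, "large"),
    "jindo": (17.8, "large"),
    "poodle": (9.3, "medium"),
    "beagle": (7.8, "medium"),
    "maltese": (4.6, "small"),
    "shih_tzu": (5.7, "small"),
    "other": (9.8, "medium"),
}


def profile_from_levels(levels: dict[BehaviorKind, int]) -> CategoryProfile:
    return category_profile({k.value: LEVEL_VALUES[k][v] for k, v in levels.items()})


def profile_from_row(row) -> CategoryProfile:
    s, l, sw, sl = row
    return category_profile({"scratch": s, "lick": l, "swallow": sw, "sleep": sl})


def level_grid():
    """All 4 x 4 x 3 x 3 = 144 ordinal-level combinations."""
    for s, l, sw, sl in itertools.product(range(4), range(4), range(3), range(3)):
        yield {
            BehaviorKind.SCRATCH: s, BehaviorKind.LICK: l,
            BehaviorKind.SWALLOW: sw, BehaviorKind.SLEEP: sl,
        }


def match_events(true, found):
    """Greedy overlap matching; returns number of matched true events."""
    used = set()
    matched = 0
    for s, e in true:
        for i, (s2, e2) in enumerate(found):
            if i in used:
                continue
            if s2 < e and e2 > s:
                matched += 1
                used.add(i)
                break
    return matched


@pytest.fixture(scope="session")
def reference_fam():
    from caninescore.fam import reference_model
    return reference_model()
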