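"""Shared fixtures: rule set, random snapshots, small simulated cohorts."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

import ddiscreen as d

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from ddiscreen.rulebase import atc_matches
from ddiscreen.simulate import FILLER_POOL, witness_codes


@pytest.fixture(scope="session")
def rules():
    return d.load_default_rules()


@pytest.fixture(scope="session")
def code_vocab(rules):
    """A vocabulary mixing rule witnesses, fillers and assorted valid codes:
    rich enough that random snapshots regularly trigger rules."""
    vocab = set(FILLER_POOL)
    for r in rules:
        for v in range(3):
            vocab.update(witness_codes(r, v))
    vocab.update(["C07AB02", "C08CA01", "C10AA01", "C01BD01", "J01FA09",
                  "N06AB05", "L02BA01", "H02AB06", "A12BA01", "C09CA01"])
    return sorted(vocab)


def random_snapshot(rng, vocab, max_codes=10):
    k = int(rng.integers(0, max_codes + 1))
    return frozenset(rng.choice(vocab, size=k, replace=False))


def brute_force_rule_ids(codes, rules) -> set[int]:
    """Independent oracle: exhaustive enumeration over code pairs/subsets.

    Shares only the prefix-membership primitive (tested separately against
    hand-computed cases); the hit logic is re-derived from scratch.
    """
    codes = sorted(codes)
    out = set()
    for r in rules:
        if r.kind == "pairwise":
            g1, g2 = r.groups
            if any(
                a != b and atc_matches(a, g1) and atc_matches(b, g2)
                for a, b in itertools.permutations(codes, 2)
            ):
                out.add(r.rule_id)
        else:
            (g,) = r.groups
            if any(
                all(atc_matches(c, g) for c in comb)
                for comb in itertools.combinations(codes, r.min_count)
            ):
                out.add(r.rule_id)
    return out


@pytest.fixture(scope="session")
def small_cohort(rules):
    """A 300-patient cohort with follow-up, shared across read-only tests."""
    cfg = d.SimulationConfig(n_patients=300, seed=20240901)
    return d.generate_cohort(cfg, rules)


@pytest.fixture(scope="session")
def small_cohort_screen(small_cohort, rules):
    return d.screen_cohort(small_cohort.medications, rules)
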