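"""Shared fixtures: one default synthetic dataset and one full pipeline run
per session, reused across detection, orthology, replication and tree tests."""

import numpy as np
import pytest

from mge_atlas.pipeline_cli import analyze
from mge_atlas.synthetic_data import GeneratorConfig, generate_dataset

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def dataset():
    """Default-condition dataset (two orders, 6+6 hosts, one remnant,
    two free elements) at a fixed seed."""
    return generate_dataset(GeneratorConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def report(dataset):
    """Full pipeline report over the default dataset (families stage is
    exercised separately on a smaller protein set to keep the run short)."""
    return analyze(
        dataset.hosts,
        dataset.free_elements,
        dataset.spacers,
        dataset.metadata,
        dataset.core_ref,
        dataset.int_ref,
        dataset.host_markers,
        run_families=False,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 2+2-host dataset for fast determinism and CLI tests."""
    return generate_dataset(
        GeneratorConfig(seed=7, n_hosts_per_order=2, host_length=40_000)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ori_recovery_stats():
    """Ori recovery over 20 seeds: (hits, total) across every element with
    an implanted skew switch + repeat cluster."""
    from mge_atlas.replication import (
        call_ori,
        gc_skew_profile,
        repeat_ori_candidate,
        skew_ori_candidate,
    )

    hits = total = 0
    for seed in range(20):
        ds = generate_dataset(
            GeneratorConfig(seed=100 + seed, n_hosts_per_order=2)
        )
        for eid, t in ds.truth["elements"].items():
            if t["ori"] is None:
                continue
            seq = ds.element_sequence(eid)
            mid = (t["ori"][0] + t["ori"][1]) // 2 - t["span"][0]
            skew = skew_ori_candidate(
                gc_skew_profile(seq, circular=(t["host"] is None))
            )
            rep = repeat_ori_candidate(seq)
            calls = call_ori(skew, rep)
            total += 1
            hits += any(c.start - 2000 <= mid <= c.end + 2000 for c in calls)
    return hits, total


@pytest.fixture(scope="session")
def monophyly_stats():
    """Two-clade recovery on concatenated core NJ trees over 20 seeds:
    fraction of seeds where both order leaf-sets are monophyletic."""
    from mge_atlas.coevolution import (
        concatenated_distances,
        nj_tree,
        test_monophyly,
    )

    ok = 0
    for seed in range(20):
        ds = generate_dataset(GeneratorConfig(seed=200 + seed))
        fams = {
            eid: {k: v for k, v in t["families"].items()
                  if k.startswith("t26-")}
            for eid, t in ds.truth["elements"].items()
        }
        tree = nj_tree(concatenated_distances(fams))
        orders = {eid: t["order"]
                  for eid, t in ds.truth["elements"].items()}
        a = {e for e, o in orders.items() if o == "A"}
        b = {e for e, o in orders.items() if o == "B"}
        ok += test_monophyly(tree, a) and test_monophyly(tree, b)
    return ok / 20


def random_protein(rng, n):
    return "M" + "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, n - 1))


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
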