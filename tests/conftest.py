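import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tnscreen import ConstructSpec, parse_construct_spec
from tnscreen.simulate import sim_genome, sim_library

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def spec4() -> ConstructSpec:
    """Small construct: 4-bp barcode, 10-bp anchor."""
    return ConstructSpec(barcode_length=4, end_sequence="GTGTATAAGA")


@pytest.fixture(scope="session")
def tn5_spec() -> ConstructSpec:
    return parse_construct_spec("B17GTGTATAAGAGACAG")


@pytest.fixture(scope="session")
def small_genome():
    return sim_genome(seed=1, length_bp=120_000, n_genes=60)


@pytest.fixture(scope="session")
def small_library(small_genome):
    return sim_library(small_genome, n_insertions=60, seed=2)


def dp_levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming edit distance oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_force_merge(tally: dict, max_edit_distance: int) -> dict:
    """All-pairs DP-Levenshtein greedy-by-abundance clustering oracle."""
    merged: dict = {}
    accepted: list = []
    for bc in sorted(tally, key=lambda b: (-tally[b], b)):
        target = None
        for acc in accepted:
            if dp_levenshtein(bc, acc) < max_edit_distance:
                target = acc
                break
        if target is None:
            accepted.append(bc)
            merged[bc] = tally[bc]
        else:
            merged[target] += tally[bc]
    return merged


def random_barcode_tally(rng: np.random.Generator, n_barcodes: int, length: int = 6) -> dict:
    """Random tally with deliberate near-duplicates to exercise merging."""
    bases = np.array(list("ACGT"))
    tally = {}
    while len(tally) < n_barcodes:
        bc = "".join(rng.choice(bases, size=length))
        if rng.random() < 0.4 and tally:
            parent = list(tally)[int(rng.integers(0, len(tally)))]
            pos = int(rng.integers(0, length))
            bc = parent[:pos] + str(rng.choice(bases)) + parent[pos + 1 :]
        if bc not in tally:
            tally[bc] = int(rng.integers(1, 100))
    return tally
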