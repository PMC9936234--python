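"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from repclon import SubtypeProfile
from repclon.io_clonotypes import CELL_TYPES_22, CLONOTYPE_COLUMNS

NT = "ACGT"


def make_records(rows, sample_id="S1", chain="IGH"):
    """Build a clonotype record frame from (v, j, cdr3, count) tuples."""
    return pd.DataFrame(
        [
            dict(sample_id=sample_id, chain=chain, v_gene=v, j_gene=j,
                 cdr3_nt=c, read_count=n)
            for v, j, c, n in rows
        ],
        columns=list(CLONOTYPE_COLUMNS),
    )


def random_instance(rng: np.random.Generator, n: int, chain="IGH") -> pd.DataFrame:
    """Random clonotype set with intentionally colliding keys and near-identical
    CDR3s, to exercise the clone rule's grouping and linkage paths."""
    founders = {}
    rows = []
    for _ in range(n):
        v = f"{chain}V{rng.integers(1, 4)}"
        j = f"{chain}J{rng.integers(1, 3)}"
        length = int(rng.choice([9, 12, 15, 21]))
        key = (v, j, length)
        pool = founders.setdefault(key, [])
        if pool and rng.random() < 0.7:
            # mutate an existing sequence by 0-3 positions
            base = list(pool[rng.integers(0, len(pool))])
            for p in rng.choice(length, size=rng.integers(0, 4), replace=False):
                base[p] = NT[rng.integers(0, 4)]
            seq = "".join(base)
        else:
            seq = "".join(NT[i] for i in rng.integers(0, 4, length))
        pool.append(seq)
        rows.append((v, j, seq, int(rng.integers(1, 50))))
    return make_records(rows, chain=chain)


def brute_force_clones(records: pd.DataFrame, threshold: float):
    """Independent clone-partition oracle: enumerate all record pairs, link
    those satisfying the rule in a networkx graph, take components."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(records)))
    rows = list(records[["v_gene", "j_gene", "cdr3_nt"]].itertuples(index=False))
    for i in range(len(rows)):
        for k in range(i + 1, len(rows)):
            a, b = rows[i], rows[k]
            if a.v_gene != b.v_gene or a.j_gene != b.j_gene:
                continue
            if len(a.cdr3_nt) != len(b.cdr3_nt):
                continue
            matches = sum(x == y for x, y in zip(a.cdr3_nt, b.cdr3_nt))
            if matches / len(a.cdr3_nt) >= threshold - 1e-12:
                g.add_edge(i, k)
    return {frozenset(c) for c in nx.connected_components(g)}


def partition_sets(labels) -> set[frozenset]:
    out = {}
    for idx, lab in enumerate(labels):
        out.setdefault(lab, set()).add(idx)
    return {frozenset(s) for s in out.values()}


def light_profile(
    n_samples: int,
    *,
    chain: str = "TRB",
    log10_clones: float = 1.5,
    depth: float = 300.0,
    alpha: float = 0.7,
    log_hr: float = 0.0,
    rho: float = 0.0,
) -> SubtypeProfile:
    """Single-chain profile for fast simulation-based statistics tests."""
    return SubtypeProfile(
        name="LumP",
        n_samples=n_samples,
        mean_log10_clones={chain: log10_clones},
        read_depth={chain: depth},
        dirichlet_alpha=alpha,
        survival_log_hr=log_hr,
        target_rho=rho,
        chains=(chain,),
    )


@pytest.fixture
def cell_fractions():
    """A valid 22-type fraction map summing to 0.22."""
    return {c: 0.01 for c in CELL_TYPES_22}


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
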