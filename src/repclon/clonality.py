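"""Clone definition, richness (expression), and Shannon-entropy diversity.

A *clone* groups receptor sequences presumed to share a common ancestor:
records with the same V gene, same J gene, same CDR3 length, and CDR3
nucleotide identity at or above a receptor-class threshold — 90% for B-cell
receptors (IGH/IGK/IGL) and 95% for T-cell receptors (TRA/TRB). Because
CDR3 length is part of the grouping key, identity is position-wise (Hamming)
identity on equal-length sequences; no alignment or gap model is involved.
Linkage is transitive: within a (V, J, length) group, any pair at or above
the threshold is connected and clones are the connected components
(single linkage), so two sequences can fall in one clone through an
intermediate even if their direct identity is below the threshold.

Two per-sample, per-chain summary measures follow:

richness (expression)
    M / (N + M): receptor-mapped reads over total sequenced reads in the
    sample's RNA-seq library — an infiltration-abundance proxy that
    normalises for sequencing depth.
diversity (Shannon entropy)
    H = −Σ p_i log2 p_i in bits, where p_i is the read-frequency of clone i
    among the sample × chain's clones. A monoclonal repertoire has H = 0;
    a chain with no records at all has *undefined* entropy (reported as
    missing, never as 0, so that "no infiltration" is not conflated with
    "monoclonal").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_clonotypes import BCR_CHAINS, DEFAULT_CHAINS, TCR_CHAINS, CohortTable

#: Identity thresholds per receptor class (inclusive, i.e. >=).
BCR_IDENTITY_THRESHOLD = 0.90
TCR_IDENTITY_THRESHOLD = 0.95


def chain_threshold(chain: str) -> float:
    """Identity threshold for a chain's receptor class."""
    if chain in BCR_CHAINS:
        return BCR_IDENTITY_THRESHOLD
    if chain in TCR_CHAINS:
        return TCR_IDENTITY_THRESHOLD
    raise ValueError(f"no identity threshold defined for chain {chain!r}")


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of positions at which two equal-length CDR3s agree."""
    if len(a) != len(b):
        raise ValueError(
            f"pairwise_identity requires equal lengths, got {len(a)} and {len(b)}"
        )
    if not a:
        raise ValueError("pairwise_identity requires nonempty sequences")
    return sum(x == y for x, y in zip(a, b)) / len(a)


class _UnionFind:
    """Array-based disjoint sets with path compression and union by size."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]


@dataclass
class CloneAssignment:
    """Partition of one sample × chain's records into clones.

    ``clone_ids`` aligns with the input record order; labels are consecutive
    integers ordered by each clone's first member in input order, so the
    assignment is deterministic. ``clone_read_counts[k]`` sums the read
    counts of clone k's members.
    """

    sample_id: str | None
    chain: str | None
    clone_ids: np.ndarray
    clone_read_counts: np.ndarray

    @property
    def n_clones(self) -> int:
        return len(self.clone_read_counts)

    def members(self) -> list[list[int]]:
        """Record indices per clone, in clone-id order."""
        out: list[list[int]] = [[] for _ in range(self.n_clones)]
        for idx, cid in enumerate(self.clone_ids):
            out[cid].append(idx)
        return out


def _mismatch_budget(length: int, threshold: float) -> int:
    # identity >= threshold  <=>  mismatches <= floor((1 - threshold) * L),
    # up to float slop on the product
    return int(np.floor((1.0 - threshold) * length + 1e-9))


def assign_clones(
    records: pd.DataFrame, identity_threshold: float | None = None
) -> CloneAssignment:
    """Partition the records of one sample × chain into clones.

    Records are grouped by (v_gene, j_gene, CDR3 length); within each group
    any pair with identity >= threshold is linked and clones are the
    connected components. When ``identity_threshold`` is None it is taken
    from the chain's receptor class (0.90 BCR / 0.95 TCR).

    Empty input yields an empty assignment.
    """
    n = len(records)
    if n == 0:
        return CloneAssignment(None, None, np.array([], dtype=int), np.array([], dtype=int))

    samples = records["sample_id"].unique()
    chains = records["chain"].unique()
    if len(samples) != 1 or len(chains) != 1:
        raise ValueError("assign_clones expects records of a single sample and chain")
    chain = chains[0]
    if identity_threshold is None:
        identity_threshold = chain_threshold(chain)

    cdr3 = records["cdr3_nt"].to_numpy()
    keys = list(
        zip(records["v_gene"].to_numpy(), records["j_gene"].to_numpy(),
            [len(s) for s in cdr3])
    )
    groups: dict[tuple, list[int]] = {}
    for idx, key in enumerate(keys):
        groups.setdefault(key, []).append(idx)

    uf = _UnionFind(n)
    for (v, j, length), idxs in groups.items():
        if len(idxs) < 2:
            continue
        budget = _mismatch_budget(length, identity_threshold)
        seqs = [cdr3[i] for i in idxs]
        for a in range(len(idxs)):
            sa = seqs[a]
            for b in range(a + 1, len(idxs)):
                sb = seqs[b]
                if sa == sb:
                    uf.union(idxs[a], idxs[b])
                    continue
                mism = 0
                for x, y in zip(sa, sb):
                    if x != y:
                        mism += 1
                        if mism > budget:
                            break
                if mism <= budget:
                    uf.union(idxs[a], idxs[b])

    # relabel components by first appearance in input order
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i in range(n):
        root = uf.find(i)
        labels[i] = seen.setdefault(root, len(seen))

    counts = np.zeros(len(seen), dtype=np.int64)
    np.add.at(counts, labels, records["read_count"].to_numpy())
    return CloneAssignment(samples[0], chain, labels, counts)


def compute_expression(receptor_reads: int, total_reads: int) -> float:
    """Richness: receptor-mapped reads M over total sequenced reads N + M."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if receptor_reads < 0:
        raise ValueError("receptor read count must be nonnegative")
    if receptor_reads > total_reads:
        raise ValueError(
            f"receptor reads ({receptor_reads}) exceed total reads "
            f"({total_reads}): metadata inconsistency"
        )
    return receptor_reads / total_reads


def compute_entropy(clone_read_counts) -> float:
    """Shannon entropy H = −Σ p_i log2 p_i in bits over clone frequencies.

    A single clone gives exactly 0.0. An empty vector is *undefined* and
    returns NaN (propagated downstream as missing, distinct from 0 bits).
    """
    counts = np.asarray(clone_read_counts, dtype=float)
    if counts.size == 0:
        return float("nan")
    if np.any(counts < 1):
        raise ValueError("clone read counts must all be >= 1")
    if counts.size == 1:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def metrics_table(cohort: CohortTable, chains=DEFAULT_CHAINS) -> pd.DataFrame:
    """Per sample × chain repertoire metrics for the whole cohort.

    Returns one row per sample × chain with columns ``sample_id, chain,
    n_records, n_reads, expression, n_clones, entropy``. Chains with zero
    records get expression 0 (a true measurement of absent infiltration) and
    entropy NaN (undefined).
    """
    rows = []
    by_sample_chain = {
        key: grp for key, grp in cohort.records.groupby(["sample_id", "chain"], sort=False)
    }
    for sample_id, meta in cohort.metadata.items():
        for chain in chains:
            grp = by_sample_chain.get((sample_id, chain))
            if grp is None or len(grp) == 0:
                rows.append(
                    dict(sample_id=sample_id, chain=chain, n_records=0, n_reads=0,
                         expression=0.0, n_clones=0, entropy=np.nan)
                )
                continue
            assignment = assign_clones(grp.reset_index(drop=True))
            n_reads = int(grp["read_count"].sum())
            rows.append(
                dict(
                    sample_id=sample_id,
                    chain=chain,
                    n_records=len(grp),
                    n_reads=n_reads,
                    expression=compute_expression(n_reads, meta.total_reads),
                    n_clones=assignment.n_clones,
                    entropy=compute_entropy(assignment.clone_read_counts),
                )
            )
    return pd.DataFrame(rows)
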