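"""Distance-based neighbor-joining for sequence-identity confirmation.

Used to confirm which gene family a newly amplified exon belongs to: build a
distance tree of the query against a panel of reference sequences and read
off the gene label of the query's nearest neighborhood. Full ML/Bayesian
tree inference is out of scope; published topologies are inputs elsewhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .seqio import CodonAlignment, SequenceRecord

__all__ = [
    "DistanceMatrix",
    "NJNode",
    "distance_matrix",
    "neighbor_joining",
    "assign_identity",
    "IdentityCall",
]

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distances must be finite and nonnegative")
        self.values = d

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _pairwise_sites(a: str, b: str):
    """Indices where neither sequence has a gap (pairwise deletion)."""
    return [k for k in range(len(a)) if a[k] != "-" and b[k] != "-"]


def distance_matrix(records, model: str = "p") -> DistanceMatrix:
    """Pairwise distances under the p or K2P model (pairwise deletion).

    K2P applies the Kimura two-parameter correction
    ``-1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)`` with P/Q the transition/transversion
    proportions; saturation (log of a nonpositive number) raises, naming the
    pair.
    """
    if isinstance(records, CodonAlignment):
        records = records.records
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [r.id for r in records]
    n = len(records)
    D = np.zeros((n, n))
    transitions = {frozenset("AG"), frozenset("CT")}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i].seq, records[j].seq
            sites = _pairwise_sites(a, b)
            if not sites:
                raise ValueError(
                    f"no overlapping non-gap sites for pair "
                    f"({labels[i]!r}, {labels[j]!r})"
                )
            nts = ntv = 0
            for k in sites:
                if a[k] == b[k]:
                    continue
                if frozenset((a[k], b[k])) in transitions:
                    nts += 1
                else:
                    ntv += 1
            L = len(sites)
            if model == "p":
                d = (nts + ntv) / L
            elif model == "K2P":
                P, Q = nts / L, ntv / L
                x, y = 1 - 2 * P - Q, 1 - 2 * Q
                if x <= 0 or y <= 0:
                    raise ValueError(
                        f"K2P saturation for pair ({labels[i]!r}, "
                        f"{labels[j]!r}): P={P:.3f}, Q={Q:.3f}"
                    )
                d = -0.5 * math.log(x) - 0.25 * math.log(y)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels, D)


@dataclass
class NJNode:
    """Node of an (unrooted) NJ tree; the return value is the root-like hub."""

    label: str | None
    children: list[tuple["NJNode", float]]

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return self.label
        inner = ",".join(
            f"{c._newick()}:{bl:.10g}" for c, bl in self.children
        )
        return f"({inner})" + (self.label or "")


def neighbor_joining(dm: DistanceMatrix) -> NJNode:
    """Saitou–Nei neighbor joining.

    Deterministic: ties in the Q criterion are broken by label order.
    Negative branch lengths are clamped to 0 with a warning. On an additive
    metric the input distances are reproduced exactly.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [NJNode(lab, []) for lab in sorted(dm.labels)]
    order = [dm.labels.index(nd.label) for nd in nodes]
    D = dm.values[np.ix_(order, order)].astype(float)
    active = list(range(len(nodes)))
    all_nodes = list(nodes)
    sort_key = {i: (nodes[i].label,) for i in active}

    def clamp(x, what):
        if x < 0:
            log.warning("negative NJ branch length %.4g for %s clamped to 0",
                        x, what)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                q = (m - 2) * sub[ai, bi] - r[ai] - r[bi]
                key = (q, sort_key[active[ai]], sort_key[active[bi]])
                if best is None or key < best[0]:
                    best = (key, ai, bi)
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = sub[ai, bi]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        li = clamp(li, all_nodes[i].label or "internal")
        lj = clamp(lj, all_nodes[j].label or "internal")
        new = NJNode(None, [(all_nodes[i], li), (all_nodes[j], lj)])
        k = len(all_nodes)
        all_nodes.append(new)
        newrow = np.zeros(k + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        for other in active:
            if other in (i, j):
                continue
            d = 0.5 * (D[i, other] + D[j, other] - dij)
            D[k, other] = D[other, k] = d
        sort_key[k] = min(sort_key[i], sort_key[j])
        active = [a for a in active if a not in (i, j)] + [k]

    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = clamp(0.5 * (dij + dik - djk), "final i")
    lj = clamp(0.5 * (dij + djk - dik), "final j")
    lk = clamp(0.5 * (dik + djk - dij), "final k")
    hub_children = sorted(
        [(all_nodes[i], li), (all_nodes[j], lj), (all_nodes[k], lk)],
        key=lambda t: sort_key[all_nodes.index(t[0])],
    )
    return NJNode(None, hub_children)


def tree_distances(tree: NJNode) -> DistanceMatrix:
    """Path-length distances between all leaf pairs of an NJ tree."""
    dists: dict[frozenset, float] = {}

    def walk(node) -> dict[str, float]:
        if node.is_leaf():
            return {node.label: 0.0}
        below = []
        for child, bl in node.children:
            sub = walk(child)
            below.append({k: v + bl for k, v in sub.items()})
        for x in range(len(below)):
            for y in range(x + 1, len(below)):
                for la, da in below[x].items():
                    for lb, db in below[y].items():
                        dists[frozenset((la, lb))] = da + db
        merged: dict[str, float] = {}
        for d in below:
            merged.update(d)
        return merged

    walk(tree)
    labels = sorted({lab for pair in dists for lab in pair})
    n = len(labels)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            D[a, b] = D[b, a] = dists[frozenset((labels[a], labels[b]))]
    return DistanceMatrix(labels, D)


@dataclass(frozen=True)
class IdentityCall:
    query: str
    gene: str | None
    tie: bool
    candidates: tuple[str, ...]


def assign_identity(query: SequenceRecord, panel, gene_of,
                    model: str = "p") -> IdentityCall:
    """Assign a query sequence to a gene group via its NJ neighborhood.

    ``panel`` is a list of aligned SequenceRecords (same length as the
    query); ``gene_of`` maps panel ids to gene labels. The call is the gene
    label of the query's sister group in the NJ tree; if the sister group
    mixes labels (or the query is equidistant between groups), a tie is
    reported rather than silently broken.
    """
    if isinstance(panel, CodonAlignment):
        panel = panel.records
    panel = list(panel)
    genes = {gene_of[r.id] for r in panel}
    if len(genes) < 2:
        raise ValueError("panel must contain at least 2 gene groups")
    if all(b == "-" for b in query.seq):
        raise ValueError("query has no alignable sites")
    dm = distance_matrix(panel + [query], model=model)
    tree = neighbor_joining(dm)

    # locate the query leaf and walk up via parent links
    parent: dict[int, NJNode] = {}

    def index(node):
        for child, _ in node.children:
            parent[id(child)] = node
            index(child)

    index(tree)
    target = None

    def find(node):
        nonlocal target
        if node.is_leaf() and node.label == query.id:
            target = node
        for child, _ in node.children:
            find(child)

    find(tree)
    node = target
    while True:
        up = parent.get(id(node))
        if up is None:
            labels = {gene_of[l] for l in tree.leaves() if l != query.id}
            break
        sibs = [l for l in up.leaves() if l != query.id]
        if sibs:
            labels = {gene_of[l] for l in sibs}
            break
        node = up
    candidates = tuple(sorted(labels))
    if len(labels) == 1:
        return IdentityCall(query.id, candidates[0], False, candidates)
    return IdentityCall(query.id, None, True, candidates)
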