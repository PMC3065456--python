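"""Synthetic codon evolution on dated trees, with injected inactivating
lesions and truth tables.

Sequences evolve under the same reversible GY94 generator the inference
engine fits (branch-specific omega supported). Substitution is simulated by
exact matrix-exponential transition sampling along each branch over the
61 sense codons, so the substitution process can never create a stop codon;
inactivating lesions (nonsense codons, indels) are then applied as discrete
events on a chosen origin branch and inherited by every descendant tip,
mirroring how pseudogene lesions arise once and persist. The true alignment
is emitted directly (no aligner in the loop), so scanner tests measure the
scanner, not alignment error.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from . import studydata
from .codonml import (
    CODONS,
    CODON_INDEX,
    N_CODONS,
    FlatTree,
    _eigendecompose,
    build_rate_matrix,
)
from .seqio import CodonAlignment, SequenceRecord
from .trees import DatedTree

__all__ = [
    "LesionSpec",
    "SimConfig",
    "SimTruth",
    "TrueLesion",
    "yule_tree",
    "simulate_alignment",
    "inject_lesions",
    "pick_foreground",
    "generate_study_fixture",
]


@dataclass(frozen=True)
class LesionSpec:
    """One lesion to inject.

    ``clade`` names the tips whose MRCA's stem branch is the origin; every
    tip descending from that branch inherits the lesion. ``position`` is a
    1-based reference coordinate (codon start for nonsense, first deleted
    base for deletions, left flanking base for insertions); for nonsense
    lesions ``position=None`` with ``cpg=True`` picks a codon where every
    carrier holds CGA, so a single C->T deamination yields the TGA stop.
    """

    kind: str  # nonsense | deletion | insertion
    clade: frozenset[str]
    position: int | None = None
    length: int = 3
    cpg: bool = False
    cpg_fallback: str = "error"  # "error" | "any"

    def __post_init__(self):
        if self.kind not in ("nonsense", "deletion", "insertion"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if not self.clade:
            raise ValueError("lesion clade is empty")
        if self.kind != "nonsense" and self.length < 1:
            raise ValueError("indel length must be >= 1")


@dataclass(frozen=True)
class TrueLesion:
    kind: str
    ref_start: int
    ref_end: int
    length: int
    carriers: frozenset[str]
    origin_clade: frozenset[str]
    origin_time: float  # same units as the tree's node ages

    @property
    def key(self):
        return (self.kind, self.ref_start, self.ref_end, self.length)


@dataclass
class SimConfig:
    """Study conditions for one simulated alignment.

    Defaults emulate a single-exon (~300 codon) mammalian alignment over a
    Yule tree with root-to-tip divergence ``height * rate`` expected
    substitutions per codon.
    """

    tree: dendropy.Tree | None = None  # edge lengths in time units (MY)
    n_tips: int = 16
    height: float = 1.0  # root age in time units when simulating the tree
    rate: float = 0.3  # expected substitutions/codon per time unit
    n_codons: int = 300
    kappa: float = 2.0
    omega: float | dict = 1.0  # scalar, or {branch class: omega}
    freqs: np.ndarray | None = None  # default: equal over sense codons
    lesions: tuple[LesionSpec, ...] = ()
    ref_id: str | None = None  # default: first lesion-free tip
    seed: int = 0
    method: str = "exponential"  # or "gillespie" (validation mode)


@dataclass
class SimTruth:
    kappa: float
    omegas: dict[str, float]
    freqs: np.ndarray
    tree: dendropy.Tree
    ages: dict[str, float]  # node label -> age (internal nodes are named)
    lesions: list[TrueLesion] = field(default_factory=list)
    tip_states: dict[str, np.ndarray] = field(default_factory=dict)

    def dated_tree(self) -> DatedTree:
        """The simulation tree as a DatedTree (for chronomap)."""
        clone = self.tree.clone(depth=1)
        return DatedTree(clone, ages=dict(self.ages))


def yule_tree(n_tips: int, rng: np.random.Generator, height: float = 1.0,
              birth_rate: float = 1.0) -> dendropy.Tree:
    """Ultrametric pure-birth tree rescaled to root age ``height``.

    Tips are named t01, t02, ...; internal nodes n1, n2, ... (root n1).
    Edge lengths are in the same time units as ``height``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")

    class _Lin:
        __slots__ = ("t0", "t1", "children")

        def __init__(self, t0):
            self.t0 = t0
            self.t1 = None
            self.children = []

    root = _Lin(0.0)
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        parent = active[idx]
        parent.t1 = t
        kids = [_Lin(t), _Lin(t)]
        parent.children = kids
        active = active[:idx] + kids + active[idx + 1 :]
    present = t + rng.exponential(1.0 / (birth_rate * n_tips))
    scale = height / (present - root.t1)  # root (first split) at age=height

    tip_counter = [0]
    node_counter = [0]

    def serialize(lin) -> str:
        if not lin.children:
            tip_counter[0] += 1
            return f"t{tip_counter[0]:02d}"
        node_counter[0] += 1
        my_name = f"n{node_counter[0]}"
        parts = []
        for c in lin.children:
            t_child = c.t1 if c.children else present
            bl = (t_child - lin.t1) * scale
            parts.append(f"{serialize(c)}:{bl:.12g}")
        return f"({','.join(parts)}){my_name}"

    text = serialize(root) + ";"
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    tree.is_rooted = True
    return tree


def _node_ages(tree: dendropy.Tree) -> dict[str, float]:
    """Node label -> age for an ultrametric tree with time edge lengths.

    Internal nodes without labels get deterministic names (a1, a2, ...).
    """
    depth = {}
    counter = [0]
    for node in tree.preorder_node_iter():
        d = 0.0 if node.parent_node is None else (
            depth[id(node.parent_node)] + (node.edge.length or 0.0)
        )
        depth[id(node)] = d
        if node.taxon is None and not node.label:
            counter[0] += 1
            node.label = f"a{counter[0]}"
    height = max(depth[id(leaf)] for leaf in tree.leaf_node_iter())
    ages = {}
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        ages[label] = max(height - depth[id(node)], 0.0)
    return ages


def simulate_alignment(config: SimConfig) -> tuple[CodonAlignment, SimTruth]:
    """Simulate codon sequences (and apply any configured lesions)."""
    rng = np.random.default_rng(config.seed)
    tree = config.tree if config.tree is not None else yule_tree(
        config.n_tips, rng, height=config.height
    )
    ages = _node_ages(tree)
    single = np.isscalar(config.omega)
    ft = FlatTree.from_dendropy(tree, single_class=single)
    freqs = (
        np.asarray(config.freqs, dtype=float)
        if config.freqs is not None
        else np.full(N_CODONS, 1.0 / N_CODONS)
    )
    omegas = (
        {c: float(config.omega) for c in set(ft.classes)}
        if single
        else {str(k): float(v) for k, v in config.omega.items()}
    )
    eigs = {
        c: _eigendecompose(build_rate_matrix(config.kappa, w, freqs), freqs)
        for c, w in omegas.items()
    }
    Qs = {c: build_rate_matrix(config.kappa, w, freqs) for c, w in omegas.items()}

    n = config.n_codons
    if n < 1:
        raise ValueError("n_codons must be >= 1")
    states = np.empty((ft.n_nodes, n), dtype=np.int64)
    states[ft.root] = rng.choice(N_CODONS, size=n, p=freqs)
    for v in reversed(ft.postorder):  # parents before children
        if v == ft.root:
            continue
        t_sub = ft.lengths[v] * config.rate
        cls = ft.classes[v]
        parent_states = states[ft.parent[v]]
        if config.method == "exponential":
            P = eigs[cls].P(t_sub)
            P = P / P.sum(axis=1, keepdims=True)
            out = np.empty(n, dtype=np.int64)
            for s in np.unique(parent_states):
                idx = np.nonzero(parent_states == s)[0]
                out[idx] = rng.choice(N_CODONS, size=idx.size, p=P[s])
            states[v] = out
        elif config.method == "gillespie":
            states[v] = _gillespie_branch(parent_states, Qs[cls], t_sub, rng)
        else:
            raise ValueError(f"unknown simulation method {config.method!r}")

    tip_states = {name: states[i].copy() for name, i in ft.tip_of.items()}
    truth = SimTruth(config.kappa, omegas, freqs, tree, ages,
                     tip_states=tip_states)
    records = [
        SequenceRecord(name, "".join(CODONS[s] for s in tip_states[name]))
        for name in sorted(ft.tip_of)
    ]
    ref_id = config.ref_id or _pick_reference(records, config.lesions, tree)
    aln = CodonAlignment(records, ref_id=ref_id, ref_offset=1)
    if config.lesions:
        aln, truth = inject_lesions(aln, truth, config.lesions, rng)
    return aln, truth


def _gillespie_branch(parent_states, Q, t_total, rng):
    """Jump-chain simulation of one branch (validation path)."""
    out = parent_states.copy()
    exit_rates = -np.diag(Q)
    for site in range(out.size):
        s = out[site]
        t = 0.0
        while True:
            t += rng.exponential(1.0 / exit_rates[s])
            if t >= t_total:
                break
            probs = Q[s].copy()
            probs[s] = 0.0
            probs /= probs.sum()
            s = int(rng.choice(N_CODONS, p=probs))
        out[site] = s
    return out


def _pick_reference(records, lesions, tree) -> str:
    carried = set()
    if lesions:
        dt = _as_dated(tree)
        for spec in lesions:
            carried |= dt.leaf_labels_under(dt.mrca(spec.clade))
    for rec in records:
        if rec.id not in carried:
            return rec.id
    raise ValueError("no lesion-free tip available as reference; set ref_id")


def _as_dated(tree) -> DatedTree:
    clone = tree.clone(depth=1)
    return DatedTree(clone, ages=_node_ages(clone))


def inject_lesions(aln: CodonAlignment, truth: SimTruth, specs,
                   rng: np.random.Generator) -> tuple[CodonAlignment, SimTruth]:
    """Apply lesions to the alignment; carriers are all tips descending from
    each spec's origin branch. Returns the modified alignment and truth with
    origin branches/times recorded."""
    tree = truth.tree
    ages = truth.ages
    dt = _as_dated(tree)
    seq_len = aln.length
    rows = {r.id: list(r.seq) for r in aln.records}
    occupied: list[tuple[int, int, tuple]] = []

    resolved = []
    for spec in specs:
        mrca = dt.mrca(spec.clade)
        carriers = frozenset(dt.leaf_labels_under(mrca))
        if dt.parent_age(mrca) is None:
            raise ValueError(
                f"lesion clade {sorted(spec.clade)} spans the whole tree: "
                "no origin branch exists"
            )
        lo = dt.age(mrca)
        hi = dt.parent_age(mrca)
        origin_time = float(rng.uniform(lo, hi))
        if aln.ref_id in carriers:
            raise ValueError("reference sequence would carry a lesion; "
                             "choose a reference outside all lesion clades")

        if spec.kind == "nonsense":
            pos = spec.position
            if pos is None:
                pos = _choose_cpg_site(truth, carriers, spec, rng)
            if pos < 1 or pos + 2 > seq_len or pos % 3 != 1:
                raise ValueError(f"nonsense position {pos} not a codon start "
                                 "inside the alignment")
            start, end, length = pos, pos + 2, 3
        elif spec.kind == "deletion":
            pos = spec.position
            if pos is None:
                raise ValueError("deletion lesion needs a position")
            start, end, length = pos, pos + spec.length - 1, spec.length
            if start < 1 or end > seq_len:
                raise ValueError(f"deletion {start}-{end} outside alignment")
        else:  # insertion
            pos = spec.position
            if pos is None:
                raise ValueError("insertion lesion needs a position")
            if pos < 1 or pos + 1 > seq_len:
                raise ValueError(f"insertion flank {pos} outside alignment")
            start, end, length = pos, pos + 1, spec.length

        key = (spec.kind, start, end, length)
        for s0, e0, k0 in occupied:
            if k0 == key:
                continue  # identical event on another branch: homoplasy
            if start <= e0 and s0 <= end:
                raise ValueError(
                    f"lesion {key} overlaps earlier lesion {k0}"
                )
        occupied.append((start, end, key))
        resolved.append((spec, start, end, length, carriers, origin_time))

    # point lesions and deletions first (columns == reference positions),
    # then insertions right-to-left so coordinates stay valid
    for spec, start, end, length, carriers, _ in resolved:
        if spec.kind == "nonsense":
            for sp in carriers:
                rows[sp][start - 1 : start + 2] = list("TGA")
        elif spec.kind == "deletion":
            for sp in carriers:
                rows[sp][start - 1 : end] = ["-"] * length
    insertions = [r for r in resolved if r[0].kind == "insertion"]
    for spec, start, end, length, carriers, _ in sorted(
        insertions, key=lambda r: -r[1]
    ):
        bases = "".join(rng.choice(list("ACGT"), size=length))
        for sp, row in rows.items():
            filler = list(bases) if sp in carriers else ["-"] * length
            rows[sp] = row[:start] + filler + row[start:]

    new_records = [SequenceRecord(r.id, "".join(rows[r.id]))
                   for r in aln.records]
    new_aln = CodonAlignment(new_records, ref_id=aln.ref_id,
                             ref_offset=aln.ref_offset)
    lesions = [
        TrueLesion(spec.kind, start, end, length, carriers,
                   frozenset(spec.clade), origin_time)
        for spec, start, end, length, carriers, origin_time in resolved
    ]
    return new_aln, replace_truth(truth, lesions)


def replace_truth(truth: SimTruth, lesions) -> SimTruth:
    truth.lesions = list(truth.lesions) + list(lesions)
    return truth


def _choose_cpg_site(truth: SimTruth, carriers, spec: LesionSpec,
                     rng: np.random.Generator) -> int:
    cga = CODON_INDEX["CGA"]
    carrier_states = np.array([truth.tip_states[sp] for sp in sorted(carriers)])
    shared_cga = np.nonzero((carrier_states == cga).all(axis=0))[0]
    if shared_cga.size:
        site = int(shared_cga[rng.integers(shared_cga.size)])
        return 3 * site + 1
    if spec.cpg_fallback == "any":
        shared = np.nonzero(
            (carrier_states == carrier_states[0]).all(axis=0)
        )[0]
        if shared.size:
            site = int(shared[rng.integers(shared.size)])
            return 3 * site + 1
    raise ValueError(
        "no CGA codon shared by all carriers for a CpG nonsense lesion "
        "(set cpg_fallback='any' to allow a non-CpG source codon)"
    )


def dated_newick(truth: SimTruth) -> str:
    """Serialize the simulation tree with ``age=`` node labels (and time
    branch lengths), readable by :meth:`DatedTree.from_newick`."""

    def quote(label: str) -> str:
        if any(ch in label for ch in "|=(),:; "):
            return "'" + label + "'"
        return label

    def ser(node) -> str:
        label = node.taxon.label if node.taxon else node.label
        if node.is_leaf():
            return quote(label)
        inner = ",".join(
            f"{ser(c)}:{(c.edge.length or 0.0):.10g}"
            for c in node.child_nodes()
        )
        return f"({inner})" + quote(f"{label}|age={truth.ages[label]:.10g}")

    return ser(truth.tree.seed_node) + ";"


def pick_foreground(tree: dendropy.Tree, target: int = 4) -> frozenset[str]:
    """Deterministically choose a foreground clade of about ``target`` tips.

    Picks the internal (non-root) node whose descendant tip count is closest
    to ``target`` (ties: fewer tips, then first in postorder).
    """
    best = None
    for i, node in enumerate(tree.postorder_node_iter()):
        if node.parent_node is None or node.is_leaf():
            continue
        tips = [
            (leaf.taxon.label if leaf.taxon else leaf.label)
            for leaf in node.leaf_iter()
        ]
        key = (abs(len(tips) - target), len(tips), i)
        if best is None or key < best[0]:
            best = (key, frozenset(tips))
    if best is None:
        raise ValueError("tree has no internal non-root node")
    return best[1]


def generate_study_fixture(outdir) -> dict[str, str]:
    """Write the in-study worked-example inputs (lesion descriptor table and
    presence/absence matrix, dated Carnivora tree, diet table, reconstructed
    alignments) as a deterministic text bundle."""
    return studydata.write_study_fixture(outdir)
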