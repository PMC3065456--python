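"""Maximum-likelihood codon substitution models (GY94) with branch-specific
dN/dS and likelihood-ratio tests.

The model is the Goldman–Yang codon model: a reversible 61-state Markov chain
over sense codons where the instantaneous rate from codon i to codon j is
nonzero only for single-nucleotide changes and proportional to

    pi_j * kappa^[transition] * omega^[nonsynonymous],

with the generator scaled so one unit of branch length equals one expected
substitution per codon. ``omega`` (dN/dS) may differ between labelled branch
classes (branch model); ``omega = 1`` is neutral evolution, ``< 1`` purifying
selection. Likelihoods are computed by Felsenstein pruning with per-site
scaling; transition matrices come from a symmetric eigendecomposition of the
reversibility-symmetrized generator.

Fitting alternates a quasi-Newton step on (log kappa, log omega per free
class) with per-branch line searches performed analytically in the eigenbasis
(the site likelihood along one branch is a fixed linear combination of
exp(lambda_k * t)). Nested models are compared with chi-square LRTs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .seqio import CodonAlignment, GENETIC_CODE, STOP_CODONS

__all__ = [
    "CODONS",
    "CODON_INDEX",
    "build_rate_matrix",
    "codon_frequencies",
    "CodonEngine",
    "CodonModelFit",
    "LRTResult",
    "BranchTestResult",
    "fit_m0",
    "fit_branch_model",
    "lrt",
    "test_vs_neutral",
    "test_vs_average",
    "mark_foreground",
    "log_likelihood",
]

log = logging.getLogger(__name__)

NT = "ACGT"
NT_INDEX = {b: i for i, b in enumerate(NT)}
CODONS: list[str] = [
    "".join(c) for c in itertools.product(NT, repeat=3)
    if "".join(c) not in STOP_CODONS
]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)  # 61
_AA = [GENETIC_CODE[c] for c in CODONS]
_CODON_NT = np.array([[NT_INDEX[b] for b in c] for c in CODONS])

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}

OMEGA_MAX = 999.0
OMEGA_MIN = 1e-4
KAPPA_MIN, KAPPA_MAX = 1e-2, 1e2
BL_MIN, BL_MAX = 1e-8, 25.0

# Precompute single-step codon pairs (both directions).
_pair_i, _pair_j, _pair_ts, _pair_nonsyn = [], [], [], []
for i, ci in enumerate(CODONS):
    for j, cj in enumerate(CODONS):
        if i == j:
            continue
        diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
        if len(diffs) != 1:
            continue
        _pair_i.append(i)
        _pair_j.append(j)
        _pair_ts.append(frozenset(diffs[0]) in _TRANSITIONS)
        _pair_nonsyn.append(_AA[i] != _AA[j])
_PAIR_I = np.array(_pair_i)
_PAIR_J = np.array(_pair_j)
_PAIR_TS = np.array(_pair_ts)
_PAIR_NONSYN = np.array(_pair_nonsyn)


def build_rate_matrix(kappa: float, omega: float, codon_freqs,
                      scale: bool = True) -> np.ndarray:
    """61x61 GY94 generator; rows sum to zero.

    With ``scale=True`` (default) the matrix is normalized so the expected
    number of substitutions per codon per unit time is exactly 1.
    """
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (N_CODONS,) or not np.all(np.isfinite(pi)) or pi.sum() <= 0:
        raise ValueError("codon_freqs must be a finite positive 61-vector")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("codon frequencies must sum to 1")
    rates = pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0)
    rates = rates * np.where(_PAIR_NONSYN, omega, 1.0)
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[_PAIR_I, _PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = -float(pi @ np.diag(Q))
        if mu <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        Q /= mu
    return Q


def codon_frequencies(codon_counts: np.ndarray, model: str = "F3x4") -> np.ndarray:
    """Equilibrium codon frequencies from observed sense-codon counts.

    ``F3x4`` (default): product of position-specific nucleotide frequencies;
    ``F1x4``: product of pooled nucleotide frequencies; ``equal``: uniform;
    ``empirical``: observed codon frequencies. Stop codons are excluded and
    the vector renormalized; a small floor keeps every frequency positive.
    """
    counts = np.asarray(codon_counts, dtype=float)
    if counts.shape != (N_CODONS,):
        raise ValueError("expected a 61-vector of codon counts")
    if model == "equal":
        pi = np.full(N_CODONS, 1.0 / N_CODONS)
    elif model == "empirical":
        pi = counts + 0.5  # pseudocount keeps unseen codons possible
        pi /= pi.sum()
    elif model in ("F1x4", "F3x4"):
        nt_counts = np.zeros((3, 4))
        for idx, c in enumerate(counts):
            for pos in range(3):
                nt_counts[pos, _CODON_NT[idx, pos]] += c
        if model == "F1x4":
            pooled = nt_counts.sum(axis=0)
            pooled /= pooled.sum()
            nt_freqs = np.tile(pooled, (3, 1))
        else:
            totals = nt_counts.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            nt_freqs = nt_counts / totals
        pi = (
            nt_freqs[0, _CODON_NT[:, 0]]
            * nt_freqs[1, _CODON_NT[:, 1]]
            * nt_freqs[2, _CODON_NT[:, 2]]
        )
        pi = pi / pi.sum()
    else:
        raise ValueError(f"unknown frequency model {model!r}")
    pi = np.maximum(pi, 1e-8)
    return pi / pi.sum()


@dataclass
class _Eig:
    """Spectral form of a scaled generator: P(t) = (left * e^{lam t}) @ right."""

    lam: np.ndarray
    left: np.ndarray
    right: np.ndarray

    def P(self, t: float) -> np.ndarray:
        return np.maximum((self.left * np.exp(self.lam * t)) @ self.right, 0.0)


def _eigendecompose(Q: np.ndarray, pi: np.ndarray) -> _Eig:
    d = np.sqrt(pi)
    B = (Q * d[:, None]) / d[None, :]
    B = 0.5 * (B + B.T)  # symmetric up to rounding for reversible Q
    lam, U = np.linalg.eigh(B)
    left = U / d[:, None]
    right = U.T * d[None, :]
    return _Eig(lam, left, right)


# --------------------------------------------------------------------- trees


class FlatTree:
    """Array-indexed rooted tree used by the likelihood engine.

    Nodes are indexed in postorder (tips first within that order). Every
    non-root node owns the edge to its parent, with a length (expected
    substitutions per codon) and a branch-class label.
    """

    def __init__(self):
        self.children: list[list[int]] = []
        self.parent: list[int] = []
        self.lengths: np.ndarray | None = None
        self.classes: list[str] = []
        self.tip_of: dict[str, int] = {}
        self.postorder: list[int] = []
        self.root: int = -1
        self.pinned: set[int] = set()  # edges held fixed during fitting

    @classmethod
    def from_dendropy(cls, tree, default_length: float = 0.1,
                      single_class: bool = False) -> "FlatTree":
        ft = cls()
        nodes = list(tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        ft.children = [[] for _ in range(n)]
        ft.parent = [-1] * n
        lengths = np.full(n, default_length)
        ft.classes = ["bg"] * n
        for node in nodes:
            i = index[id(node)]
            for child in node.child_nodes():
                j = index[id(child)]
                ft.children[i].append(j)
                ft.parent[j] = i
            label = node.taxon.label if node.taxon else node.label
            if node.parent_node is not None:
                if node.edge.length is not None:
                    lengths[i] = max(float(node.edge.length), BL_MIN)
                ft.classes[i] = _branch_class(node, label)
            if node.is_leaf():
                name = label.split("#")[0] if label else label
                if name in ft.tip_of:
                    raise ValueError(f"duplicate tip label {name!r}")
                ft.tip_of[name] = i
        if single_class:
            ft.classes = ["all"] * n
        ft.lengths = lengths
        ft.postorder = list(range(n))
        ft.root = index[id(tree.seed_node)]
        # A bifurcating root of a reversible model leaves only the *sum* of
        # the two root edges identifiable when their classes agree: pin one.
        rc = ft.children[ft.root]
        if len(rc) == 2 and ft.classes[rc[0]] == ft.classes[rc[1]]:
            ft.pinned.add(rc[1])
        return ft

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def edges(self):
        return [i for i in range(self.n_nodes) if i != self.root]


def _branch_class(node, label: str | None) -> str:
    cls = getattr(node, "branch_class", None)
    if cls is not None:
        return str(cls)
    if label and "#" in label:
        return label.rsplit("#", 1)[1] or "bg"
    return "bg"


def mark_foreground(tree, tips, name: str = "fg", include_stem: bool = True):
    """Assign branch class ``name`` to the clade spanned by ``tips``.

    The foreground is every branch inside the clade plus, when
    ``include_stem`` (default), the clade's stem branch. Returns the tree
    (modified in place) for chaining.
    """
    tips = set(tips)
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()
            if (leaf.taxon.label if leaf.taxon else leaf.label) in tips]
    if len(taxa) != len(tips):
        missing = tips - {t.label for t in taxa}
        raise KeyError(f"tips not in tree: {sorted(missing)}")
    tree.is_rooted = True
    mrca = tree.mrca(taxa=taxa) if len(taxa) > 1 else [
        leaf for leaf in tree.leaf_node_iter() if leaf.taxon in set(taxa)
    ][0]
    if mrca.parent_node is None:
        raise ValueError("foreground clade spans the whole tree")
    for node in mrca.preorder_iter():
        node.branch_class = name
    if not include_stem:
        mrca.branch_class = "bg"
    return tree


# ------------------------------------------------------------------- engine


def _encode_alignment(aln: CodonAlignment, tip_labels, mask: str):
    """Codon codes per tree tip per site; -1 = missing. Returns patterns."""
    n_col = aln.length
    if n_col % 3 != 0:
        raise ValueError(f"alignment length {n_col} is not a codon multiple")
    n_sites = n_col // 3
    seqs = {}
    for name in tip_labels:
        seqs[name] = aln.get(name).seq
    codes = np.empty((len(tip_labels), n_sites), dtype=np.int32)
    for k, name in enumerate(tip_labels):
        s = seqs[name]
        for site in range(n_sites):
            codon = s[3 * site : 3 * site + 3]
            idx = CODON_INDEX.get(codon)
            if idx is not None:
                codes[k, site] = idx
            elif codon in STOP_CODONS:
                if mask == "none":
                    raise ValueError(
                        f"stop codon {codon} in {name!r} at codon site "
                        f"{site + 1} (reference position "
                        f"{aln.ref_offset + 3 * site})"
                    )
                codes[k, site] = -3
            else:
                codes[k, site] = -2
    if mask == "any":
        keep = (codes >= 0).all(axis=0)
        codes = np.where(codes < 0, -1, codes)[:, keep]
    elif mask in ("per-sequence", "none"):
        codes = np.where(codes < 0, -1, codes)
    else:
        raise ValueError(f"unknown masking policy {mask!r}")
    if codes.shape[1] == 0:
        raise ValueError("no codon sites left after masking")
    patterns, weights = np.unique(codes, axis=1, return_counts=True)
    return patterns, weights.astype(float)


_EYE_AUG = np.vstack([np.eye(N_CODONS), np.ones(N_CODONS)])


@dataclass
class CodonModelFit:
    """Result of a codon-model fit."""

    kappa: float
    omegas: dict[str, float]
    log_likelihood: float
    codon_freqs: np.ndarray
    freq_model: str
    branch_lengths: np.ndarray
    tree: "FlatTree"
    fixed: frozenset[str] = frozenset()
    converged: bool = True
    n_outer: int = 0
    degenerate: bool = False
    capped: frozenset[str] = frozenset()

    @property
    def omega(self) -> float:
        if len(self.omegas) != 1:
            raise ValueError("multiple branch classes; index omegas by class")
        return next(iter(self.omegas.values()))

    @property
    def tree_length(self) -> float:
        return float(sum(self.branch_lengths[e] for e in self.tree.edges()))


@dataclass(frozen=True)
class LRTResult:
    ll_alt: float
    ll_null: float
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class BranchTestResult:
    m0: CodonModelFit | None
    alt: CodonModelFit
    null: CodonModelFit
    lrt: LRTResult


class CodonEngine:
    """Likelihood engine bound to one alignment + one (class-labelled) tree."""

    def __init__(self, aln: CodonAlignment, tree, freq_model: str = "F3x4",
                 freqs=None, mask: str = "any", single_class: bool = False,
                 default_length: float = 0.1):
        if isinstance(tree, FlatTree):
            self.ft = tree
        else:
            self.ft = FlatTree.from_dendropy(
                tree, default_length=default_length, single_class=single_class
            )
        missing = set(self.ft.tip_of) - set(aln.species)
        if missing:
            raise KeyError(f"tree tips not in alignment: {sorted(missing)}")
        self.tip_labels = list(self.ft.tip_of)
        self.patterns, self.weights = _encode_alignment(
            aln, self.tip_labels, mask
        )
        self.npat = self.patterns.shape[1]
        self.n_sites = int(self.weights.sum())
        counts = np.bincount(
            self.patterns[self.patterns >= 0],
            weights=np.broadcast_to(
                self.weights, self.patterns.shape
            )[self.patterns >= 0],
            minlength=N_CODONS,
        )
        self.freq_model = freq_model if freqs is None else "supplied"
        self.freqs = (
            np.asarray(freqs, dtype=float)
            if freqs is not None
            else codon_frequencies(counts, freq_model)
        )
        self.classes = sorted(
            {self.ft.classes[e] for e in self.ft.edges()}
        )
        self._tip_codes = {
            self.ft.tip_of[name]: self.patterns[k]
            for k, name in enumerate(self.tip_labels)
        }
        self._eig_cache: dict[tuple[float, float], _Eig] = {}

    # ----------------------------------------------------------- primitives
    def _eig(self, kappa: float, omega: float) -> _Eig:
        key = (kappa, omega)
        eig = self._eig_cache.get(key)
        if eig is None:
            Q = build_rate_matrix(kappa, omega, self.freqs)
            eig = _eigendecompose(Q, self.freqs)
            if len(self._eig_cache) > 64:
                self._eig_cache.clear()
            self._eig_cache[key] = eig
        return eig

    def _pmatrices(self, kappa, omegas, lengths):
        eigs = {c: self._eig(kappa, omegas[c]) for c in self.classes}
        P = [None] * self.ft.n_nodes
        for e in self.ft.edges():
            P[e] = eigs[self.ft.classes[e]].P(lengths[e])
        return P, eigs

    def _tip_contrib(self, node: int, P: np.ndarray) -> np.ndarray:
        codes = self._tip_codes[node]
        P_aug = np.hstack([P, np.ones((N_CODONS, 1))])
        return P_aug[:, codes].T

    def _down_pass(self, P):
        """Postorder partials. Returns (partial, down, logscale)."""
        ft = self.ft
        partial = [None] * ft.n_nodes
        down = [None] * ft.n_nodes
        logscale = np.zeros(self.npat)
        for v in ft.postorder:
            if not ft.children[v]:
                partial[v] = _EYE_AUG[self._tip_codes[v]]
            else:
                part = np.ones((self.npat, N_CODONS))
                for c in ft.children[v]:
                    part = part * down[c]
                m = part.max(axis=1)
                m = np.where(m > 0, m, 1.0)
                part = part / m[:, None]
                logscale += np.log(m)
                partial[v] = part
            if v != ft.root:
                if not ft.children[v]:
                    down[v] = self._tip_contrib(v, P[v])
                else:
                    down[v] = partial[v] @ P[v].T
        return partial, down, logscale

    def loglik(self, kappa: float, omegas: dict[str, float],
               lengths: np.ndarray) -> float:
        P, _ = self._pmatrices(kappa, omegas, lengths)
        partial, _, logscale = self._down_pass(P)
        site = partial[self.ft.root] @ self.freqs
        site = np.maximum(site, 1e-300)
        return float(self.weights @ (np.log(site) + logscale))

    # ------------------------------------------------------- branch sweeps
    def _sweep(self, kappa, omegas, lengths):
        """One preorder pass optimizing each free branch length in place."""
        ft = self.ft
        P, eigs = self._pmatrices(kappa, omegas, lengths)
        partial, down, _ = self._down_pass(P)

        def product_excluding(nodes, skip):
            out = np.ones((self.npat, N_CODONS))
            for c in nodes:
                if c != skip:
                    out = out * down[c]
            return out

        stack = []
        for c in ft.children[ft.root]:
            f = self.freqs[None, :] * product_excluding(ft.children[ft.root], c)
            stack.append((c, f))
        while stack:
            v, f = stack.pop()
            eig = eigs[ft.classes[v]]
            if v not in ft.pinned:
                A = f @ eig.left
                B = partial[v] @ eig.right.T
                C = A * B
                w = self.weights

                def negll(t):
                    site = C @ np.exp(eig.lam * t)
                    return -float(w @ np.log(np.maximum(site, 1e-300)))

                res = minimize_scalar(
                    negll, bounds=(BL_MIN, BL_MAX), method="bounded",
                    options={"xatol": 1e-8},
                )
                lengths[v] = float(res.x)
                P[v] = eig.P(lengths[v])
                down[v] = (
                    self._tip_contrib(v, P[v])
                    if not ft.children[v]
                    else partial[v] @ P[v].T
                )
            if ft.children[v]:
                base = f @ P[v]
                for c in ft.children[v]:
                    fc = base * product_excluding(ft.children[v], c)
                    m = fc.max(axis=1)
                    m = np.where(m > 0, m, 1.0)
                    stack.append((c, fc / m[:, None]))
        return lengths

    # ------------------------------------------------------------- fitting
    def _is_degenerate(self) -> bool:
        pat = self.patterns
        observed = np.where(pat < 0, pat.max(axis=0, keepdims=True), pat)
        return bool((observed == observed[0]).all())

    def fit(self, fixed_omegas=None, init_kappa: float = 2.0,
            init_omega: float = 0.4, init_lengths=None,
            fix_kappa: float | None = None, fix_lengths: bool = False,
            tol: float = 1e-8, max_outer: int = 25,
            global_restarts: int = 1) -> CodonModelFit:
        ft = self.ft
        fixed = {str(k): float(v) for k, v in (fixed_omegas or {}).items()}
        unknown = set(fixed) - set(self.classes)
        if unknown:
            raise ValueError(f"fixed omega for absent branch class: {unknown}")
        free = [c for c in self.classes if c not in fixed]
        omegas = {c: fixed.get(c, init_omega) for c in self.classes}
        kappa = float(fix_kappa if fix_kappa is not None else init_kappa)

        lengths = (
            np.array(init_lengths, dtype=float)
            if init_lengths is not None
            else ft.lengths.copy()
        )
        for p in ft.pinned:
            if init_lengths is None and not fix_lengths:
                # fold the pinned root edge into its sibling before fitting
                sib = [c for c in ft.children[ft.root] if c != p][0]
                lengths[sib] += lengths[p] - BL_MIN
                lengths[p] = BL_MIN

        if self.n_sites < 3:
            log.warning("only %d codon site(s) after masking: estimates "
                        "and tests are degenerate", self.n_sites)
        if self._is_degenerate():
            lengths = np.full_like(lengths, BL_MIN)
            ll = self.loglik(kappa, omegas, lengths)
            for c in free:
                omegas[c] = float("nan")
            log.warning("alignment has no variable codon sites; "
                        "omega unidentifiable")
            return CodonModelFit(
                kappa, omegas, ll, self.freqs, self.freq_model, lengths,
                ft, frozenset(fixed), converged=True, degenerate=True,
            )

        do_global = bool(free) or fix_kappa is None
        ll_prev = -np.inf
        ll = self.loglik(kappa, omegas, lengths)
        n_outer = 0
        converged = False
        for n_outer in range(1, max_outer + 1):
            if do_global:
                kappa, omegas = self._global_stage(
                    kappa, omegas, free, lengths,
                    fit_kappa=fix_kappa is None,
                    restarts=global_restarts if n_outer == 1 else 1,
                )
            if not fix_lengths:
                self._sweep(kappa, omegas, lengths)
                self._sweep(kappa, omegas, lengths)
            elif not do_global:
                break
            ll_prev, ll = ll, self.loglik(kappa, omegas, lengths)
            if abs(ll - ll_prev) < tol:
                converged = True
                break
        capped = set()
        for c in free:
            if omegas[c] >= OMEGA_MAX * 0.999:
                omegas[c] = OMEGA_MAX
                capped.add(c)
                log.warning("omega for class %r hit the cap (%.0f); "
                            "estimate unreliable (dS ~ 0)", c, OMEGA_MAX)
        return CodonModelFit(
            kappa, omegas, ll, self.freqs, self.freq_model, lengths, ft,
            frozenset(fixed), converged=converged, n_outer=n_outer,
            capped=frozenset(capped),
        )

    def _global_stage(self, kappa, omegas, free, lengths, fit_kappa=True,
                      restarts=1):
        x0, bounds = [], []
        if fit_kappa:
            x0.append(np.log(kappa))
            bounds.append((np.log(KAPPA_MIN), np.log(KAPPA_MAX)))
        for c in free:
            x0.append(np.log(np.clip(omegas[c], OMEGA_MIN, OMEGA_MAX)))
            bounds.append((np.log(OMEGA_MIN), np.log(OMEGA_MAX)))
        if not x0:
            return kappa, omegas

        def unpack(x):
            k = float(np.exp(x[0])) if fit_kappa else kappa
            om = dict(omegas)
            off = 1 if fit_kappa else 0
            for ci, c in enumerate(free):
                om[c] = float(np.exp(x[off + ci]))
            return k, om

        def obj(x):
            k, om = unpack(x)
            return -self.loglik(k, om, lengths)

        starts = [np.array(x0)]
        for r in range(1, restarts):
            alt = np.array(x0)
            alt += (-1) ** r * 0.7 * (1 + np.arange(len(alt)) % 2)
            starts.append(np.clip(alt, [b[0] for b in bounds],
                                  [b[1] for b in bounds]))
        best = None
        for s in starts:
            res = minimize(obj, s, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 40, "ftol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
        return unpack(best.x)


# ----------------------------------------------------------- public drivers


def log_likelihood(aln: CodonAlignment, tree, kappa: float, omega,
                   freqs=None, freq_model: str = "F3x4",
                   mask: str = "any") -> float:
    """Log-likelihood of the alignment on a tree with given parameters.

    ``omega`` may be a scalar (applied to every branch class) or a
    {class: omega} mapping matching the tree's branch labels.
    """
    engine = CodonEngine(aln, tree, freq_model=freq_model, freqs=freqs,
                         mask=mask, single_class=np.isscalar(omega))
    omegas = (
        {c: float(omega) for c in engine.classes}
        if np.isscalar(omega)
        else dict(omega)
    )
    return engine.loglik(float(kappa), omegas, engine.ft.lengths)


def fit_m0(aln: CodonAlignment, tree, freq_model: str = "F3x4", freqs=None,
           mask: str = "any", **fit_kw) -> CodonModelFit:
    """Model 0: one dN/dS shared by every branch (the 'average value')."""
    engine = CodonEngine(aln, tree, freq_model=freq_model, freqs=freqs,
                         mask=mask, single_class=True)
    if len(engine.tip_labels) < 3:
        if len(engine.tip_labels) < 2:
            raise ValueError("need at least 2 sequences")
        log.warning("fewer than 3 sequences: omega weakly identified")
    return engine.fit(**fit_kw)


def fit_branch_model(aln: CodonAlignment, tree, fixed=None,
                     freq_model: str = "F3x4", freqs=None, mask: str = "any",
                     reuse_from: CodonModelFit | None = None,
                     **fit_kw) -> CodonModelFit:
    """Branch model: one dN/dS per branch class; classes in ``fixed`` pinned.

    ``reuse_from`` reuses another fit's branch lengths and kappa on the same
    topology (they are then held fixed and only the omegas re-optimized).
    """
    engine = CodonEngine(aln, tree, freq_model=freq_model, freqs=freqs,
                         mask=mask)
    if len(engine.classes) < 2 and not fixed:
        log.warning("branch model with a single class reduces to Model 0")
    if reuse_from is not None:
        if reuse_from.tree.n_nodes != engine.ft.n_nodes:
            raise ValueError("reuse_from fit is for a different topology")
        fit_kw.setdefault("init_lengths", reuse_from.branch_lengths)
        fit_kw.setdefault("fix_lengths", True)
        fit_kw.setdefault("fix_kappa", reuse_from.kappa)
    return engine.fit(fixed_omegas=fixed, **fit_kw)


def lrt(ll_alt: float, ll_null: float, df: int = 1,
        tol: float = 1e-4) -> LRTResult:
    """Likelihood-ratio test of nested codon models (chi-square upper tail)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (ll_alt - ll_null)
    if stat < -tol:
        raise ValueError(
            f"alternative log-likelihood below null ({ll_alt:.6f} < "
            f"{ll_null:.6f}): optimization failure, refit advised"
        )
    stat = max(stat, 0.0)
    return LRTResult(ll_alt, ll_null, stat, df, float(chi2.sf(stat, df)))


def _branch_test(aln, tree, cls, null_omega, m0=None, reuse_lengths=False,
                 **kw) -> BranchTestResult:
    reuse = None
    if reuse_lengths:
        if m0 is None:
            m0 = fit_m0(aln, tree, **kw)
        reuse = m0
    alt = fit_branch_model(aln, tree, reuse_from=reuse, **kw)
    null = fit_branch_model(
        aln, tree, fixed={cls: null_omega}, reuse_from=reuse,
        init_omega=min(alt.omegas.get("bg", 0.4), OMEGA_MAX), **kw
    )
    return BranchTestResult(m0, alt, null, lrt(alt.log_likelihood,
                                               null.log_likelihood, df=1))


def test_vs_neutral(aln: CodonAlignment, tree, cls: str = "fg",
                    m0=None, reuse_lengths: bool = False,
                    **kw) -> BranchTestResult:
    """LRT of a lineage's dN/dS against the neutral value 1.0 (1 df)."""
    if reuse_lengths and m0 is None:
        m0 = fit_m0(aln, tree, **kw)
    res = _branch_test(aln, tree, cls, 1.0, m0=m0,
                       reuse_lengths=reuse_lengths, **kw)
    n_informative = res.alt.tree and sum(
        1 for e in res.alt.tree.edges() if res.alt.tree.classes[e] == cls
    )
    if not n_informative:
        raise ValueError(f"no branches labelled {cls!r}")
    return res


def test_vs_average(aln: CodonAlignment, tree, cls: str = "fg",
                    m0: CodonModelFit | None = None,
                    reuse_lengths: bool = False, **kw) -> BranchTestResult:
    """LRT of a lineage's dN/dS against the all-species average (1 df).

    The null pins the lineage's omega to the Model-0 estimate while the
    background omega stays free — one degree of freedom.
    """
    if m0 is None:
        m0 = fit_m0(aln, tree, **kw)
    return _branch_test(aln, tree, cls, m0.omega, m0=m0,
                        reuse_lengths=reuse_lengths, **kw)
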