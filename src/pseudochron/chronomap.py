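"""Bounding lesion fixation times on a dated tree.

A lesion shared by a monophyletic set of carriers must have become fixed
after the carrier clade split from its sister lineage (stem age, the upper
bound) and before the carrier clade's own radiation (crown age, the lower
bound) — otherwise some carrier would lack it or some non-carrier would have
it. The reasoning is Dollo-style: complex lesions (frameshifts, stops) arise
once per clade and never revert. Non-monophyletic carrier sets are split into
the minimal number of independent origins, one per maximal carrier clade.

Tips with no sequence data are *missing*, never evidence of absence, and are
excluded from both carrier and non-carrier sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .trees import DatedTree

__all__ = [
    "FixationInterval",
    "HomoplasyReport",
    "NonMonophyleticCarriers",
    "carrier_mrca",
    "fixation_interval",
    "decompose_homoplasy",
    "timing_table",
]


class NonMonophyleticCarriers(ValueError):
    """Carriers are not monophyletic; use decompose_homoplasy instead."""


@dataclass(frozen=True)
class FixationInterval:
    """[lower, upper] MYA bounds on when a lesion became fixed.

    ``lower`` is the carrier clade's crown age (0 for a single carrier);
    ``upper`` is its stem age, or None when the carriers span the whole tree
    (no outgroup information). Optional (lo, hi) confidence annotations on
    the node ages are carried through unchanged when present.
    """

    event_id: str | None
    lower: float
    upper: float | None
    monophyletic: bool = True
    lower_ci: tuple[float, float] | None = None
    upper_ci: tuple[float, float] | None = None

    def __post_init__(self):
        if self.upper is not None and not self.lower < self.upper:
            raise ValueError(
                f"degenerate interval [{self.lower}, {self.upper}]"
            )

    @property
    def display(self) -> str:
        if self.upper is None:
            return f">{_fmt(self.lower)} MYA"
        if self.lower == 0:
            return f"<{_fmt(self.upper)} MYA"
        return f"{_fmt(self.lower)}–{_fmt(self.upper)} MYA"


@dataclass(frozen=True)
class HomoplasyReport:
    event_id: str | None
    clades: tuple[tuple[frozenset[str], FixationInterval], ...]

    @property
    def n_independent_origins(self) -> int:
        return len(self.clades)


def _fmt(x: float) -> str:
    return f"{x:g}"


def _carriers_of(event) -> set[str]:
    carriers = getattr(event, "carriers", event)
    return set(carriers)


def carrier_mrca(tree: DatedTree, carriers, missing=()) -> tuple[object, bool]:
    """MRCA of the carriers and whether they are monophyletic.

    Monophyly is judged over tips with data: tips listed in ``missing`` are
    ignored when comparing the MRCA's descendant set with the carriers.
    """
    carriers = set(carriers)
    missing = set(missing)
    if not carriers:
        raise ValueError("empty carrier set")
    node = tree.mrca(carriers)
    under = tree.leaf_labels_under(node) - missing
    return node, under == carriers


def fixation_interval(tree: DatedTree, event, missing=(),
                      event_id=None) -> FixationInterval:
    """Bound the fixation time of a lesion with monophyletic carriers.

    ``event`` may be a LesionEvent-like object (``.carriers``/``.id``) or a
    plain iterable of carrier tip labels.
    """
    carriers = _carriers_of(event)
    eid = event_id if event_id is not None else getattr(event, "id", None)
    node, mono = carrier_mrca(tree, carriers, missing)
    if not mono:
        raise NonMonophyleticCarriers(
            f"carriers of {eid or 'event'} are not monophyletic; "
            "use decompose_homoplasy"
        )
    lower = 0.0 if len(carriers) == 1 else tree.age(node)
    lower_ci = None if len(carriers) == 1 else tree.age_ci(node)
    upper = tree.parent_age(node)
    upper_ci = (
        tree.age_ci(node.parent_node) if node.parent_node is not None else None
    )
    return FixationInterval(eid, lower, upper, monophyletic=True,
                            lower_ci=lower_ci, upper_ci=upper_ci)


def decompose_homoplasy(tree: DatedTree, event, missing=(),
                        event_id=None) -> HomoplasyReport:
    """Partition carriers into maximal monophyletic clades (one origin each).

    Under the Dollo assumption each maximal carrier clade is one independent
    origin; each gets its own fixation interval.
    """
    carriers = _carriers_of(event)
    missing = set(missing)
    eid = event_id if event_id is not None else getattr(event, "id", None)
    if not carriers:
        raise ValueError("empty carrier set")
    for lab in carriers:
        tree.tip(lab)

    clades: list[set[str]] = []

    def visit(node) -> None:
        under = tree.leaf_labels_under(node) - missing
        if under and under <= carriers:
            clades.append(under)
            return
        for child in node.child_nodes():
            visit(child)

    visit(tree.tree.seed_node)
    out = []
    for tips in clades:
        interval = fixation_interval(tree, tips, missing, event_id=eid)
        out.append((frozenset(tips), interval))
    return HomoplasyReport(eid, tuple(out))


def timing_table(tree: DatedTree, events, missing=()) -> pd.DataFrame:
    """Fixation timing for a list of events (homoplasies decomposed)."""
    rows = []
    for ev in events:
        report = decompose_homoplasy(tree, ev, missing)
        for tips, iv in report.clades:
            rows.append(
                {
                    "event": ev.id,
                    "lower_mya": iv.lower,
                    "upper_mya": iv.upper,
                    "display": iv.display,
                    "n_origins": report.n_independent_origins,
                    "clade_size": len(tips),
                }
            )
    return pd.DataFrame(rows)
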