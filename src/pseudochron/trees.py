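"""Rooted, dated phylogenies with node ages in MYA.

Node ages arrive either embedded in Newick internal-node labels
(``name|age=10.8`` or bare ``age=10.8``) or in a separate two-column TSV
(node label, age) — source chronograms are usually published as age tables
rather than branch lengths. Tips default to age 0 (extant taxa).
"""

from __future__ import annotations

import io
import re
from pathlib import Path

import dendropy

__all__ = ["DatedTree"]

_AGE_RE = re.compile(r"(?:^|\|)\s*age\s*=\s*([0-9]*\.?[0-9]+)\s*$")


def _split_age_label(label: str | None):
    """Return (clean_label_or_None, age_or_None) from a node label."""
    if not label:
        return None, None
    m = _AGE_RE.search(label)
    if not m:
        return label, None
    clean = _AGE_RE.sub("", label).rstrip("|").strip() or None
    return clean, float(m.group(1))


class DatedTree:
    """A rooted topology whose nodes carry ages (MYA, tips may be 0)."""

    def __init__(self, tree: dendropy.Tree, ages: dict | None = None,
                 age_ci: dict | None = None):
        tree.is_rooted = True
        self.tree = tree
        self._age: dict[dendropy.Node, float] = {}
        self._age_ci: dict[dendropy.Node, tuple[float, float]] = {}
        label_ages = {}
        for node in tree:
            label = node.taxon.label if node.taxon else node.label
            clean, age = _split_age_label(label)
            if node.taxon:
                node.taxon.label = clean or label
            else:
                node.label = clean
            if age is not None:
                label_ages[node] = age
        for node in tree:
            name = node.taxon.label if node.taxon else node.label
            if ages and name is not None and name in ages:
                self._age[node] = float(ages[name])
            elif node in label_ages:
                self._age[node] = label_ages[node]
            elif node.is_leaf():
                self._age[node] = 0.0
            if age_ci and name is not None and name in age_ci:
                lo, hi = age_ci[name]
                self._age_ci[node] = (float(lo), float(hi))
        self._tips = {}
        for leaf in tree.leaf_node_iter():
            name = leaf.taxon.label if leaf.taxon else leaf.label
            if name in self._tips:
                raise ValueError(f"duplicate tip label {name!r}")
            self._tips[name] = leaf
        self._validate()

    def _validate(self):
        for node in self.tree.preorder_node_iter():
            if not node.is_leaf() and node not in self._age:
                raise ValueError(
                    f"internal node {node.label or '<unnamed>'} has no age"
                )
            if node.parent_node is not None:
                if self._age[node] >= self._age[node.parent_node]:
                    raise ValueError(
                        f"node age {self._age[node]} not younger than parent "
                        f"age {self._age[node.parent_node]}"
                    )

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_newick(cls, source: str | Path, ages=None) -> "DatedTree":
        """Read from a Newick file path or literal Newick string.

        ``ages`` may be a {node label: MYA} dict or a path to a TSV whose
        first two columns are (label, age); two further numeric columns, if
        present, are read as a (lo, hi) confidence annotation on the age.
        """
        text = str(source)
        if not text.lstrip().startswith("(") and Path(text).exists():
            text = Path(text).read_text()
        age_map = None
        ci_map: dict | None = None
        if ages is not None:
            if isinstance(ages, (str, Path)):
                age_map, ci_map = {}, {}
                for line in Path(ages).read_text().splitlines():
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    cols = line.split("\t")
                    name, value = cols[0], cols[1]
                    if name == "node" and not _is_float(value):
                        continue  # header row
                    age_map[name] = float(value)
                    if (len(cols) >= 4 and _is_float(cols[2])
                            and _is_float(cols[3])):
                        ci_map[name] = (float(cols[2]), float(cols[3]))
            else:
                age_map = dict(ages)
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls(tree, ages=age_map, age_ci=ci_map)

    # -------------------------------------------------------------- queries
    @property
    def tip_labels(self) -> list[str]:
        return list(self._tips)

    def tip(self, label: str) -> dendropy.Node:
        try:
            return self._tips[label]
        except KeyError:
            raise KeyError(f"tip {label!r} not in tree") from None

    def age(self, node: dendropy.Node) -> float:
        return self._age[node]

    def age_ci(self, node: dendropy.Node) -> tuple[float, float] | None:
        """Optional (lo, hi) confidence annotation on a node age."""
        return self._age_ci.get(node)

    def parent_age(self, node: dendropy.Node) -> float | None:
        """Age of the node's parent; None at the root (no outgroup info)."""
        if node.parent_node is None:
            return None
        return self._age[node.parent_node]

    def mrca(self, labels) -> dendropy.Node:
        labels = list(labels)
        for lab in labels:
            self.tip(lab)  # raises on unknown label
        if len(labels) == 1:
            return self._tips[labels[0]]
        taxa = [self._tips[lab].taxon for lab in labels]
        node = self.tree.mrca(taxa=taxa)
        if node is None:  # pragma: no cover - defensive
            raise ValueError("no common ancestor found")
        return node

    def leaf_labels_under(self, node: dendropy.Node) -> set[str]:
        return {
            leaf.taxon.label if leaf.taxon else leaf.label
            for leaf in node.leaf_iter()
        }

    def root_age(self) -> float:
        return self._age[self.tree.seed_node]


def _is_float(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False
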