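import numpy as np
import pytest

from pseudochron import studydata
from pseudochron.simgen import LesionSpec, SimConfig, simulate_alignment, yule_tree
from pseudochron.trees import DatedTree


@pytest.fixture(scope="session")
def felid_aln():
    return studydata.felid_alignment()


@pytest.fixture(scope="session")
def carnivora():
    return studydata.carnivora_tree()


def make_lesion_sim(seed, n_tips=8, n_codons=90, max_lesions=4,
                    kinds=("nonsense", "deletion", "insertion")):
    """Simulate an alignment with random non-overlapping injected lesions.

    Lesion origin clades are drawn from one side of the root so the other
    side always provides an intact reference tip. Returns (aln, truth).
    """
    rng = np.random.default_rng(seed)
    tree = yule_tree(n_tips, rng, height=0.6)
    left, right = tree.seed_node.child_nodes()
    # origins: any node (incl. tips) strictly inside the right subtree
    candidates = [n for n in right.preorder_iter()]
    ref_tip = next(leaf for leaf in left.leaf_iter())
    ref_id = ref_tip.taxon.label

    n_lesions = int(rng.integers(1, max_lesions + 1))
    # carve the sequence into blocks so lesions never touch
    block = n_codons // max_lesions
    specs = []
    for k in range(n_lesions):
        node = candidates[int(rng.integers(len(candidates)))]
        clade = frozenset(
            (leaf.taxon.label if leaf.taxon else leaf.label)
            for leaf in node.leaf_iter()
        )
        kind = kinds[int(rng.integers(len(kinds)))]
        codon0 = k * block + 1 + int(rng.integers(0, block - 6))
        pos = 3 * codon0 + 1  # codon start, keeps blocks separated
        if kind == "nonsense":
            specs.append(LesionSpec("nonsense", clade, position=pos))
        elif kind == "deletion":
            length = int(rng.integers(1, 13))
            specs.append(LesionSpec("deletion", clade, position=pos,
                                    length=length))
        else:
            length = int(rng.integers(1, 7))
            specs.append(LesionSpec("insertion", clade, position=pos,
                                    length=length))
    cfg = SimConfig(tree=tree, n_codons=n_codons, kappa=2.0, omega=0.5,
                    lesions=tuple(specs), ref_id=ref_id,
                    seed=int(rng.integers(2**31)))
    return simulate_alignment(cfg)
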