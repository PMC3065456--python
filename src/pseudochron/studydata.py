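"""The study fixture: printed inputs of the Carnivora UGT1A6 analysis.

This module transcribes the worked-example inputs that the source study
prints directly — the nine felid lesion descriptors with their 18-species
presence/absence matrix, the dated Carnivora phylogeny (published node ages
in MYA), the diet classification of all 40 sampled species, and the small
alignment regions around the shared CpG stop codon and the phocid frameshift
— and reconstructs alignments from them around a synthetic intact reference
exon. The reference sequence itself is synthetic (the real exon sequences
live in sequence databases and are not reproduced here): a deterministic
861+ bp open reading frame carrying CGA codons at the documented CpG stop
positions, so every coordinate, lesion and timing computation can be
exercised without external downloads.

All outputs are deterministic (fixed internal seed, no timestamps), so the
fixture bundle is byte-identical across runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import CodonAlignment, SequenceRecord, write_fasta
from .trees import DatedTree

__all__ = [
    "FELIDS",
    "LESIONS",
    "felid_lesion_matrix",
    "felid_alignment",
    "feliform_stop_alignment",
    "caniform_alignment",
    "reference_exon",
    "carnivora_newick",
    "carnivora_tree",
    "diet_table",
    "gene_status_table",
    "MISSING_UGT1A6",
    "write_study_fixture",
]

_REF_SEED = 4116  # fixes the synthetic reference exon
N_REF_CODONS = 291  # exon-1 sized (873 bp)

# Lesion descriptors: id -> (kind, ref_start, ref_end, length).
# Coordinates are 1-based reference positions (+1 = A of the start codon);
# deletions span the deleted bases, insertions give the flanking pair.
# The 1 bp deletion M3 is recorded at its single deleted base (position 399).
LESIONS: dict[str, tuple[str, int, int, int]] = {
    "M6": ("deletion", 9, 108, 100),
    "M1": ("nonsense", 274, 276, 3),
    "M7": ("deletion", 361, 364, 4),
    "M2": ("nonsense", 379, 381, 3),
    "M3": ("deletion", 399, 399, 1),
    "M4": ("deletion", 660, 669, 10),
    "M8": ("insertion", 691, 692, 2),
    "M9": ("insertion", 768, 769, 1),
    "M5": ("deletion", 827, 827, 1),
}

# Extra-felid lesions (brown hyena; northern elephant seal).
EXTRA_LESIONS: dict[str, tuple[str, int, int, int]] = {
    "M10": ("nonsense", 274, 276, 3),
    "M11": ("insertion", 398, 399, 1),
    "M12": ("nonsense", 667, 669, 3),
}

FELIDS = [
    "domestic_cat", "leopard_cat", "puma", "florida_panther", "cheetah",
    "canada_lynx", "bobcat", "geoffroys_cat", "margay", "tigrina",
    "african_golden_cat", "serval", "asian_golden_cat", "jaguar", "lion",
    "leopard", "tiger", "snow_leopard",
]

_SHARED = ("M1", "M2", "M3", "M4")  # carried by all 18 felids
_EXTRA_BY_SPECIES = {
    "domestic_cat": ("M5",),
    "leopard_cat": ("M5",),
    "puma": ("M7",),
    "florida_panther": ("M7",),
    "serval": ("M8",),
    "jaguar": ("M6", "M9"),
    "lion": ("M6",),
    "leopard": ("M6",),
    "tiger": ("M6",),
    "snow_leopard": ("M6",),
}

_EVENT_ORDER = ["M6", "M1", "M7", "M2", "M3", "M4", "M8", "M9", "M5"]


def felid_lesion_matrix() -> pd.DataFrame:
    """18 felid species x 9 events presence/absence matrix."""
    data = {}
    for sp in FELIDS:
        carried = set(_SHARED) | set(_EXTRA_BY_SPECIES.get(sp, ()))
        data[sp] = [m in carried for m in _EVENT_ORDER]
    return pd.DataFrame.from_dict(
        data, orient="index", columns=_EVENT_ORDER
    ).astype(bool)


def reference_exon() -> str:
    """Synthetic intact reference reading frame (873 bp, no internal stops).

    Carries CGA at positions 274-276 and 379-381 (the CpG stop-codon sites)
    and CAA at 667-669 (the phocid in-frame stop site), so the documented
    lesions are single C->T events away.
    """
    from .codonml import CODONS  # sense codons only -> no stops possible

    rng = np.random.default_rng(_REF_SEED)
    codons = [CODONS[i] for i in rng.integers(0, len(CODONS), N_REF_CODONS)]
    codons[0] = "ATG"
    codons[(274 - 1) // 3] = "CGA"
    codons[(379 - 1) // 3] = "CGA"
    codons[(667 - 1) // 3] = "CAA"
    return "".join(codons)


def _apply_lesions(ref: str, carried_by: dict[str, set[str]],
                   lesions: dict[str, tuple[str, int, int, int]],
                   inserted_bases: dict[str, str]) -> list[SequenceRecord]:
    """Reconstruct aligned sequences from an intact reference + descriptors."""
    rows = {sp: list(ref) for sp in carried_by}
    rows["human"] = list(ref)
    for sp, carried in carried_by.items():
        for m in carried:
            kind, start, end, length = lesions[m]
            if kind == "nonsense":
                rows[sp][start - 1 : end] = list("TGA" if m != "M12" else "TAA")
            elif kind == "deletion":
                rows[sp][start - 1 : end] = ["-"] * length
    insertions = sorted(
        (m for m in lesions if lesions[m][0] == "insertion"),
        key=lambda m: -lesions[m][1],
    )
    for m in insertions:
        _, flank, _, length = lesions[m]
        bases = inserted_bases[m]
        assert len(bases) == length
        for sp, row in rows.items():
            has = sp in carried_by and m in carried_by[sp]
            filler = list(bases) if has else ["-"] * length
            rows[sp] = row[:flank] + filler + row[flank:]
    order = ["human"] + [sp for sp in rows if sp != "human"]
    return [SequenceRecord(sp, "".join(rows[sp])) for sp in order]


def felid_alignment() -> CodonAlignment:
    """Human intact reference + the 18 felid sequences implied by the
    lesion descriptors and presence/absence matrix."""
    ref = reference_exon()
    matrix = felid_lesion_matrix()
    carried_by = {
        sp: {m for m in matrix.columns if matrix.at[sp, m]}
        for sp in matrix.index
    }
    records = _apply_lesions(
        ref, carried_by, LESIONS, inserted_bases={"M8": "CA", "M9": "G"}
    )
    return CodonAlignment(records, ref_id="human", ref_offset=1)


def feliform_stop_alignment() -> CodonAlignment:
    """The alignment region (bp 253-297) around the shared CpG stop codon.

    The intact reference and the hyaenids carry the ancestral CGA arginine
    codon at 274-276 (spotted hyena shows the antisense-deamination CAA);
    brown hyena and domestic cat carry the TGA stop.
    """
    ref = reference_exon()[252:297]  # reference positions 253..297
    rows = {
        "human": ref,
        "aardwolf": ref,
        "striped_hyena": ref,
        "spotted_hyena": _set(ref, 274 - 253, "CAA"),
        "brown_hyena": _set(ref, 274 - 253, "TGA"),
        "domestic_cat": _set(ref, 274 - 253, "TGA"),
    }
    records = [SequenceRecord(sp, s) for sp, s in rows.items()]
    return CodonAlignment(records, ref_id="human", ref_offset=253)


def caniform_alignment() -> CodonAlignment:
    """Full-length reconstruction of the phocid lesions: the northern
    elephant seal's 1 bp insertion between bp 398 and 399 and its in-frame
    TAA stop at bp 667-669; harbor seal intact."""
    ref = reference_exon()
    carried_by = {
        "harbor_seal": set(),
        "northern_elephant_seal": {"M11", "M12"},
    }
    records = _apply_lesions(
        ref, carried_by, EXTRA_LESIONS, inserted_bases={"M11": "A"}
    )
    return CodonAlignment(records, ref_id="human", ref_offset=1)


def _set(seq: str, idx0: int, repl: str) -> str:
    return seq[:idx0] + repl + seq[idx0 + len(repl):]


# --------------------------------------------------------------------- tree

# Dated Carnivora phylogeny. Printed ages (MYA): felid crown 10.8 and stem
# 36.5; Panthera crown 3.7; jaguar split 2.1; puma/cheetah 4.9; serval 5.6;
# domestic-cat/leopard-cat pair 6.2 with stem 6.7; brown hyena 4.2; elephant
# seal/harbor seal 16. Other internal ages are plausible published-era
# values used only to complete the chronogram (see ages TSV provenance).
def carnivora_newick() -> str:
    panthera = ("((jaguar,(lion,leopard)'age=2.0')'Jaguar_split|age=2.1',"
                "(tiger,snow_leopard)'age=2.9')'Panthera|age=3.7'")
    lynx = "(canada_lynx,bobcat)'age=3.2'"
    ocelot = "(geoffroys_cat,(margay,tigrina)'age=1.6')'age=2.9'"
    caracal = "(serval,african_golden_cat)'age=5.6'"
    puma_lineage = "(cheetah,(puma,florida_panther)'age=0.5')'age=4.9'"
    domleop = "(domestic_cat,leopard_cat)'age=6.2'"
    rest5 = f"({puma_lineage},{domleop})'age=6.7'"
    rest4 = f"({lynx},{rest5})'age=7.2'"
    rest3 = f"({ocelot},{rest4})'age=8.0'"
    rest2 = f"({caracal},{rest3})'age=8.5'"
    rest = f"(asian_golden_cat,{rest2})'age=9.4'"
    felidae = f"({panthera},{rest})'Felidae|age=10.8'"
    hyaenidae = ("(aardwolf,(spotted_hyena,(striped_hyena,brown_hyena)"
                 "'BrownHyena_split|age=4.2')'age=8.6')'Hyaenidae|age=10.6'")
    viverridae = "(binturong,african_civet)'Viverridae|age=16.2'"
    felirest = f"(({hyaenidae},mongoose)'age=29.0',{viverridae})'age=34.0'"
    feliformia = f"({felidae},{felirest})'Feliformia|age=36.5'"
    canidae = ("(((domestic_dog,gray_wolf)'age=0.8',coyote)'age=1.1',"
               "red_fox)'Canidae|age=9.0'")
    ursidae = "(polar_bear,asiatic_black_bear)'Ursidae|age=5.0'"
    otariidae = ("((northern_fur_seal,southern_fur_seal)'age=4.5',"
                 "new_zealand_sea_lion)'Otariidae|age=6.0'")
    phocidae = "(northern_elephant_seal,harbor_seal)'Phocidae|age=16.0'"
    pinnipedia = f"({otariidae},{phocidae})'age=22.0'"
    mustelidae = "(ferret,sea_otter)'Mustelidae|age=12.0'"
    musteloidea = f"(({mustelidae},raccoon)'age=18.0',red_panda)'age=25.0'"
    arctoidea = f"({ursidae},({pinnipedia},{musteloidea})'age=38.0')'age=42.0'"
    caniformia = f"({canidae},{arctoidea})'Caniformia|age=48.0'"
    return f"({feliformia},{caniformia})'Carnivora|age=53.0';"


# Published confidence intervals on the ages that carry the headline timing
# statements (MYA).
PRINTED_AGE_CI = {
    "Felidae": (8.4, 14.5),
    "Feliformia": (28.9, 46.5),
    "BrownHyena_split": (2.6, 6.4),
    "Phocidae": (14.2, 17.8),
    "Jaguar_split": (1.2, 3.5),
}


def carnivora_tree(with_ci: bool = False) -> DatedTree:
    """The dated fixture tree; ``with_ci`` attaches the published confidence
    annotations to the named nodes."""
    return DatedTree.from_newick(
        carnivora_newick(),
    ) if not with_ci else _tree_with_ci()


def _tree_with_ci() -> DatedTree:
    import dendropy

    tree = dendropy.Tree.get(data=carnivora_newick(), schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    return DatedTree(tree, age_ci=dict(PRINTED_AGE_CI))


# --------------------------------------------------------------------- diet

_DIET = {
    **{sp: "hypercarnivore" for sp in FELIDS},
    "aardwolf": "hypercarnivore",
    "spotted_hyena": "hypercarnivore",
    "striped_hyena": "hypercarnivore",
    "brown_hyena": "hypercarnivore",
    "mongoose": "hypercarnivore",
    "ferret": "hypercarnivore",
    "sea_otter": "hypercarnivore",
    "northern_fur_seal": "hypercarnivore",
    "southern_fur_seal": "hypercarnivore",
    "new_zealand_sea_lion": "hypercarnivore",
    "northern_elephant_seal": "hypercarnivore",
    "harbor_seal": "hypercarnivore",
    "domestic_dog": "mesocarnivore",
    "gray_wolf": "mesocarnivore",
    "coyote": "mesocarnivore",
    "red_fox": "mesocarnivore",
    "polar_bear": "mesocarnivore",
    "african_civet": "mesocarnivore",
    "raccoon": "hypocarnivore",
    "red_panda": "hypocarnivore",
    "asiatic_black_bear": "hypocarnivore",
    "binturong": "hypocarnivore",
}

# Species whose membership in a diet class is stated at family level only;
# flagged so downstream reports can distinguish direct from inferred support.
_DIET_INFERRED = {"domestic_dog", "gray_wolf", "coyote", "red_fox",
                  "ferret", "sea_otter", "mongoose"}

MISSING_UGT1A6 = (
    "northern_fur_seal", "southern_fur_seal", "new_zealand_sea_lion",
)  # gene could not be amplified: missing data, not absence of lesions

_PSEUDOGENE = set(FELIDS) | {"brown_hyena", "northern_elephant_seal"}


def diet_table() -> pd.DataFrame:
    rows = [
        {
            "species": sp,
            "category": cat,
            "evidence": (
                "family-level transcription" if sp in _DIET_INFERRED
                else "study transcription"
            ),
        }
        for sp, cat in sorted(_DIET.items())
    ]
    return pd.DataFrame(rows)


def gene_status_table() -> pd.DataFrame:
    rows = []
    for sp in sorted(_DIET):
        if sp in MISSING_UGT1A6:
            status = "missing"
        elif sp in _PSEUDOGENE:
            status = "pseudogene"
        else:
            status = "intact"
        rows.append({"species": sp, "ugt1a6_status": status})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ bundle


def write_study_fixture(outdir) -> dict[str, str]:
    """Write the deterministic fixture bundle; returns {name: path}."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> Path:
        paths[name] = str(out / name)
        return out / name

    write_fasta(felid_alignment().records, _p("felid_ugt1a6.fasta"))
    write_fasta(feliform_stop_alignment().records,
                _p("feliform_stop_region.fasta"))
    write_fasta(caniform_alignment().records, _p("phocid_ugt1a6.fasta"))
    _p("carnivora.nwk").write_text(carnivora_newick() + "\n")

    tree = carnivora_tree()
    age_rows = ["node\tage_mya\tci_lo\tci_hi\tprovenance"]
    for node in tree.tree.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        if node.is_leaf() or label is None:
            continue
        ci = PRINTED_AGE_CI.get(label)
        prov = "printed" if ci else "transcribed"
        lo = f"{ci[0]:g}" if ci else ""
        hi = f"{ci[1]:g}" if ci else ""
        age_rows.append(f"{label}\t{tree.age(node):g}\t{lo}\t{hi}\t{prov}")
    _p("node_ages.tsv").write_text("\n".join(age_rows) + "\n")

    lesion_rows = ["id\tkind\tref_start\tref_end\tlength"]
    for m in _EVENT_ORDER:
        kind, start, end, length = LESIONS[m]
        lesion_rows.append(f"{m}\t{kind}\t{start}\t{end}\t{length}")
    for m in ("M10", "M11", "M12"):
        kind, start, end, length = EXTRA_LESIONS[m]
        lesion_rows.append(f"{m}\t{kind}\t{start}\t{end}\t{length}")
    _p("lesions.tsv").write_text("\n".join(lesion_rows) + "\n")

    matrix = felid_lesion_matrix()
    cells = matrix.replace({True: "+", False: "-"})
    cells.index.name = "species"
    cells.to_csv(_p("felid_matrix.tsv"), sep="\t")

    diet_table().to_csv(_p("diet.tsv"), sep="\t", index=False)
    gene_status_table().to_csv(_p("gene_status.tsv"), sep="\t", index=False)
    return paths
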