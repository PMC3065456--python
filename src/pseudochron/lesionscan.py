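"""Detection of gene-inactivating lesions in codon alignments.

A lesion is a frameshifting/non-frameshifting indel or a nonsense (premature
stop) codon, located in reference coordinates. Per-species scans are merged
into shared mutation events with a species x event presence/absence matrix,
the tabulation used to call a gene a pseudogene in each species.

Conventions
-----------
* Deletions are reported as the inclusive span of deleted reference
  positions; a 1 bp deletion is a single position.
* Insertions are reported as the flanking reference pair ``(p, p + 1)``.
* Indels are disruptive iff their length is not divisible by 3; nonsense
  codons are always disruptive.
* Nonsense events are called in the *unshifted reference frame*: the species
  bases aligned to each reference codon are read off directly. Stop codons
  that appear only in the shifted frame downstream of a frameshift are
  consequences of the indel, not independent events, and are not reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .seqio import CodonAlignment, STOP_CODONS, map_to_reference, _AMBIGUITY

__all__ = [
    "LesionEvent",
    "GeneStatus",
    "scan_species",
    "scan_alignment",
    "merge_events",
    "annotate_cpg",
    "gene_status",
    "events_table",
]

log = logging.getLogger(__name__)

NONSENSE = "nonsense"
DELETION = "deletion"
INSERTION = "insertion"


@dataclass(frozen=True)
class LesionEvent:
    """One inactivating mutation event.

    ``ref_start``/``ref_end`` are 1-based inclusive reference positions; for
    insertions they are the flanking pair. ``carriers`` is the set of species
    sharing the event.
    """

    kind: str
    ref_start: int
    ref_end: int
    length: int
    carriers: frozenset[str]
    id: str | None = None
    cpg_hotspot: bool = False

    def __post_init__(self):
        if self.kind not in (NONSENSE, DELETION, INSERTION):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.ref_start > self.ref_end:
            raise ValueError("ref_start must be <= ref_end")
        if not self.carriers:
            raise ValueError("lesion event with no carriers")

    @property
    def disruptive(self) -> bool:
        if self.kind == NONSENSE:
            return True
        return self.length % 3 != 0

    @property
    def key(self):
        return (self.kind, self.ref_start, self.ref_end, self.length)


@dataclass(frozen=True)
class GeneStatus:
    species: str
    status: str  # "intact" | "pseudogene"
    n_disruptive: int


def _species_columns(aln: CodonAlignment):
    """Columns of the alignment holding reference bases, as (ref_pos, col)."""
    refmap = map_to_reference(aln)
    return refmap


def scan_species(aln: CodonAlignment, species: str) -> list[LesionEvent]:
    """Scan one species against the reference; return single-carrier events."""
    rec = aln.get(species)
    ref = aln.reference.seq
    seq = rec.seq
    refmap = map_to_reference(aln)

    if species == aln.ref_id:
        _check_reference_intact(aln)
        return []
    _check_reference_intact(aln)

    events: list[LesionEvent] = []
    carriers = frozenset([species])

    # --- indel runs: maximal gap runs in exactly one of (species, reference)
    n = aln.length
    col = 0
    while col < n:
        s, r = seq[col], ref[col]
        if s == "-" and r != "-":  # deletion in species
            start_col = col
            while col < n and seq[col] == "-" and ref[col] != "-":
                col += 1
            start = refmap.ref_position(start_col + 1)
            end = refmap.ref_position(col)  # col is 1-based index of last run col
            length = end - start + 1
            events.append(
                LesionEvent(DELETION, start, end, length, carriers)
            )
        elif r == "-" and s != "-":  # insertion relative to reference
            start_col = col
            length = 0
            while col < n and ref[col] == "-":
                if seq[col] != "-":
                    length += 1
                col += 1
            p, q = refmap.ref_position(start_col + 1)
            events.append(LesionEvent(INSERTION, p, q, length, carriers))
        else:
            col += 1

    # --- nonsense codons in the unshifted reference frame
    first = refmap.first
    last = refmap.last
    p = first
    while p + 2 <= last:
        cols = (refmap.column(p), refmap.column(p + 1), refmap.column(p + 2))
        codon = seq[cols[0] - 1] + seq[cols[1] - 1] + seq[cols[2] - 1]
        ref_codon = ref[cols[0] - 1] + ref[cols[1] - 1] + ref[cols[2] - 1]
        if "-" not in codon and not (set(codon) & _AMBIGUITY):
            if codon in STOP_CODONS and ref_codon not in STOP_CODONS:
                events.append(LesionEvent(NONSENSE, p, p + 2, 3, carriers))
        p += 3

    events.sort(key=lambda e: (e.ref_start, e.kind, e.length))
    return events


def _check_reference_intact(aln: CodonAlignment):
    ref = aln.reference.seq.replace("-", "")
    for i in range(0, len(ref) - len(ref) % 3, 3):
        codon = ref[i : i + 3]
        if codon in STOP_CODONS and i + 3 < len(ref):
            raise ValueError(
                f"reference {aln.ref_id!r} contains a premature stop codon "
                f"at reference position {aln.ref_offset + i}"
            )


def scan_alignment(aln: CodonAlignment, species=None) -> dict[str, list[LesionEvent]]:
    """Scan every (or the given) non-reference species."""
    names = list(species) if species is not None else [
        s for s in aln.species if s != aln.ref_id
    ]
    return {name: scan_species(aln, name) for name in names}


def merge_events(per_species, aln: CodonAlignment | None = None,
                 ) -> tuple[list[LesionEvent], pd.DataFrame]:
    """Merge per-species events into shared events + presence/absence matrix.

    Events are identified across species by (kind, ref_start, ref_end,
    length) alone — inserted nucleotides are not compared. When the source
    alignment is supplied, shared insertions whose carriers disagree on the
    inserted sequence are logged (they still merge). Ids are assigned
    deterministically by position, then kind. Accepts either a mapping
    {species: [events]} or a flat iterable of single-carrier events.
    """
    if isinstance(per_species, dict):
        flat = [e for evs in per_species.values() for e in evs]
        all_species = sorted(per_species)
    else:
        flat = list(per_species)
        all_species = sorted({s for e in flat for s in e.carriers})

    groups: dict[tuple, set[str]] = {}
    for ev in flat:
        groups.setdefault(ev.key, set()).update(ev.carriers)

    merged = []
    for key in sorted(groups, key=lambda k: (k[1], k[0], k[2], k[3])):
        kind, start, end, length = key
        merged.append(
            LesionEvent(kind, start, end, length, frozenset(groups[key]))
        )
    merged = [replace(ev, id=f"E{i}") for i, ev in enumerate(merged, start=1)]

    if aln is not None:
        refmap = map_to_reference(aln)
        ref = aln.reference.seq
        for ev in merged:
            if ev.kind != INSERTION or len(ev.carriers) < 2:
                continue
            cols = [
                c for c in range(1, aln.length + 1)
                if ref[c - 1] == "-"
                and refmap.ref_position(c) == (ev.ref_start, ev.ref_end)
            ]
            inserted = {
                "".join(aln.get(sp).seq[c - 1] for c in cols).replace("-", "")
                for sp in ev.carriers
            }
            if len(inserted) > 1:
                log.warning(
                    "insertion %s at (%d, %d) merged across carriers with "
                    "differing inserted sequence: %s",
                    ev.id, ev.ref_start, ev.ref_end, sorted(inserted),
                )

    matrix = pd.DataFrame(
        {
            ev.id: [sp in ev.carriers for sp in all_species]
            for ev in merged
        },
        index=all_species,
        dtype=bool,
    )
    return merged, matrix


def annotate_cpg(event: LesionEvent, aln: CodonAlignment) -> LesionEvent:
    """Flag a nonsense event as a CpG-hotspot candidate.

    True iff the observed stop codon is one C->T transition (sense strand,
    e.g. CGA->TGA) or one G->A change (antisense-strand C->T) away from a
    non-stop codon observed at the same reference codon in at least one
    non-carrier sequence — the signature of recurrent deamination at a
    methylated CpG site, and hence of possible homoplasy.
    """
    if event.kind != NONSENSE:
        raise ValueError("annotate_cpg applies only to nonsense events")
    refmap = map_to_reference(aln)
    cols = [refmap.column(p) - 1 for p in range(event.ref_start, event.ref_end + 1)]

    def codon_of(species: str) -> str | None:
        seq = aln.get(species).seq
        codon = "".join(seq[c] for c in cols)
        if "-" in codon or set(codon) & _AMBIGUITY:
            return None
        return codon

    carrier = next(iter(sorted(event.carriers)))
    stop = codon_of(carrier)
    hotspot = False
    if stop is not None and stop in STOP_CODONS:
        for sp in aln.species:
            if sp in event.carriers:
                continue
            src = codon_of(sp)
            if src is None or src in STOP_CODONS:
                continue
            diffs = [(a, b) for a, b in zip(src, stop) if a != b]
            if len(diffs) == 1 and diffs[0] in (("C", "T"), ("G", "A")):
                hotspot = True
                break
    return replace(event, cpg_hotspot=hotspot)


def gene_status(matrix: pd.DataFrame, events: list[LesionEvent]) -> list[GeneStatus]:
    """Per-species gene status: pseudogene iff >=1 disruptive event carried."""
    disruptive_ids = {ev.id for ev in events if ev.disruptive}
    statuses = []
    for sp in matrix.index:
        carried = [c for c in matrix.columns if matrix.at[sp, c]]
        n_dis = sum(1 for c in carried if c in disruptive_ids)
        statuses.append(
            GeneStatus(sp, "pseudogene" if n_dis >= 1 else "intact", n_dis)
        )
    return statuses


def events_table(events: list[LesionEvent]) -> pd.DataFrame:
    """Tabulate merged events (one row per event) for reporting."""
    return pd.DataFrame(
        {
            "id": [e.id for e in events],
            "kind": [e.kind for e in events],
            "ref_start": [e.ref_start for e in events],
            "ref_end": [e.ref_end for e in events],
            "length": [e.length for e in events],
            "disruptive": [e.disruptive for e in events],
            "cpg_hotspot": [e.cpg_hotspot for e in events],
            "carriers": [",".join(sorted(e.carriers)) for e in events],
        }
    )
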