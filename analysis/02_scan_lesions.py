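#!/usr/bin/env python
"""Scan the reconstructed felid alignment for inactivating lesions, merge
shared events across species, flag CpG-hotspot stop codons, and call gene
status per species.

Finding: 9 distinct disruptive events; 4 (two stop codons, two frameshift
deletions) are carried by all 18 felids, so the gene is a pseudogene in
every felid sampled."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from pseudochron import studydata
from pseudochron.lesionscan import (
    annotate_cpg,
    events_table,
    gene_status,
    merge_events,
    scan_alignment,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "scan"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    aln = studydata.felid_alignment()
    events, matrix = merge_events(scan_alignment(aln))
    events = [annotate_cpg(e, aln) if e.kind == "nonsense" else e
              for e in events]
    table = events_table(events)
    table.to_csv(OUT / "events.tsv", sep="\t", index=False)
    cells = matrix.replace({True: "+", False: "-"})
    cells.index.name = "species"
    cells.to_csv(OUT / "matrix.tsv", sep="\t")
    statuses = gene_status(matrix, events)
    pd.DataFrame(
        [{"species": s.species, "status": s.status,
          "n_disruptive": s.n_disruptive} for s in statuses]
    ).to_csv(OUT / "status.tsv", sep="\t", index=False)

    universal = [e for e in events if len(e.carriers) == len(matrix.index)]
    print(f"{len(events)} distinct events across {len(matrix.index)} species")
    print(f"{len(universal)} events carried by every species: "
          + ", ".join(f"{e.id} ({e.kind})" for e in universal))
    n_pseudo = sum(s.status == "pseudogene" for s in statuses)
    print(f"{n_pseudo}/{len(statuses)} species carry a disruptive lesion")
    cpg = [e.id for e in events if e.cpg_hotspot]
    print(f"CpG-hotspot stop codons: {', '.join(cpg) or 'none'}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
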