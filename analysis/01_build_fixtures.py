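#!/usr/bin/env python
"""Build the study fixture bundle: lesion descriptors + presence/absence
matrix, reconstructed alignments around a synthetic intact reference exon,
the dated Carnivora tree, and the diet table. Everything downstream reads
from results/fixtures/."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pseudochron.simgen import generate_study_fixture

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main():
    paths = generate_study_fixture(OUT)
    print(f"wrote {len(paths)} fixture files to {OUT}:")
    for name in sorted(paths):
        print(f"  {name}")


if __name__ == "__main__":
    main()
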