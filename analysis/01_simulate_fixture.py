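#!/usr/bin/env python
"""Generate the synthetic slide + cohort fixture set.

Writes a small-scale fixture (two stained/control slide pairs with truth
annotations and tables, plus a study-sized cohort CSV) under
scratch/fixture_small/ — images are binary and stay out of results/ — and
copies the text tables into results/ for inspection.
"""
import shutil
from pathlib import Path

from fibroquant.synthetic import write_fixture_set

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "fixture_small"
RESULTS = ROOT / "results"


def main() -> None:
    manifest = write_fixture_set(OUT, scale="small", seed=7)
    RESULTS.mkdir(exist_ok=True)
    for name in ("truth_tiles.csv", "truth_nuclei.csv", "cohort.csv", "manifest.json"):
        shutil.copy(OUT / name, RESULTS / f"fixture_{name}")
    print(f"fixture written to {OUT} ({len(manifest['files'])} files, seed 7)")
    print("slides: fap (cytoplasmic DAB) and sox11 (nuclear DAB), each with a")
    print("hematoxylin-only negative control and one truth exclusion artifact;")
    print("truth tables and the cohort CSV copied into results/ as fixture_*.")


if __name__ == "__main__":
    main()
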