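"""Regenerate the bundled default beta error table.

Run from the repository root:

    python scripts/build_default_error_table.py

Writes ``src/ascna/data/error_table_default.tsv``. The build is
deterministic: the seed and grids below are recorded in the file's
metadata header.
"""

import pathlib
import time

from ascna.beta_core import build_error_table

OUT = pathlib.Path(__file__).resolve().parents[1] / "src/ascna/data/error_table_default.tsv"

NSNPS_GRID = (5, 10, 20, 50, 100, 200, 400)
COV_GRID = (10, 20, 50, 100, 200, 500)
BETA_GRID = (0.2, 0.5, 0.8, 1.0)
REPS = 1000
CONFIDENCE = 0.9
SEED = 2024


def main() -> None:
    t0 = time.time()
    tb = build_error_table(nsnps_grid=NSNPS_GRID, cov_grid=COV_GRID,
                           beta_grid=BETA_GRID, reps=REPS,
                           confidence=CONFIDENCE, seed=SEED)
    tb.to_tsv(OUT)
    print(f"wrote {OUT} ({len(tb.table)} cells) in {time.time() - t0:.1f}s")


if __name__ == "__main__":
    main()
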