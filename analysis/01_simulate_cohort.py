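"""Generate the synthetic study cohort.

Simulates 19 overweight/obese-like (YO) and 19 matched normal-weight-like
(YN) subjects, each standing on firm and foam surfaces at two visits
(152 trials of 60 s tri-axial trunk acceleration at 500 Hz), and writes
the trial text files, the metadata table and the ground-truth knob table
under results/cohort/.
"""

import pathlib
import sys

from swaylab.cli import main

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "cohort"

if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    code = main(["simulate", "--out", str(OUT), "--n-per-group", "19", "--seed", str(seed)])
    if code == 0:
        print(f"cohort written to {OUT} (seed {seed})")
    sys.exit(code)
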