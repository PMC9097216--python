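"""Compute the four sway measures for every trial and axis.

RMS (mm·s⁻²), sample entropy (M = 3, r = 0.07·SD for ML / 0.06·SD for AP),
the largest Lyapunov exponent (m = 4, τ = 17/20 samples, divergence-slope
fit over steps 0-75, bits·s⁻¹) and the 2-10 Hz-band DFA scaling exponent.
Writes the long-format measure table to results/measures.csv.
"""

import pathlib
import sys

from swaylab.cli import main

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    code = main(["complexity", "--inputs", str(ROOT / "cohort"), "--out", str(ROOT)])
    sys.exit(code)
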