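"""Preprocess every trial and screen for artifacts.

Downsamples 500 → 100 Hz, crops to the middle 50 s (5,000 samples),
tilt-corrects into the anatomical ML/AP frame, applies the 0.3-10 Hz
zero-lag Butterworth bandpass, and runs the fivefold windowed-SD screen
on the resultant acceleration.  Writes results/verdicts.csv; a "fail"
verdict means the whole subject would be excluded downstream.
"""

import pathlib
import sys

from swaylab.cli import main

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    code = main(["process", "--inputs", str(ROOT / "cohort"), "--out", str(ROOT)])
    sys.exit(code)
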