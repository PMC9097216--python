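"""Reliability and inference over the measure table.

Computes the ICC(1,1) test-retest grid per measure × axis × group ×
condition, excludes any measure × axis with a poor (≤ 0.40) cell from
inferential testing, then runs the three-way mixed ANOVA (condition and
visit within, group between) on ln(x+1)-transformed values with
Benjamini-Hochberg-controlled pairwise post-hocs (visit-pooled when all
visit terms are negligible).  Writes icc.csv plus per measure × axis
anova_*/posthoc_* reports under results/.
"""

import pathlib
import sys

from swaylab.cli import main

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    code = main(["stats", "--table", str(ROOT / "measures.csv"), "--out", str(ROOT)])
    sys.exit(code)
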