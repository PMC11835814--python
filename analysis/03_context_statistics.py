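#!/usr/bin/env python
"""Summarize the cross-context comparisons of the simulated study.

Condenses the analyze output into one table per figure-level result
(learning by context and order, early learning, song rate, song speed,
entropy) and prints the statistical test battery: per-bird proportion
tests, one-way ANOVAs across contexts, the 3-way main-effects ANOVA on
degree of learning, paired t-tests on relative learning speed, and the
early-vs-total learning correlation.
"""

from pathlib import Path

import pandas as pd

from songseq.pipeline import cmd_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    analysis = ROOT / "scratch" / "analysis"
    tables = cmd_report(analysis, ROOT / "results" / "report")
    for name, frame in tables.items():
        print(f"\n== {name} ==")
        print(frame.to_string(index=False, float_format="%.3f"))

    tests = pd.read_csv(analysis / "tests.csv")
    print("\n== statistical tests ==")
    group = tests[~tests.test.str.startswith("prop_test")]
    print(group.to_string(index=False, float_format="%.4f"))
    prop = tests[tests.test.str.startswith("prop_test")]
    n_sig = int((prop.p < 0.001).sum())
    print(f"\nper-bird proportion tests: {n_sig}/{len(prop)} blocks show a "
          "significant (p < 0.001) reduction of the target transition.")


if __name__ == "__main__":
    main()
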