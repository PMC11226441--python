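#!/usr/bin/env python
"""Sample-size planning for the two-mode agency comparison.

The prior dataset on detecting control changes gives a Cohen's d of 0.617 for
the difference in d' between detecting increases and decreases of control.
This script computes the minimal sample size for 80% power at a one-tailed
alpha of .05 under the matched-pairs noncentral-t formulation (which is the
formulation that yields n = 18), alongside the independent-groups answer for
comparison, and writes both to results/power.json.
"""

import json
from pathlib import Path

from facemix.stats import PowerSpec, power_t, sample_size_t

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    d = 0.617
    rows = {}
    for design in ("paired", "independent"):
        spec = PowerSpec(d=d, alpha=0.05, power_target=0.8, tails=1, design=design)
        n = sample_size_t(spec)
        rows[design] = {"n": n, "power_at_n": round(power_t(n, spec), 4)}
        print(f"{design:12s} d={d}: minimal n = {n} (power {rows[design]['power_at_n']})")
    OUT.mkdir(exist_ok=True)
    (OUT / "power.json").write_text(json.dumps(rows, indent=2))
    print(f"wrote {OUT / 'power.json'}")


if __name__ == "__main__":
    main()
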