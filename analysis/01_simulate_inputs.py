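#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Writes a two-group metabolite table (12 planted differential metabolites, 3 SD
shifts), a ten-pathway database with three planted core pathways, a
metabolite->gene annotation, three tumor/normal expression cohorts with four
informative targets at coupling 0.8, and a target-gene link table, plus the
pipeline config — everything the downstream scripts consume.
"""

import json
from pathlib import Path

from macsnet.demo import write_demo_bundle

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "results" / "inputs"
SEED = 11


def main():
    bundle = write_demo_bundle(INPUTS, seed=SEED)
    truth = json.loads((INPUTS / "truth.json").read_text())
    print(f"wrote inputs under {INPUTS}")
    print(f"planted differential metabolites: {len(truth['differential_metabolites'])}")
    print(f"planted core pathways: {truth['planted_core_pathways']}")
    print(f"planted informative targets: {truth['informative_targets']}")


if __name__ == "__main__":
    main()
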