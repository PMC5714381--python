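#!/usr/bin/env python
"""Run the property-based validation experiments and summarize them.

Thin driver over peaklink.experiments: oracle agreement for the
classifier / overlap rule / state assignment / hypergeometric test,
bootstrap calibration and power, skew-normal fit behavior, expression
recovery, and end-to-end determinism.  Writes results/validation.json.
This is the same battery `scripts/acceptance.py` reports.
"""

import json
import tempfile
from pathlib import Path

from peaklink import experiments as ex

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260919


def run() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    report = {
        "hypergeom_oracle": ex.hypergeom_oracle_check(),
        "classifier": ex.classifier_oracle_check(SEED),
        "venn": ex.venn_oracle_check(SEED),
        "states": ex.state_recovery_check(SEED),
        "skewnorm_normal_limit": ex.skewnorm_normal_limit(SEED),
        "skewnorm_tails": ex.skewnorm_tail_agreement(SEED),
        "bootstrap_calibration": ex.bootstrap_calibration(SEED),
        "bootstrap_power": ex.bootstrap_power(SEED),
        "expression": ex.expression_recovery(SEED),
    }
    with tempfile.TemporaryDirectory() as tmp:
        report["endtoend"] = ex.endtoend_determinism(SEED % (2**31 - 1), tmp)
    with open(OUT / "validation.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for k, v in report.items():
        print(k, v)


if __name__ == "__main__":
    run()
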