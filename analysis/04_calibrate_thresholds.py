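"""Calibrate score-filter thresholds on a synthetic control panel.

Evaluates the full threshold grid for SNVs (inclusive DS/QS windows) and
INDELs (strict DS ceiling with the fixed stringent criteria) on panel call
sets whose known (database-member) calls carry well-separated SNV scores
but noisy INDEL scores, targeting 95% known-call retention.  Writes the
chosen thresholds and both metrics to results/calibration.json.
"""

from __future__ import annotations

import json
from pathlib import Path

from famexome.calibrate import calibrate_thresholds
from famexome.synth import SyntheticConfig, gen_score_panel

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    snv_panel, indel_panel = gen_score_panel(SyntheticConfig(seed=1))
    out = {}
    for vtype, panel in (("SNV", snv_panel), ("INDEL", indel_panel)):
        res = calibrate_thresholds(panel, vtype, target_retention=0.95)
        out[vtype] = {
            "chosen": res.chosen,
            "known_retention": res.known_retention,
            "total_retained": res.total_retained,
            "meets_target": res.meets_target,
            "n_panel": len(panel),
        }
        print(
            f"{vtype}: chosen {res.chosen}, known retention "
            f"{100 * res.known_retention:.1f}%, {res.total_retained} calls retained "
            f"({'meets' if res.meets_target else 'CANNOT meet'} the 95% target)"
        )
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "calibration.json").write_text(json.dumps(out, indent=2) + "\n")
    print(
        "\nSNV scores separate cleanly, so a window retaining >=95% of known "
        "calls exists; INDEL calls are artifact-dominated, so the stringent "
        "criteria retain only a minority of known calls — the expected "
        "asymmetry between the two variant classes."
    )


if __name__ == "__main__":
    main()
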