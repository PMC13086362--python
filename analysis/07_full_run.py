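#!/usr/bin/env python
"""Run the whole pipeline end-to-end through the orchestration layer.

Equivalent to drivers 02-06 in one reproducible, config-driven run; outputs
land in results/full_run/ together with the config copy and run report.
"""

import json

from paleoherd.pipeline import RunConfig, run_all

from site_common import MASTER_SEED, RESULTS_DIR, build_site


def main() -> None:
    paths = build_site()
    cfg = RunConfig(
        out_dir=str(RESULTS_DIR / "full_run"),
        sequences_csv=str(paths["sequences"]),
        collagen_csv=str(paths["collagen"]),
        mortality_csv=str(paths["mortality"]),
        spectra_dir=str(paths["spectra"]),
        phase_group_column="pattern",
        seed=MASTER_SEED,
    )
    report = run_all(cfg)
    print(json.dumps(report, indent=2, default=float))


if __name__ == "__main__":
    main()
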