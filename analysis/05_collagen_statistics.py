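#!/usr/bin/env python
"""Collagen QC and site statistics: C:N, summaries, correlation, ellipse.

Writes results/collagen_stats.json.
"""

import dataclasses
import json

from paleoherd.collagen import (
    confidence_ellipse,
    correlate,
    iqr_outliers,
    read_collagen,
    summarize,
)

from site_common import RESULTS_DIR, build_site


def main() -> None:
    paths = build_site()
    samples = read_collagen(paths["collagen"])
    passing = [s for s in samples if s.qc_pass]
    d13 = [s.d13C for s in passing]
    d15 = [s.d15N for s in passing]

    s13, s15 = summarize(d13), summarize(d15)
    corr = correlate(d13, d15, n_permutations=2000, seed=1)
    kept13, out13 = iqr_outliers(d13)
    kept15, out15 = iqr_outliers(d15)
    ellipse = confidence_ellipse(list(zip(d13, d15)))

    report = {
        "n": len(samples),
        "n_qc_pass": len(passing),
        "cn_range": [min(s.cn_atomic for s in samples), max(s.cn_atomic for s in samples)],
        "d13C": dataclasses.asdict(s13),
        "d15N": dataclasses.asdict(s15),
        "correlation": dataclasses.asdict(corr),
        "n_iqr_outliers": int(out13.size + out15.size),
        "ellipse_95": dataclasses.asdict(ellipse),
    }
    out = RESULTS_DIR / "collagen_stats.json"
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2, default=float)

    print(f"{len(passing)}/{len(samples)} samples pass QC "
          f"(C:N {report['cn_range'][0]:.2f}-{report['cn_range'][1]:.2f})")
    print(f"d13C mean {s13.mean:.1f} +/- {s13.sd:.1f} permil; "
          f"d15N mean {s15.mean:.1f} +/- {s15.sd:.1f} permil")
    print(f"Pearson r = {corr.pearson_r:.2f} (p = {corr.pearson_p:.2f}); "
          f"Spearman rho = {corr.spearman_rho:.2f} (p = {corr.spearman_p:.2f})")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
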