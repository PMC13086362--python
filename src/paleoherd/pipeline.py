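"""Orchestration of a full site analysis run.

``run_all`` ties the stages together in dependency order — ZooMS taxon
calls feed the sequence labels, cosine fits feed both the birth-season and
the seasonal-diet stages — and writes flat CSV/JSON outputs plus a run log
with the package version, a config hash and all seeds, so two runs with
the same config are numerically identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, collagen, dietmix, herdprof, seqmodel, zooms

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("paleoherd")


@dataclass
class RunConfig:
    """Serialisable configuration for one reproducible run.

    Any input path left as None skips that stage.  A copy of the config is
    written into the output directory.
    """

    out_dir: str
    sequences_csv: str | None = None
    collagen_csv: str | None = None
    mortality_csv: str | None = None
    spectra_dir: str | None = None
    screening: dict = field(default_factory=dict)        # ScreeningRules fields
    mixing: dict = field(default_factory=dict)           # MixingConfig fields
    cosine_model: str = "basic"
    dirichlet_prior: float = 1.0
    dirichlet_draws: int = 10_000
    seed: int = 42
    zooms_tolerance: float = 0.5
    #: column in the sequences CSV assigning specimens to pattern groups for
    #: pooled phase-shift fits; None pools all modelled specimens together
    phase_group_column: str | None = None
    anova_group_column: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _require(path: str | None, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} input not found: {p}")
    return p


def run_all(config: RunConfig) -> dict:
    """Execute all configured stages and assemble the run report.

    Stage order: zooms → seqmodel → dietmix → collagen → herdprof.  Partial
    outputs are retained on stage failure; the raised error names the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    report: dict = {
        "package_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "setup"
    try:
        taxon_by_specimen: dict[str, str] = {}
        if config.spectra_dir is not None:
            stage = "zooms"
            _require(config.spectra_dir, "spectra directory")
            table, summary = zooms.batch_report(
                config.spectra_dir, tolerance=config.zooms_tolerance
            )
            table.to_csv(out / "zooms_calls.csv", index=False)
            taxon_by_specimen = dict(zip(table["specimen_id"], table["call"]))
            report["stages"]["zooms"] = {"calls": summary, "n_spectra": len(table)}

        fits: dict[str, seqmodel.SeasonalFit] = {}
        seqs: dict[str, seqmodel.ToothSequence] = {}
        if config.sequences_csv is not None:
            stage = "seqmodel"
            rules = seqmodel.ScreeningRules(**config.screening)
            sequences = seqmodel.read_tooth_sequences(_require(config.sequences_csv, "sequence"))
            bands = seqmodel.default_season_bands()
            rows = []
            for seq in sequences:
                if seq.specimen_id in taxon_by_specimen:
                    seq.taxon = taxon_by_specimen[seq.specimen_id]
                seqs[seq.specimen_id] = seq
                screen = seqmodel.screen_sequence(seq, rules)
                row = {
                    "specimen_id": seq.specimen_id,
                    "taxon": seq.taxon,
                    "eligible": screen.eligible,
                    "reasons": ";".join(screen.reasons),
                    "tentative": "no_clear_min" in screen.warnings,
                }
                if screen.eligible:
                    fit = seqmodel.fit_cosine(seq, model=config.cosine_model, rules=rules)
                    fits[seq.specimen_id] = fit
                    est = seqmodel.estimate_birth_season(
                        fit, bands, tentative="no_clear_min" in screen.warnings
                    )
                    row.update(
                        A=fit.A, X=fit.X, x0=fit.x0, M=fit.M, rmse=fit.rmse,
                        x0_over_X=fit.x0_over_X, angle_deg=est.angle_deg,
                        season_call=est.season_call, converged=fit.converged,
                    )
                rows.append(row)
            fit_table = pd.DataFrame(rows)
            fit_table.to_csv(out / "seasonality_fits.csv", index=False)
            if "angle_deg" in fit_table.columns:
                circular = fit_table.loc[
                    fit_table["converged"].fillna(False).astype(bool),
                    ["specimen_id", "angle_deg", "season_call"],
                ]
                circular.to_csv(out / "circular_plot_data.csv", index=False)
            report["stages"]["seqmodel"] = {
                "n_sequences": len(sequences),
                "n_modelled": len(fits),
            }

            stage = "phase_shift"
            paired = [s for s in seqs.values() if s.d13C is not None and s.specimen_id in fits and len(s) >= 6]
            if paired:
                groups: dict[str, list[seqmodel.ToothSequence]] = {"all": paired}
                if config.phase_group_column is not None:
                    df = pd.read_csv(config.sequences_csv)
                    if config.phase_group_column not in df.columns:
                        raise ValueError(
                            f"phase_group_column {config.phase_group_column!r} "
                            "not found in sequences CSV"
                        )
                    label = df.groupby("specimen_id")[config.phase_group_column].first()
                    groups = {}
                    for s in paired:
                        groups.setdefault(str(label[s.specimen_id]), []).append(s)
                report["stages"]["phase_shift"] = {
                    name: {
                        "phase_shift_deg": ps.phase_shift_deg,
                        "D_mm": ps.D,
                        "n_specimens": ps.n_specimens,
                    }
                    for name, ps in (
                        (name, seqmodel.fit_phase_shift(members))
                        for name, members in sorted(groups.items())
                    )
                }

            stage = "dietmix"
            mix_cfg = dietmix.MixingConfig(**config.mixing)
            diet_rows = []
            for sid, fit in fits.items():
                seq = seqs[sid]
                if seq.d13C is None:
                    continue
                pcts = [dietmix.pct_c4(v, "enamel", mix_cfg).pct_C4 for v in seq.d13C]
                seasonal = dietmix.classify_seasonal_diet(fit, seq.distance_mm, pcts)
                diet_rows.append(
                    {
                        "specimen_id": sid,
                        "winter_pct_c4_mean": seasonal["winter"]["mean"],
                        "summer_pct_c4_mean": seasonal["summer"]["mean"],
                    }
                )
            if diet_rows:
                pd.DataFrame(diet_rows).to_csv(out / "seasonal_diet.csv", index=False)
                report["stages"]["dietmix"] = {"n_specimens": len(diet_rows)}

        if config.collagen_csv is not None:
            stage = "collagen"
            samples = collagen.read_collagen(_require(config.collagen_csv, "collagen"))
            passing = [s for s in samples if s.qc_pass]
            d13 = [s.d13C for s in passing]
            d15 = [s.d15N for s in passing]
            stats_block = {
                "n": len(samples),
                "n_qc_pass": len(passing),
                "d13C": asdict(collagen.summarize(d13)),
                "d15N": asdict(collagen.summarize(d15)),
                "cn_max": max(s.cn_atomic for s in samples),
                "cn_min": min(s.cn_atomic for s in samples),
            }
            if len(passing) >= 3:
                corr = collagen.correlate(d13, d15)
                stats_block["pearson_r"] = corr.pearson_r
                stats_block["pearson_p"] = corr.pearson_p
                stats_block["spearman_rho"] = corr.spearman_rho
                stats_block["spearman_p"] = corr.spearman_p
            pd.DataFrame([dataclasses.asdict(s) for s in samples]).to_csv(
                out / "collagen_qc.csv", index=False
            )
            report["stages"]["collagen"] = stats_block

        if config.mortality_csv is not None:
            stage = "herdprof"
            counts = herdprof.read_mortality_counts(_require(config.mortality_csv, "mortality"))
            profile = herdprof.dirichlet_profile(
                counts,
                prior=config.dirichlet_prior,
                n_draws=config.dirichlet_draws,
                seed=config.seed,
            )
            profile.as_frame().to_csv(out / "mortality_profile.csv", index=False)
            report["stages"]["herdprof"] = {
                "n_total": counts.n_total,
                "classes_present": [
                    l for l, c in zip(counts.labels, counts.counts) if c > 0
                ],
            }
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        report["failed_stage"] = stage
        report["error"] = str(exc)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        raise

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
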