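"""End-to-end runs: simulate a cohort, score it, run the association battery
and the polychoric EFA, and render a report.

Everything is driven by a :class:`RunConfig` that round-trips through YAML;
each run writes its resolved configuration (plus seed, config hash and
package version) next to its outputs so any report can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import spearman_ci, tertile_summary
from .efa import FactorSolution, fit_efa, mask_loadings, polychoric_matrix, variance_explained
from .generator import (
    CalibrationResult,
    CalibrationTargets,
    GeneratorProfile,
    calibrate_profile,
    generate_cohort,
)
from .scoring import LevelBounds, ScoringScheme, item_columns, score_cohort

__all__ = ["RunConfig", "AnalysisReport", "run_simulate", "run_analyze", "render_report"]


@dataclass
class RunConfig:
    """Resolved settings for a pipeline run."""

    seed: int = 0
    n: int = 293
    calibration_n: int = 100_000
    scheme_points: dict = field(default_factory=lambda: dict(ScoringScheme().points))
    level_bounds: dict = field(default_factory=lambda: {"low_max": 0, "moderate_max": 3})
    #: outcome column -> 'binary' | 'continuous'; empty = auto-detect
    outcome_types: dict = field(default_factory=dict)
    #: family name -> list of outcome columns sharing one Sidak family
    correlation_families: dict = field(default_factory=dict)
    confidence_level: float = 0.95
    efa_power: int = 4
    efa_mask_threshold: float = 0.50
    tetrachoric_cap: float = 0.999
    score_col: str = "scpi"
    exclude_columns: tuple = ("id", "scpi", "scpi_level", "scpi_complete",
                              "scpi_none_endorsed")

    @property
    def scheme(self) -> ScoringScheme:
        return ScoringScheme(self.scheme_points)

    @property
    def bounds(self) -> LevelBounds:
        return LevelBounds(**self.level_bounds)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "exclude_columns" in data:
            data["exclude_columns"] = tuple(data["exclude_columns"])
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class AnalysisReport:
    config: RunConfig
    scored: pd.DataFrame
    cohort_summary: dict
    table3: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    efa: FactorSolution | None = None
    efa_variance: dict | None = None
    polychoric: pd.DataFrame | None = None
    errors: dict = field(default_factory=dict)

    @property
    def provenance(self) -> dict:
        return {
            "seed": self.config.seed,
            "config_hash": self.config.digest(),
            "version": __version__,
        }


def run_simulate(
    config: RunConfig,
    profile: GeneratorProfile | None = None,
    targets: CalibrationTargets | None = None,
    out_path: str | Path | None = None,
) -> tuple[pd.DataFrame, GeneratorProfile, CalibrationResult | None]:
    """Calibrate (unless a calibrated profile is supplied) and generate.

    The calibration and generation streams are split deterministically from
    ``config.seed``, so (config, seed) fully determines the CSV.
    """
    cal = None
    if profile is None or not profile.is_calibrated():
        profile, cal = calibrate_profile(
            profile, targets, n=config.calibration_n, seed=config.seed
        )
        if not cal.converged:
            raise RuntimeError("calibration failed:\n" + cal.report())
    gen_seed = int(np.random.SeedSequence(config.seed).generate_state(2)[1] % (2**31))
    cohort = generate_cohort(profile, config.n, seed=gen_seed)
    if out_path is not None:
        cohort.to_csv(out_path, index=False)
    return cohort, profile, cal


def _load_cohort(cohort: pd.DataFrame | str | Path) -> pd.DataFrame:
    if isinstance(cohort, (str, Path)):
        df = pd.read_csv(cohort)
        missing = [c for c in item_columns() if c not in df.columns]
        if missing:
            raise ValueError(
                f"{cohort}: not a cohort CSV, missing item column(s) {missing}"
            )
        return df
    return cohort.copy()


def run_analyze(cohort: pd.DataFrame | str | Path, config: RunConfig) -> AnalysisReport:
    """Score the cohort, then run the three analysis stages.

    A stage that fails (e.g. a degenerate EFA input) is recorded in
    ``report.errors`` and the remaining stages still run.
    """
    df = _load_cohort(cohort)
    scheme, bounds = config.scheme, config.bounds
    scored = score_cohort(df, scheme, bounds)
    complete = scored[scored["scpi_complete"]]
    scores = complete[config.score_col].astype(float)
    summary = {
        "n": int(len(scored)),
        "n_complete": int(len(complete)),
        "n_none_endorsed": int(scored["scpi_none_endorsed"].sum()),
        "scpi_mean": float(scores.mean()),
        "scpi_sd": float(scores.std(ddof=1)),
        "level_counts": {
            lv: int((complete["scpi_level"] == lv).sum())
            for lv in ("low", "moderate", "high")
        },
    }
    report = AnalysisReport(config, scored, summary)

    outcome_cols = [
        c for c in df.columns
        if c not in config.exclude_columns and not c.startswith("item_")
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    if config.outcome_types:
        outcomes: dict | list = dict(config.outcome_types)
    else:
        outcomes = outcome_cols

    try:
        report.table3 = tertile_summary(complete, outcomes)
    except Exception as exc:  # degraded but keep going
        report.errors["tertile_summary"] = str(exc)

    try:
        fam_of = {}
        for fam, cols in config.correlation_families.items():
            for c in cols:
                fam_of[c] = len(cols)
        rows = []
        for col in outcome_cols:
            m = fam_of.get(col, 1)
            try:
                res = spearman_ci(
                    scores, complete[col].astype(float),
                    level=config.confidence_level, m=m,
                )
                rows.append({
                    "outcome": col, "r": res.r, "n": res.n,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "m": m, "level_per_comparison": res.level_per_comparison,
                    "p": res.p_value, "p_sidak": res.p_adjusted,
                    "undefined": res.undefined,
                })
            except ValueError as exc:
                rows.append({"outcome": col, "r": np.nan, "n": len(complete),
                             "undefined": True, "note": str(exc)})
        report.correlations = pd.DataFrame(rows)
    except Exception as exc:
        report.errors["correlations"] = str(exc)

    try:
        items = complete[item_columns()]
        pm = polychoric_matrix(items, cap=config.tetrachoric_cap)
        sol = fit_efa(pm, promax_power=config.efa_power)
        report.efa = sol
        report.efa_variance = variance_explained(sol)
        report.polychoric = pd.DataFrame(
            pm.rho, index=pm.item_names, columns=pm.item_names
        )
    except Exception as exc:
        report.errors["efa"] = str(exc)

    return report


def _fmt_table3(t3: pd.DataFrame) -> str:
    lines = []
    for _, row in t3.iterrows():
        cells = [f"{row['outcome']:<24s}"]
        for lv in ("low", "moderate", "high"):
            if row["type"] == "binary":
                cells.append(f"{row[f'stat_{lv}']:>5.0f} ({row[f'pct_{lv}']:.1f}%)")
            else:
                cells.append(f"{row[f'mean_{lv}']:>7.2f} ({row[f'sd_{lv}']:.2f})")
        p = row["trend_p"]
        cells.append("p<0.001" if p < 0.001 else f"p={p:.3f}")
        lines.append("  ".join(cells))
    return "\n".join(lines)


def render_report(
    report: AnalysisReport,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("txt", "csv"),
) -> list[Path]:
    """Write the report: plain-text summary plus machine-readable tables.

    Display tables round the way the index is reported (scores integer,
    correlations 2 dp, percentages 1 dp) and apply the loading mask; the CSV
    outputs keep full precision and the unmasked pattern matrix.
    """
    unknown = set(formats) - {"txt", "csv"}
    if unknown:
        raise ValueError(f"unknown report format(s): {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        if "csv" in formats and df is not None:
            p = out / name
            df.to_csv(p, index=index)
            written.append(p)

    save_csv(report.scored, "scored_cohort.csv")
    if report.table3 is not None:
        save_csv(report.table3, "tertile_summary.csv")
    if report.correlations is not None:
        save_csv(report.correlations, "correlations.csv")
    if report.efa is not None:
        sol = report.efa
        k = sol.n_factors
        cols = [f"factor_{i+1}" for i in range(k)]
        save_csv(pd.DataFrame(sol.pattern, index=sol.item_names, columns=cols),
                 "efa_pattern.csv", index=True)
        save_csv(pd.DataFrame(sol.phi, columns=cols, index=cols),
                 "efa_factor_corr.csv", index=True)
        save_csv(sol.scree, "efa_scree.csv")
        save_csv(report.polychoric, "polychoric.csv", index=True)

    if "txt" in formats:
        s = report.cohort_summary
        lines = [
            "SCPI analysis report",
            "====================",
            f"seed={report.provenance['seed']}  config={report.provenance['config_hash']}"
            f"  version={report.provenance['version']}",
            "",
            f"cohort: n={s['n']} ({s['n_complete']} complete, "
            f"{s['n_none_endorsed']} with no option endorsed)",
            f"SCPI mean (SD): {s['scpi_mean']:.2f} ({s['scpi_sd']:.2f})",
            "levels: " + ", ".join(
                f"{lv} {cnt} ({100 * cnt / max(s['n_complete'], 1):.1f}%)"
                for lv, cnt in s["level_counts"].items()
            ),
            "",
        ]
        if report.table3 is not None:
            lines += ["Outcomes by preparedness level (trend p-values)",
                      "-" * 48, _fmt_table3(report.table3), ""]
        if report.correlations is not None:
            lines += ["Spearman correlations with SCPI", "-" * 48]
            for _, r in report.correlations.iterrows():
                if r.get("undefined", False):
                    lines.append(f"{r['outcome']:<24s} undefined (constant input)")
                else:
                    lines.append(
                        f"{r['outcome']:<24s} r={r['r']:+.2f} "
                        f"[{r['ci_low']:+.2f}, {r['ci_high']:+.2f}] "
                        f"(m={r['m']:.0f}, p_sidak={r['p_sidak']:.3g})"
                    )
            lines.append("")
        if report.efa is not None:
            sol = report.efa
            masked = mask_loadings(
                sol.pattern, report.config.efa_mask_threshold, sol.item_names
            )
            lines += [
                f"Polychoric EFA: {sol.n_factors} factor(s) retained (Kaiser)",
                "-" * 48,
                f"eigenvalues: {np.array2string(sol.eigenvalues, precision=2)}",
                f"pattern matrix (|loading| < "
                f"{report.config.efa_mask_threshold} masked):",
                masked.to_string(),
                "variance explained: " + ", ".join(
                    f"{k}={v:.1%}" for k, v in report.efa_variance.items()),
                "",
            ]
        if report.errors:
            lines += ["Stage failures", "-" * 48] + [
                f"{k}: {v}" for k, v in report.errors.items()
            ]
        p = out / "report.txt"
        p.write_text("\n".join(lines))
        written.append(p)

    cfg = out / "resolved_config.yaml"
    report.config.to_yaml(cfg)
    written.append(cfg)
    return written
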