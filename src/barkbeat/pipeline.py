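"""End-to-end orchestration: read -> metrics -> compare -> report/plots.

A run either loads annotated bouts (Raven selection tables or event CSVs
plus a manifest) or simulates a study from the presets, then writes:

* ``metrics.csv``       one row per bout, the canonical intermediate
* ``elements.csv``      per-element beat-precision values
* ``comparison.csv``    per-index group comparison (Table-style layout)
* ``lm_rate.csv`` / ``lmm_duration.csv``  regression coefficient tables
* ``report.txt``        human-readable summary (every number also lives
                        in a machine-readable CSV)
* ``raster.png``        event raster, one row per bout
* ``run_manifest.yaml`` config hash, seed, software version, exclusions

Bouts with fewer than three events are excluded with a logged reason;
off-grid intervals found during silent-beat detection are logged too.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_events import BarkBout, load_study
from .metrics import (
    DEFAULT_SILENT_BEAT_TOL,
    InsufficientEventsError,
    RhythmSummary,
    compute_iois,
    detect_silent_beats,
    estimate_beat_period,
    per_element_table,
    summarize_bout,
)
from .simulate import SimConfig, preset_config, simulate_study, write_study
from .stats import (
    compare_element_level,
    compare_groups,
    lm_beat_precision_on_rate,
    lmm_beat_precision_on_duration,
)

logger = logging.getLogger("barkbeat")


@dataclass
class RunConfig:
    """Configuration for one analysis run."""

    input_dir: str | None = None
    manifest: str | None = None
    simulate: bool = False
    n_per_class: int = 17
    adult_config: SimConfig = field(default_factory=lambda: preset_config("adult"))
    pup_config: SimConfig = field(default_factory=lambda: preset_config("pup"))
    bp_normalization: str = "half-period"
    include_first: bool = True
    silent_beat_tol: float = DEFAULT_SILENT_BEAT_TOL
    min_events: int = 3
    out_dir: str = "barkbeat_out"
    seed: int = 0
    convention_sweep: bool = False

    def validate(self) -> None:
        has_input = self.input_dir is not None
        if has_input == self.simulate:
            raise ValueError(
                "exactly one of input_dir / simulate must be set"
            )
        if has_input and self.manifest is None:
            raise ValueError("input_dir requires a manifest")
        if not (0 < self.silent_beat_tol < 0.5):
            raise ValueError("silent_beat_tol must lie in (0, 0.5)")
        if self.bp_normalization not in ("half-period", "period"):
            raise ValueError("bp_normalization must be half-period or period")


def summarize_study(
    bouts: list[BarkBout],
    include_first: bool = True,
    bp_normalization: str = "half-period",
    silent_beat_tol: float = DEFAULT_SILENT_BEAT_TOL,
    min_events: int = 3,
) -> tuple[list[RhythmSummary], list[tuple[str, str]]]:
    """Summaries for every includable bout plus (bout_id, reason) exclusions."""
    summaries, excluded = [], []
    for bout in bouts:
        if bout.n_events < min_events:
            reason = f"{bout.n_events} events < minimum {min_events}"
            logger.warning("excluding bout %s: %s", bout.bout_id, reason)
            excluded.append((str(bout.bout_id), reason))
            continue
        summaries.append(
            summarize_bout(
                bout,
                include_first=include_first,
                bp_normalization=bp_normalization,
                silent_beat_tol=silent_beat_tol,
            )
        )
        # audit trail: off-grid intervals
        iois = compute_iois(bout)
        T = estimate_beat_period(iois, tol=silent_beat_tol)
        _, mult = detect_silent_beats(iois, T, tol=silent_beat_tol)
        for i, m in enumerate(mult):
            if m is None:
                logger.info(
                    "bout %s: interval %d (%.3f s) off-grid for period %.3f s",
                    bout.bout_id, i, iois.iois[i], T,
                )
    return summaries, excluded


def plot_event_raster(bouts: list[BarkBout], path: str | Path) -> None:
    """One row per bout, a tick at each onset re-zeroed to the first onset."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not bouts:
        raise ValueError("need at least one bout to plot")
    fig, ax = plt.subplots(figsize=(8, 0.25 * len(bouts) + 1.5))
    colors = {"adult": "firebrick", "pup": "steelblue", None: "gray"}
    for row, bout in enumerate(bouts):
        t0 = bout.onsets[0]
        xs = [o - t0 for o in bout.onsets]
        ax.scatter(
            xs,
            [row] * len(xs),
            marker="|",
            s=120,
            color=colors.get(bout.age_class, "gray"),
        )
    ax.set_yticks(range(len(bouts)))
    ax.set_yticklabels([b.bout_id or str(i) for i, b in enumerate(bouts)], fontsize=6)
    ax.set_xlabel("time from first bark (s)")
    ax.set_ylabel("bout")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _fmt_model(name: str, fit) -> str:
    lines = [name, "-" * len(name)]
    for term, row in fit.terms.iterrows():
        lines.append(
            f"  {term:<12} estimate {row['estimate']:.3f}  SE {row['se']:.3f}  "
            f"t {row['t']:.3f}  p {row['p']:.3g}"
        )
    q = fit.residual_quantiles
    lines.append(
        f"  scaled residuals: min {q[0]:.3f}  1Q {q[1]:.3f}  median {q[2]:.3f}  "
        f"3Q {q[3]:.3f}  max {q[4]:.3f}"
    )
    lines.append(f"  p-values: {fit.p_value_method}")
    if fit.random_effect:
        lines.append(f"  random intercept: {fit.random_effect}"
                     + ("  [singular fit]" if fit.singular else ""))
    return "\n".join(lines)


def run_analysis(config: RunConfig) -> dict:
    """Execute a full run; returns the result bundle as a dict of frames."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        sims, manifest = simulate_study(
            config.adult_config, config.pup_config, config.n_per_class, config.seed
        )
        bouts = [s.bout for s in sims]
        write_study(sims, manifest, out / "simulated_input")
    else:
        bouts = load_study(config.input_dir, config.manifest)
    if not bouts:
        raise ValueError("no bouts to analyse")

    summaries, excluded = summarize_study(
        bouts,
        include_first=config.include_first,
        bp_normalization=config.bp_normalization,
        silent_beat_tol=config.silent_beat_tol,
        min_events=config.min_events,
    )
    if not summaries:
        raise ValueError("all bouts excluded; nothing to analyse")
    included_ids = {s.bout_id for s in summaries}
    kept_bouts = [b for b in bouts if b.bout_id in included_ids]

    metrics_df = pd.DataFrame([s.as_dict() for s in summaries])
    metrics_df.to_csv(out / "metrics.csv", index=False)

    elements = []
    for bout in kept_bouts:
        elements.extend(per_element_table(bout, normalization=config.bp_normalization))
    elements_df = pd.DataFrame(elements)
    elements_df.to_csv(out / "elements.csv", index=False)

    classes = {s.age_class for s in summaries}
    bundle = {"metrics": metrics_df, "elements": elements_df}

    if classes >= {"adult", "pup"}:
        by_class = {
            cls: [b for b, s in zip(kept_bouts, summaries) if s.age_class == cls]
            for cls in ("adult", "pup")
        }
        comparison = pd.concat(
            [compare_element_level(by_class), compare_groups(summaries)],
            ignore_index=True,
        )
        comparison.to_csv(out / "comparison.csv", index=False)
        bundle["comparison"] = comparison

        lm = lm_beat_precision_on_rate(summaries)
        lm.terms.to_csv(out / "lm_rate.csv")
        lmm = lmm_beat_precision_on_duration(summaries)
        lmm.terms.to_csv(out / "lmm_duration.csv")
        bundle["lm_rate"] = lm
        bundle["lmm_duration"] = lmm
    else:
        lm = lmm = None

    plot_event_raster(kept_bouts, out / "raster.png")

    # per-class mean table (the headline summary), full precision in CSV
    if "comparison" in bundle:
        per_class = (
            metrics_df.groupby("age_class")[
                [
                    "mean_ioi", "mean_integer_ratio", "unbiased_cv", "npvi_ioi",
                    "beat_hz", "mean_beat_precision", "cv_beat_precision",
                    "npvi_beat_precision", "n_silent_beats", "mean_bark_duration",
                ]
            ]
            .mean()
        )
        per_class.to_csv(out / "per_class_means.csv")
        bundle["per_class_means"] = per_class

    if config.convention_sweep:
        sweep_rows = []
        for inc_first in (True, False):
            for norm in ("half-period", "period"):
                s2, _ = summarize_study(
                    bouts, include_first=inc_first, bp_normalization=norm,
                    silent_beat_tol=config.silent_beat_tol,
                    min_events=config.min_events,
                )
                df2 = pd.DataFrame([s.as_dict() for s in s2])
                for cls, grp in df2.groupby("age_class"):
                    sweep_rows.append(
                        {
                            "include_first": inc_first,
                            "bp_normalization": norm,
                            "age_class": cls,
                            "mean_beat_precision": grp["mean_beat_precision"].mean(),
                            "cv_beat_precision": grp["cv_beat_precision"].mean(),
                            "npvi_beat_precision": grp["npvi_beat_precision"].mean(),
                        }
                    )
        sweep = pd.DataFrame(sweep_rows)
        sweep.to_csv(out / "convention_sweep.csv", index=False)
        bundle["convention_sweep"] = sweep

    report_lines = [
        f"barkbeat {__version__} analysis report",
        f"bouts analysed: {len(summaries)} (excluded: {len(excluded)})",
        "",
        "Per-class means (2 decimals; full precision in per_class_means.csv):",
    ]
    if "per_class_means" in bundle:
        report_lines.append(bundle["per_class_means"].round(2).to_string())
        report_lines += ["", "Group comparison (comparison.csv):"]
        report_lines.append(bundle["comparison"].round(3).to_string(index=False))
        report_lines += ["", _fmt_model("LM: beat precision ~ beat (Hz)", lm)]
        report_lines += ["", _fmt_model(
            "LMM: beat precision ~ mean bark duration + (1 | age class)", lmm
        )]
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")

    run_manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "excluded_bouts": [{"bout_id": b, "reason": r} for b, r in excluded],
        "bp_normalization": config.bp_normalization,
        "include_first": config.include_first,
        "silent_beat_tol": config.silent_beat_tol,
    }
    (out / "run_manifest.yaml").write_text(yaml.safe_dump(run_manifest))
    bundle["excluded"] = excluded
    return bundle
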