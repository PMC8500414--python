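"""End-to-end pipeline: simulate -> preprocess -> measure -> analyze -> report.

Everything is driven by a :class:`PipelineConfig` that round-trips
losslessly through YAML; every output directory receives a manifest
carrying the configuration hash, and CSV outputs carry the hash as a
leading comment line, so a run is fully reproducible from
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .paradigm import SessionPlan, generate_session, validate_balance
from .synthetic_eeg import (
    EpochSet,
    GenerativeConfig,
    config_hash,
    simulate_subject,
)
from .preprocessing import (
    FilterSpec,
    RejectionSpec,
    SubjectAverages,
    preprocess_subject,
)
from .erp_measures import (
    MeasureWindows,
    component_table,
    measure_cell_matrix,
    pooled_condition_wave,
    subject_diff_wave,
)
from .stats import (
    ClusterPermutationTest,
    RepeatedMeasures2x2,
    CONDITION_ORDER,
)

ANALYSIS_WINDOW_MS = (-100.0, 500.0)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


@dataclass
class PipelineConfig:
    """Complete run description: generator, preprocessing, measures, stats."""

    seed: int = 0
    generative: GenerativeConfig = field(default_factory=GenerativeConfig)
    filter: FilterSpec | None = field(default_factory=FilterSpec)
    rejection: RejectionSpec | None = field(default_factory=RejectionSpec)
    windows: MeasureWindows = field(default_factory=MeasureWindows)
    alpha: float = 0.05
    n_perm: int = 10_000
    red_dot_hit_rate: float = 0.984   # simulated vigilance accuracy
    accuracy_gate: float = 0.90       # subjects below this are excluded
    write_epochs: bool = False        # epoch CSVs are bulky; opt in

    def __post_init__(self) -> None:
        if self.generative.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generative"]["seed"] = self.seed  # single seed governs the run
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.pop("generative", {})
        filt = d.pop("filter", "default")
        rej = d.pop("rejection", "default")
        win = d.pop("windows", {})
        cfg = cls(
            generative=GenerativeConfig(**gen),
            filter=(
                FilterSpec() if filt == "default"
                else None if filt is None
                else FilterSpec(**filt)
            ),
            rejection=(
                RejectionSpec() if rej == "default"
                else None if rej is None
                else RejectionSpec(**rej)
            ),
            windows=MeasureWindows(
                **{k: tuple(v) for k, v in win.items()}
            ) if win else MeasureWindows(),
            **d,
        )
        return cfg

    def to_yaml(self, path=None) -> str | None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is None:
            return text
        Path(path).write_text(text)
        return None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def hash(self) -> str:
        gen = dataclasses.replace(self.generative, seed=self.seed)
        return config_hash(gen)


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_csv(path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the config-hash comment line."""
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# stages

def simulate_stage(
    config: PipelineConfig, plan: SessionPlan
) -> tuple[list[EpochSet], pd.DataFrame]:
    """Simulate every subject plus their red-dot vigilance accuracy.

    Subjects must respond to more than ``accuracy_gate`` of red-dot
    sequences to enter the analysis (mirroring the behavioural inclusion
    rule); hits are Bernoulli draws at ``red_dot_hit_rate``.
    """
    gen = dataclasses.replace(config.generative, seed=config.seed)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 987_654]))
    n_dots = sum(1 for s in plan.sequences if s.is_red_dot)
    subjects, rows = [], []
    for s in range(1, gen.n_subjects + 1):
        es = simulate_subject(gen, plan, subject_seed=s)
        hits = int(rng.binomial(n_dots, config.red_dot_hit_rate)) if n_dots else 0
        acc = hits / n_dots if n_dots else 1.0
        included = acc > config.accuracy_gate
        rows.append(
            dict(subject=es.subject_id, red_dot_sequences=n_dots,
                 hits=hits, accuracy=acc, included=included)
        )
        if included:
            subjects.append(es)
    behaviour = pd.DataFrame(rows)
    if not subjects:
        raise StageError("simulate: no subject passed the red-dot accuracy gate")
    return subjects, behaviour


def preprocess_stage(
    config: PipelineConfig, subjects: list[EpochSet]
) -> tuple[list[SubjectAverages], pd.DataFrame]:
    averages, rows = [], []
    for es in subjects:
        avg, log = preprocess_subject(es, config.filter, config.rejection)
        averages.append(avg)
        rows.append(
            dict(subject=es.subject_id, n_input=log.n_input,
                 n_rejected=log.n_rejected, n_kept=log.n_kept)
        )
    return averages, pd.DataFrame(rows)


def expectation_diff_waves(
    averages: list[SubjectAverages], window_ms: tuple = ANALYSIS_WINDOW_MS
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (unpredictable - predictable) N2pc subtraction waveforms
    restricted to the analysis window. Returns (waves, times)."""
    return _contrast_diff_waves(
        averages,
        plus=("unpredictable_cued", "unpredictable_noncued"),
        minus=("predictable_cued", "predictable_noncued"),
        window_ms=window_ms,
    )


def cueing_diff_waves(
    averages: list[SubjectAverages], window_ms: tuple = ANALYSIS_WINDOW_MS
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (cued - non-cued) N2pc subtraction waveforms."""
    return _contrast_diff_waves(
        averages,
        plus=("predictable_cued", "unpredictable_cued"),
        minus=("predictable_noncued", "unpredictable_noncued"),
        window_ms=window_ms,
    )


def _contrast_diff_waves(averages, plus, minus, window_ms):
    t = averages[0].time_ms
    lo, hi = window_ms
    sel = (t >= lo) & (t <= hi)
    waves = []
    for avg in averages:
        p = np.mean(
            [subject_diff_wave(avg, c).amplitude_uv for c in plus], axis=0
        )
        m = np.mean(
            [subject_diff_wave(avg, c).amplitude_uv for c in minus], axis=0
        )
        waves.append((p - m)[sel])
    return np.asarray(waves), t[sel]


def analyze_stage(
    config: PipelineConfig,
    averages: list[SubjectAverages],
    measures: pd.DataFrame,
) -> dict:
    """Both omnibus ANOVAs plus both cluster permutation contrasts."""
    out = {}
    for name, measure in (("n170", "n170_p2p"), ("n2pc", "n2pc_mean")):
        res = RepeatedMeasures2x2(measure_cell_matrix(measures, measure)).fit()
        out[f"anova_{name}"] = res
    for name, fn in (
        ("expectation", expectation_diff_waves),
        ("cueing", cueing_diff_waves),
    ):
        waves, times = fn(averages)
        res = ClusterPermutationTest(
            waves, times, alpha=config.alpha, n_perm=config.n_perm
        ).fit(seed=config.seed)
        out[f"cluster_{name}"] = res
    return out


# ---------------------------------------------------------------------------
# serialisation of results

def anova_to_dict(res) -> dict:
    return {
        "anova_table": res.anova_table.reset_index().to_dict(orient="records"),
        "cell_means": {k: float(v) for k, v in res.cell_means.items()},
        "cell_sems": {k: float(v) for k, v in res.cell_sems.items()},
        "marginal_means": res.marginal_means,
        "cm_ci_halfwidth": {
            k: float(v) for k, v in res.cousineau_morey_ci().items()
        },
        "n_subjects": res.n_subjects,
    }


def cluster_to_dict(res) -> dict:
    return {
        "height_threshold": float(res.height_threshold),
        "percentile_95": float(res.percentile_95),
        "n_subjects": res.n_subjects,
        "n_perm": int(res.n_perm),
        "alpha": res.alpha,
        "clusters": res.clusters.to_dict(orient="records"),
        "any_significant": res.any_significant,
    }


# ---------------------------------------------------------------------------
# report

def write_report(
    results: dict, out_dir: Path, cfg_hash: str, with_figures: bool = True
) -> Path:
    """Markdown summary with condition means +- Cousineau-Morey CIs, the
    cluster tables, and (optionally) deterministic figures."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = [
        "# Trajectory-ERP analysis report",
        "",
        f"config hash: `{cfg_hash}`",
        "",
    ]
    for comp in ("n170", "n2pc"):
        key = f"anova_{comp}"
        if key not in results:
            raise StageError(f"report: missing input {key}")
        res = results[key]
        label = "peak-to-peak N170" if comp == "n170" else "N2pc mean amplitude"
        lines += [f"## {label}: repeated-measures ANOVA", "", "```",
                  res.summary(), "```", ""]
    for contrast in ("expectation", "cueing"):
        key = f"cluster_{contrast}"
        if key not in results:
            raise StageError(f"report: missing input {key}")
        res = results[key]
        lines += [f"## Cluster permutation: {contrast} contrast", "", "```"]
        if len(res.clusters) == 0:
            lines += [res.summary(), "",
                      "no clusters exceeded threshold"]
        else:
            lines.append(res.summary())
        lines += ["```", ""]
    if with_figures:
        figs = plot_results(results, out_dir)
        lines += ["## Figures", ""]
        lines += [f"![{p.stem}]({p.name})" for p in figs]
    path = out_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path


def plot_results(results: dict, out_dir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    paths = []
    # bar charts of cell means with within-subject CIs
    for comp, ylabel in (
        ("n170", "peak-to-peak N170 (uV)"),
        ("n2pc", "N2pc mean amplitude (uV)"),
    ):
        res = results[f"anova_{comp}"]
        ci = res.cousineau_morey_ci()
        fig, ax = plt.subplots(figsize=(5, 3.2))
        xs = np.arange(len(CONDITION_ORDER))
        ax.bar(
            xs,
            [res.cell_means[c] for c in CONDITION_ORDER],
            yerr=[ci[c] for c in CONDITION_ORDER],
            capsize=4,
            color="0.6",
        )
        ax.set_xticks(xs)
        ax.set_xticklabels(
            [c.replace("_", "\n") for c in CONDITION_ORDER], fontsize=8
        )
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        p = out_dir / f"cell_means_{comp}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    # t-series with cluster shading
    for contrast in ("expectation", "cueing"):
        res = results[f"cluster_{contrast}"]
        fig, ax = plt.subplots(figsize=(6, 3.2))
        ax.plot(res.times_ms, res.t_series, color="k", lw=1)
        ax.axhline(res.height_threshold, color="r", ls="--", lw=0.8)
        ax.axhline(-res.height_threshold, color="r", ls="--", lw=0.8)
        for _, row in res.clusters.iterrows():
            ax.axvspan(
                row["start_ms"], row["end_ms"],
                color="0.8" if not row["significant"] else "0.6",
            )
        ax.set_xlim(res.times_ms[0], res.times_ms[-1])
        ax.set_xlabel("time (ms, final stimulus onset = 0)")
        ax.set_ylabel("t")
        ax.set_title(f"{contrast} contrast")
        fig.tight_layout()
        p = out_dir / f"t_series_{contrast}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# the orchestrator

def run_pipeline(config: PipelineConfig, out_dir, with_figures: bool = True) -> dict:
    """Run every stage and write the report bundle into ``out_dir``.

    Outputs: ``plan.json``, optional epoch CSVs, ``averages.csv``,
    ``measures.csv``, ``anova_*.json``, ``cluster_*.json``, ``report.md``
    and figure PNGs, plus ``run_manifest.json`` with the config hash.
    Stage failures raise :class:`StageError` naming the stage; outputs
    written before the failure are retained.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash
    config.to_yaml(out_dir / "config.yaml")

    def run(stage, fn, *args):
        try:
            return fn(*args)
        except StageError:
            raise
        except Exception as err:
            raise StageError(f"{stage}: {err}") from err

    gen = dataclasses.replace(config.generative, seed=config.seed)
    plan = run(
        "paradigm",
        lambda: generate_session(
            per_condition=gen.trials_per_condition,
            red_dot_total=gen.red_dot_total,
            seed=config.seed,
        ),
    )
    plan.to_json(out_dir / "plan.json")
    balance = validate_balance(plan)

    subjects, behaviour = run("simulate", simulate_stage, config, plan)
    _write_csv(behaviour, out_dir / "behaviour.csv", cfg_hash)
    if config.write_epochs:
        for es in subjects:
            es.save(out_dir / "epochs")

    averages, rejection = run("preprocess", preprocess_stage, config, subjects)
    _write_csv(rejection, out_dir / "rejection_log.csv", cfg_hash)
    avg_frame = pd.concat([a.to_frame() for a in averages], ignore_index=True)
    _write_csv(avg_frame, out_dir / "averages.csv", cfg_hash)

    measures = run("measure", component_table, averages, config.windows)
    _write_csv(measures, out_dir / "measures.csv", cfg_hash)

    results = run("analyze", analyze_stage, config, averages, measures)
    for comp in ("n170", "n2pc"):
        with open(out_dir / f"anova_{comp}.json", "w") as fh:
            json.dump(
                {"config_hash": cfg_hash, **anova_to_dict(results[f"anova_{comp}"])},
                fh, indent=1,
            )
    for contrast in ("expectation", "cueing"):
        with open(out_dir / f"cluster_{contrast}.json", "w") as fh:
            json.dump(
                {"config_hash": cfg_hash,
                 **cluster_to_dict(results[f"cluster_{contrast}"])},
                fh, indent=1,
            )

    run("report", write_report, results, out_dir, cfg_hash, with_figures)

    manifest = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "n_subjects_included": len(subjects),
        "balance_flags": balance.flags,
        "epochs_rejected": int(rejection["n_rejected"].sum()),
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    results["plan"] = plan
    results["behaviour"] = behaviour
    results["rejection"] = rejection
    results["measures"] = measures
    results["averages"] = averages
    results["manifest"] = manifest
    return results
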