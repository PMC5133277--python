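"""End-to-end orchestration: simulate -> preprocess -> measure -> fit -> report.

A :class:`RunConfig` captures every knob of a run (design sizes, screen
geometry, generator coefficients, filter settings, models to fit) plus one
root seed; :func:`run_pipeline` executes all stages into an output
directory and returns a :class:`RunManifest` with content hashes of every
artifact, so that determinism is a checkable statement: identical config and
seed reproduce identical hashes for every deterministic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import design, io, measures
from .contrasts import TERM_NAMES
from .inference import fit_accuracy_glmm, fit_gca, fit_lmm_maximal, FitResult, GCASpec
from .preprocess import angle_profiles, preprocess_trials
from .simulate import ScreenGeometry, SimulationParams, simulate_experiment

logger = logging.getLogger(__name__)

#: Gaussian measures fit by default, keyed by their column in the measure table.
DEFAULT_FIT_MEASURES = ("rt_s", "initial_degree", "latency_s", "xflips", "auc")


@dataclass(frozen=True)
class DesignConfig:
    n_scenes: int = 225
    n_lists: int = 4
    n_participants: int = 64
    per_participant: int = 100


@dataclass(frozen=True)
class FilterConfig:
    k_sd: float = 4.0
    jitter_px: float = 3.0
    n_bins: int = 101


@dataclass(frozen=True)
class ModelConfig:
    measures: tuple[str, ...] = DEFAULT_FIT_MEASURES
    accuracy: bool = True
    accuracy_random: str = "intercepts"
    gca: bool = False
    gca_poly_order: int = 3
    df_policy: str = "normal"


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    seed: int = 1
    design: DesignConfig = field(default_factory=DesignConfig)
    geometry: dict = field(default_factory=dict)  # ScreenGeometry overrides
    params: dict = field(default_factory=dict)  # SimulationParams overrides
    filter: FilterConfig = field(default_factory=FilterConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def screen_geometry(self) -> ScreenGeometry:
        geo = dict(self.geometry)
        for key in ("start", "yes_pos", "no_pos"):
            if key in geo:
                geo[key] = tuple(geo[key])
        return ScreenGeometry(**geo)

    def simulation_params(self) -> SimulationParams:
        par = dict(self.params)
        for key in ("beta_conflict", "beta_accuracy", "beta_rt_s"):
            if key in par:
                par[key] = tuple(par[key])
        return SimulationParams(**par)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"]["measures"] = list(self.model.measures)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = DesignConfig(**d["design"])
        if "filter" in d:
            d["filter"] = FilterConfig(**d["filter"])
        if "model" in d:
            m = dict(d["model"])
            if "measures" in m:
                m["measures"] = tuple(m["measures"])
            d["model"] = ModelConfig(**m)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io.load_yaml(path))

    def to_yaml(self, path) -> Path:
        return io.dump_yaml(self.to_dict(), path)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def file_sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record of a pipeline run: config hash, file hashes, counts."""

    config_sha256: str
    files: dict
    versions: dict
    timestamps: dict
    filter_report: dict
    stages: list

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --------------------------------------------------------------------------
# table rendering

_CELL_ORDER = [
    (o, c, p)
    for o in ("sentence_first", "scene_first")
    for c in ("congruent", "incongruent")
    for p in ("plausible", "implausible")
]

_MEASURE_LABELS = {
    "accuracy": "Accuracy (%)",
    "rt_s": "Response time (second)",
    "initial_degree": "Initial degree (degree)",
    "latency_s": "Latency (second)",
    "xflips": "X-flips (count)",
    "auc": "Area under curve (AUC)",
}


def render_table1(summary: pd.DataFrame) -> str:
    """Mean ± SD grid per order x congruency x plausibility cell (markdown)."""
    header = (
        "| Measure | "
        + " | ".join(f"{o.replace('_', '-')}: {c}/{p}" for o, c, p in _CELL_ORDER)
        + " |"
    )
    sep = "|" + "---|" * (len(_CELL_ORDER) + 1)
    lines = [header, sep]
    idx = summary.set_index(["order", "congruency", "plausibility", "measure"])
    for m in measures.MEASURE_COLUMNS:
        cells = []
        for key in _CELL_ORDER:
            try:
                row = idx.loc[key + (m,)]
            except KeyError:
                cells.append("—")
                continue
            if row["n"] == 0 or pd.isna(row["mean"]):
                cells.append("—")
            else:
                sd = 0.0 if pd.isna(row["sd"]) else row["sd"]
                cells.append(f"{row['mean']:.2f} ±{sd:.2f}")
        lines.append(f"| {_MEASURE_LABELS.get(m, m)} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def render_table2(fits: dict[str, FitResult]) -> str:
    """Coefficient grid (beta with stars, and t) per fitted measure (markdown)."""
    names = list(fits)
    header = "| Term | " + " | ".join(f"{n} β | {n} t" for n in names) + " |"
    sep = "|" + "---|" * (2 * len(names) + 1)
    lines = [header, sep]
    if not names:
        logger.warning("render_table2: no fits to render")
        return header + "\n" + sep + "\n"
    for term in TERM_NAMES:
        cells = []
        for n in names:
            tab = fits[n].table
            row = tab[tab["term"] == term]
            if row.empty:
                cells.extend(["—", "—"])
            else:
                r = row.iloc[0]
                beta = f"{r['beta']:.2f} {r['stars']}".rstrip()
                cells.extend([beta, f"{r['t']:.2f}"])
        lines.append(f"| {term} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def fit_table_frame(fit: FitResult) -> pd.DataFrame:
    return fit.table.copy()


def fit_sidecar(fit: FitResult) -> dict:
    return {
        "family": fit.family,
        "method": fit.method,
        "df_policy": fit.df_policy,
        "n_obs": fit.n_obs,
        "random": fit.random,
        "pruned": fit.pruned,
        "converged": fit.converged,
        "singular": fit.singular,
        "notes": fit.notes,
        "vcomp": fit.vcomp.to_dict(orient="records"),
    }


def plot_mean_trajectories(trials, samples, geometry, path) -> Path:
    """Static per-condition mean canonical trajectory plot (time-normalized)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .preprocess import canonicalize, time_normalize
    from .simulate import Trajectory

    grouped = dict(tuple(samples.groupby(["participant_id", "trial_index"], sort=False)))
    fig, ax = plt.subplots(figsize=(5, 5))
    for (plaus, cong), sub in trials.groupby(["plausibility", "congruency"]):
        profs = []
        for tr in sub.itertuples(index=False):
            arr = grouped[(tr.participant_id, tr.trial_index)][
                ["t_ms", "x_px", "y_px"]
            ].to_numpy(dtype=float)
            side = tr.correct_side if bool(tr.correct) else (
                "right" if tr.correct_side == "left" else "left"
            )
            ct = canonicalize(Trajectory(arr, geometry, side), tr.correct_side)
            profs.append(time_normalize(ct, 101)[["x_std", "y_std"]].to_numpy())
        mean = sum(profs) / len(profs)
        ax.plot(mean[:, 0], mean[:, 1], label=f"{plaus}/{cong}")
    ax.set_xlabel("x (standardized; + = toward incorrect)")
    ax.set_ylabel("y (standardized)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


# --------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig, outdir: str | Path, *, plot: bool = False) -> RunManifest:
    """Execute every stage into ``outdir`` and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geometry = config.screen_geometry()
    params = config.simulation_params()
    stages: list[dict] = []
    files: dict[str, str] = {}
    timestamps: dict[str, str] = {}

    def record(name: str, path: Path):
        files[path.name] = file_sha256(path)

    def stamp(stage: str):
        timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    # 1. design
    bank = design.build_item_bank(config.design.n_scenes)
    lists = design.build_latin_lists(bank, config.design.n_lists, seed=config.seed)
    schedules = design.build_schedules(
        lists, config.design.n_participants, config.design.per_participant,
        seed=config.seed,
    )
    stages.append({"stage": "design", "n_items": len(bank), "n_trials": len(schedules)})
    stamp("design")
    logger.info("design: %d items, %d scheduled trials", len(bank), len(schedules))

    # 2. simulate
    trials, samples = simulate_experiment(schedules, params, geometry, seed=config.seed)
    record("trials", io.write_trials(trials, outdir / "trials.csv"))
    record("samples", io.write_samples(samples, outdir / "samples.csv"))
    stages.append({"stage": "simulate", "n_trials": len(trials), "n_samples": len(samples)})
    stamp("simulate")
    logger.info("simulate: %d trials, %d cursor samples", len(trials), len(samples))

    # 3. preprocess
    retained, report = preprocess_trials(trials, k=config.filter.k_sd)
    record("retained", io.write_trials(retained, outdir / "retained_trials.csv"))
    record("filter_report", io.write_json(report.to_dict(), outdir / "filter_report.json"))
    stages.append({"stage": "preprocess", **report.to_dict()})
    stamp("preprocess")
    logger.info(
        "preprocess: %d in, %d removed by RT cutoff (%.1f%%), %d error trials, %d retained",
        report.n_input, report.n_removed_rt,
        100.0 * report.n_removed_rt / max(report.n_input, 1),
        report.n_removed_error_trials, report.n_retained,
    )

    # 4. measure (accuracy/RT summaries keep post-RT-filter error trials;
    # dynamics measures are summarized over the accurate subset)
    post_rt = trials[trials["rt_s"] <= report.rt_cutoff_s].reset_index(drop=True)
    mtable = measures.measure_trials(
        post_rt, samples, geometry, jitter_px=config.filter.jitter_px
    )
    record("measures", _write_csv(mtable, outdir / "measures.csv"))
    summary = measures.summarize_cells(mtable)
    record("cell_summary", _write_csv(summary, outdir / "cell_summary.csv"))
    (outdir / "table1.md").write_text(render_table1(summary))
    record("table1", outdir / "table1.md")
    stages.append({"stage": "measure", "n_rows": len(mtable)})
    stamp("measure")

    # 5. fit
    analysis = mtable[mtable["correct"]].reset_index(drop=True)
    fits: dict[str, FitResult] = {}
    if config.model.accuracy:
        fits["accuracy"] = fit_accuracy_glmm(
            mtable, random=config.model.accuracy_random,
            df_policy=config.model.df_policy,
        )
    for m in config.model.measures:
        fits[m] = fit_lmm_maximal(analysis, m, df_policy=config.model.df_policy)
    if config.model.gca:
        profiles = angle_profiles(analysis, samples, geometry, n_bins=config.filter.n_bins)
        fits["gca_angle"] = fit_gca(
            profiles,
            GCASpec(n_bins=config.filter.n_bins, poly_order=config.model.gca_poly_order),
        )
    for name, fit in fits.items():
        record(f"fit_{name}", _write_csv(fit.table, outdir / f"fit_{name}.csv"))
        record(
            f"fit_{name}_spec",
            io.write_json(fit_sidecar(fit), outdir / f"fit_{name}.json"),
        )
    table2_fits = {k: v for k, v in fits.items() if k != "gca_angle"}
    (outdir / "table2.md").write_text(render_table2(table2_fits))
    record("table2", outdir / "table2.md")
    stages.append({
        "stage": "fit",
        "measures": list(fits),
        "converged": {k: bool(v.converged) for k, v in fits.items()},
    })
    stamp("fit")

    if plot:
        plot_mean_trajectories(analysis, samples, geometry, outdir / "mean_trajectories.png")

    import numpy as np  # versions block

    manifest = RunManifest(
        config_sha256=config_hash(config),
        files=files,
        versions={
            "mtverify": _package_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        timestamps=timestamps,
        filter_report=report.to_dict(),
        stages=stages,
    )
    io.write_json(manifest.to_dict(), outdir / "manifest.json")
    config.to_yaml(outdir / "run_config.yaml")
    return manifest


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def _package_version() -> str:
    from . import __version__

    return __version__
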