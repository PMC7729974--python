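"""One-config orchestration of the full analysis.

``run_pipeline`` executes the stages in dependency order — simulate (or
load) -> gestational binning -> per-fluid frequency filter -> overlap ->
paired origin screen -> panel training and validation — writes every stage
output as CSV/JSON under the output directory and returns a run summary
with a SHA-256 hash per file. All randomness flows through two named seeds
(``data_seed`` via the simulation config, ``model_seed`` for the forest), so
re-running an identical configuration reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datamodel import DEFAULT_SCHEME, GaBinScheme, frequency_filter
from .errors import ConfigError, UsageError
from .io import read_peptidome
from .origin import paired_origin_screen, screen_table, selected_ids
from .overlap import mass_summary, overlap_by_bin, venn_partition
from .panel import optimize_cutoff, score, select_candidates, train_classifier, validate_panel
from .synthetic import SimulationConfig, generate_cohort, generate_puv_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one of simulation / input directories."""

    simulation: SimulationConfig | None = None
    af_dir: Path | None = None
    fu_dir: Path | None = None
    out_dir: Path = Path("amniopep-run")
    bin_scheme: GaBinScheme = DEFAULT_SCHEME
    min_freq: float = 0.5
    screen_alpha: float = 0.05
    min_detected_pairs: int = 3
    panel_alpha: float = 0.05
    n_trees: int = 1000
    model_seed: int = 0
    #: "optimize" = Youden's J on training scores; "fixed" = keep cutoff at 0
    cutoff_mode: str = "optimize"
    #: (discovery ESRD, discovery noESRD, validation ESRD, validation noESRD)
    #: or None for a cohort without outcome labels
    puv_arms: tuple[int, int, int, int] | None = (6, 8, 8, 8)

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_paths = self.af_dir is not None or self.fu_dir is not None
        if has_sim == has_paths:
            raise ConfigError(
                "exactly one of a simulation config or input directories is required"
            )
        if has_paths and (self.af_dir is None or self.fu_dir is None):
            raise ConfigError("both af_dir and fu_dir are required when loading data")
        if self.cutoff_mode not in ("optimize", "fixed"):
            raise ConfigError("cutoff_mode must be 'optimize' or 'fixed'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim = doc.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        scheme = doc.pop("bin_scheme", None)
        kwargs = dict(doc)
        if scheme is not None:
            kwargs["bin_scheme"] = GaBinScheme(tuple(map(tuple, scheme)))
        for key in ("af_dir", "fu_dir", "out_dir"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        if kwargs.get("puv_arms") is not None:
            kwargs["puv_arms"] = tuple(kwargs["puv_arms"])
        return cls(simulation=sim, **kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _params_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return str(o)

    params = dataclasses.asdict(config)
    params.pop("out_dir", None)  # output location does not affect results
    blob = json.dumps(params, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run summary (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def save_csv(name: str, frame: pd.DataFrame, **kwargs) -> None:
        path = out / name
        frame.to_csv(path, **kwargs)
        written[name] = path

    # --- stage: data ---------------------------------------------------
    try:
        if config.simulation is not None:
            if config.puv_arms is not None:
                cohort = generate_puv_cohort(config.simulation, *config.puv_arms,
                                             scheme=config.bin_scheme)
            else:
                cohort = generate_cohort(config.simulation, scheme=config.bin_scheme)
            catalog, samples = cohort.catalog, cohort.samples
            af_all, fu_all = cohort.af, cohort.fu
        else:
            af_pep = read_peptidome(config.af_dir)
            fu_pep = read_peptidome(config.fu_dir)
            catalog = af_pep.catalog
            samples = pd.concat([af_pep.samples, fu_pep.samples], ignore_index=True)
            af_all, fu_all = af_pep.matrix, fu_pep.matrix
    except Exception as exc:
        raise type(exc)(f"[stage: data] {exc}; check the simulation/input section") from exc

    af_samples = samples[samples["fluid"] == "AF"]
    fu_samples = samples[samples["fluid"] == "FU"]
    af_all = af_all.loc[af_all.index.isin(af_samples["sample_id"])]
    fu_all = fu_all.loc[fu_all.index.isin(fu_samples["sample_id"])]
    save_csv("samples.csv", samples, index=False)

    # --- stage: frequency filter ---------------------------------------
    af = frequency_filter(af_all, af_samples, config.min_freq)
    fu = frequency_filter(fu_all, fu_samples, config.min_freq)

    # --- stage: overlap -------------------------------------------------
    part = venn_partition(af, fu)
    per_bin = overlap_by_bin(af, fu, samples, config.bin_scheme, config.min_freq)
    bin_rows = [{"ga_bin": label, **p.report()} for label, p in per_bin.items()]
    save_csv("overlap_by_bin.csv", pd.DataFrame(bin_rows), index=False)
    masses = {
        "AF": dataclasses.asdict(mass_summary(catalog, af.columns)),
        "FU": dataclasses.asdict(mass_summary(catalog, fu.columns)),
    }

    # --- stage: origin screen -------------------------------------------
    origin_summary: dict = {"skipped": False}
    fu_origin: list[str] = []
    try:
        results = paired_origin_screen(
            af, fu, samples,
            alpha=config.screen_alpha,
            min_detected_pairs=config.min_detected_pairs,
        )
        save_csv("origin_screen.csv", screen_table(results), index=False)
        fu_origin = selected_ids(results)
        origin_summary.update(n_tested=len(results), n_selected=len(fu_origin))
    except UsageError as exc:
        logger.warning("[stage: origin] skipped: %s", exc)
        origin_summary = {"skipped": True, "reason": str(exc)}

    # --- stage: panel ----------------------------------------------------
    panel_summary: dict = {"skipped": False}
    has_outcomes = samples["outcome"].isin(["ESRD", "noESRD"]).any()
    if has_outcomes and fu_origin:
        selected = select_candidates(af, samples, fu_origin, alpha=config.panel_alpha)
        if selected:
            model = train_classifier(
                af, samples, selected, n_trees=config.n_trees, seed=config.model_seed
            )
            meta = samples.set_index("sample_id")
            disc = meta[
                (meta["cohort"] == "discovery") & meta["outcome"].isin(["ESRD", "noESRD"])
            ]
            train_scores = score(model, af, disc.index.intersection(af.index))
            if config.cutoff_mode == "optimize":
                labels = disc.loc[train_scores.index, "outcome"] == "ESRD"
                model.cutoff = optimize_cutoff(train_scores, labels)
            report = validate_panel(model, af, samples)
            panel_summary.update(
                panel_peptides=list(selected),
                n_trees=config.n_trees,
                cutoff=model.cutoff,
                validation=report.summary(),
            )
        else:
            panel_summary = {"skipped": True, "reason": "no candidate survived selection"}
    else:
        reason = "no outcome labels" if not has_outcomes else "origin screen selected nothing"
        panel_summary = {"skipped": True, "reason": reason}

    # --- run summary -----------------------------------------------------
    summary = {
        "version": __version__,
        "params_hash": _params_hash(config),
        "seeds": {
            "data": config.simulation.seed if config.simulation else None,
            "model": config.model_seed,
        },
        "venn": part.report(),
        "mass": masses,
        "origin": origin_summary,
        "panel": panel_summary,
        "files": {},
    }
    for name, path in written.items():
        summary["files"][name] = _sha256(path)
    summary_path = out / "run_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
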