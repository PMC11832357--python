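"""Config-driven orchestration of the full analysis.

A single YAML config declares either real inputs (episode + population CSVs)
or a synthetic scenario, the study window, the subgroups, and the inference
settings.  ``run_pipeline`` executes the stages — simulate (synthetic only),
describe, fit, report — and writes every table as delimited text stamped with
the config hash and seed.  Any stage failure aborts with the stage name and
the offending subgroup.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import descriptive, io as eio, ratios
from .model import DEFAULT_MAX_DEGREE, select_by_aic
from .plotting import plot_observed_vs_expected
from .series import MonthlyCountSeries, PopulationSeries, month_number
from .simulate import ScenarioConfig, TrueModelParams, simulate_episode_table, simulate_monthly_counts

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SubgroupSpec", "run_pipeline", "PipelineError"]

STAGES = ("simulate", "describe", "fit", "report")


class PipelineError(RuntimeError):
    """A pipeline stage failed; message carries stage and subgroup."""


def _parse_ym(value) -> tuple[int, int]:
    if isinstance(value, str):
        y, m = value.split("-")
        return int(y), int(m)
    y, m = value
    return int(y), int(m)


@dataclass(frozen=True)
class SubgroupSpec:
    label: str
    sex: str | None = None
    band: str | None = None
    condition: str | None = None
    stratum: str | None = None  # population stratum; defaults to label


@dataclass
class PipelineConfig:
    """Validated pipeline settings; exactly one of real inputs or synthetic scenario."""

    start: tuple[int, int]
    pre_end: tuple[int, int]
    intervention: tuple[int, int]
    end: tuple[int, int]
    subgroups: list[SubgroupSpec]
    seed: int = 0
    outdir: Path = Path("itscount-out")
    n_max: int = DEFAULT_MAX_DEGREE
    replicates: int = 1000
    offset_mode: str = "interpolated"  # or "yearly_constant"
    synthetic: dict | None = None
    inputs: dict | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("config must declare exactly one of 'synthetic' or 'inputs'")
        a = month_number(*self.start)
        p = month_number(*self.pre_end)
        i = month_number(*self.intervention)
        b = month_number(*self.end)
        if not (a <= p < i <= b):
            raise ValueError(
                "windows overlap or are out of order: require "
                "start <= pre_end < intervention <= end")
        if i != p + 1:
            raise ValueError("intervention month must immediately follow pre_end")
        if self.offset_mode not in ("interpolated", "yearly_constant"):
            raise ValueError(f"unknown offset_mode {self.offset_mode!r}")
        if not self.subgroups:
            raise ValueError("at least one subgroup required")
        if self.replicates < 1000:
            raise ValueError("replicates must be >= 1000")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        w = raw["window"]
        subgroups = [SubgroupSpec(**s) if isinstance(s, dict) else SubgroupSpec(label=s)
                     for s in raw.get("subgroups", [])]
        return cls(
            start=_parse_ym(w["start"]), pre_end=_parse_ym(w["pre_end"]),
            intervention=_parse_ym(w["intervention"]), end=_parse_ym(w["end"]),
            subgroups=subgroups,
            seed=int(raw.get("seed", 0)),
            outdir=Path(raw.get("outdir", "itscount-out")),
            n_max=int(raw.get("n_max", DEFAULT_MAX_DEGREE)),
            replicates=int(raw.get("replicates", 1000)),
            offset_mode=raw.get("offset_mode", "interpolated"),
            synthetic=raw.get("synthetic"),
            inputs=raw.get("inputs"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        d["subgroups"] = [dataclasses.asdict(s) for s in self.subgroups]
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the analysis settings (the output destination is excluded)."""
        d = self.canonical()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _child_seed(seed: int, *keys: int) -> int:
    return int(np.random.SeedSequence([seed, *keys]).generate_state(1)[0] % (2**31))


def _stable_label_key(label: str) -> int:
    """Run-independent integer key for a subgroup label (str hash is salted)."""
    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")


def _stamp_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash}\n# seed={config.seed}\n")
        df.to_csv(fh, index=False)


def read_stamped_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _true_params_from(raw: dict) -> TrueModelParams:
    return TrueModelParams(
        beta0=float(raw["beta0"]),
        beta_trend=float(raw.get("beta_trend", 0.0)),
        harmonics=tuple(tuple(map(float, h)) for h in raw.get("harmonics", [])),
        dispersion=float(raw.get("dispersion", 50.0)),
        effect_by_year={int(k): float(v) for k, v in raw.get("effect_by_year", {}).items()},
    )


def _synthetic_series(config: PipelineConfig) -> dict[str, MonthlyCountSeries]:
    syn = config.synthetic
    params = _true_params_from(syn["params"])
    pops = {int(k): float(v) for k, v in syn["population_by_year"].items()}
    out = {}
    for i, sub in enumerate(config.subgroups):
        scen = ScenarioConfig(start=config.start, end=config.end,
                              intervention=config.intervention,
                              population_by_year=pops, subgroup=sub.label,
                              seed=_child_seed(config.seed, 1, i))
        out[sub.label] = simulate_monthly_counts(params, scen)
    return out


def _population_lookup(config: PipelineConfig) -> dict[str, PopulationSeries]:
    if config.synthetic is not None:
        pops = {int(k): float(v) for k, v in config.synthetic["population_by_year"].items()}
        anchors = pd.DataFrame({"year": list(pops), "population": list(pops.values()),
                                "anchor_type": "year"})
        # one shared stratum for every synthetic subgroup
        return {sub.label: PopulationSeries(stratum=sub.label, anchors=anchors)
                for sub in config.subgroups}
    return eio.read_population(config.inputs["population"])


def _offset_frame(config: PipelineConfig, pop: PopulationSeries) -> pd.DataFrame:
    if config.offset_mode == "interpolated":
        return pop.monthly(config.start, config.end)
    return pop.yearly_constant(config.start, config.end)


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Execute the requested stages and return a manifest of written paths.

    Stage order is fixed (simulate, describe, fit, report); requesting a late
    stage runs the earlier in-memory work it depends on but only writes the
    requested outputs.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash, "seed": config.seed}
    with open(out / "run.json", "w") as fh:
        json.dump({"config_hash": config.config_hash, "seed": config.seed,
                   "config": config.canonical(), "stages": list(stages)},
                  fh, indent=2, sort_keys=True, default=str)

    episodes = None
    series_by_label: dict[str, MonthlyCountSeries] = {}

    # ---- inputs / simulate -------------------------------------------------
    stage = "simulate" if config.synthetic is not None else "load-inputs"
    try:
        if config.synthetic is not None:
            series_by_label = _synthetic_series(config)
            epi_cfg = config.synthetic.get("episodes")
            if epi_cfg:
                episodes = simulate_episode_table(
                    n_pre=int(epi_cfg["n_pre"]), n_post=int(epi_cfg["n_post"]),
                    attribute_probs=epi_cfg.get("attribute_probs"),
                    seed=_child_seed(config.seed, 2))
            if "simulate" in stages:
                inp = out / "inputs"
                inp.mkdir(exist_ok=True)
                for label, s in series_by_label.items():
                    s.meta["config_hash"] = config.config_hash
                    s.to_csv(inp / f"series_{label}.csv")
                    manifest.setdefault("series", []).append(str(inp / f"series_{label}.csv"))
                if episodes is not None:
                    eio.write_episodes(episodes, inp / "episodes.csv")
                    manifest["episodes"] = str(inp / "episodes.csv")
        else:
            episodes = eio.read_episodes(config.inputs["episodes"],
                                         config.inputs.get("dialect"))
            for sub in config.subgroups:
                pred = eio.subgroup_predicate(sub.sex, sub.band, sub.condition)
                series_by_label[sub.label] = eio.aggregate_monthly(
                    episodes, (config.start, config.end), config.intervention,
                    subgroup=sub.label, predicate=pred)
    except (ValueError, KeyError, OSError) as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # ---- describe ----------------------------------------------------------
    if "describe" in stages:
        if episodes is None:
            logger.info("no episode-level data; skipping characteristics table")
        else:
            try:
                iy, im = config.intervention
                import datetime as dt
                table = descriptive.build_characteristics_table(
                    episodes, dt.date(iy, im, 1))
            except ValueError as exc:
                raise PipelineError(f"stage describe: {exc}") from exc
            _stamp_csv(table.data, out / "characteristics.csv", config)
            (out / "characteristics.txt").write_text(table.to_text() + "\n")
            manifest["characteristics"] = str(out / "characteristics.csv")

    if not ({"fit", "report"} & set(stages)):
        return manifest

    # ---- fit + report per subgroup ----------------------------------------
    populations = _population_lookup(config)
    ir_rows = []
    for sub in config.subgroups:
        label = sub.label
        series = series_by_label[label]
        pop = populations.get(sub.stratum or label)
        if pop is None:
            raise PipelineError(f"stage fit, subgroup {label}: no population stratum "
                                f"{sub.stratum or label!r}")
        offs = _offset_frame(config, pop)["population"].to_numpy()
        n_pre = len(series.pre)
        try:
            model = select_by_aic(series, offs[:n_pre], range(0, config.n_max + 1))
        except Exception as exc:
            raise PipelineError(f"stage fit, subgroup {label}: {exc}") from exc

        if "fit" in stages:
            mdir = out / "models"
            mdir.mkdir(exist_ok=True)
            summary = model.summary_dict()
            summary["config_hash"] = config.config_hash
            summary["seed"] = config.seed
            with open(mdir / f"{label}.yaml", "w") as fh:
                yaml.safe_dump(summary, fh, sort_keys=True)
            manifest.setdefault("models", []).append(str(mdir / f"{label}.yaml"))

        if "report" in stages:
            try:
                post = series.post
                expected = ratios.predict_expected(model, post, offs[n_pre:])
                results = ratios.incidence_ratio_table(
                    model, series, offs[n_pre:],
                    replicates=config.replicates,
                    seed=_child_seed(config.seed, 3, _stable_label_key(label)))
            except Exception as exc:
                raise PipelineError(f"stage report, subgroup {label}: {exc}") from exc
            ir_rows.extend(results)

            sdir = out / "series"
            sdir.mkdir(exist_ok=True)
            obs_out = series.data[["month_index", "year", "month", "count", "period"]]
            _stamp_csv(obs_out, sdir / f"{label}_observed.csv", config)
            exp_all = ratios.predict_expected(
                model, series.data, offs)  # expected over the whole window
            exp_df = series.data[["month_index", "year", "month"]].copy()
            exp_df["expected"] = exp_all
            _stamp_csv(exp_df, sdir / f"{label}_expected.csv", config)

            fdir = out / "figures"
            fdir.mkdir(exist_ok=True)
            i0 = month_number(*config.intervention) - month_number(*config.start)
            plot_observed_vs_expected(series.data, exp_df, i0, label,
                                      fdir / f"{label}.svg")
            manifest.setdefault("figures", []).append(str(fdir / f"{label}.svg"))

    if "report" in stages and ir_rows:
        ir = ratios.results_frame(ir_rows)
        _stamp_csv(ir, out / "ir_table.csv", config)
        manifest["ir_table"] = str(out / "ir_table.csv")
    return manifest
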