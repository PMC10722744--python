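"""End-to-end pipeline: simulate -> prepare -> select -> assess -> weight -> balance.

One reproducible run writes, per selection method and per wave: the selected
model, selection traces, discrimination and calibration reports, the weight
set and the balance report, plus a manifest recording the config hash, seed
and package versions. Every stage communicates only through serialized
artifacts, so stages can be re-run in isolation. A single global seed fans
out to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortTable,
    VariableSpec,
    prepare_for_modelling,
    read_cohort,
    write_cohort,
)
from .balance import balance_table, multiwave_balance
from .model import ParticipationModel
from .simulate import GeneratorConfig, default_true_model, generate_cohort
from .weighting import refit_for_wave

logger = logging.getLogger(__name__)

_STAGE_SEED_OFFSETS = {"simulate": 0, "selection": 101, "folds": 211}


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    seed: int = 0
    n_participants: int = 3351
    methods: tuple[str, ...] = ("apriori", "lasso")
    selection_wave: str = "3y"
    waves: tuple[str, ...] = ("3y", "5y", "8y", "covid")
    alpha: float = 0.05
    k_folds: int = 10
    truncation: tuple[float, float] = (0.5, 99.5)
    demographic_list: tuple[str, ...] | None = None
    curated_list: tuple[str, ...] | None = None
    cohort_csv: str | None = None  # load instead of simulating
    dictionary_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for m in cfg.methods:
            if m not in ("apriori", "lasso"):
                raise ValueError(f"unknown selection method {m!r}")
        if cfg.selection_wave not in cfg.waves:
            raise ValueError("selection_wave must be one of waves")
        if (cfg.cohort_csv is None) != (cfg.dictionary_csv is None):
            raise ValueError("cohort_csv and dictionary_csv go together")
        for p in (cfg.cohort_csv, cfg.dictionary_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_or_simulate(config: RunConfig):
    if config.cohort_csv is not None:
        table, specs = read_cohort(config.cohort_csv, config.dictionary_csv)
        true_model = None
    else:
        gen = GeneratorConfig(
            n_participants=config.n_participants,
            seed=config.seed + _STAGE_SEED_OFFSETS["simulate"],
            wave_labels=tuple(config.waves),
        )
        table, specs, true_model = generate_cohort(gen)
    return table, specs, true_model


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the whole analysis; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "warnings": [],
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("simulate")
        table, specs, true_model = _load_or_simulate(config)
        write_cohort(
            table, specs, outdir / "cohort.csv", outdir / "dictionary.csv"
        )
        if true_model is not None:
            true_model.to_json(outdir / "true_model.json")

        stage("prepare")
        ptable, pspecs = prepare_for_modelling(table, specs)

        for method in config.methods:
            stage(f"select:{method}")
            if method == "apriori":
                pm = ParticipationModel.from_curated_list(
                    ptable,
                    pspecs,
                    config.selection_wave,
                    curated_list=config.curated_list,
                )
            else:
                pm = ParticipationModel.from_lasso_selection(
                    ptable,
                    pspecs,
                    config.selection_wave,
                    k_folds=config.k_folds,
                    alpha=config.alpha,
                    seed=config.seed + _STAGE_SEED_OFFSETS["selection"],
                )
            res = pm.fit()
            res.selected.to_json(outdir / f"selected_model_{method}.json")
            if res.traces:
                with open(outdir / f"selection_trace_{method}.json", "w") as fh:
                    json.dump(
                        {t: tr.to_dict() for t, tr in res.traces.items()},
                        fh,
                        indent=2,
                    )

            stage(f"assess:{method}")
            disc = res.discrimination()
            cal = res.calibration()
            with open(outdir / f"assessment_{method}.json", "w") as fh:
                json.dump(
                    {"discrimination": disc.to_dict(), "calibration": cal.to_dict()},
                    fh,
                    indent=2,
                )
            pd.DataFrame(
                list(cal.curve_points), columns=["predicted", "observed_smoothed"]
            ).to_csv(outdir / f"calibration_curve_{method}.csv", index=False)

            stage(f"weight:{method}")
            dem = (
                list(config.demographic_list)
                if config.demographic_list
                else None
            )
            wave_summaries = {}
            for wave in config.waves:
                wmodel, ws = refit_for_wave(
                    res.selected.variables
                    if res.selected.variables
                    else list(res.selected.coefficients),
                    ptable,
                    pspecs,
                    wave,
                    truncation=config.truncation,
                )
                ws.to_csv(outdir / f"weights_{method}_{wave}.csv")
                wave_summaries[wave] = ws.summary()
            with open(outdir / f"weights_summary_{method}.json", "w") as fh:
                json.dump(wave_summaries, fh, indent=2)

            stage(f"balance:{method}")
            reports, long_df = multiwave_balance(
                ptable,
                pspecs,
                res.selected.variables,
                waves=config.waves,
                demographic_list=dem,
                truncation=config.truncation,
                scheme_name=method,
            )
            long_df.to_csv(outdir / f"balance_long_{method}.csv", index=False)
            with open(outdir / f"balance_summary_{method}.json", "w") as fh:
                json.dump(
                    {w: r.summary() for w, r in reports.items()}, fh, indent=2
                )
    except Exception as exc:  # fail loudly with stage context
        failed = manifest["stages"][-1] if manifest["stages"] else "init"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
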