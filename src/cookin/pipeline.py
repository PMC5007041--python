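"""End-to-end orchestration: simulate -> extract -> dfa -> dyads -> fit.

A run is driven by a single :class:`RunConfig` (loadable from YAML).  Every
stage writes plain interchange files (WAV, CSV, JSON) into the output
directory so any stage can be re-run or replaced standalone, and a
``manifest.json`` records the configuration, seeds and SHA-256 hash of
every artifact for exact replay verification.
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

from . import __version__, dfa, features, lmm, pedigree, synth

log = logging.getLogger("cookin")

__all__ = ["RunConfig", "run_all", "load_config", "fit_report_to_json"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``scenario`` selects the named study conditions (paper_like,
    kin_effect, null) or ``custom`` to take population/acoustics sections
    verbatim.  Module seeds derive from the global seed.
    """

    scenario: str = "paper_like"
    seed: int = 0
    out_dir: str = "cookin_run"
    population: dict = field(default_factory=dict)
    acoustics: dict = field(default_factory=dict)
    spectro: dict = field(default_factory=dict)
    dfa: dict = field(default_factory=dict)
    lmm: dict = field(default_factory=dict)
    write_wavs: bool = True
    unrelated_only: bool = True

    def configs(self) -> tuple[synth.PopulationConfig, synth.AcousticEffectConfig]:
        if self.scenario == "custom":
            pop = synth.PopulationConfig(**{**self.population, "seed": self.seed})
            ac = synth.AcousticEffectConfig(**{**self.acoustics, "seed": self.seed + 1})
            return pop, ac
        over = {f"pop_{k}": v for k, v in self.population.items()}
        over |= {f"ac_{k}": v for k, v in self.acoustics.items()}
        pop, ac = synth.scenario_config(self.scenario, seed=self.seed, **over)
        return dataclasses.replace(pop), dataclasses.replace(ac, seed=self.seed + 1)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _lrt_dict(r: lmm.LrtResult) -> dict:
    return {"chi_sq": r.chi_sq, "df": r.df, "p": r.p}


def fit_report_to_json(report: dict) -> dict:
    """JSON-serializable view of a reduce_and_report / unrelated_only dict."""
    out: dict = {}
    for key, val in report.items():
        if isinstance(val, lmm.LrtResult):
            out[key] = _lrt_dict(val)
        elif isinstance(val, lmm.LmmFit):
            out[key] = {
                "loglik": val.loglik,
                "reml": val.reml,
                "sigma2": val.sigma2,
                "converged": val.converged,
                "singular": val.singular,
                "coef": val.coef.reset_index().rename(columns={"index": "term"})
                .to_dict(orient="records"),
                "varcomp": val.varcomp.to_dict(),
            }
        elif isinstance(val, dict):
            out[key] = fit_report_to_json(val)
        elif isinstance(val, (np.bool_,)):
            out[key] = bool(val)
        else:
            out[key] = val
    return out


def run_all(config: RunConfig) -> dict:
    """Execute all stages, write artifacts, return the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def record(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = _sha256(path)

    pop_cfg, ac_cfg = config.configs()

    log.info("stage 1/5: simulating population and calls")
    ds = synth.simulate_dataset(pop_cfg, ac_cfg)
    if config.write_wavs:
        synth.write_dataset(ds, out)
        for p in sorted((out / "wav").glob("*.wav")):
            record(p)
        record(out / "calls.csv")
        record(out / "pedigree.csv")
        record(out / "truth.json")
    else:
        ds.pedigree.to_csv(out / "pedigree.csv")
        record(out / "pedigree.csv")

    log.info("stage 2/5: extracting %d-call feature table", len(ds.calls))
    sp = features.SpectroParams(**config.spectro)
    feat = features.extract_table(ds.calls, sp)
    feat.to_csv(out / "features.csv")
    record(out / "features.csv")
    features.feature_catalogue().to_json(out / "catalogue.json", orient="records")
    record(out / "catalogue.json")

    log.info("stage 3/5: stepwise DFA over %d callers", feat["female_id"].nunique())
    drop = [c for c in ("female_id", "imputed_tonal") if c in feat.columns]
    model = dfa.StepwiseLDA(**config.dfa).fit(feat.drop(columns=drop), feat["female_id"])
    model.steps_.to_csv(out / "stepwise.csv", index=False)
    record(out / "stepwise.csv")
    dist = model.pairwise_f()
    dist.to_csv(out / "distance_matrix.csv")
    record(out / "distance_matrix.csv")
    report = model.classification_report()
    with open(out / "classification.json", "w") as fh:
        json.dump({k: (v if not isinstance(v, pd.DataFrame) else v.to_dict())
                   for k, v in report.items()}, fh, indent=2)
    record(out / "classification.json")

    log.info("stage 4/5: dyad classification")
    dyads = pedigree.classify_dyads(ds.pedigree, ds.membership["id"])
    dyads.to_csv(out / "dyads.csv", index=False)
    record(out / "dyads.csv")
    pedigree.table1_summary(dyads).to_csv(out / "table1.csv", index=False)
    record(out / "table1.csv")

    log.info("stage 5/5: dyadic mixed model")
    data = lmm.build_dyad_table(dist, dyads)
    lmm_kw = dict(config.lmm)
    fit_report = lmm.reduce_and_report(data, **lmm_kw)
    with open(out / "model_report.json", "w") as fh:
        json.dump(fit_report_to_json(fit_report), fh, indent=2)
    record(out / "model_report.json")
    if config.unrelated_only and (data["kin_class"] == "nonkin").sum() >= 30:
        unrel = lmm.unrelated_only(data, random=lmm_kw.get("random", "slopes"))
        with open(out / "model_unrelated.json", "w") as fh:
            json.dump(fit_report_to_json(unrel), fh, indent=2)
        record(out / "model_unrelated.json")

    summary = {
        "classification_accuracy_resub": report["accuracy_resubstitution"],
        "classification_accuracy_loo": report["accuracy_loo"],
        "chance_level": report["chance_level"],
        "n_selected_features": report["n_selected"],
        "n_analysed_dyads": len(data),
        "full_vs_null": _lrt_dict(fit_report["full_vs_null"]),
        "main_effects": {k: _lrt_dict(v) for k, v in fit_report["main"].items()},
        "truth": ds.truth,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    record(out / "summary.json")

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
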