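"""Configuration-driven experiment runner and result archives.

An archive is a directory holding the tables an experiment produced
(CSV), a machine-readable ``summary.json``, and a copy of the resolved
configuration, so that every number in a report traces to a stored table
and a run is reproducible from its config + seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import experiments as ex


@dataclass
class ExperimentConfig:
    experiment: str
    seed: int = 0
    n_networks: int = 2
    out: str = "results"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _scalarize(obj):
    if isinstance(obj, dict):
        return {k: _scalarize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_scalarize(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    if hasattr(obj, "pvalue"):  # scipy test results
        return {"statistic": float(obj.statistic), "pvalue": float(obj.pvalue)}
    return str(obj)


def _run_pe_bias_v1(cfg: ExperimentConfig):
    res = ex.pe_bias_v1_experiment(n_networks=cfg.n_networks, seed=cfg.seed, **cfg.params)
    tables = {"per_net": res["per_net"]}
    summary = {k: _scalarize(v) for k, v in res.items() if k not in ("per_net", "nets")}
    return tables, summary


def _run_pe_bias_v2(cfg: ExperimentConfig):
    res = ex.pe_bias_v2_experiment(n_networks=cfg.n_networks, seed=cfg.seed, **cfg.params)
    tables = {"per_net": res["per_net"]}
    summary = {k: _scalarize(v) for k, v in res.items() if k not in ("per_net", "nets")}
    return tables, summary


def _run_dissociation(cfg: ExperimentConfig):
    res = ex.dissociation_experiment(n_networks=cfg.n_networks, seed=cfg.seed, **cfg.params)
    tables = {"per_net": res["per_net"], "condition_means": res["condition_means"].reset_index()}
    summary = {
        "mu3": res["mu3"],
        "mu_conditions": list(map(float, res["mu_conditions"])),
        "xi": res["xi"],
        "spearman_dprime_meta_s1": res["spearman_dprime_meta_s1"],
    }
    return tables, summary


def _run_blindsight(cfg: ExperimentConfig):
    res = ex.blindsight_experiment(n_networks=cfg.n_networks, seed=cfg.seed, **cfg.params)
    table = res["table"].drop(columns=["conf_correct", "conf_incorrect"])
    return {"sweep": table}, _scalarize(res["summary"])


def _run_tms(cfg: ExperimentConfig):
    params = dict(cfg.params)
    layer = params.pop("layer", 0)
    nets = ex.train_two_choice_cohort(cfg.n_networks, seed=cfg.seed, **params.pop("cohort", {}))
    table = ex.tms_sweep_experiment(nets, layer=layer, seed=cfg.seed, **params)
    means = table.groupby("xi")[["d_prime", "meta_d", "mean_confidence"]].mean().reset_index()
    return {"sweep": table, "means": means}, {"layer": layer, "means": _scalarize(means.to_dict("records"))}


def _run_single_unit(cfg: ExperimentConfig):
    res = ex.single_unit_experiment(n_networks=cfg.n_networks, seed=cfg.seed, **cfg.params)
    summary = {
        "n_networks": res["n_networks"],
        "n_significant": res["n_significant"],
        "proportion_significant": res["proportion_significant"],
    }
    return {"per_net": res["per_net"]}, summary


def _run_evidence_grid(cfg: ExperimentConfig):
    res = ex.evidence_grid_experiment(n_networks=cfg.n_networks, seed=cfg.seed, **cfg.params)
    tables = {"fits": res["fits"]}
    for k, g in enumerate(res["grids"]):
        tables[f"grid_net{k}"] = g.df
    cols = [c for c in res["fits"].columns if not c.endswith("used_logit") and c != "net"]
    summary = {"mean_r2": _scalarize(res["fits"][cols].mean().to_dict())}
    return tables, summary


def _run_latent_io(cfg: ExperimentConfig):
    res = ex.latent_io_experiment(n_networks=cfg.n_networks, seed=cfg.seed, **cfg.params)
    return {"per_vae": res["per_vae"]}, {"confidence_diff": res["confidence_diff"]}


EXPERIMENTS = {
    "pe-bias-v1": _run_pe_bias_v1,
    "pe-bias-v2": _run_pe_bias_v2,
    "dissociation": _run_dissociation,
    "blindsight": _run_blindsight,
    "tms": _run_tms,
    "single-unit": _run_single_unit,
    "evidence-grid": _run_evidence_grid,
    "latent-io": _run_latent_io,
}


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute a registered experiment end-to-end and write its archive
    (tables + summary + resolved config + state fingerprint)."""
    if config.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {config.experiment!r}; registered: {sorted(EXPERIMENTS)}"
        )
    outdir = Path(config.out) / config.experiment
    outdir.mkdir(parents=True, exist_ok=True)
    tables, summary = EXPERIMENTS[config.experiment](config)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps(_scalarize(summary), indent=1))
    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    fingerprint = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "tables": sorted(tables),
    }
    (outdir / "fingerprint.json").write_text(json.dumps(fingerprint, indent=1))
    return outdir


def report(archive: str | Path) -> str:
    """Human-readable summary of an archive; every number comes from the
    stored summary/tables, nothing is recomputed."""
    archive = Path(archive)
    if not archive.exists():
        raise FileNotFoundError(archive)
    summary_path = archive / "summary.json"
    tables = sorted(archive.glob("*.csv"))
    if not summary_path.exists() and not tables:
        return f"{archive.name}: no results"
    lines = [f"Experiment archive: {archive.name}"]
    if summary_path.exists():
        try:
            summary = json.loads(summary_path.read_text())
        except json.JSONDecodeError as e:
            raise ValueError(f"corrupt archive: unreadable summary.json ({e})") from e
        for k, v in summary.items():
            lines.append(f"  {k}: {v}")
        if summary.get("accuracy_balanced") is False:
            lines.append("  WARNING: accuracy-balance gate failed; confidence comparison not interpretable")
    for t in tables:
        n = sum(1 for _ in open(t)) - 1
        lines.append(f"  table {t.name}: {n} rows")
    return "\n".join(lines)
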