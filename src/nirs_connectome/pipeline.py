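"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
metrics -> group inference -> symptom correlation, with a run manifest.

A single YAML configuration controls every analysis threshold (band
edges, segment length, sparsity, edge p threshold, permutation count,
alpha levels), all defaulting to the pipeline's canonical values.  Each
stage reads only the previous stage's files, so the subcommands can also
be run independently; the manifest records the config snapshot, seeds,
package version and SHA-256 of every output so a run can be audited and
reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import connectivity as conn
from . import inference, network_metrics
from . import layout_io as lio
from . import preprocessing as prep
from .synthetic_data import (
    CovarianceSpec,
    EffectSpec,
    NoiseSpec,
    SimulationConfig,
    SymptomSpec,
    simulate_cohort,
)

log = logging.getLogger("nirs_connectome")

__all__ = ["PipelineConfig", "PipelineError", "run_all", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclasses.dataclass
class PipelineConfig:
    simulation: SimulationConfig
    band: tuple[float, float] = (0.01, 0.1)
    segment_s: float = 480.0
    ica_seed: int = 0
    sparsity: float = 0.2
    p_edge: float = 0.001
    n_permutations: int = 1000
    nbs_seed: int = 0
    alpha: float = 0.05
    raw: dict = dataclasses.field(default_factory=dict)


def _build_dataclass(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise PipelineError(
            f"unknown {cls.__name__} option(s): {sorted(unknown)}"
        )
    return cls(**data)


def load_config(source: str | Path | dict) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file path or an equivalent dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    sim_data = dict(data.get("simulation", {}))
    for key, cls in (
        ("covariance", CovarianceSpec),
        ("effect", EffectSpec),
        ("noise", NoiseSpec),
        ("symptoms", SymptomSpec),
    ):
        if key in sim_data:
            sub = dict(sim_data[key])
            if key == "effect" and "edges" in sub:
                sub["edges"] = tuple(tuple(e) for e in sub["edges"])
            sim_data[key] = _build_dataclass(cls, sub)
    sim = _build_dataclass(SimulationConfig, sim_data)
    cfg = PipelineConfig(simulation=sim, raw=data)
    for key in (
        "segment_s",
        "ica_seed",
        "sparsity",
        "p_edge",
        "n_permutations",
        "nbs_seed",
        "alpha",
    ):
        if key in data:
            setattr(cfg, key, data[key])
    if "band" in data:
        cfg.band = tuple(float(v) for v in data["band"])
    return cfg


def demo_config(seed: int = 0) -> PipelineConfig:
    """A small configuration that exercises every stage in seconds."""
    return load_config(
        {
            "simulation": {
                "n_channels": 20,
                "duration_s": 300.0,
                "n_per_group": 10,
                "seed": seed,
            },
            "segment_s": 240.0,
            "n_permutations": 200,
        }
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=1, sort_keys=True, default=_json_default) + "\n"
    )


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg.simulation)
    lio.write_channel_layout(cohort.layout, out / "layout.tsv")
    lio.write_cohort(cohort.cohort, out / "cohort.tsv")
    rec_dir = out / "recordings"
    rec_dir.mkdir(exist_ok=True)
    for rec in cohort.recordings:
        lio.write_recording(
            rec, rec_dir / lio.recording_filename(rec.subject_id, rec.species)
        )
    _write_json(cohort.truth, out / "truth.json")
    return {"n_recordings": len(cohort.recordings)}


def stage_preprocess(cfg: PipelineConfig, sim_dir: Path, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    layout = lio.load_channel_layout(sim_dir / "layout.tsv")
    clean_dir = out / "cleaned"
    clean_dir.mkdir(exist_ok=True)
    reports = []
    paths = sorted((sim_dir / "recordings").glob("*_HbO.tsv"))
    if not paths:
        raise PipelineError("no HbO recordings found to preprocess")
    for path in paths:
        rec = lio.load_recording(path, fs=cfg.simulation.fs, layout=layout)
        clean, flags = prep.preprocess_recording(
            rec, band=cfg.band, segment_s=cfg.segment_s, ica_seed=cfg.ica_seed
        )
        lio.write_recording(clean, clean_dir / path.name)
        flags = flags.copy()
        flags.insert(0, "subject_id", rec.subject_id)
        reports.append(flags)
    pd.concat(reports, ignore_index=True).to_csv(
        out / "ica_report.tsv", sep="\t", index=False
    )
    return {"n_subjects": len(paths)}


def stage_connectivity(cfg: PipelineConfig, pre_dir: Path, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    paths = sorted((pre_dir / "cleaned").glob("*_HbO.tsv"))
    for path in paths:
        rec = lio.load_recording(path, fs=cfg.simulation.fs)
        cm = conn.pearson_matrix(rec)
        net = conn.binarize_at_sparsity(cm, sparsity=cfg.sparsity)
        subj_dir = out / rec.subject_id
        subj_dir.mkdir(exist_ok=True)
        lio.write_matrix(cm.r, subj_dir / "r.tsv")
        lio.write_matrix(cm.z, subj_dir / "z.tsv")
        lio.write_matrix(net.adjacency, subj_dir / "adj.tsv")
    return {"n_subjects": len(paths), "sparsity": cfg.sparsity}


def _load_group_matrices(
    conn_dir: Path, cohort: pd.DataFrame, name: str, group: str
) -> np.ndarray:
    mats = []
    for sid in cohort.loc[cohort["group"] == group, "subject_id"]:
        m = lio.load_matrix(conn_dir / sid / name)
        np.fill_diagonal(m, 0.0)
        mats.append(m)
    return np.stack(mats)


def stage_metrics(cfg: PipelineConfig, conn_dir: Path, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    subj_dirs = sorted(d for d in conn_dir.iterdir() if d.is_dir())
    for d in subj_dirs:
        adj = lio.load_matrix(d / "adj.tsv")
        net = conn.BinaryNetwork(
            adjacency=adj.astype(np.uint8), sparsity=cfg.sparsity,
            subject_id=d.name,
        )
        res = network_metrics.efficiency_metrics(net)
        row = {"subject_id": d.name, "e_glob": res.e_glob, "e_loc": res.e_loc}
        row.update(
            {f"e_nod_{k + 1}": v for k, v in enumerate(res.e_nod.tolist())}
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(
        out / "efficiencies.tsv", sep="\t", index=False, float_format="%.17g"
    )
    return {"n_subjects": len(rows)}


def stage_nbs(
    cfg: PipelineConfig, sim_dir: Path, conn_dir: Path, out: Path
) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    cohort = lio.load_cohort(sim_dir / "cohort.tsv")
    layout = lio.load_channel_layout(sim_dir / "layout.tsv")
    za = _load_group_matrices(conn_dir, cohort, "z.tsv", "patient")
    zb = _load_group_matrices(conn_dir, cohort, "z.tsv", "control")
    result = inference.nbs(
        za,
        zb,
        p_edge=cfg.p_edge,
        n_permutations=cfg.n_permutations,
        seed=cfg.nbs_seed,
    )
    comps = []
    for k, comp in enumerate(result.components):
        classes = inference.classify_edges(comp, layout)
        comps.append(
            {
                "edges": [
                    [int(layout.channel_id[a]), int(layout.channel_id[b])]
                    for a, b in comp
                ],
                "size": int(result.sizes[k]),
                "p": float(result.p_values[k]),
                "sign": int(result.component_sign[k]),
                "edge_classes": classes["edge_class"].tolist(),
            }
        )
    payload = {
        "config": {
            "p_edge": cfg.p_edge,
            "n_permutations": cfg.n_permutations,
            "seed": cfg.nbs_seed,
        },
        "components": comps,
        "null_max_sizes": result.null_max_sizes,
        "significant": result.significant,
    }
    _write_json(payload, out / "nbs.json")
    return {
        "n_components": len(comps),
        "n_significant": len(result.significant),
    }


def stage_correlate(
    cfg: PipelineConfig,
    sim_dir: Path,
    conn_dir: Path,
    metrics_dir: Path,
    nbs_dir: Path,
    out: Path,
) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    cohort = lio.load_cohort(sim_dir / "cohort.tsv")
    layout = lio.load_channel_layout(sim_dir / "layout.tsv")
    nbs_payload = json.loads((nbs_dir / "nbs.json").read_text())
    eff = pd.read_csv(metrics_dir / "efficiencies.tsv", sep="\t")

    patients = cohort[cohort["group"] == "patient"].reset_index(drop=True)
    covariates = patients[["age_months", "sex", "education_years"]]
    scores = patients[["inattentive", "hyperactive_impulsive", "total"]]

    # Features: z-values of edges in significant components...
    feature_cols = {}
    sig_idx = nbs_payload["significant"]
    edge_list = []
    for k in sig_idx:
        edge_list.extend(nbs_payload["components"][k]["edges"])
    if edge_list:
        za = _load_group_matrices(conn_dir, cohort, "z.tsv", "patient")
        for ca, cb in edge_list:
            ia, ib = layout.index_of(ca), layout.index_of(cb)
            feature_cols[f"edge_{ca}_{cb}"] = za[:, ia, ib]
    # ... plus nodal efficiencies with a group difference at alpha.
    eff_by_sid = eff.set_index("subject_id")
    nod_cols = [c for c in eff.columns if c.startswith("e_nod_")]
    pat_eff = eff_by_sid.loc[patients["subject_id"], nod_cols].to_numpy()
    ctl_ids = cohort.loc[cohort["group"] == "control", "subject_id"]
    ctl_eff = eff_by_sid.loc[ctl_ids, nod_cols].to_numpy()
    nod_table = inference.group_difference_table(
        pat_eff, ctl_eff, names=nod_cols, alpha=cfg.alpha
    )
    nod_table.to_csv(out / "nodal_group_tests.tsv", sep="\t", index=False)
    for name in nod_table.loc[nod_table["significant"], "feature"]:
        feature_cols[name] = eff_by_sid.loc[
            patients["subject_id"], name
        ].to_numpy()

    if feature_cols:
        features = pd.DataFrame(feature_cols)
        table = inference.symptom_correlation(
            features, scores, covariates, alpha=cfg.alpha
        )
    else:
        table = pd.DataFrame(
            columns=["feature", "score", "r", "p", "significant"]
        )
    table.to_csv(out / "corr.tsv", sep="\t", index=False)
    return {"n_features": len(feature_cols), "n_pairs": len(table)}


_STAGES = ["simulate", "preprocess", "connectivity", "metrics", "nbs", "correlate"]


def run_all(config: str | Path | dict | PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage in order and write a run manifest.

    Any stage failure halts the run with the failing stage named; the
    manifest is written last, after all outputs exist.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dirs = {name: out_dir / name for name in _STAGES}
    manifest: dict = {
        "package_version": __version__,
        "config": cfg.raw,
        "seeds": {
            "simulation": cfg.simulation.seed,
            "ica": cfg.ica_seed,
            "nbs": cfg.nbs_seed,
        },
        "stages": {},
    }
    calls = {
        "simulate": lambda: stage_simulate(cfg, dirs["simulate"]),
        "preprocess": lambda: stage_preprocess(
            cfg, dirs["simulate"], dirs["preprocess"]
        ),
        "connectivity": lambda: stage_connectivity(
            cfg, dirs["preprocess"], dirs["connectivity"]
        ),
        "metrics": lambda: stage_metrics(
            cfg, dirs["connectivity"], dirs["metrics"]
        ),
        "nbs": lambda: stage_nbs(
            cfg, dirs["simulate"], dirs["connectivity"], dirs["nbs"]
        ),
        "correlate": lambda: stage_correlate(
            cfg,
            dirs["simulate"],
            dirs["connectivity"],
            dirs["metrics"],
            dirs["nbs"],
            dirs["correlate"],
        ),
    }
    for name in _STAGES:
        log.info("stage %s: starting", name)
        t0 = time.monotonic()
        try:
            info = calls[name]()
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        elapsed = time.monotonic() - t0
        outputs = sorted(
            p for p in dirs[name].rglob("*") if p.is_file()
        )
        manifest["stages"][name] = {
            "info": info,
            "seconds": round(elapsed, 3),
            "outputs": {
                str(p.relative_to(out_dir)): _sha256(p) for p in outputs
            },
        }
        log.info("stage %s: done in %.1fs", name, elapsed)
    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S%z")
    _write_json(manifest, out_dir / "manifest.json")
    return manifest
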