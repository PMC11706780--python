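"""Run orchestration: configuration, staged execution, manifests, reports.

A run is described by a single flat-ish YAML/dict configuration with one
block per stage (synthetic, morphometry, membrane, cable) plus a global
seed and output directory.  Stages execute in dependency order; each
stage's seed is derived deterministically from the global seed and the
stage name, so identical configurations reproduce identical outputs
bit-for-bit.  A JSON manifest records the configuration hash, per-stage
outputs, wall time and convergence flags.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["RunConfig", "RunManifest", "stage_seed", "run_experiment", "report"]

DEFAULT_CONFIG: dict = {
    "experiment": "nanopearl-run",
    "seed": 0,
    "outdir": "nanopearl_out",
    "stages": ["synthetic", "morphometry"],
    "synthetic": {
        "dim_means": [600.0, 311.0, 552.0, 127.0],  # dissociated-culture cohort
        "dim_sds": [90.0, 50.0, 140.0, 30.0],
        "n_axons": 20,
        "n_periods": 8,
        "noise_sd": 0.0,
        "synaptic_fraction": 0.0,
    },
    "morphometry": {"smoothing_window": 15.0},
    "membrane": {
        "kappa": 50.0,
        "sigma": 0.05,
        "c_ext_mosm": [150.0, 300.0, 600.0],
        "grid_n": 96,
        "tol": 1e-4,
        "max_iter": 15000,
    },
    "cable": {
        "geometries": "reference",  # or list of 4-dim rows (nm)
        "layout": "periodic",
        "dx_nm": 20.0,
        "dt_ms": 0.002,
    },
}


@dataclass
class RunConfig:
    """Validated run configuration (dict-backed, YAML round-trippable)."""

    data: dict

    @classmethod
    def from_dict(cls, d: Optional[dict] = None) -> "RunConfig":
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        for key, val in (d or {}).items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
        cfg = cls(merged)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)

    def validate(self) -> None:
        known = {"synthetic", "morphometry", "membrane", "cable"}
        stages = self.data.get("stages", [])
        bad = set(stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if "morphometry" in stages and "synthetic" not in stages:
            raise ValueError("morphometry stage requires the synthetic stage")
        if not isinstance(self.data.get("seed"), int):
            raise ValueError("seed must be an integer")

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)  # name -> {status, outputs, seconds, ...}

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "version": self.version, "stages": self.stages},
            indent=2,
            sort_keys=True,
        )

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_experiment(config: RunConfig, outdir: Optional[str] = None) -> RunManifest:
    """Execute the configured stages; write outputs and a manifest.

    Stage failures are recorded in the manifest without discarding the
    outputs of completed stages.
    """
    from . import __version__

    out = Path(outdir or config.data["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.digest, version=__version__)
    config.to_yaml(out / "config.yaml")

    ctx: dict = {}
    for stage in config.data["stages"]:
        t0 = time.time()
        entry = {"status": "ok", "outputs": []}
        try:
            entry["outputs"] = _STAGE_RUNNERS[stage](config, out, ctx)
        except Exception as exc:  # recorded, not raised: partial runs are useful
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
        entry["seconds"] = round(time.time() - t0, 3)
        manifest.stages[stage] = entry
    manifest.write(out / "manifest.json")
    return manifest


def _run_synthetic(config: RunConfig, out: Path, ctx: dict) -> list[str]:
    from .synthetic import gen_population

    cfg = config.data["synthetic"]
    seed = stage_seed(config.data["seed"], "synthetic")
    profiles, truths, table = gen_population(
        cfg["dim_means"],
        cfg["dim_sds"],
        cfg["n_axons"],
        synaptic_fraction=cfg.get("synaptic_fraction", 0.0),
        seed=seed,
        n_periods=cfg.get("n_periods", 8),
        noise_sd=cfg.get("noise_sd", 0.0),
    )
    d = out / "profiles"
    d.mkdir(exist_ok=True)
    files = []
    for i, p in enumerate(profiles):
        f = d / f"axon_{i:04d}.tsv"
        p.write(f)
        files.append(str(f))
    tf = out / "truth_table.tsv"
    table.to_csv(tf, sep="\t", index=False)
    ctx["profiles"] = profiles
    ctx["truth_table"] = table
    return files + [str(tf)]


def _run_morphometry(config: RunConfig, out: Path, ctx: dict) -> list[str]:
    from .morphometry import measure_profile, apply_exclusions, summarize

    cfg = config.data["morphometry"]
    profiles = ctx["profiles"]
    records = [
        measure_profile(p, smoothing_window=cfg.get("smoothing_window", 15.0))
        for p in profiles
    ]
    records, counts = apply_exclusions(records)
    summary = summarize(records, ["cohort"] * len(records))
    f = out / "morphometry_summary.tsv"
    summary.to_csv(f, sep="\t", index=False)
    ctx["morphometry"] = summary
    ctx["exclusion_counts"] = counts
    return [str(f)]


def _run_membrane(config: RunConfig, out: Path, ctx: dict) -> list[str]:
    from .membrane import MembraneParams, sweep_parameters

    cfg = dict(config.data["membrane"])
    base = MembraneParams(
        kappa=cfg.get("kappa", 50.0),
        sigma=cfg.get("sigma", 0.05),
    )
    c_vals = cfg.get("c_ext_mosm", [150.0, 300.0, 600.0])
    df = sweep_parameters(
        c_ext_mosm=np.asarray(c_vals, dtype=float),
        base=base,
        grid_n=int(cfg.get("grid_n", 96)),
        seed=stage_seed(config.data["seed"], "membrane"),
        tol=float(cfg.get("tol", 1e-4)),
        max_iter=int(cfg.get("max_iter", 15000)),
    )
    f = out / "membrane_sweep.tsv"
    df.to_csv(f, sep="\t", index=False)
    ctx["membrane"] = df
    return [str(f)]


def _run_cable(config: RunConfig, out: Path, ctx: dict) -> list[str]:
    import pandas as pd

    from .cable import REFERENCE_GEOMETRIES, predict_from_measurements

    cfg = config.data["cable"]
    geoms = cfg.get("geometries", "reference")
    if geoms == "reference":
        rows = [(name,) + dims for name, dims in REFERENCE_GEOMETRIES.items()]
    else:
        rows = [(f"row{i}",) + tuple(map(float, g)) for i, g in enumerate(geoms)]
    recs = []
    for name, *dims in rows:
        vel = predict_from_measurements(
            tuple(dims),
            layout_mode=cfg.get("layout", "periodic"),
            dx_nm=float(cfg.get("dx_nm", 20.0)),
            dt_ms=float(cfg.get("dt_ms", 0.002)),
        )
        recs.append(
            {
                "geometry": name,
                "nsv_length_nm": dims[0],
                "nsv_width_nm": dims[1],
                "connector_length_nm": dims[2],
                "connector_width_nm": dims[3],
                "velocity_m_per_s": vel,
            }
        )
    df = pd.DataFrame(recs)
    f = out / "velocity_predictions.tsv"
    df.to_csv(f, sep="\t", index=False)
    ctx["cable"] = df
    return [str(f)]


_STAGE_RUNNERS = {
    "synthetic": _run_synthetic,
    "morphometry": _run_morphometry,
    "membrane": _run_membrane,
    "cable": _run_cable,
}


def report(manifest: RunManifest, outdir: Optional[str] = None) -> str:
    """Human-readable per-stage summary of a completed run."""
    lines = [f"nanopearl run {manifest.config_hash} (v{manifest.version})", ""]
    if not manifest.stages:
        return lines[0] + "\n"
    base = Path(outdir) if outdir else None
    for name, entry in manifest.stages.items():
        lines.append(f"[{name}] status={entry['status']} ({entry.get('seconds', '?')} s)")
        if entry["status"] != "ok":
            lines.append(f"    error: {entry.get('error')}")
            lines.append("    section unavailable")
            continue
        if base is not None:
            for f in entry.get("outputs", []):
                fp = Path(f)
                if fp.name == "morphometry_summary.tsv" and fp.exists():
                    import pandas as pd

                    df = pd.read_csv(fp, sep="\t")
                    for _, row in df.iterrows():
                        lines.append(
                            f"    {row['dimension']}: {row['mean_nm']:.0f} "
                            f"+/- {row['sem_nm']:.0f} nm (n={row['n']})"
                        )
                elif fp.name == "membrane_sweep.tsv" and fp.exists():
                    import pandas as pd

                    df = pd.read_csv(fp, sep="\t")
                    widths = df["nsv_width_nm"].values
                    trend = "decreasing" if np.all(np.diff(widths) < 0) else "non-monotone"
                    lines.append(f"    NSV width vs osmolarity: {trend}")
                elif fp.name == "velocity_predictions.tsv" and fp.exists():
                    import pandas as pd

                    df = pd.read_csv(fp, sep="\t")
                    for _, row in df.iterrows():
                        lines.append(
                            f"    {row['geometry']}: {row['velocity_m_per_s']:.3f} m/s"
                        )
        n_out = len(entry.get("outputs", []))
        lines.append(f"    {n_out} output file(s)")
    return "\n".join(lines) + "\n"
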