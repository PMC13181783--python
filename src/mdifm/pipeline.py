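"""End-to-end orchestration: trajectories/synthetic boxes → clusters →
frequencies → observables → FFCF → benchmark, with deterministic seeding
and a machine-readable run manifest.

Every output CSV starts with a provenance comment line carrying the
package version, the config hash and the master seed; rerunning an
identical config on mock/synthetic inputs reproduces the files byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .benchmark import build_benchmark, metric_table
from .engine import (
    EngineAdapter,
    MockEngine,
    XTBEngine,
    assign_probe_modes,
    build_engine_input,
    run_engine,
)
from .errors import ConfigError, FitConvergenceError, ModeAssignmentError
from .ffcf import compute_ffcf, extract_tau_c, fit_biexponential
from .frames import Frame, read_pdb, read_xyz
from .kubo import SyntheticBoxParams, evolve_water_box, generate_water_box
from .observables import (
    FREQS_COLUMNS,
    decompose_by_coordination,
    series_from_dataframe,
    summarize,
)
from .shells import (
    ProbeSpec,
    ShellCutoffs,
    carve_cluster,
    compute_rdf,
    locate_shell_cutoffs,
    perceive_waters,
)

__all__ = ["DatasetSpec", "RunConfig", "load_config", "run_pipeline"]


@dataclass(frozen=True)
class DatasetSpec:
    """One labelled input: either trajectory files (one per replica) or a
    synthetic Brownian water-box trajectory."""

    label: str
    kind: str = "synthetic"  # "synthetic" | "trajectory"
    files: tuple[str, ...] = ()
    seed: int = 0
    n_waters: int = 200
    box_length: float = 18.2
    #: "brownian": rigid-body random walk (time-correlated, suits FFCF runs);
    #: "iid": independent box per snapshot (ensemble properties only)
    dynamics: str = "brownian"


@dataclass(frozen=True)
class RunConfig:
    """Declarative pipeline configuration (TOML-loadable)."""

    out_dir: str
    datasets: tuple[DatasetSpec, ...]
    seed: int = 0
    replicas: int = 12
    usable_ps: float = 50.0
    stride_fs: float = 50.0
    probe_index: int = 0  # 0-based water-molecule index
    deuterium_position: int = 1
    cluster_mode: str = "nearest_n"
    cluster_size: int = 30  # total molecules incl. probe (nearest_n mode)
    cutoffs: str = "fixed"  # "fixed" | "rdf"
    r_first: float = 3.4
    r_third: float = 7.8
    engine: str = "mock"
    xtb_cmd: str = "xtb"
    max_lag_ps: float | None = None
    coordination_counts: tuple[int, ...] = (3, 4, 5)
    reference: str | None = None

    def validate(self) -> None:
        if not self.datasets:
            raise ConfigError("config lists no datasets")
        labels = [d.label for d in self.datasets]
        if len(set(labels)) != len(labels):
            raise ConfigError("dataset labels must be unique")
        for ds in self.datasets:
            if ds.kind not in ("synthetic", "trajectory"):
                raise ConfigError(f"unknown dataset kind {ds.kind!r}")
            if ds.kind == "trajectory":
                if not ds.files:
                    raise ConfigError(f"dataset {ds.label!r} lists no trajectory files")
                for f in ds.files:
                    if not Path(f).exists():
                        raise ConfigError(f"trajectory file not found: {f}")
        if self.engine not in ("mock", "xtb"):
            raise ConfigError(f"unknown engine {self.engine!r}")
        if self.reference is not None and self.reference not in labels:
            raise ConfigError(f"reference {self.reference!r} is not a dataset label")
        if self.cluster_size < 1:
            raise ConfigError("cluster_size must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    """Parse a TOML run configuration."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    ds_raw = raw.pop("datasets", [])
    datasets = tuple(
        DatasetSpec(**{**d, "files": tuple(d.get("files", ()))}) for d in ds_raw
    )
    counts = tuple(raw.pop("coordination_counts", (3, 4, 5)))
    cfg = RunConfig(datasets=datasets, coordination_counts=counts, **raw)
    cfg.validate()
    return cfg


def _config_hash(config: RunConfig) -> str:
    # out_dir is excluded: the same analysis in two directories is the same run
    d = asdict(config)
    d.pop("out_dir", None)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _make_engine(config: RunConfig) -> EngineAdapter:
    if config.engine == "mock":
        return MockEngine(r1=config.r_first)
    return XTBEngine(cmd=config.xtb_cmd)


def _dataset_frames(config: RunConfig, ds: DatasetSpec, ds_index: int):
    """Yield (replica, frame-iterator) pairs for one dataset."""
    if ds.kind == "trajectory":
        for r, path in enumerate(ds.files):
            path = Path(path)
            frames = read_pdb(path) if path.suffix.lower() == ".pdb" else read_xyz(path)
            yield r, iter(frames)
        return
    if ds.dynamics not in ("brownian", "iid"):
        raise ConfigError(f"unknown synthetic dynamics {ds.dynamics!r}")
    n_steps = int(round(config.usable_ps * 1000.0 / config.stride_fs))
    for r in range(config.replicas):
        def gen(r=r):
            box_seed = int((config.seed * 1_000_003 + ds.seed * 7919 + ds_index * 1009 + r)
                           % 2**31)
            frame = generate_water_box(
                SyntheticBoxParams(ds.n_waters, ds.box_length, seed=box_seed),
                time_ps=config.stride_fs / 1000.0,
            )
            rng = np.random.default_rng([config.seed, ds.seed, ds_index, r])
            for k in range(n_steps):
                t = (k + 1) * config.stride_fs / 1000.0
                if k > 0:
                    if ds.dynamics == "brownian":
                        frame = evolve_water_box(frame, rng, time_ps=t)
                    else:
                        frame = generate_water_box(
                            SyntheticBoxParams(
                                ds.n_waters, ds.box_length,
                                seed=int((box_seed + 7919 * k) % 2**31),
                            ),
                            time_ps=t,
                        )
                yield frame
        yield r, gen()


def _resolve_cutoffs(config: RunConfig, sample_frames: list[Frame]) -> ShellCutoffs:
    if config.cutoffs == "fixed":
        return ShellCutoffs(config.r_first, config.r_third)
    waters = [perceive_waters(f) for f in sample_frames]
    rdf = compute_rdf(sample_frames, waters,
                      r_max=min(f.box.min() for f in sample_frames) / 2 - 0.1)
    return locate_shell_cutoffs(rdf)


def _extract_freqs(config: RunConfig, ds: DatasetSpec, ds_index: int,
                   adapter: EngineAdapter) -> pd.DataFrame:
    """Carve, compute and assign frequencies for one dataset."""
    rows = []
    cutoffs: ShellCutoffs | None = None
    for replica, frames in _dataset_frames(config, ds, ds_index):
        waters = None
        for frame in frames:
            if waters is None:  # atom order is stable within a replica
                waters = perceive_waters(frame)
                if cutoffs is None:
                    cutoffs = _resolve_cutoffs(config, [frame])
                probe = ProbeSpec(
                    waters[config.probe_index],
                    waters[config.probe_index].h1 if config.deuterium_position == 1
                    else waters[config.probe_index].h2,
                )
            cluster = carve_cluster(
                frame, probe, cutoffs, mode=config.cluster_mode,
                n=config.cluster_size - 1, waters=waters, replica=replica,
            )
            inp = build_engine_input(cluster, config.deuterium_position)
            result = run_engine(inp, adapter)
            if not result.converged:
                for label in ("bend", "OD", "OH"):
                    rows.append((replica, frame.time_ps, label, np.nan, 0.0,
                                 cluster.n_first_shell, False))
                continue
            try:
                records = assign_probe_modes(result)
            except ModeAssignmentError:
                for label in ("bend", "OD", "OH"):
                    rows.append((replica, frame.time_ps, label, np.nan, 0.0,
                                 cluster.n_first_shell, False))
                continue
            for label, rec in records.items():
                rows.append((replica, frame.time_ps, label, rec.frequency,
                             rec.intensity, cluster.n_first_shell, True))
    return pd.DataFrame(rows, columns=FREQS_COLUMNS)


def _write_csv(df: pd.DataFrame, path: Path, header_line: str) -> None:
    with open(path, "w") as fh:
        fh.write(header_line + "\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all requested stages; returns the run manifest.

    Stage order per dataset: extract → frequencies → observables → FFCF;
    then one benchmark across datasets when a reference label is set and
    at least two datasets exist. A stage failure aborts with the failing
    stage named; outputs written so far are left in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    prov = f"# mdifm {__version__} config={chash} seed={config.seed}"
    adapter = _make_engine(config)

    summary_rows, tau_rows, subdist_rows, metric_rows = [], [], [], []
    outputs: list[str] = []
    stage = "init"
    try:
        for ds_index, ds in enumerate(config.datasets):
            stage = f"extract+freq[{ds.label}]"
            freqs = _extract_freqs(config, ds, ds_index, adapter)
            fpath = out / f"freqs_{_safe(ds.label)}.csv"
            _write_csv(freqs, fpath, prov)
            outputs.append(fpath.name)

            stage = f"analyze[{ds.label}]"
            usable = freqs[freqs["converged"]]
            n_excluded = int((~freqs["converged"]).sum()) // 3
            series_by_mode = series_from_dataframe(usable, config.stride_fs)
            for label, series in series_by_mode.items():
                summ = summarize(series)
                summary_rows.append({
                    "force_field": ds.label, "mode": label,
                    "omega0": summ.omega0, "omega0_err": summ.omega0_err,
                    "sigma": summ.sigma, "sigma_err": summ.sigma_err,
                    "N": summ.n, "n_excluded": n_excluded,
                })
                metric_rows += [
                    {"force_field": ds.label, "mode": label, "metric": "omega0",
                     "value": summ.omega0, "err": summ.omega0_err},
                    {"force_field": ds.label, "mode": label, "metric": "sigma",
                     "value": summ.sigma, "err": summ.sigma_err},
                ]
                subs = decompose_by_coordination(series, set(config.coordination_counts))
                for c, sl in sorted(subs.slices.items()):
                    subdist_rows.append({
                        "force_field": ds.label, "mode": label, "n_first_shell": c,
                        "fraction": sl.fraction, "omega0": sl.omega0,
                        "sigma": sl.sigma, "asymmetry": sl.asymmetry, "N": sl.n,
                    })

            stage = f"ffcf[{ds.label}]"
            ffcf_frames = []
            for label, series in series_by_mode.items():
                corr = compute_ffcf(series, config.max_lag_ps)
                ffcf_frames.append(pd.DataFrame({
                    "mode": label, "lag_ps": corr.lag_ps, "C": corr.c,
                    "n_pairs": corr.n_pairs,
                }))
                try:
                    fit = fit_biexponential(corr)
                    tau_c, tau_err = extract_tau_c(fit)
                    tau_rows.append({
                        "force_field": ds.label, "mode": label, "A1": fit.a1,
                        "tau1": fit.tau1, "A2": fit.a2, "tau_c": tau_c, "y0": fit.y0,
                        "R2": fit.r2, "tau_c_err": tau_err,
                    })
                    metric_rows.append({"force_field": ds.label, "mode": label,
                                        "metric": "tau_c", "value": tau_c,
                                        "err": tau_err})
                except (FitConvergenceError, ValueError) as err:
                    warnings.warn(f"FFCF fit failed for {ds.label}/{label}: {err}",
                                  stacklevel=2)
                    tau_rows.append({
                        "force_field": ds.label, "mode": label, "A1": np.nan,
                        "tau1": np.nan, "A2": np.nan, "tau_c": np.nan, "y0": np.nan,
                        "R2": np.nan, "tau_c_err": np.nan,
                    })
            fpath = out / f"ffcf_{_safe(ds.label)}.csv"
            _write_csv(pd.concat(ffcf_frames, ignore_index=True), fpath, prov)
            outputs.append(fpath.name)

        stage = "write-tables"
        for name, rows in (("summary.csv", summary_rows), ("subdist.csv", subdist_rows),
                           ("taus.csv", tau_rows)):
            _write_csv(pd.DataFrame(rows), out / name, prov)
            outputs.append(name)

        if config.reference is not None and len(config.datasets) >= 2:
            stage = "benchmark"
            metrics = metric_table([r for r in metric_rows if np.isfinite(r["value"])])
            # a metric that failed for any dataset (e.g. an unconverged FFCF
            # fit) is dropped from the comparison rather than aborting it
            n_cells = len(config.datasets) * metrics["mode"].nunique()
            complete = [m for m, grp in metrics.groupby("metric") if len(grp) == n_cells]
            dropped = sorted(set(metrics["metric"]) - set(complete))
            if dropped:
                warnings.warn(f"benchmark skips incomplete metrics: {dropped}", stacklevel=2)
            diffs, pairs = build_benchmark(metrics[metrics["metric"].isin(complete)],
                                           config.reference)
            _write_csv(diffs, out / "benchmark.csv", prov)
            _write_csv(pairs, out / "correlation_pairs.csv", prov)
            outputs += ["benchmark.csv", "correlation_pairs.csv"]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _safe(label: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in label)
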