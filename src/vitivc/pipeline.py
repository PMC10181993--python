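"""End-to-end orchestration: simulate -> fit -> aggregate -> cluster -> risk.

A :class:`RunConfig` fixes every knob (pressure grid, noise, optical
thresholds, cluster count, coverage threshold) and one seed; per-stage
sub-seeds are derived deterministically from it, so a run is reproducible
bit-for-bit.  :func:`run_all` executes the stages in dependency order,
writes all artefacts under the output directory and returns a
:class:`RunManifest` with a checksum for every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, clustering, io, risk, synthetic, vcfit


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str = "vitivc-run"
    seed: int = 0
    n_plants_per_variety: int = 4
    pressures: tuple[float, ...] = synthetic.DEFAULT_PRESSURES
    noise_cv: float = 0.05
    # optical stage
    optical_threshold: float = 5.0
    optical_min_area_px: int = 20
    # clustering / risk
    n_clusters: int = 4
    min_coverage: float = risk.DEFAULT_MIN_COVERAGE
    n_regions: int = 3
    # input files; when None the synthetic stage generates them
    sweeps_csv: str | None = None
    bearing_csv: str | None = None

    def __post_init__(self) -> None:
        if self.n_plants_per_variety < 1:
            raise ValueError("n_plants_per_variety must be >= 1")
        if np.any(np.diff(self.pressures) >= 0):
            raise ValueError("pressure grid must be strictly decreasing")
        if self.noise_cv < 0 or self.optical_threshold <= 0:
            raise ValueError("invalid noise/threshold settings")
        if self.n_clusters != 4:
            raise ValueError("the vulnerability classification is defined for 4 clusters")
        for f in (self.sweeps_csv, self.bearing_csv):
            if f is not None and not Path(f).exists():
                raise FileNotFoundError(f"input file not found: {f}")


@dataclass
class RunManifest:
    """Record of a pipeline run: stages executed, outputs and checksums."""

    seed: int
    version: str
    started: float
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # relpath -> sha256

    def add_output(self, out_dir: Path, path: Path) -> None:
        self.outputs[str(path.relative_to(out_dir))] = hashlib.sha256(
            path.read_bytes()
        ).hexdigest()


def _subseed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def make_fixtures(out_dir: str | Path, seed: int = 0, n_regions: int = 3,
                  n_plants: int = 4) -> dict[str, Path]:
    """Write a small demo dataset: sweeps, one image stack + psi timeline,
    vessels and a bearing table.  Deterministic per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    varieties = synthetic.reference_varieties()
    sweeps, truth = synthetic.gen_cohort(
        varieties, n_plants_per_variety=n_plants, noise_cv=0.05,
        seed=_subseed(seed, "sweeps"),
    )
    paths["sweeps"] = out / "sweeps.csv"
    io.write_sweeps(sweeps, paths["sweeps"])
    paths["sweeps_truth"] = out / "sweeps_truth.json"
    io.write_json(truth.to_dict(orient="records"), paths["sweeps_truth"])

    rng = np.random.default_rng(_subseed(seed, "stack"))
    events = [(int(f), 30, (int(rng.integers(5, 59)), int(rng.integers(5, 59))))
              for f in sorted(rng.choice(np.arange(2, 38), size=6, replace=False))]
    stack, stack_truth = synthetic.gen_dehydration_stack(
        40, (64, 64), events, background_noise_sd=0.5,
        seed=_subseed(seed, "stacknoise"), variety="Syrah", season="summer",
    )
    paths["stack"] = out / "stack.tif"
    io.write_stack(stack, paths["stack"])
    paths["stack_truth"] = out / "stack_truth.json"
    io.write_json(stack_truth, paths["stack_truth"])
    timeline = synthetic.gen_psi_timeline(-0.5, -4.0, duration_h=40 * 5 / 60.0)
    paths["psi"] = out / "psi.csv"
    io.write_timeline(timeline, paths["psi"])

    vessel_sets = []
    for i, vt in enumerate(varieties):
        vs, _ = synthetic.gen_vessels(
            60, seed=_subseed(seed, f"vessels{i}"),
            section_id=f"sec-{vt.variety_name}", variety=vt.variety_name,
        )
        vessel_sets.append(vs)
    paths["vessels"] = out / "vessels.csv"
    io.write_vessels(vessel_sets, paths["vessels"])

    bearing, bearing_truth = synthetic.gen_bearing_table(
        n_regions, [vt.variety_name for vt in varieties],
        uncovered_fraction_range=(0.0, 0.3), seed=_subseed(seed, "bearing"),
    )
    paths["bearing"] = out / "bearing.csv"
    bearing.to_csv(paths["bearing"], index=False)
    paths["bearing_truth"] = out / "bearing_truth.json"
    io.write_json(bearing_truth, paths["bearing_truth"])
    return paths


def run_all(config: RunConfig) -> RunManifest:
    """Execute the full pipeline under ``config``.

    Stages: simulate (skipped for inputs supplied in the config) -> PLC +
    sigmoid fits -> variety aggregation -> Ward clustering -> regional
    risk.  A failing stage aborts the run with the stage named; outputs of
    completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, version=__version__, started=time.time())
    # out_dir is where the copy sits; leaving it out keeps runs with the
    # same seed byte-identical regardless of destination
    config_dict = {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}
    io.write_json(config_dict, out / "config.json")
    manifest.add_output(out, out / "config.json")

    def stage(name: str):
        manifest.stages.append(name)

    try:
        stage("simulate")
        if config.sweeps_csv is None or config.bearing_csv is None:
            fixture_paths = make_fixtures(
                out / "inputs", seed=config.seed,
                n_regions=config.n_regions, n_plants=config.n_plants_per_variety,
            )
            sweeps_csv = config.sweeps_csv or fixture_paths["sweeps"]
            bearing_csv = config.bearing_csv or fixture_paths["bearing"]
            for p in fixture_paths.values():
                manifest.add_output(out, Path(p))
        else:
            sweeps_csv, bearing_csv = config.sweeps_csv, config.bearing_csv

        stage("fit")
        sweeps = io.read_sweeps(sweeps_csv)
        fits, qc = [], []
        for s in sweeps:
            curve = vcfit.compute_plc(s)
            try:
                fit = vcfit.fit_pammenter(curve)
            except vcfit.FitError as exc:
                qc.append(dict(plant_id=s.plant_id, refused=str(exc)))
                continue
            if curve.has_negative:
                qc.append(dict(plant_id=s.plant_id, note="negative PLC retained"))
            fits.append(fit)
        fit_df = vcfit.fits_to_frame(fits)
        fit_df.to_csv(out / "fits.csv", index=False)
        io.write_json(qc, out / "fit_qc.json")
        manifest.add_output(out, out / "fits.csv")
        manifest.add_output(out, out / "fit_qc.json")

        stage("aggregate")
        summary = vcfit.aggregate_variety(fit_df)
        summary.to_csv(out / "variety_summary.csv", index=False)
        manifest.add_output(out, out / "variety_summary.csv")

        stage("cluster")
        means = summary.rename(
            columns={"psi12_mean": "psi12", "psi50_mean": "psi50", "psi88_mean": "psi88"}
        )[["variety", "psi12", "psi50", "psi88"]]
        assignment = clustering.cluster_varieties(means, k=config.n_clusters)
        assignment.to_csv(out / "clusters.csv", index=False)
        manifest.add_output(out, out / "clusters.csv")

        stage("risk")
        bearing = io.read_bearing(bearing_csv)
        risks = risk.regional_risk(bearing, assignment, min_coverage=config.min_coverage)
        report, stats = risk.ri_report(risks)
        report.to_csv(out / "risks.csv", index=False)
        io.write_json(stats, out / "risk_summary.json")
        manifest.add_output(out, out / "risks.csv")
        manifest.add_output(out, out / "risk_summary.json")
    except Exception as exc:
        failed = manifest.stages[-1] if manifest.stages else "config"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    io.write_json(
        dict(seed=manifest.seed, version=manifest.version, started=manifest.started,
             stages=manifest.stages, outputs=manifest.outputs),
        out / "manifest.json",
    )
    return manifest
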