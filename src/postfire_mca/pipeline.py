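"""Configuration, orchestration and command-line interface.

`run_pipeline` turns a directory of standard input files (rasters as
ESRI ASCII grids, vectors as GeoJSON, tables as CSV) into the two
composite products - the soil-erosion-risk and vegetation-recovery maps
- plus banded versions, the Monte-Carlo weight-sensitivity study, and
the field validation report.  Every run writes a machine-readable log
stamped with a hash of the configuration actually used.

Input directory conventions (as written by ``synthgen``):
    dem.asc, pre_{blue,red,nir,swir}.asc, post_{...}.asc,
    perimeter.geojson, vegetation.geojson, fire_history.geojson,
    k_factor.asc, aridity.asc, scene_catalog.csv,
    judgments_ser.csv, judgments_vrp.csv, field_plots.csv
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import click
import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape as shapely_shape

from . import sensitivity as sens
from .ahp import (
    WeightVector,
    aggregate_weights,
    consistency_ratio,
    derive_weights,
    read_judgments_csv,
    write_weights_csv,
)
from .composite import classify_index
from .criteria import (
    ContinuousCriterionSpec,
    EROSION_THRESHOLDS,
    read_perimeters_geojson,
    read_vegetation_geojson,
)
from .errors import PipelineStageError
from .fieldval import (
    plot_erosion_score,
    plot_vegetation_recovery,
    read_plots_csv,
    sample_map_at_plots,
    scatter_plot,
    validate_predictions,
    write_validation_report,
)
from .raster import read_ascii_grid, write_ascii_grid
from .spectral import BandStack, classify_severity, read_scene_catalog, select_scene_pair
from .synthgen import SyntheticScenario, write_scenario_inputs
from .workflow import (
    AssessmentInputs,
    compute_criterion_layers,
    compute_indices,
)


@dataclass
class RunConfig:
    """Pipeline run settings; defaults reproduce the standard assessment."""

    input_dir: str
    output_dir: str
    seed: int = 0
    target_resolution: float = 10.0
    scenario: str = "averaged"  # or a participant id
    n_bands: int = 3
    p_levels: tuple[float, ...] = (0.1, 0.2, 0.3)
    n_reps: int = 1000
    overlap_threshold: float = 0.25
    # optional overrides: {"slope": {"min": 9, "max": 80}, ...}
    thresholds: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        if "p_levels" in raw:
            raw["p_levels"] = tuple(raw["p_levels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["p_levels"] = list(self.p_levels)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def erosion_thresholds(self) -> dict[str, ContinuousCriterionSpec]:
        specs = dict(EROSION_THRESHOLDS)
        for name, ov in self.thresholds.items():
            base = specs[name]
            specs[name] = ContinuousCriterionSpec(
                name,
                float(ov.get("min", base.min_threshold)),
                float(ov.get("max", base.max_threshold)),
                base.polarity,
            )
        return specs


def load_inputs(input_dir: str | Path) -> AssessmentInputs:
    """Read the standard input files into an :class:`AssessmentInputs`."""
    d = Path(input_dir)

    def stack(tag: str) -> BandStack:
        return BandStack(
            blue=read_ascii_grid(d / f"{tag}_blue.asc"),
            red=read_ascii_grid(d / f"{tag}_red.asc"),
            nir=read_ascii_grid(d / f"{tag}_nir.asc"),
            swir=read_ascii_grid(d / f"{tag}_swir.asc"),
        )

    with (d / "perimeter.geojson").open() as fh:
        fc = json.load(fh)
    feat = fc["features"][0]
    perimeter = shapely_shape(feat["geometry"])
    props = feat["properties"]
    return AssessmentInputs(
        dem=read_ascii_grid(d / "dem.asc"),
        pre_stack=stack("pre"),
        post_stack=stack("post"),
        perimeter=perimeter,
        fire_start=dt.date.fromisoformat(props["fire_start"]),
        fire_end=dt.date.fromisoformat(props["fire_end"]),
        vegetation=read_vegetation_geojson(d / "vegetation.geojson"),
        k_factor=read_ascii_grid(d / "k_factor.asc"),
        aridity=read_ascii_grid(d / "aridity.asc"),
        history_perimeters=read_perimeters_geojson(d / "fire_history.geojson"),
        fire_year=int(props.get("fire_year", dt.date.fromisoformat(props["fire_start"]).year)),
        catalog=read_scene_catalog(d / "scene_catalog.csv"),
    )


class _RunLog:
    def __init__(self, path: Path, config_hash: str):
        self.path = path
        self.config_hash = config_hash
        self.records: list[dict] = []

    def record(self, stage: str, **info):
        rec = {"stage": stage, "config_hash": self.config_hash, **info}
        self.records.append(rec)

    def flush(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with self.path.open("w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _weights_for_scenario(
    matrices, scenario: str
) -> tuple[WeightVector, dict[str, WeightVector]]:
    per_participant = {pid: derive_weights(m) for pid, m in matrices.items()}
    if scenario == "averaged":
        chosen = aggregate_weights(list(per_participant.values()))
    else:
        if scenario not in per_participant:
            raise KeyError(f"unknown participant {scenario!r}")
        chosen = per_participant[scenario]
    return chosen, per_participant


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage; returns the artifact paths.

    Deterministic given the configuration (including the seed); any stage
    failure is re-raised as :class:`PipelineStageError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.jsonl", config.config_hash())
    artifacts: dict[str, Path] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - stage boundary
                log.record(name, status="error", error=str(exc))
                log.flush()
                raise PipelineStageError(name, str(exc)) from exc

        return wrap

    inputs = stage("load_inputs")(lambda: load_inputs(config.input_dir))
    log.record("load_inputs", status="ok", input_dir=str(config.input_dir))

    def _scenes():
        pre, post = select_scene_pair(
            inputs.catalog, inputs.fire_start, inputs.fire_end
        )
        return pre, post

    pre_scenes, post_scenes = stage("scene_selection")(_scenes)
    log.record(
        "scene_selection",
        status="ok",
        pre=[s.scene_id for s in pre_scenes],
        post=[s.scene_id for s in post_scenes],
    )

    def _ahp():
        d = Path(config.input_dir)
        ser_m = read_judgments_csv(d / "judgments_ser.csv")
        vrp_m = read_judgments_csv(d / "judgments_vrp.csv")
        reports = {
            f"ser/{pid}": consistency_ratio(m) for pid, m in ser_m.items()
        } | {f"vrp/{pid}": consistency_ratio(m) for pid, m in vrp_m.items()}
        bad = [k for k, r in reports.items() if not r.acceptable]
        if bad:
            raise ValueError(f"inconsistent judgments (CR >= 0.1): {bad}")
        ser_w, ser_all = _weights_for_scenario(ser_m, config.scenario)
        vrp_w, vrp_all = _weights_for_scenario(vrp_m, config.scenario)
        return ser_w, vrp_w, ser_all, vrp_all, reports

    ser_w, vrp_w, ser_all, vrp_all, cr_reports = stage("ahp")(_ahp)
    log.record(
        "ahp",
        status="ok",
        scenario=config.scenario,
        ser_weights=ser_w.as_dict(),
        vrp_weights=vrp_w.as_dict(),
        consistency={k: round(r.cr, 6) for k, r in cr_reports.items()},
    )
    artifacts["weights_ser"] = write_weights_csv(
        {**ser_all, "averaged": aggregate_weights(list(ser_all.values()))},
        out / "weights_ser.csv",
    )
    artifacts["weights_vrp"] = write_weights_csv(
        {**vrp_all, "averaged": aggregate_weights(list(vrp_all.values()))},
        out / "weights_vrp.csv",
    )

    thresholds = config.erosion_thresholds()
    layers = stage("criteria")(
        lambda: compute_criterion_layers(
            inputs,
            target_resolution=config.target_resolution,
            erosion_thresholds=thresholds,
        )
    )
    log.record(
        "criteria",
        status="ok",
        grid=list(layers.template.shape),
        thresholds={
            n: [s.min_threshold, s.max_threshold] for n, s in thresholds.items()
        },
    )
    severity = classify_severity(layers.dnbr)
    artifacts["severity"] = write_ascii_grid(severity.classes, out / "severity.asc")
    artifacts["dnbr"] = write_ascii_grid(layers.dnbr, out / "dnbr.asc")

    ser_map, vrp_map = stage("compose")(
        lambda: compute_indices(layers, ser_w, vrp_w)
    )
    artifacts["ser"] = write_ascii_grid(ser_map.index, out / "ser.asc")
    artifacts["vrp"] = write_ascii_grid(vrp_map.index, out / "vrp.asc")
    artifacts["ser_bands"] = write_ascii_grid(
        classify_index(ser_map, config.n_bands), out / "ser_bands.asc"
    )
    artifacts["vrp_bands"] = write_ascii_grid(
        classify_index(vrp_map, config.n_bands), out / "vrp_bands.asc"
    )
    log.record(
        "compose",
        status="ok",
        ser_range=list(ser_map.value_range),
        vrp_range=list(vrp_map.value_range),
    )

    def _sensitivity():
        results = {}
        for kind, w in (("ser", ser_w), ("vrp", vrp_w)):
            def model(wv, _kind=kind):
                s, v = compute_indices(layers, wv if _kind == "ser" else ser_w,
                                       wv if _kind == "vrp" else vrp_w)
                return s if _kind == "ser" else v

            level_results = []
            for i, p in enumerate(config.p_levels):
                level_results.append(
                    sens.run_sensitivity(
                        model, w, p, n_reps=config.n_reps,
                        rng_seed=np.random.default_rng(
                            [config.seed, {"ser": 100, "vrp": 200}[kind], i]
                        ),
                    )
                )
            results[kind] = level_results
        return results

    sens_results = stage("sensitivity")(_sensitivity) if config.p_levels else {}
    for kind, level_results in sens_results.items():
        artifacts[f"sensitivity_{kind}"] = sens.write_sensitivity_csv(
            level_results, out / f"sensitivity_{kind}.csv"
        )
        report = sens.stability_report(
            level_results, overlap_threshold=config.overlap_threshold
        )
        log.record(
            "sensitivity",
            status="ok",
            model=kind.upper(),
            stable_p=report.stable_p,
            distinguishable={str(p): v for p, v in report.distinguishable_at.items()},
        )
        if config.make_plots:
            for r in level_results:
                artifacts[f"sens_plot_{kind}_{r.perturbation_fraction}"] = (
                    sens.plot_weight_distributions(
                        r, out / f"sensitivity_{kind}_p{int(r.perturbation_fraction * 100)}.png"
                    )
                )

    def _validate():
        plots = read_plots_csv(Path(config.input_dir) / "field_plots.csv")
        reports = {}
        for kind, cim, observed in (
            ("ser", ser_map, [plot_erosion_score(p.erosion_observations) for p in plots]),
            (
                "vrp",
                vrp_map,
                [
                    plot_vegetation_recovery(p.shrub_cover_pct, p.grass_cover_pct)
                    for p in plots
                ],
            ),
        ):
            sampled = sample_map_at_plots(cim, plots)
            predicted = sampled["value"].to_numpy()
            rep = validate_predictions(observed, predicted, plots)
            artifacts[f"validation_{kind}"] = write_validation_report(
                rep, out / f"validation_{kind}.csv"
            )
            if config.make_plots:
                artifacts[f"scatter_{kind}"] = scatter_plot(
                    observed, predicted, plots,
                    out / f"validation_{kind}.png",
                    title=f"{kind.upper()}: field vs map",
                )
            reports[kind] = rep
        return reports

    val_reports = stage("validate")(_validate)
    for kind, rep in val_reports.items():
        log.record(
            "validate",
            status="ok",
            model=kind.upper(),
            n_plots=rep.n_plots,
            spearman_rho=round(rep.spearman_rho, 6),
            r_squared=round(rep.r_squared, 6),
        )

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "scenario": config.scenario,
        "ser_weights": ser_w.as_dict(),
        "vrp_weights": vrp_w.as_dict(),
        "pre_scenes": [s.scene_id for s in pre_scenes],
        "post_scenes": [s.scene_id for s in post_scenes],
    }
    artifacts["provenance"] = out / "provenance.yaml"
    with artifacts["provenance"].open("w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)
    log.flush()
    artifacts["run_log"] = log.path
    return artifacts


# ---------------------------------------------------------------------------
# CLI


@click.group()
def cli():
    """Participatory multi-criteria post-fire assessment toolkit."""


@cli.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "outdir", required=True, type=click.Path())
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="optional scenario YAML overriding generator defaults")
def synth(seed, outdir, config_path):
    """Generate a synthetic input directory."""
    kwargs = {}
    if config_path:
        with open(config_path) as fh:
            kwargs = yaml.safe_load(fh) or {}
    scenario = SyntheticScenario(seed=seed, **kwargs)
    paths = write_scenario_inputs(scenario, outdir)
    click.echo(f"wrote {len(paths)} input files to {outdir}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--inputs", "input_dir", type=click.Path(exists=True), default=None)
@click.option("--out", "output_dir", type=click.Path(), default=None)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--participant", default=None, help="use one participant's weights")
@click.option("--averaged", "averaged", is_flag=True, default=False,
              help="use the averaged ('democratic') weights (default)")
def run(config_path, input_dir, output_dir, seed, participant, averaged):
    """Run the full assessment pipeline."""
    if config_path:
        config = RunConfig.from_yaml(config_path)
    else:
        if not (input_dir and output_dir):
            raise click.UsageError("provide --config or both --inputs and --out")
        config = RunConfig(input_dir=input_dir, output_dir=output_dir, seed=seed)
    if participant:
        config.scenario = participant
    elif averaged:
        config.scenario = "averaged"
    artifacts = run_pipeline(config)
    click.echo(f"pipeline complete: {len(artifacts)} artifacts in {config.output_dir}")


@cli.command("ahp")
@click.option("--judgments", required=True, type=click.Path(exists=True))
@click.option("--out", "out_csv", required=True, type=click.Path())
def ahp_cmd(judgments, out_csv):
    """Derive per-participant and averaged weights from a judgments CSV."""
    matrices = read_judgments_csv(judgments)
    weights = {pid: derive_weights(m) for pid, m in matrices.items()}
    for pid, m in matrices.items():
        rep = consistency_ratio(m)
        click.echo(f"{pid}: CR={rep.cr:.4f} {'ok' if rep.acceptable else 'INCONSISTENT'}")
    weights["averaged"] = aggregate_weights(list(weights.values()))
    write_weights_csv(weights, out_csv)
    click.echo(f"wrote {out_csv}")


@cli.command()
@click.option("--inputs", "input_dir", required=True, type=click.Path(exists=True))
@click.option("--out", "outdir", required=True, type=click.Path())
def severity(input_dir, outdir):
    """Compute dNBR and the burn-severity classification."""
    from .spectral import compute_dnbr, compute_nbr

    inputs = load_inputs(input_dir)
    pre, post = select_scene_pair(inputs.catalog, inputs.fire_start, inputs.fire_end)
    dnbr = compute_dnbr(compute_nbr(inputs.pre_stack), compute_nbr(inputs.post_stack))
    sev = classify_severity(dnbr)
    out = Path(outdir)
    write_ascii_grid(dnbr, out / "dnbr.asc")
    write_ascii_grid(sev.classes, out / "severity.asc")
    click.echo(
        f"scenes pre={[s.scene_id for s in pre]} post={[s.scene_id for s in post]}; "
        f"wrote dnbr.asc, severity.asc"
    )


@cli.command("criteria")
@click.option("--inputs", "input_dir", required=True, type=click.Path(exists=True))
@click.option("--out", "outdir", required=True, type=click.Path())
@click.option("--resolution", type=float, default=10.0, show_default=True)
def criteria_cmd(input_dir, outdir, resolution):
    """Write all normalized/scored criterion layers."""
    inputs = load_inputs(input_dir)
    layers = compute_criterion_layers(inputs, target_resolution=resolution)
    out = Path(outdir)
    for name, r in {**layers.ser_layers(), **layers.vrp_layers()}.items():
        write_ascii_grid(r, out / f"criterion_{name}.asc")
    write_ascii_grid(layers.mask, out / "mask.asc")
    click.echo(f"wrote criterion layers to {outdir}")


@cli.command()
@click.option("--inputs", "input_dir", required=True, type=click.Path(exists=True))
@click.option("--out", "outdir", required=True, type=click.Path())
@click.option("--participant", default="averaged", show_default=True)
def compose(input_dir, outdir, participant):
    """Compute the SER and VRP composite maps."""
    config = RunConfig(
        input_dir=input_dir, output_dir=outdir, scenario=participant,
        p_levels=(), make_plots=False,
    )
    run_pipeline(config)
    click.echo(f"wrote composites to {outdir}")


@cli.command("sensitivity")
@click.option("--inputs", "input_dir", required=True, type=click.Path(exists=True))
@click.option("--out", "outdir", required=True, type=click.Path())
@click.option("--seed", type=int, required=True)
@click.option("--n-reps", type=int, default=1000, show_default=True)
@click.option("--p", "p_levels", type=float, multiple=True, default=(0.1, 0.2, 0.3),
              show_default=True)
def sensitivity_cmd(input_dir, outdir, seed, n_reps, p_levels):
    """Monte-Carlo weight sensitivity for both composite models."""
    config = RunConfig(
        input_dir=input_dir, output_dir=outdir, seed=seed,
        p_levels=tuple(p_levels), n_reps=n_reps,
    )
    run_pipeline(config)
    click.echo(f"wrote sensitivity results to {outdir}")


@cli.command()
@click.option("--inputs", "input_dir", required=True, type=click.Path(exists=True))
@click.option("--out", "outdir", required=True, type=click.Path())
def validate(input_dir, outdir):
    """Field-plot validation of the composite maps."""
    config = RunConfig(input_dir=input_dir, output_dir=outdir, p_levels=())
    run_pipeline(config)
    click.echo(f"wrote validation reports to {outdir}")


if __name__ == "__main__":
    cli()
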