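"""Config-driven end-to-end runs: simulate an array, quantify it, compare.

The experiment config is one YAML document describing the spot layout, the
per-condition probes (protein bond strength + reference duplex), the force
ramp, optics/noise, and the analysis thresholds.  One master seed makes the
whole run reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from mfassay import __version__
from mfassay.bond_kinetics import (
    BellBond,
    ForceRamp,
    SerialProbe,
    bond_from_characteristic_force,
)
from mfassay.quantify import (
    QuantifyConfig,
    SpotResult,
    aggregate_condition,
    compare_all_conditions,
    quantify_spot,
)
from mfassay.reference_catalog import (
    DEFAULT_LIGANDS,
    DNAReference,
    StabilizerLigand,
    effective_reference_bond,
)
from mfassay.synthetic_images import (
    CHANNELS,
    ArrayExperiment,
    GaussianIllumination,
    NoiseModel,
    OpticalModel,
    SpotImageSet,
    circular_spot_mask,
    simulate_array_experiment,
)

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "load_config",
    "run_simulate",
    "run_quantify",
    "QuantifyRun",
]


class ConfigError(ValueError):
    """Invalid experiment configuration; the message names the field path."""


@dataclass
class ExperimentConfig:
    """Validated, materialized experiment description."""

    seed: int
    layout: list[list[str | None]]
    probes: dict[str, SerialProbe]
    coupling_efficiency: dict[str, float]
    ramp: ForceRamp
    optical: OpticalModel
    noise: NoiseModel
    shape: tuple[int, int] = (128, 128)
    probe_density: float = 50.0
    analysis: QuantifyConfig = field(default_factory=QuantifyConfig)
    raw: dict = field(default_factory=dict)


def _require(mapping: Mapping, key: str, path: str) -> Any:
    if key not in mapping:
        raise ConfigError(f"missing required field '{path}.{key}'")
    return mapping[key]


def _build_ligand(spec: Any, path: str) -> StabilizerLigand:
    if isinstance(spec, str):
        if spec not in DEFAULT_LIGANDS:
            raise ConfigError(
                f"{path}: unknown ligand '{spec}' "
                f"(known: {sorted(DEFAULT_LIGANDS)})"
            )
        return DEFAULT_LIGANDS[spec]
    return StabilizerLigand(
        name=_require(spec, "name", path),
        kd_pM=_require(spec, "kd_pM", path),
        concentration_uM=_require(spec, "concentration_uM", path),
        delta_force=_require(spec, "delta_force", path),
    )


def _build_reference(name: str, spec: Mapping, path: str) -> DNAReference:
    ligand = spec.get("ligand")
    return DNAReference(
        name=name,
        length_bp=int(_require(spec, "length_bp", path)),
        geometry=_require(spec, "geometry", path),
        propynyl_count=int(spec.get("propynyl_count", 0)),
        ligand=_build_ligand(ligand, f"{path}.ligand") if ligand else None,
        sequence=spec.get("sequence"),
        complement=spec.get("complement"),
    )


def load_config(source: str | Path | Mapping) -> ExperimentConfig:
    """Parse and validate a YAML config file (or an equivalent mapping)."""
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    try:
        seed = int(_require(raw, "seed", "$"))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"$.seed must be an integer: {exc}") from None

    ramp_spec = raw.get("ramp", {})
    try:
        ramp = ForceRamp(
            loading_rate=ramp_spec.get("loading_rate"),
            retraction_speed=ramp_spec.get("retraction_speed", 1.0),
            effective_stiffness=ramp_spec.get("effective_stiffness", 100.0),
            kT=ramp_spec.get("kT", 4.11),
        )
    except ValueError as exc:
        raise ConfigError(f"$.ramp: {exc}") from None

    dx = float(raw.get("bond_width_nm", 1.0))

    references: dict[str, DNAReference] = {}
    for name, spec in (raw.get("references") or {}).items():
        try:
            references[name] = _build_reference(name, spec, f"$.references.{name}")
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"$.references.{name}: {exc}") from None

    probes: dict[str, SerialProbe] = {}
    coupling: dict[str, float] = {}
    cond_specs = raw.get("conditions") or {}
    for name, spec in cond_specs.items():
        path = f"$.conditions.{name}"
        ref_name = _require(spec, "reference", path)
        if ref_name not in references:
            raise ConfigError(f"{path}.reference: unknown reference '{ref_name}'")
        reference_bond = effective_reference_bond(references[ref_name], ramp, dx=dx)
        if "protein_bond" in spec:
            pb = spec["protein_bond"]
            protein_bond = BellBond(
                k0=float(_require(pb, "k0", f"{path}.protein_bond")),
                dx=float(_require(pb, "dx", f"{path}.protein_bond")),
                label=name,
            )
        elif "protein_force" in spec:
            protein_bond = bond_from_characteristic_force(
                float(spec["protein_force"]), ramp, dx=dx, label=name
            )
        else:
            raise ConfigError(
                f"{path}: needs either 'protein_force' or 'protein_bond'"
            )
        probes[name] = SerialProbe(
            protein_bond=protein_bond, reference_bond=reference_bond
        )
        coupling[name] = float(spec.get("coupling_efficiency", 0.8))
        if not 0.0 <= coupling[name] <= 1.0:
            raise ConfigError(f"{path}.coupling_efficiency must be in [0, 1]")

    layout_spec = raw.get("layout")
    if not layout_spec:
        raise ConfigError("missing required field '$.layout'")
    layout: list[list[str | None]] = []
    for r, row in enumerate(layout_spec):
        out_row: list[str | None] = []
        for c, cell in enumerate(row):
            if cell in (None, "", "~"):
                out_row.append(None)
            elif cell not in probes:
                raise ConfigError(
                    f"$.layout[{r}][{c}]: condition '{cell}' is not defined "
                    f"under $.conditions"
                )
            else:
                out_row.append(cell)
        layout.append(out_row)
    if len(layout) > 4 or any(len(row) > 4 for row in layout):
        raise ConfigError("$.layout must be at most 4x4")

    optical_spec = dict(raw.get("optical") or {})
    illum_spec = optical_spec.pop("illumination", None) or {}
    illumination = GaussianIllumination(
        center=tuple(illum_spec["center"]) if illum_spec.get("center") else None,
        sigma=tuple(illum_spec["sigma"]) if illum_spec.get("sigma") else None,
        amplitude=float(illum_spec.get("amplitude", 1.0)),
    )
    try:
        optical = OpticalModel(illumination=illumination, **optical_spec)
        noise = NoiseModel(**(raw.get("noise") or {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"$.optical/$.noise: {exc}") from None

    image_spec = raw.get("image") or {}
    shape = tuple(image_spec.get("shape", (128, 128)))
    density = float(image_spec.get("probe_density", 50.0))

    try:
        analysis = QuantifyConfig(**(raw.get("analysis") or {}))
    except TypeError as exc:
        raise ConfigError(f"$.analysis: {exc}") from None

    return ExperimentConfig(
        seed=seed,
        layout=layout,
        probes=probes,
        coupling_efficiency=coupling,
        ramp=ramp,
        optical=optical,
        noise=noise,
        shape=shape,  # type: ignore[arg-type]
        probe_density=density,
        analysis=analysis,
        raw=raw,
    )


def _provenance(config: ExperimentConfig) -> dict:
    blob = json.dumps(config.raw, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "mfassay_version": __version__,
        "numpy_version": np.__version__,
    }


def run_simulate(config: ExperimentConfig, out_dir: str | Path) -> ArrayExperiment:
    """Simulate the configured array into ``out_dir`` (images + tables)."""
    out_dir = Path(out_dir)
    experiment = simulate_array_experiment(
        layout=config.layout,
        probes=config.probes,
        ramp=config.ramp,
        optical=config.optical,
        noise=config.noise,
        seed=config.seed,
        coupling_efficiency=config.coupling_efficiency,
        probe_density=config.probe_density,
        shape=config.shape,
        out_dir=out_dir,
    )
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(_provenance(config), fh, indent=2)
    return experiment


@dataclass
class QuantifyRun:
    """Outputs of a quantification pass over one manifest."""

    results: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    spot_results: list[SpotResult]
    errors: dict[str, str]


def load_spot_imageset(
    manifest_row: Mapping, base_dir: Path, spot_radius: float | None = None
) -> SpotImageSet:
    """Read the four TIFF channels named by one manifest row."""
    images = {}
    for channel in CHANNELS:
        path = base_dir / str(manifest_row[channel])
        if not path.exists():
            raise FileNotFoundError(f"missing image file: {path}")
        try:
            images[channel] = tifffile.imread(path)
        except Exception as exc:
            raise ValueError(f"malformed TIFF {path}: {exc}") from exc
    shape = images["red_start"].shape
    return SpotImageSet(
        spot_mask=circular_spot_mask(shape, radius=spot_radius),
        metadata={
            "spot_id": manifest_row.get("spot_id", ""),
            "condition": manifest_row.get("condition", ""),
        },
        **images,
    )


def run_quantify(
    manifest: str | Path | pd.DataFrame,
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
) -> QuantifyRun:
    """Quantify every spot of a manifest; aggregate and compare conditions.

    Per-spot failures are collected (not fatal here) and surfaced in
    ``errors``; the CLI turns a non-empty error dict into a non-zero exit.
    """
    if isinstance(manifest, pd.DataFrame):
        table = manifest.copy()
        base_dir = Path(".")
    else:
        manifest_path = Path(manifest)
        table = pd.read_csv(manifest_path)
        base_dir = manifest_path.parent
    if table.empty:
        raise ValueError("manifest is empty: nothing to quantify")

    spot_results: list[SpotResult] = []
    errors: dict[str, str] = {}
    for _, row in table.iterrows():
        spot_id = str(row.get("spot_id", ""))
        try:
            image_set = load_spot_imageset(row, base_dir)
            spot_results.append(quantify_spot(image_set, config.analysis))
        except (FileNotFoundError, ValueError) as exc:
            errors[spot_id] = str(exc)

    results = pd.DataFrame(
        [
            {
                "spot_id": s.spot_id,
                "condition": s.condition,
                "nf": s.nf,
                "nf_sigma": s.nf_sigma,
                "ce": s.coupling_efficiency,
                "n_pixels": s.n_pixels,
                "fit_ok": s.fit_ok,
                "valid": s.valid,
            }
            for s in spot_results
        ]
    )

    summaries_list = []
    for condition in sorted({s.condition for s in spot_results}):
        group = [s for s in spot_results if s.condition == condition]
        if any(s.valid for s in group):
            summaries_list.append(aggregate_condition(group, condition))
    summaries = pd.DataFrame(
        [
            {
                "condition": s.condition,
                "mean_nf": s.mean_nf,
                "sd_nf": s.sd_nf,
                "n_spots": s.n_spots,
                "n_invalid": s.n_invalid,
            }
            for s in summaries_list
        ]
    )

    comparisons = pd.DataFrame(
        [
            {
                "condition_a": c.condition_a,
                "condition_b": c.condition_b,
                "delta": c.delta,
                "max_deviation": c.max_deviation,
                "distinguishable": c.distinguishable,
            }
            for c in compare_all_conditions(summaries_list)
        ]
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "results.csv", index=False)
        summaries.to_csv(out_dir / "summaries.csv", index=False)
        comparisons.to_csv(out_dir / "comparisons.csv", index=False)
        if errors:
            with open(out_dir / "errors.json", "w") as fh:
                json.dump(errors, fh, indent=2)

    return QuantifyRun(results, summaries, comparisons, spot_results, errors)
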