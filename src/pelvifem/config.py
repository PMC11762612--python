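"""Run configuration (validated), pipeline driver and output bundle."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import fileio
from .analysis import (STANCE_CASES, ComparisonResult, _config_hash,
                       compare_constructs, prepare_inputs,
                       run_validation_loads)
from .materials import MappingConstants
from .phantom import PhantomParams


class PhantomConfig(BaseModel):
    sacrum_width: float = 50.0
    sacrum_height: float = 60.0
    sacrum_depth: float = 30.0
    ilium_width: float = 30.0
    ilium_depth: float = 70.0
    ilium_height: float = 90.0
    cartilage_thickness: float = 3.0
    pubic_body_width: float = 7.0
    ramus_section: float = 12.0
    hu_cortical: float = Field(1800.0, ge=220.0, le=2000.0)
    hu_trabecular: float = Field(300.0, ge=220.0, le=2000.0)
    hu_noise_sd: float = Field(100.0, ge=0.0)
    target_edge_length: float = Field(5.0, ge=1.0, le=5.0)

    @field_validator("sacrum_width", "sacrum_height", "sacrum_depth",
                     "ilium_width", "ilium_depth", "ilium_height",
                     "cartilage_thickness", "pubic_body_width", "ramus_section")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("dimensions must be positive")
        return v

    def to_params(self, seed: int) -> PhantomParams:
        return PhantomParams(rng_seed=seed, **self.model_dump())


class MaterialConfig(BaseModel):
    a: float = 0.00032362
    b: float = 1.0
    c: float = 1958.6
    p: float = 2.33
    hu_min: float = 220.0
    hu_max: float = 2000.0
    E_min: float = 200.0
    E_max: float = 6530.0
    bin_width: float = Field(5.0, gt=0.0)
    rho_cap: float = 1.8

    def to_constants(self) -> MappingConstants:
        return MappingConstants(**self.model_dump())


class RunConfig(BaseModel):
    """Schema-validated configuration of the full pipeline."""

    phantom: PhantomConfig = PhantomConfig()
    materials: MaterialConfig = MaterialConfig()
    ligament_source: str = "eichenseer+shi"
    breakpoint_strain: float = Field(0.10, gt=0.0)
    injured_side: str = "right"
    variants: list = ["USI", "BSI", "TSI"]
    load_cases: list = list(STANCE_CASES)
    fracture_contact: bool = False
    out_dir: str = "pelvifem_out"
    seed: int = 0

    @field_validator("injured_side")
    @classmethod
    def _side(cls, v):
        if v not in ("left", "right"):
            raise ValueError("injured_side must be 'left' or 'right'")
        return v

    @field_validator("variants")
    @classmethod
    def _variants(cls, v):
        bad = set(v) - {"USI", "BSI", "TSI"}
        if bad:
            raise ValueError(f"unknown construct variants {sorted(bad)}")
        return v

    @staticmethod
    def from_file(path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return RunConfig.model_validate(data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute phantom -> materials -> springs -> fracture -> fixation ->
    solve -> reports; write the output bundle; return paths and results."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    t0 = time.time()
    inputs = prepare_inputs(
        params=config.phantom.to_params(config.seed),
        injured_side=config.injured_side,
        ligament_source=config.ligament_source,
        breakpoint_strain=config.breakpoint_strain)
    timings["prepare_inputs_s"] = round(time.time() - t0, 3)

    from .materials import assign_materials
    materials = assign_materials(inputs.intact, inputs.hu,
                                 config.materials.to_constants())
    fileio.write_vtu(inputs.intact, out / "phantom.vtu",
                     cell_data={"E_MPa": materials.E[:, None],
                                "HU": inputs.hu[:, None]})
    fileio.write_hu_csv(inputs.hu, out / "hu_table.csv")
    fileio.write_material_csv(inputs.intact, materials, out / "materials.csv")

    t0 = time.time()
    result = compare_constructs(inputs, variants=tuple(config.variants),
                                load_cases=tuple(config.load_cases),
                                fracture_contact=config.fracture_contact)
    timings["compare_constructs_s"] = round(time.time() - t0, 3)

    (out / "gap_report.csv").write_text(result.gap_csv())
    (out / "stress_report.csv").write_text(result.stress_csv())
    manifest = dict(result.manifest)
    # hash covers everything that affects the numbers (not the output path)
    manifest["config_hash"] = _config_hash(
        config.model_dump(exclude={"out_dir"}))
    manifest["timings"] = timings
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["wall_time_s"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return {"out_dir": str(out), "result": result, "manifest": manifest,
            "paths": {p.name: str(p) for p in sorted(out.iterdir())}}
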