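"""YAML configuration loading for the pipeline and cohort generator."""

from __future__ import annotations

from pathlib import Path

import yaml

from .pipeline import PipelineConfig, default_cohort_config
from .simulate import BlockSpec, CohortConfig, EnvSpec


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    blocks = [BlockSpec(**{**b, "effect": tuple(b["effect"]) if b.get("effect") else None})
              for b in d.pop("blocks", [])]
    env = [EnvSpec(**e) for e in d.pop("env", [])]
    if "maf_range" in d:
        d["maf_range"] = tuple(d["maf_range"])
    return CohortConfig(blocks=blocks, env=env, **d)


def pipeline_config_from_yaml(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort = (
        cohort_config_from_dict(raw.pop("cohort"))
        if "cohort" in raw
        else default_cohort_config()
    )
    for key in ("genotype_k", "phenotype_k", "env_k"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(cohort=cohort, **raw)
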