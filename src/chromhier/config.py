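"""Run configuration: strict YAML schema holding every pipeline constant.

All the numeric conventions of the analysis live here as overridable
defaults — the 100 kb compartment / 10 kb TAD / {10, 25} kb loop
resolutions, the 50 Mb macro-chromosome threshold, the 40 kb boundary pad,
the 1 Mb loop-distance cap, the FPKM > 20 high-expression cut, the
|lfc| > 1 & Padj < 0.01 DEG thresholds, the loop FDR, and the 1e9 read-pair
library target. Unknown keys are rejected.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticConfig(_Strict):
    n_mac: int = 0
    n_mic: int = 3
    mac_range: tuple[int, int] = (60_000_000, 160_000_000)
    mic_range: tuple[int, int] = (8_000_000, 12_000_000)
    comp_block_bp: int = 1_000_000
    n_boundaries_per_chrom: int = 8
    n_loops: int = 50
    max_loop_span: int = 1_000_000
    min_loop_span: int = 100_000
    switch_frac: float = 0.2
    p_a: float = 0.7
    depth: float = 1e7
    decay_alpha: float = 1.0
    comp_strength: float = 2.5
    tad_strength: float = 2.0
    loop_strength: float = 8.0
    trans_level: float = 0.01
    mic_trans_boost: float = 2.0
    genes_per_mb_a: float = 8.0
    genes_per_mb_b: float = 3.0
    lfc_switch_effect: float = 1.5
    dispersion: float = 0.1
    a_bias: float = 0.9
    peak_len_mean: int = 1_500
    n_peaks: int = 500
    mark_expression_r: tuple[float, float] = (0.56, -0.45)


class Resolutions(_Strict):
    compartment: int = 100_000
    tad: int = 10_000
    loop: tuple[int, ...] = (10_000, 25_000)

    @model_validator(mode="after")
    def _multiples_of_1kb(self):
        vals = [self.compartment, self.tad, *self.loop]
        if any(v <= 0 or v % 1000 != 0 for v in vals):
            raise ValueError("resolutions must be positive multiples of 1 kb")
        return self


class Thresholds(_Strict):
    mac: int = 50_000_000
    pad: int = 40_000
    max_loop_dist: int = 1_000_000
    insulation_window: int = 100_000
    delta_window: int = 100_000
    min_boundary_strength: float = 0.1
    fpkm_high: float = 20.0
    lfc: float = 1.0
    padj: float = 0.01
    fdr: float = 0.1
    min_fold: float = 1.5
    target_total: float = 1e9

    @field_validator("mac", "pad", "max_loop_dist", "insulation_window",
                     "delta_window")
    @classmethod
    def _bp_multiple_of_1kb(cls, v, info):
        if v <= 0 or v % 1000 != 0:
            raise ValueError(f"{info.field_name} must be a positive multiple of 1 kb")
        return v


class InputPaths(_Strict):
    contacts: Optional[str] = None
    contacts2: Optional[str] = None
    chromsizes: Optional[str] = None
    genes: Optional[str] = None
    expression: Optional[str] = None
    h3ac_peaks: Optional[str] = None
    h3k27me3_peaks: Optional[str] = None


class RunConfig(_Strict):
    seed: int = 0
    synthetic: Optional[SyntheticConfig] = SyntheticConfig()
    inputs: InputPaths = InputPaths()
    resolutions: Resolutions = Resolutions()
    thresholds: Thresholds = Thresholds()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        return cls.model_validate(obj)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
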