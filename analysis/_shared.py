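"""Shared plumbing for the numbered analysis drivers.

Stage outputs (genotype VCFs, per-individual tables) live under scratch/ — they are
large and regenerable.  Each driver copies only its small headline tables into
results/ and prints what it found.
"""

from __future__ import annotations

import shutil
from pathlib import Path

from lifemr.pipeline import PipelineConfig, validate_config

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"
CONFIG = Path(__file__).resolve().parent / "config.yaml"
CONFIG_T2D = Path(__file__).resolve().parent / "config_t2d.yaml"


def load_config(path: Path = CONFIG) -> PipelineConfig:
    return validate_config(path)


def workdir(name: str = "main") -> Path:
    d = SCRATCH / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def publish(src: Path, rename: str | None = None) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    dst = RESULTS / (rename or src.name)
    shutil.copyfile(src, dst)
    return dst
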