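"""Shared run configuration for the numbered analysis scripts.

The pipeline workspace (genome, tracks, matrices) lives under scratch/,
which is disposable; each script copies its headline tables into results/.
"""

import logging
import shutil
from pathlib import Path

from chromfate.pipeline import RunConfig, Workspace

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "pipeline_run"
RESULTS = ROOT / "results"
SEED = 1


def get_config() -> RunConfig:
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    return RunConfig(out_dir=str(RUN_DIR), seed=SEED)


def get_workspace() -> Workspace:
    return Workspace(RUN_DIR)


def publish(*relpaths: str) -> None:
    """Copy workspace tables into results/ for the record."""
    RESULTS.mkdir(exist_ok=True)
    for rel in relpaths:
        src = RUN_DIR / rel
        shutil.copy(src, RESULTS / Path(rel).name)
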