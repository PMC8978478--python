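"""Shared configuration of the analysis scripts: one run directory, one seed."""

from pathlib import Path

from potholes import RunConfig

RUN_DIR = Path("results/run")
CONFIG = RunConfig(out_dir=str(RUN_DIR), n_subjects=100, seed=1)
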