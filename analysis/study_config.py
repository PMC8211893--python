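"""Shared configuration for the numbered analysis scripts.

The study runs at the default synthetic conditions: a balanced 2 x 2 cohort
(25 subjects per group x gender cell), a female-only 0.8-mm inward effect
on the superior genu, K = 100 template points, 2,000 permutations.  Every
script drives the cached pipeline, so they can be run in order or
individually (completed stages are skipped via content hashes).
"""

import argparse
from pathlib import Path

from ccshape.lddmm import RegistrationConfig
from ccshape.pipeline import RunConfig
from ccshape.synthetic import SyntheticConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"


def study_config(seed: int = 1) -> RunConfig:
    return RunConfig(
        out_dir=str(RESULTS),
        synthetic=SyntheticConfig(n_per_cell=25, seed=seed),
        registration=RegistrationConfig(max_iters=150),
        k_points=100,
        n_perm=2000,
        seed=seed,
    )


def parse_seed() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    return ap.parse_args().seed
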