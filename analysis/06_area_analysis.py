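"""Global area comparisons for CC, gCC, bCC, sCC by scope.

Prints the adjusted group comparisons (permutation p, Cohen's d, FES - HC
difference) for the whole cohort and within each gender.
"""

import json

import pandas as pd

from ccshape.pipeline import run_pipeline
from study_config import RESULTS, parse_seed, study_config


def main():
    cfg = study_config(parse_seed())
    run_pipeline(cfg)
    summary = json.loads((RESULTS / "stats_summary.json").read_text())
    print("gender x group interaction on areas (p):",
          {k: round(v, 4) for k, v in summary["interaction"]["area_p"].items()})
    for scope in ("all", "female", "male"):
        df = pd.read_csv(RESULTS / f"areas_{scope}.csv")
        print(f"\nscope {scope}:")
        cols = ["structure", "hc_mean", "fes_mean", "p_value", "cohens_d",
                "group_difference"]
        print(df[cols].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
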