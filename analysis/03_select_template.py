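"""Select the cohort template curve (area closest to the cohort mean)."""

import json

import pandas as pd

from ccshape.pipeline import run_pipeline
from study_config import RESULTS, parse_seed, study_config


def main():
    cfg = study_config(parse_seed())
    run_pipeline(cfg)
    meta = json.loads((RESULTS / "template.json").read_text())
    sel = meta["selection"]
    tpl = pd.read_csv(RESULTS / "template.csv")
    sid = tpl.subject_id.iloc[0]
    print(f"template subject: {sid}")
    print(f"cohort mean area: {sel['mean_area_mm2']:.1f} mm^2; "
          f"template deviation {sel['abs_deviation'][sid]:.2f} mm^2")
    print(f"template resampled to {len(tpl)} points "
          f"({(tpl.region == 'gCC').sum()} genu, {(tpl.region == 'bCC').sum()} body, "
          f"{(tpl.region == 'sCC').sum()} splenium)")


if __name__ == "__main__":
    main()
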