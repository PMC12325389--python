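"""Univariate ACE / AE / CE / E model ladders per preset.

Each submodel is compared to the full ACE model by delta -2LL; the preferred
model (lowest AIC) should match the generating structure: AE for the
AE-dominant presets, ACE for the cortical-surface-like preset.
"""

from pathlib import Path

from twinprs import comparison_table, read_pair_table, residualize, univariate_ladder
from twinprs.pair_data import default_schema
from twinprs.synthetic import PRESETS

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    out = ROOT / "univariate"
    out.mkdir(parents=True, exist_ok=True)
    for name in PRESETS:
        data = read_pair_table(ROOT / "data" / f"{name}.csv", default_schema())
        data = residualize(data, "roi", list(data.schema.covariate_names))
        rows, preferred, _ = univariate_ladder(data, "roi")
        comparison_table(rows).to_csv(out / f"{name}.csv", index=False)
        print(f"{name}: preferred {preferred}")


if __name__ == "__main__":
    main()
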