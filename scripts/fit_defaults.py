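"""Fit the default trafficking rate constants and freeze them into the
packaged config (src/prpflux/data/default_params.yaml).

Run from the repository root:

    python scripts/fit_defaults.py
"""

from pathlib import Path

import yaml

from prpflux.calibrate import evaluate_params, fit_default_params

OUT = Path(__file__).resolve().parents[1] / "src" / "prpflux" / "data" / "default_params.yaml"


def main() -> None:
    config = fit_default_params()
    OUT.write_text(
        "# Calibrated default rate constants (1/min).\n"
        "# Generated by scripts/fit_defaults.py -- do not edit by hand.\n"
        + yaml.safe_dump(config, sort_keys=False)
    )
    print(f"wrote {OUT}")
    for key, value in evaluate_params(config).items():
        print(f"  {key}: {value:.6g}")


if __name__ == "__main__":
    main()
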