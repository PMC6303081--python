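"""Train and persist the shipped default model (data/default_model.json).

The original method's regression weights are not published, so the packaged
default is fit on the package's synthetic reference dataset (219 mutations,
49 complexes, noise SD 0.86 kcal/mol, seed 2018).  Rerunning this script
reproduces the file byte-identically.

Run from the repository root:  python scripts/make_default_model.py
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dnabind.model import curate_dataset, fit_mlr          # noqa: E402
from dnabind.synthetic import generate_feature_dataset     # noqa: E402


def main() -> None:
    df = curate_dataset(generate_feature_dataset(
        n=219, noise_sd=0.86, n_complexes=49, seed=2018))
    model = fit_mlr(df)
    out = (Path(__file__).resolve().parents[1]
           / "src" / "dnabind" / "data" / "default_model.json")
    model.to_json(out)
    print(f"wrote {out}")
    print(f"training R = {model.training_r:.3f}, "
          f"RMSE = {model.training_rmse:.3f} kcal/mol")


if __name__ == "__main__":
    main()
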