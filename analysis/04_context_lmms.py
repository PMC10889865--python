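"""Per-parameter linear mixed models for the direction of the context
effect: response = parameter, context fixed (handling = reference), chick
identity random, parametric-bootstrap p-values; mean entropy modelled on the
log(x + 1 - min(x)) scale.

Reads results/dataset/features.csv, writes results/lmm.json and the fixed-
effect table, and prints which parameters shift during handling.
"""
import json
from pathlib import Path

from aukcalls.io import read_feature_csv
from aukcalls.mixedmodels import format_lmm_table, run_context_models

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    features = read_feature_csv(ROOT / "results" / "dataset" / "features.csv")
    features = features.dropna(subset=["mean_f0_hz"])
    reports = run_context_models(features, n_boot=1000, seed=SEED)
    table = format_lmm_table(reports)
    print(table)
    out = ROOT / "results"
    (out / "lmm.json").write_text(json.dumps(
        {k: v.as_dict() for k, v in reports.items()}, indent=2))
    (out / "table_lmm.txt").write_text(table + "\n")
    sig = [k for k, v in reports.items() if v.p_bootstrap < 0.05]
    print(f"\n-> {len(sig)}/7 parameters shift with context: {', '.join(sig)}")


if __name__ == "__main__":
    main()
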