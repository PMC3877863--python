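#!/usr/bin/env python
"""Generate the preset synthetic datasets with their ground-truth manifests.

Writes one directory per scenario under results/simulated/: the expression
TSV the downstream stages consume, true component labels for mixture
scenarios, and a JSON manifest of the generating spec and expected verdict.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

import fungiflow as ff
from fungiflow.quantify import write_expression_vector

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "simulated"
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, scenario in sorted(ff.preset_scenarios().items()):
        out_dir = OUT / name
        out_dir.mkdir(exist_ok=True)
        spec = scenario.spec.with_seed(SEED)
        if isinstance(spec, ff.MixtureSpec):
            vector, labels = ff.simulate_mixture(spec)
            pd.Series(labels, index=vector.values.index, name="component").to_frame().to_csv(
                out_dir / "true_labels.tsv", sep="\t", index_label="locus_tag"
            )
        else:
            vector = ff.simulate_zipf(spec)
        write_expression_vector(out_dir / "expression.tsv", vector)
        manifest = {
            "scenario": name,
            "spec_kind": type(spec).__name__,
            "spec": dataclasses.asdict(spec),
            "expected": scenario.expected,
        }
        (out_dir / "ground_truth.json").write_text(json.dumps(manifest, indent=2) + "\n")
        print(f"{name}: {vector.n_genes} genes -> {out_dir.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
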