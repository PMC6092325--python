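"""The whole analysis chain on a synthetic study-shaped dataset.

Writes a paper-like bundle (environment, stomachs, isotopes, sources, fatty
acids + ground truth), then runs every stage from one YAML config and prints
the manifest's per-stage status. Equivalent shell commands:

    jellytroph synth --preset paper-like --seed 42 --out data/
    jellytroph run config.yml
"""

import json
import tempfile
from pathlib import Path

import yaml

from jellytroph.pipeline import run_pipeline
from jellytroph.synth import gen_paper_like

with tempfile.TemporaryDirectory() as tmp:
    base = Path(tmp)
    tables, truth = gen_paper_like(seed=42, out_dir=base)
    print("injected truth: weights", truth.weights)

    cfg = {
        "seed": 7,
        "out_dir": "out",
        "inputs": {"diet": "diet.csv", "env": "env.csv", "isotopes": "iso.csv",
                   "sources": "sources.csv", "fa": "fa.csv"},
        "selectivity": {"env_pseudo_n": "match"},
        "trophic": {"baseline": 1.6},
        "mixing": {"chains": 4, "iterations": 8000, "burnin": 4000, "thin": 4},
        "permanova": {"n_perm": 999},
    }
    (base / "config.yml").write_text(yaml.safe_dump(cfg))
    manifest = run_pipeline(base / "config.yml")
    print(json.dumps({k: v["status"] for k, v in manifest.stages.items()},
                     indent=2))
    print("outputs:", ", ".join(manifest.outputs))
# Every stage should report "ok" (mixing may report "ok-not-converged" when
# the realistic, closely spaced sources leave the posterior weakly identified
# — the result is flagged rather than discarded). All outputs are CSV/JSON in
# the out/ directory; rerunning with the same seeds reproduces them exactly.
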