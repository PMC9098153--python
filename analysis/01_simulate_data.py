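#!/usr/bin/env python
"""Generate every synthetic input of the study and write it under results/data.

Produces the questionnaire matrix (283 respondents, 18 items, planted 3-factor
structure, 5% outlier contamination), a retest administration targeting
R = 0.87, a criterion scale targeting r = 0.65, a balanced three-class text
corpus, and a 300-subject multi-channel cohort manifest.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import smht
from smht.experiments import planted_config
from smht.io import write_corpus, write_response_csv

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

cfg = planted_config(n=283, outlier_fraction=0.05, seed=args.seed)
sim = smht.simulate_responses(cfg)
retest = smht.simulate_retest(sim.responses, 0.87, args.seed + 1)
criterion = smht.simulate_criterion(sim.responses, 0.65, args.seed + 2)
corpus = smht.simulate_corpus(smht.default_class_unigrams(), 200, 40, args.seed + 3)
cohort = smht.simulate_cohort(smht.CohortConfig(n_subjects=300), args.seed + 4)

args.out.mkdir(parents=True, exist_ok=True)
write_response_csv(sim.responses, args.out / "responses.csv")
write_response_csv(retest, args.out / "retest.csv")
np.savetxt(args.out / "criterion.csv", criterion, header="criterion", comments="", fmt="%.6f")
write_corpus(corpus, args.out / "corpus.txt", args.out / "labels.txt")
np.savetxt(args.out / "prosody.csv", cohort.prosody, delimiter=",",
           header=",".join(f"f{i+1}" for i in range(cohort.prosody.shape[1])),
           comments="", fmt="%.6f")
manifest = {
    "seed": args.seed,
    "channels": {p.name: str(p) for p in sorted(args.out.iterdir())},
    "planted": {"factors": 3, "loading": 0.7, "outliers": int(len(sim.outlier_indices)),
                "retest_target": 0.87, "validity_target": 0.65},
}
(args.out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

print(f"questionnaire: {sim.responses.n_respondents} x {sim.responses.n_items} "
      f"({len(sim.outlier_indices)} contaminated respondents)")
print(f"corpus: {len(corpus)} documents, vocabulary {len(corpus.vocabulary)}")
print(f"cohort: {cohort.n_subjects} subjects, "
      f"{int(cohort.true_state.sum())} at-risk; wrote {args.out}/manifest.json")
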