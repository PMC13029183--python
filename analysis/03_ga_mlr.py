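#!/usr/bin/env python
"""GA-MLR descriptor selection on a planted-signal descriptor matrix.

Preprocesses a 60 x 50 synthetic descriptor table (variance filter,
|r| > 0.90 collinearity filter, autoscaling), then evolves 4-descriptor
subsets (500 generations, population 10, 20% mutation) scored by LOO Q2.
Finding: the four planted signal columns are recovered and the fitted
model's LOO Q2 is ~1 at the sigma = 0.1 noise level.
"""

import json
from pathlib import Path

from sertqsar.gamlr import GAConfig, ga_select, preprocess
from sertqsar.metrics import basic_stats, leverage_ad
from sertqsar.simulate import gen_descriptor_matrix

OUT = Path("results")
SEED = 1


def main():
    OUT.mkdir(exist_ok=True)
    matrix, y, truth = gen_descriptor_matrix(
        n=60, p=50, k_signal=4, noise_sd=0.1, seed=SEED,
        n_collinear=3, n_constant=2,
    )
    pre = preprocess(matrix, activities=y)
    print(f"preprocess: {matrix.X.shape[1]} -> {len(pre.names)} descriptors")
    model = ga_select(pre, y, GAConfig(k=4, generations=500, seed=SEED))
    pred = model.predict(pre.X[:, [pre.names.index(n) for n in model.names]])
    lev = leverage_ad(pre.X[:, [pre.names.index(n) for n in model.names]], y - pred)
    summary = {
        "selected": model.names,
        "planted": list(truth["signal"]),
        "recovered": set(model.names) == set(truth["signal"]),
        "loo_q2": model.fitness,
        "train": basic_stats(y, pred),
        "h_star": lev.h_star,
        "n_leverage_out": int(lev.leverage_out.sum()),
        "n_response_out": int(lev.response_out.sum()),
    }
    with open(OUT / "ga_mlr.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"selected {model.names} (planted {truth['signal']})")
    print(f"LOO Q2 = {model.fitness:.4f}, train r2 = {summary['train']['r2']:.4f}")
    print(f"Williams AD: h* = {lev.h_star:.3f}, "
          f"{summary['n_leverage_out']} leverage / {summary['n_response_out']} response outliers")


if __name__ == "__main__":
    main()
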