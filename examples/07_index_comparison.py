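"""Compare diet indices against known true diets by simulation.

Simulates diet datasets at several sample sizes and amplification-bias
magnitudes (up to an extreme 20-fold), computes RRA, POO and wPOO, and
scores each against the true population diet with Bray-Curtis
dissimilarity (0 = perfect recovery).
"""

from sealdiet.evaluation import EvaluationConfig, run_evaluation

cfg = EvaluationConfig(
    n_samples_grid=(25, 100), bias_grid=(1.0, 20.0), replicates=20, seed=0
)
res = run_evaluation(cfg)
print(res.pivot(index=["n_samples", "bias"], columns="index",
                values="mean_bc").round(3))
# RRA is near-perfect without bias and stays more accurate than POO even
# at 20x bias; occurrence indices carry a floor of error from flattening
# the diet regardless of sample size.
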