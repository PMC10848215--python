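"""Calibration of three degree-based predictors.

Reconstructs a power-law network from its own degree information using the
permutation edge prior, the closed-form approximation, and the scaled
degree product. All three rank pairs almost identically (similar AUROC),
but only the edge prior is a well-calibrated probability, which shows up
as a much smaller Brier calibration component.
"""

from edgeprior import GeneratorSpec, generate_network, run_task

net = generate_network(
    GeneratorSpec(kind="configuration_model", n_nodes=300, exponent=2.2, min_degree=2, seed=0)
)
res = run_task(
    1, net,
    predictors=["prior", "approximation", "degree_product"],
    n_permutations=100, seed=1,
)
print(res[["predictor", "auroc", "brier", "calibration", "refinement"]].to_string(index=False))
print("\nAUROC is rank-based, so the three columns agree to ~3 decimals;")
print("the calibration column separates them: the edge prior's component is smallest.")
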