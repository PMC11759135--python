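"""Benchmark GBLUP, kernel ridge regression and Adaboost.RT by 10-fold CV.

All three predictors see the same blended relationship matrix: GBLUP uses
it as the covariance of the random animal effect; KRR and Adaboost.RT use
its rows (relationships to the training animals) as features. Accuracy is
the Pearson correlation between predictions and phenotypes adjusted for
fixed effects estimated on the training folds only. A small, dense marker
panel (400 SNPs, 100 causal) is used so the baseline accuracy is well
above its noise floor at this population size.
"""

from caprigen import (SimConfig, blend, cross_validate, make_folds,
                      simulate_genotypes, simulate_phenotypes, vanraden_g)

cfg = SimConfig(n_individuals=300, n_markers=400, n_causal=100, seed=3,
                genetic_cov=[[35.07]], residual_cov=[[74.52]],
                trait_names=["udder_depth"], trait_means=[29.65])
genos = simulate_genotypes(cfg)
phenos = simulate_phenotypes(genos, cfg)
G = blend(vanraden_g(genos), 0.95)
folds = make_folds(phenos.sample_ids, k=10, seed=3)

report = cross_validate(["gblup", "krr", "adaboost_rt"], phenos, G, folds)
print(report.summary().to_string(index=False))
print()
print(report.improvements("gblup").to_string(index=False))
print("\nmean_accuracy: average held-out correlation over the 10 folds;")
print("improvement_pct: integer percent change versus the GBLUP baseline.")
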