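"""Bayesian diet-source mixing from stable isotopes.

Simulates 50 consumers eating a 45/40/15 mix of three plankton size classes
(with the standard trophic enrichment of 2 +/- 0.3 per mil d13C and
3.2 +/- 0.1 per mil d15N), then recovers the diet proportions by MCMC.
"""

from jellytroph.datamodel import MCMCConfig
from jellytroph.mixing import DEFAULT_TEF, sample_posterior, summarize_posterior
from jellytroph.synth import WELL_SEPARATED_SOURCES, gen_isotopes

TRUE_P = (0.45, 0.40, 0.15)
iso = gen_isotopes(TRUE_P, WELL_SEPARATED_SOURCES, DEFAULT_TEF,
                   n_consumers=50, resid_sd=0.3, seed=11)

draws = sample_posterior(iso, WELL_SEPARATED_SOURCES, DEFAULT_TEF,
                         config=MCMCConfig(chains=4, iterations=20_000,
                                           burnin=10_000, thin=5),
                         seed=3)
summary = summarize_posterior(draws, level=0.95)
print(summary.table.round(3).to_string(index=False))
print(f"acceptance rate {draws.acceptance_rate:.2f}, "
      f"converged: {summary.converged}")
# Each p_<source> row is that size class's estimated share of the diet with a
# 95% equal-tailed credibility interval; the means sum to 1. Compare against
# the simulated truth (0.45, 0.40, 0.15): each mean should land within a few
# hundredths. R-hat near 1 means the four chains agree.
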