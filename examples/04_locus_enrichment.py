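"""Test GWAS loci for enrichment in annotation intervals.

Simulates a locus catalog in which 40% of target loci but only 10% of
background loci have a SNP inside an annotation feature (a planted 4-fold
enrichment), then runs the size-bin-matched permutation test and the
peak-shift null.
"""

import numpy as np

from chromadelta import SimulationConfig, permute_enrichment, shift_enrichment
from chromadelta.synthetic import simulate_annotation, simulate_locus_catalog

cfg = SimulationConfig(seed=4)
rng = np.random.default_rng(4)
annotation = simulate_annotation(cfg, rng)
targets, background, truth = simulate_locus_catalog(cfg, annotation, rng)

res = permute_enrichment(targets, background, annotation,
                         n_permutations=10_000, seed=4)
print(f"target loci: {res.n_target_loci}, overlapping: {res.observed}")
print(f"permutation expected: {res.expected:.2f}")
print(f"fold = {res.fold:.2f}  binomial p = {res.binomial_p:.2g}  "
      f"empirical p = {res.empirical_p:.2g}")
# fold ~ 4 recovers the planted pi_target/pi_background ratio; both p-values
# reject the matched-background null.

sites = [iv for iv in annotation[:60]]
shift = shift_enrichment(sites, annotation, cfg.genome,
                         max_shift=10_000, n_permutations=100, seed=4)
print(f"shift null (self-overlap demo): observed {shift.observed}, "
      f"background {shift.background_mean:.1f} +- {shift.background_sd:.1f}, "
      f"fold {shift.fold:.2f}, p = {shift.empirical_p:.2g}")
# Shifting sites by up to +-10 kb destroys their exact coincidence with the
# annotation, so self-overlap shows up as a strong fold over the shifted null.
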