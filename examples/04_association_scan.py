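"""Genotype-environment association with linear and categorical encodings.

Plants one linear tract-length effect, scans every (locus, axis) pair with
both encodings, compares them by a nested F-test, and contrasts the result
with the mock-genotype negative control (per-locus shuffling).
"""

from strhab.assoc import best_per_locus, mock_scan, ols_scan
from strhab.envspace import decompose
from strhab.synth import CohortSpec, PlantedEffect, generate_cohort

spec = CohortSpec(
    n_accessions=150, n_subpops=6, n_str_loci=30, n_snps=50, n_env_vars=24,
    n_env_factors=4, drift_scale=0.5, confound_strength=0.3, seed=21,
    planted_effects=(PlantedEffect("L0010", env_axis=1, beta=2.0, shape="linear"),),
)
geno, _, env, _, truth = generate_cohort(spec)
pca = decompose(env, rule="cumulative:0.8")

records = ols_scan(geno, pca)
best = best_per_locus(records)
hit = best[best["locus"] == "L0010"].iloc[0]
n_sig = int(records["bonferroni_significant"].sum())
print(f"{len(records)} tests ({records['locus'].nunique()} loci x {records['axis'].nunique()} axes); "
      f"{n_sig} Bonferroni-significant")
print(f"planted locus L0010: best axis {hit.axis}, model {hit.model}, "
      f"R^2 = {hit.r2:.3f}, p = {hit.p:.2e}, significant = {bool(hit.bonferroni_significant)}")

mock = mock_scan(geno, pca, seed=22)
print(f"mock control (shuffled genotypes): {100 * mock.fraction_significant:.2f}% significant")
print(f"-> the planted effect is recovered (as {hit.model}: the nested F-test picks the "
      "encoding the data favor) while the shuffled control stays at the noise floor.")
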