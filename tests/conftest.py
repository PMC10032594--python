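import pytest

from strhab.envspace import decompose
from strhab.synth import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 100-accession, 5-subpop cohort shared by read-only tests."""
    spec = CohortSpec(
        n_accessions=100,
        n_subpops=5,
        n_str_loci=30,
        n_snps=200,
        n_env_vars=20,
        seed=17,
    )
    geno, snps, env, subpops, truth = generate_cohort(spec)
    return {
        "spec": spec,
        "geno": geno,
        "snps": snps,
        "env": env,
        "subpops": subpops,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_pca(small_cohort):
    return decompose(small_cohort["env"], rule="cumulative:0.8", max_axes=5)
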