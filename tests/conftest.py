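import numpy as np
import pandas as pd
import pytest

from nimrescue import synthetic_data as sd


@pytest.fixture(scope="session")
def spec():
    return sd.canonical_allele_spec()


@pytest.fixture(scope="session")
def field_dataset(spec):
    """A study-sized noninvasive dataset: 36 individuals over four regions,
    ~3 scat samples each, realistic allelic dropout."""
    return sd.gen_genotype_dataset(
        spec,
        n_individuals={"Jabal Samhan": 17, "Jabal Qara": 5, "Jabal Qamar": 11, "Nejd": 3},
        replicates=3.0,
        dropout_rate=0.048,
        seed=5,
    )


def make_long_rows(genotypes, locus="L1", region="X", sex="M"):
    """Rows for a single-locus dataset from a list of (a1, a2) genotypes."""
    rows = []
    for i, (a1, a2) in enumerate(genotypes):
        rows.append(dict(sample_id=f"s{i}", individual_id=f"s{i}", region=region,
                         period="", x_km=0.0, y_km=0.0, locus=locus,
                         allele1=a1, allele2=a2, sex_call=sex))
    return rows


@pytest.fixture
def single_locus_dataset_factory():
    def factory(genotypes, **kw):
        return sd.GenotypeDataset(long=pd.DataFrame(make_long_rows(genotypes, **kw)),
                                  loci=(kw.get("locus", "L1"),))
    return factory


def two_deme_freqs(fst_param, seed, n_loci=8, k=4):
    """Balding–Nichols-style deme frequencies around random ancestral freqs."""
    rng = np.random.default_rng(seed)
    c = (1 - fst_param) / fst_param
    out = []
    for _ in range(n_loci):
        anc = rng.dirichlet(np.full(k, 2.0))
        out.append([rng.dirichlet(anc * c) for _ in range(2)])
    return out


def two_deme_dataset(freqs, n_per_deme, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for l, (p_a, p_b) in enumerate(freqs):
        for dx, (deme, p) in enumerate((("demeA", p_a), ("demeB", p_b))):
            for i in range(n_per_deme):
                g = rng.choice(len(p), size=2, p=p)
                rows.append(dict(sample_id=f"{deme}_{i}", individual_id=f"{deme}_{i}",
                                 region=deme, period="", x_km=100.0 * dx, y_km=0.0,
                                 locus=f"L{l}", allele1=str(g[0] + 1),
                                 allele2=str(g[1] + 1), sex_call="M"))
    return sd.GenotypeDataset(long=pd.DataFrame(rows),
                              loci=tuple(f"L{l}" for l in range(len(freqs))))
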