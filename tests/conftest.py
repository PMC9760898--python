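import numpy as np
import pandas as pd
import pytest

import isodimorph as iso


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scale synthetic dataset: records, tree, N15 MD table, corr."""
    truth = iso.SimTruth(seed=11)
    records, tree = iso.simulate_dataset(truth)
    df = iso.effect_table(records, "MD", "N15")
    corr = iso.correlation_from_tree(tree, sorted(df["species"].unique()))
    return {"truth": truth, "records": records, "tree": tree,
            "effects": df, "corr": corr}


@pytest.fixture()
def twelve_effects():
    """Small single-level meta-regression dataset for oracle comparisons."""
    rng = np.random.default_rng(3)
    n = 12
    x = rng.normal(size=n)
    v = rng.uniform(0.05, 0.2, size=n)
    y = 0.5 + 0.3 * x + rng.normal(0, 0.8, size=n) + rng.normal(0, np.sqrt(v))
    return pd.DataFrame({
        "study_id": [f"s{i}" for i in range(n)],
        "species": "sp",
        "value": y,
        "sampling_variance": v,
        "x": x,
    })


def make_record(**kw):
    base = dict(
        study_id="s1", species="Genus species", tissue="muscle", isotope="N15",
        male_mean=12.0, male_sd=1.0, male_n=10,
        female_mean=10.5, female_sd=1.2, female_n=12,
        male_mass=2.0, female_mass=1.0, diet_class="carnivore",
        gape_limited=False, pub_year=2010, taxon_class="mammal",
    )
    base.update(kw)
    return iso.StudyRecord(**base)


@pytest.fixture()
def record_factory():
    return make_record
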