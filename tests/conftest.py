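import numpy as np
import pytest

from dilinet.data_model import EndpointDataset
from dilinet.endpoint_models import train_panel_models
from dilinet.featurenet import StackedBuilder
from dilinet.featurization import ChemFeaturizer, FeatureBlock
from dilinet.simulation import fast_space, recovery_spec
from dilinet.splitting import butina_split
from dilinet.synthetic_fixtures import GenerativeSpec, make_panel


@pytest.fixture(scope="session")
def small_spec():
    return GenerativeSpec(
        n_compounds=120,
        seed=7,
        toxicophore_rate=0.5,
        gold_fraction=0.5,
        conflict_rate=0.1,
        salt_rate=0.15,
        stereo_rate=0.15,
    )


@pytest.fixture(scope="session")
def synthetic(small_spec):
    """Small panel with planted conflicts, salts and stereocenters."""
    from dilinet.synthetic_fixtures import make_panel

    return make_panel(small_spec)


@pytest.fixture(scope="session")
def pipeline():
    """One trained mini pipeline shared across model-level tests."""
    spec = recovery_spec(seed=11, n_compounds=180)
    sp = make_panel(spec)
    panel = sp.panel
    featurizer = ChemFeaturizer.fit([c for p in panel.proxies for c in p.compounds])

    def featurize(ds):
        st = featurizer.structural(ds.compounds)
        de = featurizer.descriptors(ds.compounds)
        return FeatureBlock(
            name="chem-all",
            matrix=np.hstack([st.matrix, de.matrix]),
            feature_names=st.feature_names + de.feature_names,
        )

    space = fast_space(n_estimators=60)
    models = train_panel_models(panel, featurize, space=space, seed=3)
    builder = StackedBuilder(featurizer, models)
    split = butina_split(panel.gold.compounds, cutoff=0.70, test_fraction=0.2)
    train_keys = set(split.train_keys)
    gold_train = EndpointDataset(
        name="DILI",
        compounds=[c for c in panel.gold.compounds if c.key14 in train_keys],
        kind="binary",
    )
    gold_test = EndpointDataset(
        name="DILI",
        compounds=[c for c in panel.gold.compounds if c.key14 not in train_keys],
        kind="binary",
    )
    return {
        "sp": sp,
        "panel": panel,
        "featurizer": featurizer,
        "featurize": featurize,
        "space": space,
        "models": models,
        "builder": builder,
        "split": split,
        "gold_train": gold_train,
        "gold_test": gold_test,
    }
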