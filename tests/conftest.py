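import numpy as np
import pytest

import mpcstanet as m


@pytest.fixture(scope="session")
def small_spec():
    """32-px phantom spec shared by dataset-level tests."""
    return m.PhantomSpec(image_size=32, seed=7)


@pytest.fixture(scope="session")
def desk_dataset(small_spec):
    """1/16-scale skewed phantom dataset (200/140/56/4) at 32 px."""
    return m.generate_dataset(
        m.ClassDistribution(dict(m.DESK_SCALE_COUNTS)), small_spec
    )


@pytest.fixture(scope="session")
def balanced_desk_dataset(desk_dataset):
    plan = m.plan_balance(desk_dataset.distribution())
    return m.balance_dataset(
        desk_dataset, plan, m.SmoteParams(seed=7), m.AugmentationConfig(seed=7)
    )


def mini_variant(use_dc=True, use_mprb=True, use_scam=True, seed=0):
    """Depth-reduced model for fast training tests."""
    return m.assemble_variant(
        m.VariantSpec(use_dc, use_mprb, use_scam, head_classes=4),
        seed=seed, stage_blocks=(1, 1, 1, 1), width=8,
    )
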