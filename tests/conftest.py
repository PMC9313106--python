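import numpy as np
import pytest

from dtiradiomics import CohortSpec, EffectSpec, generate_subject


def small_spec(**kw) -> CohortSpec:
    """Down-scaled phantom spec for fast unit tests."""
    base = dict(shape=(24, 24, 16), spacing=(2.0, 2.0, 2.0),
                brain_semi_axes_mm=(20.0, 18.0, 13.0), seed=0)
    base.update(kw)
    effect = base.pop("effect", EffectSpec())
    return CohortSpec(effect=effect, **base)


@pytest.fixture(scope="session")
def small_subject():
    return generate_subject(small_spec(), group=0, subject_seed=7)


@pytest.fixture(scope="session")
def small_fa(small_subject):
    return small_subject.fa_map()


@pytest.fixture(scope="session")
def small_md(small_subject):
    return small_subject.md_map()


@pytest.fixture(scope="session")
def small_mask(small_fa):
    from dtiradiomics import make_brain_mask

    return make_brain_mask(small_fa)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
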