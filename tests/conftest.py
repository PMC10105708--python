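import numpy as np
import pytest

from absp.phantom import (
    PhantomSpec,
    build_template_geometry,
    default_signatures,
    synthesize_subject,
)


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(noise_sd=0.0, deform_amplitude=0.5, rng_seed=0)


@pytest.fixture(scope="session")
def template(noiseless_spec):
    return build_template_geometry(noiseless_spec)


@pytest.fixture(scope="session")
def signatures():
    return default_signatures()


@pytest.fixture(scope="session")
def hc_subject(template, signatures, noiseless_spec):
    """One noiseless healthy-control phantom."""
    return synthesize_subject(template, signatures["HC"], noiseless_spec, 7)


@pytest.fixture(scope="session")
def ipd_subject(template, signatures, noiseless_spec):
    return synthesize_subject(template, signatures["iPD"], noiseless_spec, 8)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def truth_mask_dict(subject):
    """Non-brainstem truth masks keyed for quantify.measure_subject."""
    return {k: v for k, v in subject.truth_masks.items() if k[1] != "brainstem"}


def measure_truth_subject(subject, k=2.0):
    """Measure a phantom against its own truth masks (no registration)."""
    from absp import quantify

    volumes = {"NM": subject.nm_volume, "iron": subject.iron_volume}
    brainstems = {
        "NM": subject.truth_masks[("NM", "brainstem", "both")],
        "iron": subject.truth_masks[("iron", "brainstem", "both")],
    }
    return quantify.measure_subject(
        volumes,
        truth_mask_dict(subject),
        brainstems,
        subject.gm_volume,
        subject_id=subject.subject_id,
        group=subject.group,
        k=k,
    )
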