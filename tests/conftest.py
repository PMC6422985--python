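import numpy as np
import pytest

from ctgrp.records import FHRRecord
from ctgrp.synthetic import SynthConfig, generate_fhr, normal_preset


@pytest.fixture
def clean_record():
    """Artifact-free normal record (no dropouts/spikes), fixed seed."""
    cfg = normal_preset(duration_s=300.0, dropout_rate=0.0, spike_rate=0.0, seed=11)
    return generate_fhr(cfg)


@pytest.fixture
def noisy_record():
    """Record with dropouts and spikes present, fixed seed."""
    cfg = normal_preset(duration_s=600.0, dropout_rate=30.0, spike_rate=60.0, seed=23)
    rec = generate_fhr(cfg)
    assert (rec.samples == 0).any(), "fixture must contain dropouts"
    return rec


@pytest.fixture
def flat_record():
    return FHRRecord(record_id="flat", samples=np.full(200, 130.0), fs=4.0)
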