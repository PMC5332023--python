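import numpy as np
import pytest

from hyladelim.synthetic_data import CallSpec, NoteSpec, synthesize_call


@pytest.fixture(scope="session")
def trill_call():
    """Single-note pulsed trill at the published clade-A scale:
    17 pulses, ~0.19 s, carrier 2655.37 Hz."""
    spec = CallSpec(
        notes=(NoteSpec(n_pulses=17, pulse_period_s=0.01118),),
        carrier_hz=2655.37,
    )
    return spec, synthesize_call(spec)


@pytest.fixture(scope="session")
def two_note_type_call():
    """1 Type I + 2 Type II call at the published clade-B scale:
    Type I 0.10 s / 12 pulses, Type II 0.027 s / 4 pulses, 46 ms gaps,
    carrier 2748.69 Hz."""
    spec = CallSpec(
        notes=(
            NoteSpec(n_pulses=12, pulse_period_s=0.10 / 12),
            NoteSpec(n_pulses=4, pulse_period_s=0.027 / 4),
            NoteSpec(n_pulses=4, pulse_period_s=0.027 / 4),
        ),
        inter_note_gap_s=0.046,
        carrier_hz=2748.69,
    )
    return spec, synthesize_call(spec)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Full synthetic study generated once per session."""
    from hyladelim.pipeline import make_fixtures

    out = tmp_path_factory.mktemp("study")
    return make_fixtures(seed=7, out_dir=out)
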