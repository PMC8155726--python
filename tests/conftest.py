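import numpy as np
import pytest

from pwvest import (ArterialSegment, ArterialTreeModel, CardiacInflow,
                    TerminalWindkessel, generate_cohort)
from pwvest.tree import SITE_NAMES, default_ejection_fraction


def make_tube(length=0.5, area=5e-4, speed=8.0, terminal="matched",
              compliance=0.0):
    """Single uniform segment with sites at both ends.

    terminal='matched' closes the tube with its own characteristic impedance
    (reflectionless); a float closes it with that resistance [Pa s/m^3].
    """
    from pwvest.units import BLOOD_DENSITY
    c_a = area / (BLOOD_DENSITY * speed * speed)
    seg = ArterialSegment("tube", length, area, c_a)
    r = seg.characteristic_impedance if terminal == "matched" else float(terminal)
    sites = {name: ("tube", 0.0) for name in SITE_NAMES}
    sites["carotid_L"] = ("tube", 0.0)   # proximal end
    sites["femoral_L"] = ("tube", 1.0)   # distal end
    return ArterialTreeModel(
        segments={"tube": seg},
        terminals=[TerminalWindkessel("tube", r, compliance)],
        sites=sites,
    )


class OffsetInflow(CardiacInflow):
    """Ejection wave riding on a constant baseline flow [mL/s].

    Keeps tube-fixture pressures positive under a purely resistive matched
    termination (where diastolic pressure would otherwise touch zero)."""

    def __init__(self, *args, offset=0.0, **kwargs):
        super().__init__(*args, **kwargs)
        self.offset = offset

    def sample(self, t):
        return super().sample(t) + self.offset * 1e-6


def make_inflow(hr=72.0, sv=80.0, shape="asymmetric", offset=0.0):
    if offset:
        return OffsetInflow(hr, sv, default_ejection_fraction(hr),
                            waveform_shape=shape, offset=offset)
    return CardiacInflow(hr, sv, default_ejection_fraction(hr),
                         waveform_shape=shape)


@pytest.fixture(scope="session")
def small_cohort():
    """120 accepted subjects, fixed seed; shared across tests."""
    return generate_cohort(120, rng_seed=101)


@pytest.fixture(scope="session")
def small_cohort_records():
    """60 subjects with central waveforms retained."""
    return generate_cohort(
        60, rng_seed=202, return_records=True,
        keep_waveforms=["pressure:aortic_root", "flow:aortic_root"])
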