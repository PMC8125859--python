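"""Shared fixtures: synthetic runs and suspect lists used across modules."""

import pytest

from honeyscreen.screening import SuspectEntry, TargetEntry
from honeyscreen.synthetic import SimCompound, simulate_run

ABSCISIC_FRAGMENTS_TRANS = [219.1396, 204.1159]
ABSCISIC_FRAGMENTS_CIS = [153.0922, 219.1396, 204.1159]


@pytest.fixture(scope="session")
def abscisic_run():
    """Two abscisic-acid isomer peaks (4.02 / 4.45 min) at m/z 263.1289.

    The cis isomer carries the diagnostic fragment 153.0922 that the
    trans isomer lacks.
    """
    compounds = [
        SimCompound(
            "2-trans,4-trans-abscisic acid", "C15H20O4", 4.02, 2.5e4,
            fragments=ABSCISIC_FRAGMENTS_TRANS,
        ),
        SimCompound(
            "2-cis,4-trans-abscisic acid", "C15H20O4", 4.45, 3.5e4,
            fragments=ABSCISIC_FRAGMENTS_CIS,
        ),
    ]
    return simulate_run(compounds, noise=0.0, seed=11, rt_span=(3.0, 5.5))


@pytest.fixture(scope="session")
def abscisic_suspects():
    return [
        SuspectEntry(
            "2-trans,4-trans-abscisic acid", "C15H20O4",
            rt_predicted=4.44, expected_fragments=ABSCISIC_FRAGMENTS_TRANS,
        ),
        SuspectEntry(
            "2-cis,4-trans-abscisic acid", "C15H20O4",
            rt_predicted=4.44, expected_fragments=ABSCISIC_FRAGMENTS_CIS,
        ),
    ]


@pytest.fixture(scope="session")
def apigenin_run():
    """Single spiked flavone peak for target-screening tests."""
    compound = SimCompound(
        "apigenin", "C15H10O5", 4.00, 3.0e4, fragments=[117.0346, 151.0037],
    )
    return simulate_run([compound], noise=0.0, seed=5, rt_span=(3.0, 5.0))


@pytest.fixture(scope="session")
def apigenin_target():
    return TargetEntry(
        "apigenin", "C15H10O5", rt_expected=4.00,
        qualifier_ions=[117.0346, 151.0037],
    )
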