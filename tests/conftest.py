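import pandas as pd
import pytest

from saccs.observer import default_observer
from saccs.scheduler import build_study, run_study


@pytest.fixture(scope="session")
def small_study_log() -> pd.DataFrame:
    """A 2-participant simulated study at one eccentricity (shared across tests).

    Both modes, the four spatial frequencies common to every eccentricity,
    default observer — enough cells for triplet pairing and report assembly
    while staying cheap.
    """
    manifest = build_study(n_participants=2, seed=1234)
    manifest = manifest[
        (manifest["eccentricity_deg"] == 11.0)
    ].reset_index(drop=True)
    return run_study(manifest, default_observer())


@pytest.fixture(scope="session")
def small_study_bundle(small_study_log):
    """Agreement report for the shared small study (fits are the slow part)."""
    from saccs.report import build_report

    return build_report(small_study_log)
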