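import pandas as pd
import pytest

from lnconcord import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def hand_cohort():
    """Two-patient fixture with hand-computable concordance.

    P1 (sigmoid): stations 241 (2 CT susp / 4 harvested, 2 met),
    242 (1 susp / 1 clean), 253 (1 non-susp / 1 clean).
    P2 (superior rectum): 251 (1 non-susp / 1 met), 252 (1 susp / 2 clean),
    253 (0 CT / 1 clean).
    """
    patients = pd.DataFrame({
        "patient_id": ["P1", "P2"],
        "sex": ["M", "F"],
        "age": [64.0, 71.0],
        "tumor_site": ["sigmoid", "superior_rectum"],
    })
    ct = pd.DataFrame(
        [
            ("n1", "P1", "241", 12.0, 0, 0, 0, "dotted"),
            ("n2", "P1", "241", 6.0, 1, 1, 0, "homogenous"),
            ("n3", "P1", "242", 4.0, 1, 1, 1, "linear"),
            ("n4", "P1", "253", 6.0, 1, 0, 0, "homogenous"),
            ("n5", "P2", "251", 4.0, 1, 1, 0, "central"),
            ("n6", "P2", "252", 11.0, 0, 0, 0, "peripheral"),
        ],
        columns=["node_id", "patient_id", "station_code", "short_axis_mm",
                 "roundness", "heterogeneous_density", "irregular_border",
                 "pattern"],
    )
    ct["roundness"] = ct["roundness"].astype(bool)
    ct["heterogeneous_density"] = ct["heterogeneous_density"].astype(bool)
    ct["irregular_border"] = ct["irregular_border"].astype(bool)
    # suspicion by the rule: large always; mid needs >=2; small needs 3
    ct["suspicious"] = [True, True, True, False, False, True]
    histo = pd.DataFrame(
        [
            ("h1", "P1", "241", 1), ("h2", "P1", "241", 1),
            ("h3", "P1", "241", 0), ("h4", "P1", "241", 0),
            ("h5", "P1", "242", 0), ("h6", "P1", "253", 0),
            ("h7", "P2", "251", 1), ("h8", "P2", "252", 0),
            ("h9", "P2", "252", 0), ("h10", "P2", "253", 0),
        ],
        columns=["node_id", "patient_id", "station_code", "metastatic"],
    )
    histo["metastatic"] = histo["metastatic"].astype(bool)
    return patients, ct, histo
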